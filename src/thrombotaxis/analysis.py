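"""Trajectory statistics: flow-relative angles, thrombus proximity with a
matched random null, velocity summaries, model-cell selection and
model-vs-reference scoring.

The proximity analysis compares, for every tracked cell, the distance from
its centre to the nearest thrombus edge against the same quantity for a
random trajectory with identical step lengths (hence identical speeds)
started at a uniformly random point.  Significance is assessed with a
two-sided Mann-Whitney U test.  By default the test operates on per-cell
mean distances rather than pooled per-point distances: successive points of
one track are strongly autocorrelated, and pooling them would overstate the
sample size; the pooled distances are still returned for inspection.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import DataError, ParameterError
from .io import FieldGrid, ThrombusMask, Trajectory
from .walker import SimTrajectory, wrap_angle

__all__ = [
    "AngleDistribution", "ProximityResult", "EnsembleResult",
    "step_angles", "angle_distribution", "resample_min_duration",
    "distance_to_thrombus", "random_trajectory", "proximity_test",
    "mean_speed", "select_model_cells", "score_run", "classify_success",
    "thrombus_area_fraction",
]


@dataclass
class AngleDistribution:
    """Histogram of flow-relative step angles over (-pi, pi]."""

    edges: np.ndarray
    counts: np.ndarray
    resultant_length: float
    resultant_direction: float
    n: int


@dataclass
class ProximityResult:
    """Experimental vs random-null distances to the nearest thrombus edge."""

    r_exp: np.ndarray            # pooled per-point distances, um
    r_rand: np.ndarray           # pooled matched-null distances, um
    cell_mean_exp: np.ndarray    # per-cell mean distances, um
    cell_mean_rand: np.ndarray
    statistic: float             # Mann-Whitney U
    pvalue: float
    reduction: str               # "cells" or "points"


@dataclass
class EnsembleResult:
    """A bundle of model runs scored against one reference cell."""

    cell_id: str
    runs: list
    scores: np.ndarray           # mean point-wise distance per run, um
    successes: np.ndarray        # score <= one cell length

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.successes = np.asarray(self.successes, dtype=bool)
        if np.any(self.scores < 0):
            raise DataError("run scores must be >= 0")

    @property
    def n_runs(self) -> int:
        return len(self.scores)

    @property
    def success_fraction(self) -> float:
        return float(self.successes.mean()) if self.n_runs else 0.0


# ---------------------------------------------------------------------------
# angles


def step_angles(traj: Trajectory, flow_direction: float = 0.0) -> np.ndarray:
    """Signed angle between each displacement and the flow axis, (-pi, pi].

    Zero-length steps carry no direction and are skipped; if every step is
    zero-length an empty array is returned with a warning.
    """
    if len(traj) < 2:
        raise DataError(f"trajectory '{traj.cell_id}' needs >= 2 points for angles")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    moving = np.hypot(dx, dy) > 0
    if not moving.any():
        warnings.warn(f"trajectory '{traj.cell_id}': all steps are zero-length")
        return np.empty(0)
    theta = np.arctan2(dy[moving], dx[moving]) - flow_direction
    return wrap_angle(theta)


def angle_distribution(angles: np.ndarray, n_bins: int = 18) -> AngleDistribution:
    """Bin angles over (-pi, pi] and compute the mean resultant vector."""
    angles = np.asarray(angles, dtype=float)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    if angles.size:
        C, S = np.cos(angles).mean(), np.sin(angles).mean()
        R, mu = float(np.hypot(C, S)), float(np.arctan2(S, C))
    else:
        R, mu = 0.0, 0.0
    return AngleDistribution(edges=edges, counts=counts, resultant_length=R,
                             resultant_direction=mu, n=int(angles.size))


# ---------------------------------------------------------------------------
# resampling


def resample_min_duration(trajs: Iterable[Trajectory], min_T: float = 250.0,
                          dt_resample: float = 5.0) -> list[Trajectory]:
    """Drop tracks shorter than ``min_T`` s; resample survivors uniformly.

    Survivors are linearly interpolated onto a grid of spacing
    ``dt_resample`` spanning their full duration.
    """
    if not dt_resample > 0:
        raise ParameterError("dt_resample must be > 0")
    out = []
    for tr in trajs:
        if tr.duration < min_T:
            continue
        grid = tr.t[0] + np.arange(int(np.floor(tr.duration / dt_resample)) + 1) \
            * dt_resample
        x = np.interp(grid, tr.t, tr.x)
        y = np.interp(grid, tr.t, tr.y)
        out.append(Trajectory(tr.cell_id, grid, x, y))
    return out


# ---------------------------------------------------------------------------
# proximity to thrombi


def _distance_map(mask: ThrombusMask) -> FieldGrid:
    """Euclidean distance (um) from each pixel to the nearest thrombus pixel."""
    if not mask.grid.values.any():
        raise DataError("mask contains no thrombus pixels")
    d = ndimage.distance_transform_edt(mask.grid.values == 0) * mask.grid.dx
    return FieldGrid(d, mask.grid.dx, mask.grid.origin, units="um")


def distance_to_thrombus(traj: Trajectory, mask: ThrombusMask,
                         _dmap: FieldGrid | None = None) -> np.ndarray:
    """Distance from each track point to the nearest thrombus edge, um.

    Computed from the Euclidean distance transform of the mask and sampled
    bilinearly at the track points; points inside a thrombus return 0.
    """
    dmap = _dmap if _dmap is not None else _distance_map(mask)
    return np.asarray(dmap.interp(traj.x, traj.y), dtype=float)


def random_trajectory(reference: Trajectory, bounds, rng: np.random.Generator,
                      max_tries: int = 1000) -> Trajectory:
    """A random trajectory with the reference's step lengths and timestamps.

    The start is uniform over ``bounds = (xmin, xmax, ymin, ymax)``; each
    step keeps the reference's step length (preserving its speed profile)
    with an independent uniform direction, re-drawn if it would leave the
    bounds so lengths are conserved exactly.
    """
    if len(reference) < 2:
        raise DataError("reference trajectory needs >= 2 points")
    xmin, xmax, ymin, ymax = map(float, bounds)
    lengths = reference.step_lengths()
    if lengths.max(initial=0.0) > math.hypot(xmax - xmin, ymax - ymin):
        raise ParameterError("bounds cannot contain the reference's largest step")
    x = [rng.uniform(xmin, xmax)]
    y = [rng.uniform(ymin, ymax)]
    for ell in lengths:
        for _ in range(max_tries):
            phi = rng.uniform(-np.pi, np.pi)
            qx, qy = x[-1] + ell * np.cos(phi), y[-1] + ell * np.sin(phi)
            if xmin <= qx <= xmax and ymin <= qy <= ymax:
                x.append(qx)
                y.append(qy)
                break
        else:
            raise DataError("could not place a step inside bounds")
    return Trajectory(f"{reference.cell_id}:null", reference.t.copy(),
                      np.asarray(x), np.asarray(y))


def proximity_test(trajs: Sequence[Trajectory], mask: ThrombusMask,
                   n_null: int = 1, rng: np.random.Generator | None = None,
                   bounds=None, reduction: str = "cells") -> ProximityResult:
    """Are the tracked cells closer to thrombi than matched random tracks?

    For each trajectory, per-point distances to the nearest thrombus edge
    are computed, and ``n_null`` random trajectories with the same step
    lengths provide the null distances.  A two-sided Mann-Whitney U test
    compares experimental and null distances, on per-cell means by default
    (``reduction="cells"``) or on pooled per-point distances
    (``reduction="points"``).
    """
    if not trajs:
        raise DataError("proximity_test needs at least one trajectory")
    if reduction not in ("cells", "points"):
        raise ParameterError(f"unknown reduction '{reduction}'")
    rng = rng if rng is not None else np.random.default_rng()
    dmap = _distance_map(mask)
    if bounds is None:
        bounds = mask.grid.bounds
    r_exp_all, r_rand_all = [], []
    mean_exp, mean_rand = [], []
    for tr in trajs:
        r = distance_to_thrombus(tr, mask, _dmap=dmap)
        r_exp_all.append(r)
        mean_exp.append(r.mean())
        for _ in range(n_null):
            if len(tr) >= 2:
                null = random_trajectory(tr, bounds, rng)
            else:  # single-point track: the null is a single random point
                null = Trajectory(f"{tr.cell_id}:null", tr.t.copy(),
                                  np.array([rng.uniform(bounds[0], bounds[1])]),
                                  np.array([rng.uniform(bounds[2], bounds[3])]))
            rn = distance_to_thrombus(null, mask, _dmap=dmap)
            r_rand_all.append(rn)
            mean_rand.append(rn.mean())
    r_exp = np.concatenate(r_exp_all)
    r_rand = np.concatenate(r_rand_all)
    mean_exp = np.asarray(mean_exp)
    mean_rand = np.asarray(mean_rand)
    if reduction == "cells":
        a, b = mean_exp, mean_rand
    else:
        a, b = r_exp, r_rand
    method = "exact" if (len(a) <= 20 and len(b) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ProximityResult(r_exp=r_exp, r_rand=r_rand,
                           cell_mean_exp=mean_exp, cell_mean_rand=mean_rand,
                           statistic=float(res.statistic),
                           pvalue=float(res.pvalue), reduction=reduction)


# ---------------------------------------------------------------------------
# speeds and selection


def mean_speed(traj: Trajectory) -> float:
    """Total path length over total duration, um/s."""
    if len(traj) < 2:
        raise DataError(f"trajectory '{traj.cell_id}' needs >= 2 points")
    if traj.duration <= 0:
        raise DataError(f"trajectory '{traj.cell_id}' has zero duration")
    return traj.path_length() / traj.duration


def _rolling_fraction(traj: Trajectory, flow_direction: float,
                      speed_thresh: float) -> float:
    """Fraction of steps moving fast and along-flow (|theta| < pi/6)."""
    dt = np.diff(traj.t)
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    speed = np.hypot(dx, dy) / dt
    theta = wrap_angle(np.arctan2(dy, dx) - flow_direction)
    rolling = (speed > speed_thresh) & (np.abs(theta) < np.pi / 6)
    return float(rolling.mean())


def select_model_cells(trajs: Sequence[Trajectory], bounds,
                       flow_direction: float = 0.0,
                       rolling_speed_thresh: float = 1.0,
                       margin: float = 10.0,
                       rolling_max_fraction: float = 0.10,
                       neighbor_radius: float = 10.0) -> list[Trajectory]:
    """Keep cells suitable for model comparison.

    Criteria: (a) fewer than 10% of steps classified as rolling (fast
    along-flow motion above ``rolling_speed_thresh`` um/s within 30 degrees
    of the flow axis); (b) no other tracked cell inside the upstream
    half-disc of radius ``neighbor_radius`` at any co-observed time (active
    neutrophils secrete their own attractant); (c) every point further than
    ``margin`` from the field edges (unseen thrombi may lie beyond them).
    """
    xmin, xmax, ymin, ymax = map(float, bounds)
    cf, sf = math.cos(flow_direction), math.sin(flow_direction)
    kept = []
    for tr in trajs:
        inside = ((tr.x > xmin + margin) & (tr.x < xmax - margin)
                  & (tr.y > ymin + margin) & (tr.y < ymax - margin))
        if not inside.all():
            continue
        if len(tr) >= 2 and _rolling_fraction(
                tr, flow_direction, rolling_speed_thresh) >= rolling_max_fraction:
            continue
        crowded = False
        for other in trajs:
            if other is tr:
                continue
            t0 = max(tr.t[0], other.t[0])
            t1 = min(tr.t[-1], other.t[-1])
            if t1 < t0:
                continue
            tt = tr.t[(tr.t >= t0) & (tr.t <= t1)]
            if tt.size == 0:
                continue
            sx = np.interp(tt, tr.t, tr.x)
            sy = np.interp(tt, tr.t, tr.y)
            ox = np.interp(tt, other.t, other.x)
            oy = np.interp(tt, other.t, other.y)
            rx, ry = ox - sx, oy - sy
            dist = np.hypot(rx, ry)
            upstream = rx * cf + ry * sf < 0
            if np.any((dist <= neighbor_radius) & upstream):
                crowded = True
                break
        if crowded:
            continue
        kept.append(tr)
    return kept


# ---------------------------------------------------------------------------
# model-vs-reference scoring


def _as_traj(obj) -> Trajectory:
    return obj.traj if isinstance(obj, SimTrajectory) else obj


def score_run(model, reference, dt_resample: float = 5.0) -> float:
    """Mean point-wise distance between two trajectories, um.

    Both are linearly resampled onto a common uniform grid over their
    temporal overlap; the score is the mean Euclidean distance between
    positions on that grid.  Symmetric and zero for identical inputs.
    """
    a, b = _as_traj(model), _as_traj(reference)
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 < t0:
        raise DataError("trajectories do not overlap in time")
    n = max(1, int(np.floor((t1 - t0) / dt_resample)) + 1)
    grid = t0 + np.arange(n) * dt_resample
    ax = np.interp(grid, a.t, a.x)
    ay = np.interp(grid, a.t, a.y)
    bx = np.interp(grid, b.t, b.x)
    by = np.interp(grid, b.t, b.y)
    return float(np.hypot(ax - bx, ay - by).mean())


def classify_success(score: float, ell_c: float) -> bool:
    """A run resembles the reference when its score is within one cell length."""
    if score < 0:
        raise ParameterError("score must be >= 0")
    return score <= ell_c


def thrombus_area_fraction(mask: ThrombusMask) -> float:
    """Percentage of the field covered by thrombi."""
    return 100.0 * mask.area_fraction()
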