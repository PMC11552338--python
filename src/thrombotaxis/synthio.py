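"""Synthetic scenario generation: thrombus masks and reference cell tracks.

The generator emulates the statistical structure of the flow-chamber data:
a square field of view of side 100-250 um, sparse convex thrombus blobs
covering a few percent of it, and crawling tracks with mean speeds of order
0.05-0.3 um/s sampled over at least 250 s.  Reference tracks are produced
by the walker model itself with known parameters, so parameter-recovery and
model-vs-null comparisons can be run with ground truth in hand.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .errors import GenerationError, ParameterError
from .fields import ConcentrationField
from .io import FieldGrid, ThrombusMask, Trajectory
from .params import WalkerParams
from .walker import edge_margin, simulate

__all__ = ["ScenarioSpec", "make_mask", "make_reference_cells"]


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic flow-chamber scenario.

    Defaults describe a typical healthy-donor field of view: a 200 um
    square at 1 um/px, a few thrombi of radius ~8 um (about 2% area
    coverage), wall shear rate 100 1/s, and 18 crawling cells observed for
    250 s at the walker's native 1 s interval.
    """

    side: float = 200.0              # um, square field of view
    dx: float = 1.0                  # um per pixel
    n_thrombi: int = 4
    thrombus_radius_mean: float = 8.0   # um
    thrombus_radius_sd: float = 2.0     # um
    shear_rate: float = 100.0        # 1/s
    walker: WalkerParams = dc_field(default_factory=WalkerParams)
    n_cells: int = 18
    duration: float = 250.0          # s, track length
    seed: int = 0
    irregular: bool = False          # ellipse-shaped blobs instead of discs

    def __post_init__(self) -> None:
        if not (100.0 <= self.side <= 250.0):
            raise ParameterError(
                f"field side {self.side} um outside the imaged range [100, 250]")
        if self.duration < 250.0:
            raise ParameterError(
                f"track duration {self.duration} s below the 250 s analysis minimum")
        if not self.dx > 0:
            raise ParameterError("dx must be > 0")
        if self.n_thrombi < 0 or self.n_cells < 0:
            raise ParameterError("n_thrombi and n_cells must be >= 0")
        if isinstance(self.walker, dict):
            self.walker = WalkerParams.from_dict(self.walker)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["walker"] = self.walker.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_mask(spec: ScenarioSpec, rng: np.random.Generator,
              max_tries: int = 1000) -> ThrombusMask:
    """Place non-overlapping disc (or ellipse) thrombi on the field.

    Radii are drawn from a truncated normal (mean/sd from the spec, floored
    at 2 um); blob centres keep one radius plus a 2 um gap from each other
    and from the field edge.  Raises :class:`GenerationError` if the
    requested blobs cannot be placed within the retry budget.
    """
    n_px = int(round(spec.side / spec.dx))
    mask = np.zeros((n_px, n_px))
    xs = (np.arange(n_px) + 0.0) * spec.dx
    X, Y = np.meshgrid(xs, xs)
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_thrombi):
        for attempt in range(max_tries):
            r = max(2.0, rng.normal(spec.thrombus_radius_mean,
                                    spec.thrombus_radius_sd))
            lo, hi = r + 2.0, spec.side - r - 2.0
            if lo >= hi:
                continue
            cx, cy = rng.uniform(lo, hi, size=2)
            if all(np.hypot(cx - px, cy - py) > r + pr + 2.0
                   for px, py, pr in placed):
                if spec.irregular:
                    ratio = rng.uniform(0.6, 1.0)
                    phi = rng.uniform(0, np.pi)
                    dxr = (X - cx) * np.cos(phi) + (Y - cy) * np.sin(phi)
                    dyr = -(X - cx) * np.sin(phi) + (Y - cy) * np.cos(phi)
                    blob = (dxr / r) ** 2 + (dyr / (r * ratio)) ** 2 <= 1.0
                else:
                    blob = (X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2
                mask[blob] = 1.0
                placed.append((cx, cy, r))
                break
        else:
            raise GenerationError(
                f"could not place thrombus {len(placed) + 1}/{spec.n_thrombi} "
                f"without overlap after {max_tries} tries")
    grid = FieldGrid(mask, spec.dx, (0.0, 0.0), units="mask")
    return ThrombusMask(grid, provenance=f"synthetic seed={spec.seed}")


def make_reference_cells(spec: ScenarioSpec, field: ConcentrationField,
                         rng: np.random.Generator,
                         mask: ThrombusMask | None = None,
                         k: float | None = None,
                         min_separation: float = 25.0,
                         max_tries: int = 1000
                         ) -> tuple[list[Trajectory], dict]:
    """Generate reference tracks by running the walker with known parameters.

    Starts are uniform over the margin-inset field, off-thrombus, and at
    least ``min_separation`` apart (so the generated cells pass the
    upstream-neighbour selection criterion by construction).  Setting
    ``k=0`` emits chemoattractant-insensitive (pure-null) tracks.

    Returns the tracks and a ground-truth dict mapping each cell id to the
    walker parameters that generated it.
    """
    wp = spec.walker if k is None else WalkerParams(
        ell_c=spec.walker.ell_c, L=spec.walker.L, dt=spec.walker.dt,
        v_avg=spec.walker.v_avg, k=k, K_d=spec.walker.K_d)
    g = field.grid
    margin = edge_margin(wp.ell_c) + wp.v_avg * wp.dt + g.dx
    xmin, xmax, ymin, ymax = g.bounds
    lo_x, hi_x = xmin + margin, xmax - margin
    lo_y, hi_y = ymin + margin, ymax - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise GenerationError("field too small for the walkable margin")
    if mask is not None:
        from scipy import ndimage
        # a cell centre cannot sit closer than half a cell to a thrombus
        clearance = ndimage.distance_transform_edt(
            mask.grid.values == 0) * g.dx
    else:
        clearance = None
    n_steps = int(round(spec.duration / wp.dt))
    tracks: list[Trajectory] = []
    truth: dict = {}
    starts: list[tuple[float, float]] = []
    for i in range(spec.n_cells):
        sim = None
        for attempt in range(max_tries):
            sx = rng.uniform(lo_x, hi_x)
            sy = rng.uniform(lo_y, hi_y)
            if clearance is not None:
                r, c = g.pixel_at(sx, sy)
                if clearance[int(r), int(c)] < wp.ell_c / 2:
                    continue
            if any(np.hypot(sx - px, sy - py) < min_separation
                   for px, py in starts):
                continue
            seed = int(rng.integers(0, 2**31 - 1))
            cand = simulate((sx, sy), n_steps, field, wp, rng_seed=seed,
                            mask=mask, cell_id=f"cell{i:03d}")
            # discard degenerate draws (pinned against an obstacle or edge)
            if cand.terminated_early or cand.traj.path_length() == 0.0:
                continue
            sim = cand
            break
        if sim is None:
            raise GenerationError(
                f"could not place cell {i + 1}/{spec.n_cells} with "
                f"separation {min_separation} um and clearance "
                f"{wp.ell_c / 2} um")
        tracks.append(sim.traj)
        starts.append((sx, sy))
        truth[sim.traj.cell_id] = {**wp.to_dict(), "seed": seed,
                                   "start": [sx, sy]}
    return tracks, truth
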