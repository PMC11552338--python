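"""Stochastic receptor-driven neutrophil walker.

At each time step the model cell samples the local chemoattractant gradient
with rotated, ellipsoid-shaped Sobel kernels (long axis = cell length
``ell_c`` along the previous heading, short axis = ``ell_c / 2``), converts
it to a differential fractional receptor occupancy

    DFRO = (ell_c / K_d) * |grad c| / (1 + c / K_d)^2,

draws a heading perturbation from a von Mises distribution with
concentration ``kappa = k * min(DFRO, 1)`` about the gradient direction,
and advances with a velocity that blends the new and previous headings with
memory weight ``B_mem = L / dt``:

    v^N = v_avg * [ e(theta^N) + B_mem * e(theta^{N-1}) ] / (1 + B_mem).

Steps that would land on a thrombus pixel or leave the walkable margin are
truncated to the last free point along the segment; the heading is kept.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .errors import DataError, DomainError, ParameterError
from .fields import ConcentrationField
from .io import FieldGrid, ThrombusMask, Trajectory
from .params import WalkerParams

__all__ = [
    "WalkerParams", "WalkerState", "SimTrajectory", "SobelSampler",
    "sobel_gradient", "dfro", "sample_theta_random", "step", "simulate",
    "run_ensemble", "edge_margin",
]

#: gradients below this magnitude (nM/um) are treated as zero
ZERO_GRAD_TOL = 1e-12
#: fractional occupancy difference cannot exceed one cell's worth of receptors
DFRO_MAX = 1.0


def wrap_angle(theta):
    """Wrap an angle to (-pi, pi]."""
    out = np.mod(-np.asarray(theta) + np.pi, 2 * np.pi)
    return -(out - np.pi)


@dataclass
class WalkerState:
    """Position, previous summed heading and step index of one walker."""

    p: tuple[float, float]
    theta_prev: float
    n: int = 0

    def __post_init__(self) -> None:
        self.theta_prev = float(wrap_angle(self.theta_prev))


@dataclass
class SimTrajectory:
    """A simulated walk plus per-step diagnostics.

    ``traj`` holds the (t, x, y) polyline; the parallel arrays hold the
    concentration, gradient magnitude, DFRO, kappa and the two heading
    components sampled at each completed step.
    """

    traj: Trajectory
    c: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    grad: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    dfro: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    kappa: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    theta_grad: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    theta_random: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    seed: Optional[int] = None
    terminated_early: bool = False
    termination_reason: str = ""

    @property
    def t(self):
        return self.traj.t

    @property
    def x(self):
        return self.traj.x

    @property
    def y(self):
        return self.traj.y


class SobelSampler:
    """Physically normalized, rotatable Sobel gradient sampler.

    The kernel footprint is an ``ell_c`` x ``ell_c/2`` box in the cell
    frame (long axis along the previous heading).  Derivative rows are
    coordinate-weighted with binomial smoothing and normalized so that a
    linear ramp ``c = a*x`` returns exactly ``a`` (nM/um) irrespective of
    the rotation angle.
    """

    def __init__(self, ell_c: float, dx: float):
        if not ell_c > 0 or not dx > 0:
            raise ParameterError("ell_c and dx must be > 0")
        n_par = max(3, int(round(ell_c / dx)) | 1)       # odd, extent ell_c
        n_perp = max(3, int(round(ell_c / 2 / dx)) | 1)  # odd, extent ell_c/2
        xi = (np.arange(n_par) - (n_par - 1) / 2) * dx
        eta = (np.arange(n_perp) - (n_perp - 1) / 2) * dx

        def binom(n):
            w = np.array([math.comb(n - 1, i) for i in range(n)], dtype=float)
            return w / w.sum()

        def deriv(coords, smooth):
            d = coords * smooth
            return d / np.sum(d * coords)

        sx, sy = binom(n_par), binom(n_perp)
        dxw, dyw = deriv(xi, sx), deriv(eta, sy)
        XI, ETA = np.meshgrid(xi, eta, indexing="ij")
        self.offsets_par = XI.ravel()
        self.offsets_perp = ETA.ravel()
        self.w_par = np.outer(dxw, sy).ravel()    # d/d(xi) kernel
        self.w_perp = np.outer(sx, dyw).ravel()   # d/d(eta) kernel
        #: radius of the rotated kernel footprint, um
        self.radius = float(np.hypot(xi[-1], eta[-1]))

    def __call__(self, grid: FieldGrid, p, theta_prev: float):
        x0, y0 = p
        ct, st = math.cos(theta_prev), math.sin(theta_prev)
        X = x0 + self.offsets_par * ct - self.offsets_perp * st
        Y = y0 + self.offsets_par * st + self.offsets_perp * ct
        xmin, xmax, ymin, ymax = grid.bounds
        if X.min() < xmin or X.max() > xmax or Y.min() < ymin or Y.max() > ymax:
            raise DomainError("gradient sampling window clipped by field edge")
        # inline bilinear gather (hot path)
        fx = (X - grid.origin[0]) / grid.dx
        fy = (Y - grid.origin[1]) / grid.dx
        j0 = np.clip(fx.astype(int), 0, grid.nx - 2)
        i0 = np.clip(fy.astype(int), 0, grid.ny - 2)
        tx = fx - j0
        ty = fy - i0
        v = grid.values
        c = ((1 - ty) * ((1 - tx) * v[i0, j0] + tx * v[i0, j0 + 1])
             + ty * ((1 - tx) * v[i0 + 1, j0] + tx * v[i0 + 1, j0 + 1]))
        g_par = float(self.w_par @ c)
        g_perp = float(self.w_perp @ c)
        mag = math.hypot(g_par, g_perp)
        if mag < ZERO_GRAD_TOL:
            return 0.0, float(theta_prev)
        theta = wrap_angle(theta_prev + math.atan2(g_perp, g_par))
        return mag, float(theta)


def sobel_gradient(field: ConcentrationField | FieldGrid, p, theta_prev: float,
                   ell_c: float):
    """Sample the local gradient with cell-frame-aligned Sobel kernels.

    Returns ``(magnitude nM/um, theta_grad)`` where ``theta_grad`` is the
    lab-frame gradient direction.  By convention a vanishing gradient
    (magnitude < 1e-12) returns ``theta_grad = theta_prev`` so that an
    insensitive walker reduces to an unbiased persistent walk.
    """
    grid = field.grid if isinstance(field, ConcentrationField) else field
    return SobelSampler(ell_c, grid.dx)(grid, p, theta_prev)


def edge_margin(ell_c: float, minimum: float = 10.0) -> float:
    """Walkable margin from the field edge, um.

    The larger of the 10 um exclusion band (unseen thrombi may lie beyond
    the edge) and the rotated Sobel footprint radius, so that gradient
    sampling never clips.
    """
    return max(minimum, math.hypot(ell_c / 2, ell_c / 4) + 1e-9)


def dfro(c: float, grad: float, ell_c: float, K_d: float) -> float:
    """Differential fractional receptor occupancy across the cell body.

    ``DFRO = (ell_c / K_d) * grad / (1 + c / K_d)^2`` with ``grad`` the
    magnitude of the sampled gradient.  Dimensionless; may exceed 1 for
    very steep gradients (callers clamp before forming kappa).
    """
    if c < 0:
        raise DomainError(f"negative concentration c={c}")
    return (ell_c / K_d) * grad / (1.0 + c / K_d) ** 2


def sample_theta_random(kappa: float, rng: np.random.Generator) -> float:
    """Draw a heading perturbation from the von Mises density centred at 0.

    ``f(theta; kappa) = exp(kappa cos theta) / (2 pi I0(kappa))``;
    ``kappa = 0`` is the uniform circle.
    """
    if kappa < 0:
        raise ParameterError(f"kappa={kappa} must be >= 0")
    return float(rng.vonmises(0.0, kappa))


def _truncate_step(p, q, mask_values, grid: FieldGrid, margin: float):
    """Shorten the segment p -> q to its last admissible point.

    Admissible means inside the margin-inset field and not on a thrombus
    pixel.  The segment is scanned at sub-pixel resolution from q backwards.
    """
    xmin, xmax, ymin, ymax = grid.bounds
    xmin += margin
    xmax -= margin
    ymin += margin
    ymax -= margin
    seg = math.hypot(q[0] - p[0], q[1] - p[1])
    nsub = max(2, int(seg / (0.5 * grid.dx)) + 1)
    ss = np.linspace(0.0, 1.0, nsub)
    xs = p[0] + ss * (q[0] - p[0])
    ys = p[1] + ss * (q[1] - p[1])
    ok = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
    if mask_values is not None:
        r, c = grid.pixel_at(xs, ys)
        r = np.clip(r, 0, grid.ny - 1)
        c = np.clip(c, 0, grid.nx - 1)
        ok &= mask_values[r, c] == 0
    # last prefix index where every point up to it is admissible
    bad = np.flatnonzero(~ok)
    last = nsub - 1 if bad.size == 0 else max(bad[0] - 1, 0)
    return float(xs[last]), float(ys[last])


def step(state: WalkerState, field: ConcentrationField, wp: WalkerParams,
         rng: np.random.Generator, mask: ThrombusMask | None = None,
         sampler: SobelSampler | None = None, diagnostics: dict | None = None
         ) -> WalkerState:
    """Advance one walker by one time step of the heading recurrence.

    Samples the gradient, forms ``kappa = k * min(DFRO, 1)``, draws the
    heading ``theta_sum = theta_grad + theta_random`` and moves with the
    memory-weighted velocity.  Propagates :class:`DomainError` if the
    gradient window is clipped by the field edge.
    """
    sampler = sampler or SobelSampler(wp.ell_c, field.grid.dx)
    x, y = state.p
    grad, theta_grad = sampler(field.grid, (x, y), state.theta_prev)
    c = float(field.grid.interp(x, y))
    occ = dfro(c, grad, wp.ell_c, wp.K_d)
    kappa = wp.k * min(occ, DFRO_MAX)
    theta_random = sample_theta_random(kappa, rng)
    theta_sum = float(wrap_angle(theta_grad + theta_random))
    B = wp.B_mem
    w_new, w_old = 1.0 / (1.0 + B), B / (1.0 + B)
    vx = wp.v_avg * (w_new * math.cos(theta_sum) + w_old * math.cos(state.theta_prev))
    vy = wp.v_avg * (w_new * math.sin(theta_sum) + w_old * math.sin(state.theta_prev))
    q = (x + vx * wp.dt, y + vy * wp.dt)
    margin = edge_margin(wp.ell_c)
    mask_values = mask.grid.values if mask is not None else None
    q = _truncate_step((x, y), q, mask_values, field.grid, margin)
    if diagnostics is not None:
        diagnostics.update(c=c, grad=grad, dfro=occ, kappa=kappa,
                           theta_grad=theta_grad, theta_random=theta_random)
    return WalkerState(p=q, theta_prev=theta_sum, n=state.n + 1)


def simulate(start, n_steps: int, field: ConcentrationField, wp: WalkerParams,
             rng_seed: int, mask: ThrombusMask | None = None,
             theta0: float | None = None, t0: float = 0.0,
             cell_id: str = "sim") -> SimTrajectory:
    """Run one walker for ``n_steps`` steps from a seeded generator.

    The initial heading is drawn uniformly unless ``theta0`` is given
    (e.g. the first-step direction of a reference track).  If the walker
    reaches the field edge the trajectory is returned truncated with
    ``terminated_early`` set and reason ``"edge"``.
    """
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    rng = np.random.default_rng(rng_seed)
    theta_prev = float(rng.uniform(-math.pi, math.pi)) if theta0 is None \
        else float(wrap_angle(theta0))
    state = WalkerState(p=(float(start[0]), float(start[1])), theta_prev=theta_prev)
    sampler = SobelSampler(wp.ell_c, field.grid.dx)
    xs, ys = [state.p[0]], [state.p[1]]
    diag_keys = ("c", "grad", "dfro", "kappa", "theta_grad", "theta_random")
    diags: dict[str, list] = {k: [] for k in diag_keys}
    terminated, reason = False, ""
    for _ in range(n_steps):
        d: dict = {}
        try:
            state = step(state, field, wp, rng, mask=mask, sampler=sampler,
                         diagnostics=d)
        except DomainError:
            terminated, reason = True, "edge"
            break
        xs.append(state.p[0])
        ys.append(state.p[1])
        for k in diag_keys:
            diags[k].append(d[k])
    t = t0 + np.arange(len(xs)) * wp.dt
    traj = Trajectory(cell_id, t, np.asarray(xs), np.asarray(ys))
    return SimTrajectory(
        traj=traj, seed=rng_seed,
        terminated_early=terminated, termination_reason=reason,
        **{k: np.asarray(v) for k, v in diags.items()})


def run_ensemble(cell: Trajectory, field: ConcentrationField, wp: WalkerParams,
                 n_runs: int = 36, base_seed: int = 0,
                 mask: ThrombusMask | None = None,
                 dt_resample: float = 5.0):
    """Simulate ``n_runs`` walkers against one reference cell.

    Each run starts at the cell's first observed position with the cell's
    first-step heading and experimental mean speed, lasts as long as the
    reference track, and uses seed ``base_seed + i``.  Runs are scored by
    the mean point-wise distance to the reference and classified successful
    when the score is within one cell length.
    """
    from . import analysis  # local import; analysis does not import walker

    if len(cell) < 2:
        raise DataError(f"reference track '{cell.cell_id}' has fewer than 2 points")
    v_avg = analysis.mean_speed(cell)
    if v_avg <= 0:
        raise DataError(f"reference track '{cell.cell_id}' is stationary")
    wp_cell = WalkerParams(ell_c=wp.ell_c, L=wp.L, dt=wp.dt, v_avg=v_avg,
                           k=wp.k, K_d=wp.K_d)
    n_steps = max(1, int(round(cell.duration / wp.dt)))
    theta0 = math.atan2(cell.y[1] - cell.y[0], cell.x[1] - cell.x[0])
    runs, scores, successes = [], [], []
    for i in range(n_runs):
        sim = simulate((cell.x[0], cell.y[0]), n_steps, field, wp_cell,
                       rng_seed=base_seed + i, mask=mask, theta0=theta0,
                       t0=float(cell.t[0]), cell_id=f"{cell.cell_id}:run{i}")
        score = analysis.score_run(sim, cell, dt_resample=dt_resample)
        runs.append(sim)
        scores.append(score)
        successes.append(analysis.classify_success(score, wp.ell_c))
    return analysis.EnsembleResult(
        cell_id=cell.cell_id, runs=runs,
        scores=np.asarray(scores), successes=np.asarray(successes, dtype=bool))
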