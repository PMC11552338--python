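"""Near-wall flow and steady chemoattractant fields around thrombi.

The chamber is reduced to a 2D depth-averaged layer of thickness
``h_layer`` at the coverslip, where neutrophils crawl.  Advection acts at
the crawling-plane speed ``u = mu * h_ref`` set by the wall shear rate.
Two flow modes are provided:

* ``uniform`` -- plug flow ``(u, 0)`` everywhere, ignoring obstacles;
* ``stokes``  -- steady incompressible 2D Stokes flow around the thrombi,
  computed in a streamfunction/vorticity formulation with Brinkman volume
  penalization enforcing no-slip on thrombus pixels.

The chemoattractant obeys the steady advection-diffusion equation
``D lap(c) - u . grad(c) + S = 0`` with a uniform areal source S on thrombus
pixels, an absorbing (c = 0) inlet, advective outflow at the outlet and
no-flux side walls.  The discretization uses exponentially fitted
(Scharfetter-Gummel) face fluxes, which remain positivity-preserving and
accurate at arbitrary cell Peclet number, and the resulting linear system
is solved directly.  Concentration is solved inside thrombi as well:
platelet aggregates are permeable to diffusion at this scale; obstacles
exclude flow and walker motion only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import DataError, DomainError, NumericalError, ParameterError
from .io import FieldGrid, ThrombusMask, Trajectory
from .params import ChemokineParams

__all__ = [
    "ChemokineParams", "VelocityField", "ConcentrationField", "CATrace",
    "wall_speed", "solve_flow", "solve_ca", "sample_c", "ca_along_trajectory",
]


@dataclass
class VelocityField:
    """Depth-plane velocity (u, v) on a shared grid, um/s."""

    u: FieldGrid
    v: FieldGrid
    mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.u.values.shape != self.v.values.shape:
            raise DataError("u and v grids must share geometry")


@dataclass
class ConcentrationField:
    """Steady chemoattractant concentration in nM on a grid."""

    grid: FieldGrid
    source_mask: ThrombusMask
    params: ChemokineParams

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class CATrace:
    """Concentration sampled along a trajectory with per-segment labels."""

    t: np.ndarray
    c: np.ndarray
    segment_sign: list  # one of "rising", "falling", "flat" per segment


def wall_speed(mu: float, h_ref: float, chamber_height: float = 100.0) -> float:
    """Advection speed at the crawling plane, ``u = mu * h_ref`` (um/s).

    Linearized near-wall profile of the laminar chamber flow: the wall shear
    rate ``mu`` (1/s) is the velocity gradient at the coverslip, so at a
    height ``h_ref`` (um, about half a neutrophil) the fluid moves at
    ``mu * h_ref``.
    """
    if mu < 0:
        raise ParameterError(f"shear rate mu={mu} must be >= 0")
    if not h_ref > 0:
        raise ParameterError(f"reference height h_ref={h_ref} must be > 0")
    if h_ref > chamber_height / 2:
        raise ParameterError(
            f"h_ref={h_ref} um exceeds chamber half-height {chamber_height / 2} um; "
            "the linearized wall profile is not valid there")
    return mu * h_ref


def _uniform_flow(mask: ThrombusMask, U: float) -> VelocityField:
    g = mask.grid
    u = FieldGrid(np.full_like(g.values, U), g.dx, g.origin, units="um/s")
    v = FieldGrid(np.zeros_like(g.values), g.dx, g.origin, units="um/s")
    return VelocityField(u, v, mode="uniform")


def solve_flow(mask: ThrombusMask, mu: float, h_ref: float,
               mode: Literal["uniform", "stokes"] = "uniform",
               chamber_height: float = 100.0,
               penalization: float = 1e4) -> VelocityField:
    """Compute the in-plane flow field around the thrombus obstacles.

    ``uniform`` mode returns plug flow at :func:`wall_speed`, ignoring
    obstacles.  ``stokes`` mode solves steady incompressible creeping flow
    with a plug inlet at x = 0, outflow at the far end, free-slip
    no-penetration side walls, and no-slip on thrombus pixels imposed by
    Brinkman penalization with dimensionless strength ``penalization``
    (friction coefficient ``penalization / dx^2``).

    The streamfunction formulation makes the discrete flow exactly
    divergence-free and conserves the inlet-to-outlet volumetric flux.
    """
    U = wall_speed(mu, h_ref, chamber_height)
    if mode == "uniform":
        return _uniform_flow(mask, U)
    if mode != "stokes":
        raise ParameterError(f"unknown flow mode '{mode}'")

    g = mask.grid
    ny, nx, dx = g.ny, g.nx, g.dx
    chi = (g.values > 0).astype(float)
    if chi.any():
        # obstacles must not span the full cross-section
        if np.any(chi.all(axis=0)):
            raise DataError("thrombus spans the full chamber cross-section")
    if U == 0.0:
        z = np.zeros((ny, nx))
        return VelocityField(FieldGrid(z, dx, g.origin, units="um/s"),
                             FieldGrid(z.copy(), dx, g.origin, units="um/s"),
                             mode="stokes")

    # Unknowns: psi (streamfunction) and omega (vorticity) at pixel centres.
    # Interior: lap(psi) + omega = 0;  lap(omega) + sigma * div(chi grad psi) = 0.
    # BCs: inlet psi = U*y, omega = 0 (plug); side walls psi fixed (no
    # penetration), omega = 0 (free slip); outlet d/dx = 0 for both.
    N = ny * nx
    sigma = penalization / dx**2

    def k(r, c):
        return r * nx + c

    rows, cols, data = [], [], []
    rhs = np.zeros(2 * N)
    yvals = np.arange(ny) * dx

    def add(i, j, a):
        rows.append(i)
        cols.append(j)
        data.append(a)

    inv2 = 1.0 / dx**2
    for r in range(ny):
        for c in range(nx):
            kk = k(r, c)
            kp, ko = kk, N + kk  # psi row, omega row
            boundary = r == 0 or r == ny - 1 or c == 0
            if boundary:
                add(kp, kk, 1.0)
                rhs[kp] = U * yvals[r]
                add(ko, N + kk, 1.0)
                continue
            if c == nx - 1:  # outlet: zero streamwise gradient
                add(kp, kk, 1.0)
                add(kp, k(r, c - 1), -1.0)
                add(ko, N + kk, 1.0)
                add(ko, N + k(r, c - 1), -1.0)
                continue
            nbrs = [k(r - 1, c), k(r + 1, c), k(r, c - 1), k(r, c + 1)]
            # lap(psi) + omega = 0
            add(kp, kk, -4.0 * inv2)
            for nb in nbrs:
                add(kp, nb, inv2)
            add(kp, N + kk, 1.0)
            # lap(omega) + sigma * div(chi grad psi) = 0, chi at faces
            add(ko, N + kk, -4.0 * inv2)
            for nb in nbrs:
                add(ko, N + nb, inv2)
            for nb, rr, cc in ((nbrs[0], r - 1, c), (nbrs[1], r + 1, c),
                               (nbrs[2], r, c - 1), (nbrs[3], r, c + 1)):
                chif = 0.5 * (chi[r, c] + chi[rr, cc])
                if chif:
                    add(ko, nb, sigma * chif * inv2)
                    add(ko, kk, -sigma * chif * inv2)

    A = sparse.csc_matrix((data, (rows, cols)), shape=(2 * N, 2 * N))
    sol = spsolve(A, rhs)
    if not np.all(np.isfinite(sol)):
        raise NumericalError("Stokes solve produced non-finite values")
    resid = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-6:
        raise NumericalError(f"Stokes solve did not converge (residual {resid:.2e})")
    psi = sol[:N].reshape(ny, nx)
    # u = dpsi/dy, v = -dpsi/dx (second-order, one-sided at edges)
    u = np.gradient(psi, dx, axis=0)
    v = -np.gradient(psi, dx, axis=1)
    return VelocityField(FieldGrid(u, dx, g.origin, units="um/s"),
                         FieldGrid(v, dx, g.origin, units="um/s"),
                         mode="stokes")


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the exponential-fitting flux weight."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    xs = np.clip(x[~small], -700.0, 700.0)
    with np.errstate(over="ignore"):
        out[~small] = np.where(xs > 0, xs * np.exp(-xs) / (-np.expm1(-xs)),
                               xs / np.expm1(xs))
    return out


def solve_ca(mask: ThrombusMask, vel: VelocityField,
             params: ChemokineParams | None = None,
             source: np.ndarray | None = None) -> ConcentrationField:
    """Solve the steady advection-diffusion equation for the chemoattractant.

    ``D lap(c) - u . grad(c) + S = 0`` with S the areal source on thrombus
    pixels (``params.source_rate_nM``), c = 0 at the inlet, advective
    outflow at the outlet and no-flux side walls.  Finite-volume
    Scharfetter-Gummel fluxes keep the scheme stable and non-negative at
    any Peclet number.

    Parameters
    ----------
    source : ndarray, optional
        Override the volumetric source field (nM/s, same shape as the
        grid); by default the source is ``params.source_rate_nM`` on
        thrombus pixels and 0 elsewhere.
    """
    params = params or ChemokineParams()
    g = mask.grid
    if vel.u.values.shape != g.values.shape:
        raise DataError("velocity and mask grids must share geometry")
    ny, nx, dx = g.ny, g.nx, g.dx
    D = params.D
    u = vel.u.values
    v = vel.v.values
    if source is None:
        S = params.source_rate_nM * (g.values > 0)
    else:
        S = np.asarray(source, dtype=float)
        if S.shape != g.values.shape:
            raise DataError("source field shape does not match grid")

    if not S.any():
        zero = FieldGrid(np.zeros((ny, nx)), dx, g.origin, units="nM")
        return ConcentrationField(zero, mask, params)

    idx = np.arange(ny * nx).reshape(ny, nx)
    kdiff = D / dx**2
    rows, cols, data = [], [], []

    def faces(iL, iR, pe):
        """Scharfetter-Gummel flux exchange between left/right cells."""
        bm = _bernoulli(-pe) * kdiff   # weight of upstream cell
        bp = _bernoulli(pe) * kdiff    # weight of downstream cell
        # row iL: -bm*cL + bp*cR ; row iR: +bm*cL - bp*cR
        rows.extend((iL, iL, iR, iR))
        cols.extend((iL, iR, iL, iR))
        data.extend((-bm, bp, bm, -bp))

    # interior x faces (between col j and j+1)
    uf = 0.5 * (u[:, :-1] + u[:, 1:])
    pe = uf * dx / D
    iL = idx[:, :-1].ravel()
    iR = idx[:, 1:].ravel()
    bm = _bernoulli(-pe).ravel() * kdiff
    bp = _bernoulli(pe).ravel() * kdiff
    rows.extend(np.concatenate([iL, iL, iR, iR]))
    cols.extend(np.concatenate([iL, iR, iL, iR]))
    data.extend(np.concatenate([-bm, bp, bm, -bp]))
    # interior y faces
    vf = 0.5 * (v[:-1, :] + v[1:, :])
    pe = vf * dx / D
    iL = idx[:-1, :].ravel()
    iR = idx[1:, :].ravel()
    bm = _bernoulli(-pe).ravel() * kdiff
    bp = _bernoulli(pe).ravel() * kdiff
    rows.extend(np.concatenate([iL, iL, iR, iR]))
    cols.extend(np.concatenate([iL, iR, iL, iR]))
    data.extend(np.concatenate([-bm, bp, bm, -bp]))
    # inlet faces (west of col 0): Dirichlet c = 0 outside
    pe = u[:, 0] * dx / D
    ii = idx[:, 0]
    rows.extend(ii)
    cols.extend(ii)
    data.extend(-_bernoulli(pe) * kdiff)
    # outlet faces (east of last col): advective outflow only
    uout = np.maximum(u[:, -1], 0.0)
    ii = idx[:, -1]
    rows.extend(ii)
    cols.extend(ii)
    data.extend(-uout / dx)
    # side walls: zero total flux -> no terms

    A = sparse.csc_matrix(
        (np.asarray(data, dtype=float),
         (np.asarray(rows), np.asarray(cols))),
        shape=(ny * nx, ny * nx))
    b = -S.ravel()
    c = spsolve(A, b)
    if not np.all(np.isfinite(c)):
        raise NumericalError("advection-diffusion solve produced non-finite values")
    cmin = c.min()
    if cmin < -1e-9 * max(c.max(), 1.0):
        raise NumericalError(
            f"oscillatory solution (min c = {cmin:.3e} nM); refine the grid")
    c = np.clip(c, 0.0, None).reshape(ny, nx)
    grid = FieldGrid(c, dx, g.origin, units="nM")
    return ConcentrationField(grid, mask, params)


def sample_c(field: ConcentrationField, p) -> float:
    """Bilinear interpolation of the concentration at a point (x, y) um."""
    x, y = p
    val = field.grid.interp(x, y)
    return float(val)


def ca_along_trajectory(field: ConcentrationField, traj: Trajectory,
                        flat_tol: float = 1e-9) -> CATrace:
    """Concentration along a trajectory with rising/falling segment labels.

    Each segment between consecutive track points is labelled ``rising`` if
    the concentration increases by more than ``flat_tol`` nM, ``falling``
    if it decreases by more, and ``flat`` otherwise.
    """
    c = field.grid.interp(traj.x, traj.y)
    dc = np.diff(c)
    labels = ["rising" if d > flat_tol else "falling" if d < -flat_tol else "flat"
              for d in dc]
    return CATrace(t=traj.t.copy(), c=np.asarray(c, dtype=float), segment_sign=labels)
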