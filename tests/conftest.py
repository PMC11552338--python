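"""Shared fixtures: small synthetic fields, masks and tracks.

Expensive field solves are session-scoped; everything is seeded so the
suite is deterministic.
"""
import numpy as np
import pytest

from thrombotaxis import fields, io as tio, synthio
from thrombotaxis.params import ChemokineParams, WalkerParams


def make_disc_mask(n=200, dx=1.0, centre=(60.0, 100.0), radius=10.0):
    """A single disc thrombus on an n x n field (um coordinates)."""
    xs = np.arange(n) * dx
    X, Y = np.meshgrid(xs, xs)
    vals = ((X - centre[0]) ** 2 + (Y - centre[1]) ** 2 <= radius ** 2).astype(float)
    return tio.ThrombusMask(tio.FieldGrid(vals, dx), provenance="synthetic disc")


@pytest.fixture(scope="session")
def disc_mask():
    return make_disc_mask()


@pytest.fixture(scope="session")
def disc_field(disc_mask):
    """Steady CA field around one disc at wall shear rate 100 1/s."""
    vel = fields.solve_flow(disc_mask, mu=100.0, h_ref=5.0)
    return fields.solve_ca(disc_mask, vel, ChemokineParams())


@pytest.fixture(scope="session")
def scenario_field():
    """Default multi-thrombus scenario (mask + CA field), seed 42."""
    spec = synthio.ScenarioSpec(seed=42)
    rng = np.random.default_rng(42)
    mask = synthio.make_mask(spec, rng)
    vel = fields.solve_flow(mask, spec.shear_rate, h_ref=5.0)
    conc = fields.solve_ca(mask, vel, ChemokineParams(K_d=spec.walker.K_d))
    return spec, mask, conc


def uniform_velocity(grid, U):
    """Plug-flow VelocityField matching a grid."""
    shape = grid.values.shape
    return fields.VelocityField(
        tio.FieldGrid(np.full(shape, float(U)), grid.dx, grid.origin),
        tio.FieldGrid(np.zeros(shape), grid.dx, grid.origin),
        mode="uniform")


def ramp_field(a=0.01, n=200, dx=1.0, axis="x", c0=1.0):
    """A linear concentration ramp c = c0 + a * coord for gradient tests."""
    xs = np.arange(n) * dx
    X, Y = np.meshgrid(xs, xs)
    vals = c0 + a * (X if axis == "x" else Y)
    grid = tio.FieldGrid(vals, dx, units="nM")
    mask = tio.ThrombusMask(tio.FieldGrid(np.zeros((n, n)), dx))
    return fields.ConcentrationField(grid, mask, ChemokineParams())


def constant_field(c0=1.0, n=200, dx=1.0):
    return ramp_field(a=0.0, n=n, dx=dx, c0=c0)


@pytest.fixture
def wp():
    return WalkerParams()
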