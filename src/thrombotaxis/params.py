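"""Physical parameter containers shared across the field and walker models.

Units are micrometres, seconds and nanomolar throughout.  Concentration is
converted from number density with 1 molecule/um^3 = 1.6606 nM.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ParameterError

#: 1 molecule per cubic micrometre expressed in nanomolar.
MOLECULES_PER_UM3_IN_NM = 1.6606


@dataclass
class ChemokineParams:
    """Molecular, transport and source parameters of the model chemoattractant.

    The defaults describe an interleukin-like platelet-derived chemokine:
    8 kDa, diffusivity 130 um^2/s, released at 2900 molecules per platelet
    over a 30-minute perfusion.  The PF4 variant is obtained by lowering
    ``D`` only.

    Parameters
    ----------
    molecular_mass : float
        Molar mass in kDa (informational; does not enter the transport solve).
    D : float
        Diffusion coefficient, um^2/s.  Sanity band [1, 500].
    release_per_platelet : float
        Molecules released per platelet over ``release_duration``.
    release_duration : float
        Duration of release used to convert the total to a rate, seconds.
    platelet_footprint : float
        Projected area per platelet inside a thrombus, um^2; thrombus area
        divided by this gives the effective platelet count.
    h_layer : float
        Effective near-wall layer thickness for 2D depth-averaging, um.
    K_d : float
        Receptor dissociation constant, nM.
    """

    molecular_mass: float = 8.0
    D: float = 130.0
    release_per_platelet: float = 2900.0
    release_duration: float = 1800.0
    platelet_footprint: float = 5.0
    h_layer: float = 10.0
    K_d: float = 1.0

    def __post_init__(self) -> None:
        for name in ("molecular_mass", "D", "release_per_platelet",
                     "release_duration", "platelet_footprint", "h_layer", "K_d"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"ChemokineParams.{name} must be > 0")
        if not (1.0 <= self.D <= 500.0):
            raise ParameterError(
                f"diffusion coefficient D={self.D} um^2/s outside sanity band [1, 500]")

    @property
    def source_rate_nM(self) -> float:
        """Volumetric release rate on thrombus pixels, nM/s.

        release rate per platelet (molecules/s) / footprint (um^2/platelet)
        / layer thickness (um) gives molecules um^-3 s^-1, converted to nM/s.
        """
        per_platelet_rate = self.release_per_platelet / self.release_duration
        density_rate = per_platelet_rate / self.platelet_footprint / self.h_layer
        return density_rate * MOLECULES_PER_UM3_IN_NM

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChemokineParams":
        return cls(**d)


@dataclass
class WalkerParams:
    """Parameters of the stochastic neutrophil walker.

    Parameters
    ----------
    ell_c : float
        Cell length, um; must lie in the physiological range [10, 20].
    L : float
        Persistence time, seconds.  The memory coefficient is
        ``B_mem = L / dt``.
    dt : float
        Model time step, seconds.
    v_avg : float
        Mean crawling speed, um/s; in ensemble runs this is set per cell
        from the reference track.
    k : float
        Sensitivity constant mapping differential receptor occupancy to the
        von Mises concentration, ``kappa = k * DFRO``.  Dimensionless; not
        experimentally constrained, treated as a fitted parameter.
    K_d : float
        Receptor dissociation constant, nM (shared with the chemokine).
    """

    ell_c: float = 15.0
    L: float = 22.0
    dt: float = 1.0
    v_avg: float = 0.15
    k: float = 5000.0
    K_d: float = 1.0

    def __post_init__(self) -> None:
        if not (10.0 <= self.ell_c <= 20.0):
            raise ParameterError(
                f"cell length ell_c={self.ell_c} um outside [10, 20]")
        for name in ("L", "dt", "v_avg", "K_d"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"WalkerParams.{name} must be > 0")
        if self.k < 0:
            raise ParameterError("WalkerParams.k must be >= 0")

    @property
    def B_mem(self) -> float:
        """Memory coefficient weighting the previous heading, L/dt."""
        return self.L / self.dt

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WalkerParams":
        return cls(**d)
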