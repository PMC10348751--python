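"""Simulation configuration: spatial grid and the scalar parameter set.

All defaults correspond to the standard study conditions: a 0.5 cm 1D
habitat at 0.005 cm resolution, mediator diffusion typical of small
molecules in water (1.8e-2 cm^2/hr = 500 um^2/s), near-immotile cells
(5e-9 cm^2/hr), serial enrichment from a total inoculum of 1e4 cells/ml
diluted back each time the community reaches 1e7 cells/ml, for 100
generations of net growth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from ._exceptions import ConfigurationError, ParameterError

__all__ = ["GridSpec", "SimulationConfig"]


@dataclass(frozen=True)
class GridSpec:
    """A uniform 1D grid with no-flux boundaries at both ends.

    Parameters
    ----------
    Z : float
        Total spatial extent of the habitat (cm).
    dz : float
        Grid spacing (cm). Grid points are cell centres, so no-flux
        (reflecting) boundary conditions sit half a cell outside the
        first and last points.
    """

    Z: float = 0.5
    dz: float = 0.005

    def __post_init__(self):
        if self.dz <= 0 or self.Z <= 0:
            raise ConfigurationError(
                "Z and dz must be positive", keys=["Z", "dz"])
        if self.n_z < 3:
            raise ConfigurationError(
                f"grid must have at least 3 points, got n_z={self.n_z}",
                keys=["Z", "dz"])

    @property
    def n_z(self) -> int:
        """Number of grid points, round(Z/dz)."""
        return int(round(self.Z / self.dz))


# fields a user may override by name (everything except derived values)
_CONFIG_FIELDS = (
    "D_cell", "D_med", "k_Y", "k_sat", "TID", "ExtTh", "DilTh",
    "n_gen", "dtau", "dt_factor", "dc_factor", "Z", "dz",
    "infinite_dispersal", "saturating_consumption", "implicit_diffusion",
    "mediator_dilution", "round_t_max", "max_rounds",
)


@dataclass(frozen=True)
class SimulationConfig:
    """All scalar parameters of the spatial enrichment model.

    Attributes
    ----------
    D_cell : float
        Cell dispersal (random-walk) coefficient, cm^2/hr.
    D_med : float
        Mediator diffusion coefficient, cm^2/hr.
    k_Y : float
        Local carrying capacity for total cell density at each grid
        point, cells/ml; enters the logistic crowding factor
        ``1 - sum_j S_j / k_Y``.
    k_sat : float
        Interaction-strength saturation level, cells/ml-equivalent
        concentration units (fmol/ml).
    TID : float
        Total initial cell density of the inoculum, cells/ml
        (spatial average, split equally among species).
    ExtTh : float
        Extinction threshold, cells/ml: a species whose spatially
        averaged density falls below this is considered extinct.
    DilTh : float
        Dilution threshold, cells/ml: a growth round ends when the
        spatially averaged total density reaches this value.
    n_gen : float
        Target accumulated generations of enrichment (default 100).
    dtau : float
        Growth/uptake update timescale, hr.
    dt_factor, dc_factor : float
        Prefactors for the diffusion time-steps
        ``dt = dt_factor * dz**2 / D_med`` and
        ``dc = dc_factor * dz**2 / D_cell``; must satisfy the explicit
        stability bound (<= 0.5).
    infinite_dispersal : bool
        If set, cell dispersal events are skipped and the species
        fields are re-uniformised across space after every growth
        update, recovering the well-mixed limit.
    saturating_consumption : bool
        If set, mediator consumption is multiplied by
        ``C/(C+k_sat)`` so uptake vanishes with the stock; default is
        the plain ``-alpha_ji * S_i`` form with clamping of C at zero.
    implicit_diffusion : bool
        Use an unconditionally stable backward-Euler mediator-diffusion
        operator (one solve per dt) instead of the explicit stencil.
        Default False; the explicit scheme is the reference.
    mediator_dilution : str
        What happens to mediators at each transfer: "dilute" (same
        factor as cells, default), "retain" (carry over unchanged) or
        "reset" (set to zero).
    round_t_max : float
        Wall cap (simulated hours) for a single growth round; a round
        that has not reached DilTh by then is ended with generations
        computed from its realized fold-growth.
    max_rounds : int
        Safety cap on the number of dilution rounds.
    """

    D_cell: float = 5e-9
    D_med: float = 1.8e-2
    k_Y: float = 1e9
    k_sat: float = 1e4
    TID: float = 1e4
    ExtTh: float = 0.1
    DilTh: float = 1e7
    n_gen: float = 100.0
    dtau: float = 0.01
    dt_factor: float = 0.1
    dc_factor: float = 0.1
    Z: float = 0.5
    dz: float = 0.005
    infinite_dispersal: bool = False
    saturating_consumption: bool = False
    implicit_diffusion: bool = False
    mediator_dilution: str = "dilute"
    round_t_max: float = 2000.0
    max_rounds: int = 1000

    def __post_init__(self):
        bad = [k for k in ("D_cell", "D_med", "k_Y", "k_sat", "TID",
                           "ExtTh", "DilTh", "n_gen", "dtau",
                           "round_t_max")
               if getattr(self, k) <= 0]
        if bad:
            raise ConfigurationError(
                f"parameters must be positive: {', '.join(bad)}", keys=bad)
        if not (0 < self.dt_factor <= 0.5):
            raise ConfigurationError(
                f"dt_factor={self.dt_factor} violates the explicit "
                "stability bound (must be in (0, 0.5])", keys=["dt_factor"])
        if not (0 < self.dc_factor <= 0.5):
            raise ConfigurationError(
                f"dc_factor={self.dc_factor} violates the explicit "
                "stability bound (must be in (0, 0.5])", keys=["dc_factor"])
        if self.mediator_dilution not in ("dilute", "retain", "reset"):
            raise ConfigurationError(
                "mediator_dilution must be 'dilute', 'retain' or 'reset'",
                keys=["mediator_dilution"])
        self.grid  # validate Z/dz

    @property
    def grid(self) -> GridSpec:
        return GridSpec(Z=self.Z, dz=self.dz)

    @property
    def dt(self) -> float:
        """Mediator diffusion time-step, dt_factor * dz^2 / D_med (hr)."""
        return self.dt_factor * self.dz ** 2 / self.D_med

    @property
    def dc(self) -> float:
        """Cell dispersal time-step, dc_factor * dz^2 / D_cell (hr)."""
        return self.dc_factor * self.dz ** 2 / self.D_cell

    @property
    def dilution_factor(self) -> float:
        """Nominal fold-dilution per transfer, DilTh/TID."""
        return self.DilTh / self.TID

    def replace(self, **overrides) -> "SimulationConfig":
        """Return a copy with the named fields overridden.

        Unknown field names raise :class:`ConfigurationError` naming
        the offending keys; derived quantities (dt, dc) follow the new
        values automatically.
        """
        unknown = [k for k in overrides if k not in _CONFIG_FIELDS]
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {', '.join(sorted(unknown))}",
                keys=unknown)
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls().replace(**d)


def check_positive(**kwargs):
    """Raise ParameterError if any named value is not strictly positive."""
    bad = [k for k, v in kwargs.items() if not v > 0]
    if bad:
        raise ParameterError(f"expected positive values for: {', '.join(bad)}")
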