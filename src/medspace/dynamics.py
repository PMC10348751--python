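"""Reaction-diffusion dynamics of species and mediators in 1D.

The model couples, at every grid point z,

    dS_i/dt = D_cell d2S_i/dz2
              + (1 - sum_j S_j / k_Y)
                * [r0_i + sum_j rho_ij * g_ij(C_j)] * S_i
    dC_j/dt = D_med d2C_j/dz2 + sum_i (beta_ji - alpha_ji) * S_i

where the mediator response is linear for inhibitory links,
g = C/k_sat (rho < 0), and saturating for facilitative links,
g = C/(C + k_sat) (rho > 0).  No-flux boundaries hold at both ends for
species and mediators.

Time stepping is asynchronous: growth/uptake updates fire every
``dtau``, mediator diffusion every ``dt = 0.1 dz^2/D_med`` and cell
dispersal every ``dc = 0.1 dz^2/D_cell``, executed in time order with
the tie-break growth, then mediator diffusion, then cell dispersal.
The growth update is multiplicative, ``S <- S * exp(rate * dtau)``,
which preserves nonnegativity exactly; mediator concentrations are
clamped at zero after each uptake update.

Diffusion uses the standard explicit second-difference stencil with
reflecting boundaries.  Because consecutive diffusion events between
two growth updates compose linearly, the integrator applies the k-step
explicit update as a single cached matrix power A^k — the same linear
map as k successive stencil applications, evaluated in one BLAS call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._exceptions import IntegrationError, ParameterError
from .config import GridSpec, SimulationConfig
from .network import InteractionNetwork

__all__ = [
    "SpatialState", "WellMixedState", "Trajectory",
    "local_growth_rate", "step_growth", "step_diffusion",
    "advance", "simulate_well_mixed", "uniform_state", "well_mixed_state",
]

# densities below this are physically meaningless (ExtTh is 0.1 cells/ml)
# and are flushed to zero to keep the arithmetic out of subnormals
_FLUSH = 1e-30


@dataclass
class SpatialState:
    """Species and mediator fields over the 1D grid at one time point.

    S has shape (n_species, n_z) in cells/ml, C has shape
    (n_mediators, n_z) in fmol/ml.
    """

    S: np.ndarray
    C: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float)).copy()
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float)).copy()
        if self.S.shape[1] != self.C.shape[1]:
            raise ParameterError("S and C must share the grid dimension")

    @property
    def n_z(self) -> int:
        return self.S.shape[1]

    def species_mean(self) -> np.ndarray:
        """Spatially averaged density per species (cells/ml)."""
        return self.S.mean(axis=1)

    def total_mean(self) -> float:
        """Spatially averaged total community density (cells/ml)."""
        return float(self.S.sum() / self.n_z)

    def copy(self) -> "SpatialState":
        return SpatialState(self.S, self.C, self.t)


@dataclass
class WellMixedState:
    """Per-species densities and per-mediator concentrations, no space."""

    S: np.ndarray
    C: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float).reshape(-1).copy()
        self.C = np.asarray(self.C, dtype=float).reshape(-1).copy()

    def species_mean(self) -> np.ndarray:
        return self.S.copy()

    def total_mean(self) -> float:
        return float(self.S.sum())

    def copy(self) -> "WellMixedState":
        return WellMixedState(self.S, self.C, self.t)


@dataclass
class Trajectory:
    """Sampled states from one integration."""

    times: np.ndarray
    S: np.ndarray          # (n_samples, n_species, n_z) or (n, n_species)
    C: np.ndarray
    final: object = None   # SpatialState or WellMixedState

    def species_mean(self) -> np.ndarray:
        """Per-sample spatially averaged density, (n_samples, n_species)."""
        if self.S.ndim == 3:
            return self.S.mean(axis=2)
        return self.S.copy()


def uniform_state(network: InteractionNetwork, config: SimulationConfig,
                  density: Optional[float] = None) -> SpatialState:
    """Spatially uniform inoculum: every species at the same density
    everywhere (total spatial average = ``density``, default TID)."""
    tot = config.TID if density is None else density
    nz = config.grid.n_z
    S = np.full((network.n_species, nz), tot / network.n_species)
    C = np.zeros((network.n_mediators, nz))
    return SpatialState(S, C, 0.0)


def well_mixed_state(network: InteractionNetwork, config: SimulationConfig,
                     density: Optional[float] = None) -> WellMixedState:
    tot = config.TID if density is None else density
    S = np.full(network.n_species, tot / network.n_species)
    C = np.zeros(network.n_mediators)
    return WellMixedState(S, C, 0.0)


# ---------------------------------------------------------------------
# local kinetics


def local_growth_rate(S_column, C_column, network: InteractionNetwork,
                      config: SimulationConfig) -> np.ndarray:
    """Net per-capita growth rate of each species at one location (1/hr).

    Implements ``(1 - sum S/k_Y) * [r0 + sum_j rho * g(C_j)]`` with the
    saturating response for facilitative links and the linear response
    for inhibitory links.  May be negative.
    """
    S = np.asarray(S_column, dtype=float)
    C = np.asarray(C_column, dtype=float)
    if (S < 0).any() or (C < 0).any():
        raise ParameterError("densities and concentrations must be >= 0")
    rho_pos = np.clip(network.rho, 0.0, None)
    rho_neg = np.clip(network.rho, None, 0.0)
    infl = rho_pos @ (C / (C + config.k_sat)) + rho_neg @ (C / config.k_sat)
    return (1.0 - S.sum() / config.k_Y) * (network.r0 + infl)


# ---------------------------------------------------------------------
# diffusion


def _diffusion_matrix(n_z: int, lam: float) -> np.ndarray:
    """Dense one-step explicit diffusion operator with reflecting
    boundaries: A = I + lam * L, L the no-flux second difference."""
    A = np.zeros((n_z, n_z))
    idx = np.arange(n_z)
    A[idx, idx] = 1.0 - 2.0 * lam
    A[idx[:-1], idx[1:]] = lam
    A[idx[1:], idx[:-1]] = lam
    # reflecting boundaries: ghost node equals edge node
    A[0, 0] = 1.0 - lam
    A[-1, -1] = 1.0 - lam
    return A


def _implicit_diffusion_matrix(n_z: int, lam: float) -> np.ndarray:
    """Backward-Euler operator (I - lam*L)^-1; unconditionally stable,
    conserves mass (column sums of I - lam*L are 1)."""
    A = _diffusion_matrix(n_z, -lam)  # = I - lam*L
    return np.linalg.inv(A)


def step_diffusion(field, D: float, dt: float, grid: GridSpec) -> np.ndarray:
    """Advance one or more 1D fields one explicit diffusion step.

    ``field`` is (n_z,) or (n_fields, n_z).  Refuses to step when the
    stability bound ``D*dt/dz^2 <= 0.5`` is violated.  Total mass
    (sum over the grid) is conserved to rounding and nonnegativity is
    preserved under the bound.
    """
    f = np.atleast_2d(np.asarray(field, dtype=float))
    if f.shape[1] != grid.n_z:
        raise ParameterError(
            f"field has {f.shape[1]} points, grid has {grid.n_z}")
    lam = D * dt / grid.dz ** 2
    if lam > 0.5:
        raise ParameterError(
            f"explicit diffusion step unstable: D*dt/dz^2 = {lam:.3g} > 0.5")
    out = f.copy()
    out[:, 1:-1] += lam * (f[:, :-2] - 2.0 * f[:, 1:-1] + f[:, 2:])
    out[:, 0] += lam * (f[:, 1] - f[:, 0])
    out[:, -1] += lam * (f[:, -2] - f[:, -1])
    return out if np.asarray(field).ndim > 1 else out[0]


# ---------------------------------------------------------------------
# the asynchronous integrator


class _Kernel:
    """Precomputed arrays for one (network, config, grid) combination.

    Holds the split influence matrices, net production matrix, and the
    cached dense diffusion-operator powers used to batch the diffusion
    events that fall between two growth updates.
    """

    def __init__(self, network: InteractionNetwork,
                 config: SimulationConfig, n_z: int):
        self.network = network
        self.config = config
        self.n_z = n_z
        self.rho_pos = np.ascontiguousarray(np.clip(network.rho, 0.0, None))
        self.rho_neg = np.ascontiguousarray(np.clip(network.rho, None, 0.0))
        self.beta = network.beta
        self.alpha = network.alpha
        self.net_prod = network.beta - network.alpha
        self.r0 = network.r0[:, None]
        self.k_sat = config.k_sat
        self.inv_kY = 1.0 / config.k_Y
        self.dtau = config.dtau
        # events-per-growth-step ratios
        self.R_med = config.dtau / config.dt
        self.R_cell = config.dtau / config.dc
        dz2 = config.dz ** 2
        if config.implicit_diffusion:
            self._A_med = _implicit_diffusion_matrix(
                n_z, config.D_med * config.dt / dz2)
        else:
            self._A_med = _diffusion_matrix(
                n_z, config.D_med * config.dt / dz2)
        self._A_cell = _diffusion_matrix(
            n_z, config.D_cell * config.dc / dz2)
        self._pow_med = {}
        self._pow_cell = {}

    def med_operator(self, k: int) -> np.ndarray:
        """Transposed k-step mediator diffusion operator (A^k).T."""
        op = self._pow_med.get(k)
        if op is None:
            op = np.ascontiguousarray(
                np.linalg.matrix_power(self._A_med, k).T)
            self._pow_med[k] = op
        return op

    def cell_operator(self, k: int) -> np.ndarray:
        op = self._pow_cell.get(k)
        if op is None:
            op = np.ascontiguousarray(
                np.linalg.matrix_power(self._A_cell, k).T)
            self._pow_cell[k] = op
        return op

    def growth_update(self, S: np.ndarray, C: np.ndarray) -> None:
        """One dtau growth/uptake update, in place, spatial or 0D."""
        crowd = 1.0 - S.sum(axis=0) * self.inv_kY
        sat = C / (C + self.k_sat)
        infl = self.rho_pos @ sat + self.rho_neg @ (C / self.k_sat)
        rate = crowd * (self.r0 + infl)
        dC = self.net_prod @ S if not self.config.saturating_consumption \
            else self.beta @ S - (self.alpha @ S) * sat
        S *= np.exp(rate * self.dtau)
        C += dC * self.dtau
        np.maximum(C, 0.0, out=C)


def _check_finite(S, C, t):
    if not (np.isfinite(S).all() and np.isfinite(C).all()):
        bad = np.argwhere(~np.isfinite(S))
        where = tuple(bad[0]) if bad.size else \
            tuple(np.argwhere(~np.isfinite(C))[0])
        raise IntegrationError(
            f"non-finite field value at t={t:.4f} hr (index {where})",
            t=t, where=where)


def _integrate(S: np.ndarray, C: np.ndarray, kern: _Kernel, t0: float,
               t_target: float, spatial: bool,
               stop_density: Optional[float] = None,
               sample_every: Optional[float] = None,
               t_max: Optional[float] = None):
    """Advance fields in place from t0; returns (t_end, samples).

    Growth fires at t0 + g*dtau; diffusion events are batched between
    growth updates and applied as cached operator powers.  Stops after
    the first growth update at which the spatially averaged total
    density reaches ``stop_density``, or at ``t_target``/``t_max``.
    """
    cfg = kern.config
    dtau = cfg.dtau
    horizon = t_target if t_max is None else min(t_target, t0 + t_max)
    n_steps = max(int(math.ceil((horizon - t0) / dtau - 1e-9)), 1)
    inf_disp = cfg.infinite_dispersal and spatial
    # with uniform fields every diffusion operator is the identity, so
    # the infinite-dispersal mode skips them when C starts uniform
    skip_med = (not spatial) or (
        inf_disp and np.all(C == C[:, :1]))
    skip_cell = (not spatial) or inf_disp
    if inf_disp:
        S[:] = S.mean(axis=1, keepdims=True)

    inv_nz = 1.0 / S.shape[1] if spatial else 1.0
    samples = []
    next_sample = t0 + sample_every if sample_every else math.inf
    m_done = c_done = 0
    t = t0
    for g in range(1, n_steps + 1):
        if not skip_med:
            m_max = math.ceil(g * kern.R_med - 1e-12) - 1
            k = m_max - m_done
            if k > 0:
                C[:] = C @ kern.med_operator(k)
                m_done = m_max
        if not skip_cell:
            c_max = math.ceil(g * kern.R_cell - 1e-12) - 1
            k = c_max - c_done
            if k > 0:
                S[:] = S @ kern.cell_operator(k)
                c_done = c_max
        kern.growth_update(S, C)
        if inf_disp:
            S[:] = S.mean(axis=1, keepdims=True)
        t = t0 + g * dtau
        if g % 256 == 0:
            _check_finite(S, C, t)
            S[S < _FLUSH] = 0.0
        if t >= next_sample - 1e-9:
            samples.append((t, S.copy(), C.copy()))
            next_sample += sample_every
        if stop_density is not None and S.sum() * inv_nz >= stop_density:
            break
    _check_finite(S, C, t)
    S[S < _FLUSH] = 0.0
    return t, samples


def _run(state, network, config, t_target, *, spatial,
         sample_every=None, stop_density=None, t_max=None,
         kern: Optional[_Kernel] = None) -> Trajectory:
    if t_target <= state.t:
        raise ParameterError(
            f"t_target={t_target} must exceed state.t={state.t}")
    out = state.copy()
    S = out.S if spatial else out.S.reshape(-1, 1)
    C = out.C if spatial else out.C.reshape(-1, 1)
    if spatial and S.shape[1] != config.grid.n_z:
        raise ParameterError(
            f"state has {S.shape[1]} grid points, config grid has "
            f"{config.grid.n_z}")
    if kern is None:
        kern = _Kernel(network, config, S.shape[1])
    t_end, samples = _integrate(
        S, C, kern, out.t, t_target, spatial,
        stop_density=stop_density, sample_every=sample_every, t_max=t_max)
    out.S, out.C, out.t = (S, C, t_end) if spatial else \
        (S[:, 0], C[:, 0], t_end)
    if not samples or samples[-1][0] < t_end:
        samples.append((t_end, S.copy(), C.copy()))
    times = np.array([s[0] for s in samples])
    S_tr = np.stack([s[1] for s in samples])
    C_tr = np.stack([s[2] for s in samples])
    if not spatial:
        S_tr, C_tr = S_tr[:, :, 0], C_tr[:, :, 0]
    return Trajectory(times=times, S=S_tr, C=C_tr, final=out)


def step_growth(state, network: InteractionNetwork,
                config: SimulationConfig):
    """Advance a state by one growth/uptake step (dtau), no diffusion.

    Returns a new state of the same kind; S is updated multiplicatively
    from the local growth rates, C by net production, clamped at zero.
    """
    spatial = isinstance(state, SpatialState)
    out = state.copy()
    S = out.S if spatial else out.S.reshape(-1, 1)
    C = out.C if spatial else out.C.reshape(-1, 1)
    kern = _Kernel(network, config, S.shape[1])
    kern.growth_update(S, C)
    _check_finite(S, C, state.t + config.dtau)
    out.S, out.C = (S, C) if spatial else (S[:, 0], C[:, 0])
    out.t = state.t + config.dtau
    return out


def advance(state: SpatialState, network: InteractionNetwork,
            config: SimulationConfig, t_target: float,
            sample_every: Optional[float] = None,
            stop_density: Optional[float] = None) -> Trajectory:
    """Integrate a spatial state to ``t_target`` with the asynchronous
    scheme; returns a Trajectory sampled every ``sample_every`` hours
    (always including the final state).

    With ``config.infinite_dispersal`` the species fields are kept
    uniform across space after every growth update and dispersal events
    are skipped, recovering the well-mixed limit.
    """
    return _run(state, network, config, t_target, spatial=True,
                sample_every=sample_every, stop_density=stop_density)


def simulate_well_mixed(state: WellMixedState, network: InteractionNetwork,
                        config: SimulationConfig, t_target: float,
                        sample_every: Optional[float] = None,
                        stop_density: Optional[float] = None) -> Trajectory:
    """Integrate the well-mixed (no-space) reduction of the model with
    the same growth/uptake kinetics and dtau stepping."""
    return _run(state, network, config, t_target, spatial=False,
                sample_every=sample_every, stop_density=stop_density)
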