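"""Tests of the reaction-diffusion integrator and its reductions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import medspace as ms
from medspace.dynamics import (advance, local_growth_rate,
                               simulate_well_mixed, step_diffusion,
                               step_growth, uniform_state,
                               well_mixed_state)
from medspace.network import InteractionNetwork, generate_network


def _single_species(r0=0.2):
    return InteractionNetwork(rho=np.zeros((1, 1)), beta=np.zeros((1, 1)),
                              alpha=np.zeros((1, 1)), r0=np.array([r0]))


class TestLocalGrowthRate:
    def test_no_mediators_gives_basal_rate(self):
        net = generate_network(seed=4)
        cfg = ms.SimulationConfig()
        rate = local_growth_rate(np.full(net.n_species, 1.0),
                                 np.zeros(net.n_mediators), net, cfg)
        assert rate == pytest.approx(net.r0 * (1 - net.n_species / cfg.k_Y))

    def test_crowding_cap_zeroes_rate(self):
        net = generate_network(seed=4)
        cfg = ms.SimulationConfig()
        S = np.full(net.n_species, cfg.k_Y / net.n_species)
        C = np.full(net.n_mediators, 123.0)
        assert local_growth_rate(S, C, net, cfg) == pytest.approx(
            np.zeros(net.n_species), abs=1e-12)

    def test_saturating_facilitation_hand_value(self):
        # rho=0.2, C=k_sat, r0=0.1 -> 0.1 + 0.2 * 1/2 = 0.2
        net = InteractionNetwork(rho=np.array([[0.2]]),
                                 beta=np.zeros((1, 1)),
                                 alpha=np.array([[0.15]]),
                                 r0=np.array([0.1]))
        cfg = ms.SimulationConfig()
        rate = local_growth_rate(np.array([1.0]), np.array([cfg.k_sat]),
                                 net, cfg)
        assert rate[0] == pytest.approx(0.2, rel=1e-9)

    def test_negative_input_rejected(self):
        net = _single_species()
        with pytest.raises(ms.ParameterError):
            local_growth_rate(np.array([-1.0]), np.array([0.0]), net,
                              ms.SimulationConfig())


def test_exponential_growth_closed_form():
    """A lone species without interactions grows as S0*exp(r0*t)."""
    net = _single_species(0.2)
    cfg = ms.SimulationConfig(k_Y=1e30)
    tr = advance(uniform_state(net, cfg, density=1e4), net, cfg, 10.0)
    expected = 1e4 * math.exp(0.2 * 10.0)
    assert tr.final.species_mean()[0] == pytest.approx(expected, rel=1e-3)
    trw = simulate_well_mixed(well_mixed_state(net, cfg, density=1e4),
                              net, cfg, 10.0)
    assert trw.final.S[0] == pytest.approx(expected, rel=1e-3)


def test_growth_step_mediator_update():
    cfg = ms.SimulationConfig()
    nz = cfg.grid.n_z
    # no links: C untouched
    net0 = _single_species()
    st0 = ms.SpatialState(np.full((1, nz), 10.0), np.full((1, nz), 5.0))
    out0 = step_growth(st0, net0, cfg)
    assert np.array_equal(out0.C, st0.C)
    # one producer: dC = beta * S * dtau at occupied points only
    net = InteractionNetwork(rho=np.zeros((1, 1)),
                             beta=np.array([[0.1]]),
                             alpha=np.zeros((1, 1)), r0=np.array([0.1]))
    S = np.zeros((1, nz))
    S[0, :10] = 1e4
    out = step_growth(ms.SpatialState(S, np.zeros((1, nz))), net, cfg)
    assert out.C[0, :10] == pytest.approx(0.1 * 1e4 * cfg.dtau)
    assert not out.C[0, 10:].any()


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        grid = ms.GridSpec()
        f = np.full(grid.n_z, 3.7)
        out = step_diffusion(f, 1.8e-2, 1e-4, grid)
        assert out == pytest.approx(f, rel=1e-14)

    def test_stability_bound_refused(self):
        grid = ms.GridSpec()
        with pytest.raises(ms.ParameterError, match="unstable"):
            step_diffusion(np.ones(grid.n_z), 1.8e-2, 1.0, grid)

    def test_mass_conservation(self):
        """No-flux diffusion conserves total mass to <=1e-10 relative
        error over 1e4 explicit steps."""
        cfg = ms.SimulationConfig()
        grid = cfg.grid
        f = np.random.default_rng(0).random(grid.n_z) * 5.0
        m0 = f.sum()
        for _ in range(10**4):
            f = step_diffusion(f, cfg.D_med, cfg.dt, grid)
        assert abs(f.sum() - m0) / m0 < 1e-10
        assert (f >= 0).all()

    def test_cosine_eigenmode_decay(self):
        """cos(pi z/Z) decays as exp(-D (pi/Z)^2 t) within 1%."""
        cfg = ms.SimulationConfig()
        grid = cfg.grid
        D, dt = cfg.D_med, cfg.dt
        z = (np.arange(grid.n_z) + 0.5) * grid.dz
        mode = np.cos(np.pi * z / grid.Z)
        f = 1.0 + 0.5 * mode
        n = int(round(0.1 * grid.Z**2 / D / dt))
        for _ in range(n):
            f = step_diffusion(f, D, dt, grid)
        measured = (f - 1.0) / (0.5 * mode)
        predicted = math.exp(-D * (np.pi / grid.Z) ** 2 * (n * dt))
        assert measured == pytest.approx(predicted, rel=1e-2)


def test_uniform_initialization_matches_well_mixed():
    """With spatially uniform fields the PDE reduces to the well-mixed
    ODE: trajectories agree within 0.1% at all sampled times."""
    cfg = ms.SimulationConfig()
    for k in range(10):
        net = generate_network(fac_ratio=0.5 + 0.04 * k, seed=(21, k))
        trs = advance(uniform_state(net, cfg), net, cfg, 20.0,
                      sample_every=2.0)
        trw = simulate_well_mixed(well_mixed_state(net, cfg), net, cfg,
                                  20.0, sample_every=2.0)
        a, b = trs.species_mean(), trw.species_mean()
        assert np.allclose(a, b, rtol=1e-3, atol=1e-9)


def test_infinite_dispersal_matches_well_mixed_trajectory():
    net = generate_network(fac_ratio=0.9, seed=(22, 0))
    cfg = ms.SimulationConfig(infinite_dispersal=True)
    state = ms.initial_condition(net, cfg.grid, cfg)  # block inoculum
    trs = advance(state, net, cfg, 30.0, sample_every=5.0)
    trw = simulate_well_mixed(well_mixed_state(net, cfg), net, cfg, 30.0,
                              sample_every=5.0)
    assert np.allclose(trs.species_mean(), trw.species_mean(),
                       rtol=1e-3, atol=1e-9)
    # species field stays uniform across z
    assert np.ptp(trs.final.S, axis=1) == pytest.approx(
        np.zeros(net.n_species), abs=1e-6)


def test_no_dispersal_events_keep_spatial_support():
    """Default D_cell gives dc ~ 500 hr: no dispersal events fire within
    a round, so species never leave their initial blocks."""
    cfg = ms.SimulationConfig()
    assert cfg.dc > 400.0
    net = generate_network(seed=(23, 0))
    state = ms.initial_condition(net, cfg.grid, cfg)
    empty = state.S == 0.0
    tr = advance(state, net, cfg, 20.0)
    assert not tr.final.S[empty].any()


def test_grid_refinement_convergence():
    """Halving dz changes per-species abundances by < 2% at t=40 hr."""
    net = generate_network(fac_ratio=0.5, seed=(24, 0))
    results = []
    for dz in (0.005, 0.0025):
        cfg = ms.SimulationConfig(dz=dz)
        state = ms.initial_condition(net, cfg.grid, cfg)
        tr = advance(state, net, cfg, 40.0)
        results.append(tr.final.species_mean())
    coarse, fine = results
    scale = max(fine.max(), 1.0)
    assert np.abs(coarse - fine).max() / scale < 0.02


def test_implicit_diffusion_option():
    """The backward-Euler mediator-diffusion mode conserves mass and
    tracks the explicit scheme closely on a short run."""
    net = generate_network(fac_ratio=0.9, seed=(25, 0))
    finals = []
    for implicit in (False, True):
        cfg = ms.SimulationConfig(implicit_diffusion=implicit)
        state = ms.initial_condition(net, cfg.grid, cfg)
        finals.append(advance(state, net, cfg, 20.0).final)
    a, b = finals
    assert np.allclose(a.species_mean(), b.species_mean(), rtol=0.01)
    assert (b.C >= 0).all()


def test_advance_rejects_past_target():
    net = _single_species()
    cfg = ms.SimulationConfig()
    with pytest.raises(ms.ParameterError):
        advance(uniform_state(net, cfg), net, cfg, -1.0)


@settings(max_examples=10, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), fac=st.floats(0, 1))
def test_fields_stay_nonnegative_and_finite(seed, fac):
    net = generate_network(fac_ratio=fac, seed=seed)
    cfg = ms.SimulationConfig()
    state = ms.initial_condition(net, cfg.grid, cfg)
    tr = advance(state, net, cfg, 5.0)
    assert (tr.final.S >= 0).all() and (tr.final.C >= 0).all()
    assert np.isfinite(tr.final.S).all() and np.isfinite(tr.final.C).all()
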