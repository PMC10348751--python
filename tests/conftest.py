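"""Shared fixtures: paired ensembles reused across trend tests.

The heavy enrichment ensembles are session-scoped so each is computed
once; all use the same master seed, so every condition is paired with
every other through common random numbers (instance k always draws the
same base network).
"""

import numpy as np
import pytest

import medspace as ms
from medspace.experiments import instance_network, shuffle_experiment

# ensemble sizes (chosen for runtime; see docs/methods.md)
MASTER_SEED = 7
FAC_N = 40       # fac:inh ensembles, both modes
AUX_N = 32       # dispersal / mediator-diffusion / crowding ensembles
INF_N = 20       # infinite-dispersal vs well-mixed pairs
FAC_LEVELS = (0.1, 0.5, 0.9)


@pytest.fixture(scope="session")
def default_config():
    return ms.SimulationConfig()


def _richness_ensemble(config, n, mode, fac_ratio, master_seed=MASTER_SEED):
    out = []
    for k in range(n):
        net = instance_network(master_seed, k, fac_ratio=fac_ratio)
        out.append(ms.run_enrichment(net, config, mode=mode).richness)
    return np.array(out)


@pytest.fixture(scope="session")
def fac_ensembles(default_config):
    """Stable richness per instance for fac:inh in {10:90, 50:50, 90:10},
    spatial and well-mixed, paired instances."""
    return {
        (fac, mode): _richness_ensemble(default_config, FAC_N, mode, fac)
        for fac in FAC_LEVELS
        for mode in ("spatial", "well_mixed")
    }


@pytest.fixture(scope="session")
def dispersal_ensemble(default_config):
    """Spatial richness at intermediate dispersal (D_cell=5e-6 cm^2/hr),
    fac:inh=90:10; paired with fac_ensembles[(0.9, 'spatial')][:AUX_N]."""
    cfg = default_config.replace(D_cell=5e-6)
    return _richness_ensemble(cfg, AUX_N, "spatial", 0.9)


@pytest.fixture(scope="session")
def slow_mediator_ensemble(default_config):
    """Spatial richness at 100x reduced mediator diffusion, 90:10."""
    cfg = default_config.replace(D_med=1.8e-4)
    return _richness_ensemble(cfg, AUX_N, "spatial", 0.9)


@pytest.fixture(scope="session")
def crowding_ensemble(default_config):
    """Spatial richness with a 10x more restrictive local cap
    (k_Y=1e8 cells/ml), 90:10."""
    cfg = default_config.replace(k_Y=1e8)
    return _richness_ensemble(cfg, AUX_N, "spatial", 0.9)


@pytest.fixture(scope="session")
def infinite_dispersal_pairs(default_config, fac_ensembles):
    """(infinite-dispersal richness, well-mixed richness) on paired
    instances at 90:10."""
    inf = _richness_ensemble(default_config, INF_N, "infinite_dispersal",
                             0.9)
    wm = fac_ensembles[(0.9, "well_mixed")][:INF_N]
    return inf, wm


def _shuffle_set(config, n_networks, n_shuffles, *, fac_ratio=0.9,
                 qp=0.5, qc=0.5, mode="spatial"):
    results = []
    for k in range(n_networks):
        net = ms.generate_network(qp=qp, qc=qc, fac_ratio=fac_ratio,
                                  seed=(MASTER_SEED, k))
        results.append(shuffle_experiment(net, n_shuffles,
                                          seed=1000 + k, config=config,
                                          mode=mode))
    return results


@pytest.fixture(scope="session")
def shuffle_rich(default_config):
    """Position shuffles of interaction-rich (90:10) networks."""
    return _shuffle_set(default_config, 8, 8)


@pytest.fixture(scope="session")
def shuffle_inhibitory(default_config):
    """Position shuffles of mostly-inhibitory (10:90) networks."""
    return _shuffle_set(default_config, 5, 5, fac_ratio=0.1)


@pytest.fixture(scope="session")
def shuffle_zero_link(default_config):
    """Position shuffles of networks without any links."""
    return _shuffle_set(default_config, 3, 3, qp=0.0, qc=0.0)


@pytest.fixture(scope="session")
def shuffle_infinite_dispersal(default_config):
    """Position shuffles under infinite dispersal (positions erased)."""
    return _shuffle_set(default_config, 3, 3, mode="infinite_dispersal")
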