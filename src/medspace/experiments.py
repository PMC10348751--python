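"""Ensemble experiments: parameter sweeps with bootstrap statistics.

Each experimental condition is evaluated over an ensemble of random
community instances.  Instance k of every condition derives its network
from SeedSequence([master_seed, k]), so conditions are paired by common
random numbers: spatial and well-mixed runs of instance k share the
identical network, and two conditions differing only in, say, the
fac:inh ratio share every draw except the influence signs.  Mean
richness per condition is reported with a percentile-bootstrap 95%
confidence interval over instances (100 resamples).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, ParameterError
from .config import SimulationConfig
from .enrichment import run_enrichment
from .network import InteractionNetwork, generate_network

__all__ = [
    "InstanceOutcome", "SweepTable", "ShuffleResult",
    "instance_network", "run_ensemble", "sweep",
    "shuffle_experiment", "bootstrap_ci",
]

logger = logging.getLogger(__name__)

_NETWORK_PARAMS = ("n_species", "n_mediators", "qp", "qc", "fac_ratio",
                   "beta0", "alpha0", "rint0", "r0_range")
_MODES = ("spatial", "well_mixed", "infinite_dispersal")


@dataclass(frozen=True)
class InstanceOutcome:
    """Result of one enrichment instance within an ensemble."""

    instance: int
    seed: tuple
    richness: int
    richness_present: int
    shannon: float
    survivors: frozenset
    generations: float
    error: Optional[str] = None


@dataclass
class SweepTable:
    """Per-instance rows and per-condition aggregates of a sweep."""

    instances: pd.DataFrame
    aggregates: pd.DataFrame

    def to_csv(self, instances_path, aggregates_path):
        self.instances.to_csv(instances_path, index=False)
        self.aggregates.to_csv(aggregates_path, index=False)


@dataclass
class ShuffleResult:
    """Richness across random spatial rearrangements of one network."""

    baseline_richness: int
    richness: List[int]
    permutations: List[tuple]

    @property
    def fraction_differing(self) -> float:
        r = np.asarray(self.richness)
        return float((r != self.baseline_richness).mean())

    @property
    def spread(self) -> tuple:
        return (int(min(self.richness)), int(max(self.richness)))


def _split_condition(condition: Dict) -> tuple:
    """Split a condition dict into network kwargs and config overrides."""
    net_kw, cfg_kw = {}, {}
    base = SimulationConfig()
    for key, val in condition.items():
        if key in _NETWORK_PARAMS:
            net_kw[key] = val
        elif key == "mode":
            continue
        else:
            try:
                base.replace(**{key: val})
            except ConfigurationError:
                raise ConfigurationError(
                    f"unknown sweep parameter {key!r}", keys=[key])
            cfg_kw[key] = val
    return net_kw, cfg_kw


def instance_network(master_seed: int, instance: int,
                     **net_kwargs) -> InteractionNetwork:
    """The network of instance k under a master seed (paired across
    conditions and modes)."""
    return generate_network(seed=(int(master_seed), int(instance)),
                            **net_kwargs)


def run_ensemble(condition: Dict, n_instances: int, master_seed: int,
                 mode: str = "spatial",
                 config: Optional[SimulationConfig] = None,
                 ) -> List[InstanceOutcome]:
    """Run ``n_instances`` independent enrichment instances of one
    condition.

    ``condition`` maps parameter names (network-generation parameters
    or SimulationConfig fields) to values overriding the defaults.
    Failures of single instances are recorded in the outcome's
    ``error`` field, not raised.
    """
    if n_instances < 1:
        raise ParameterError("n_instances must be >= 1")
    if mode not in _MODES:
        raise ParameterError(f"unknown mode {mode!r}")
    net_kw, cfg_kw = _split_condition(condition)
    cfg = (config or SimulationConfig()).replace(**cfg_kw)
    outcomes = []
    for k in range(n_instances):
        net = instance_network(master_seed, k, **net_kw)
        try:
            res = run_enrichment(net, cfg, mode=mode)
            outcomes.append(InstanceOutcome(
                instance=k, seed=net.seed, richness=res.richness,
                richness_present=res.richness_present, shannon=res.shannon,
                survivors=res.survivors_stable,
                generations=res.generations))
        except Exception as exc:  # instance-level failure is not fatal
            logger.warning("instance %d failed: %s", k, exc)
            outcomes.append(InstanceOutcome(
                instance=k, seed=net.seed, richness=0, richness_present=0,
                shannon=float("nan"), survivors=frozenset(),
                generations=float("nan"), error=str(exc)))
    return outcomes


def bootstrap_ci(values, n_boot: int = 100, level: float = 0.95,
                 seed: int = 0) -> tuple:
    """Percentile bootstrap CI of the mean; returns (mean, lo, hi)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("bootstrap_ci needs at least 2 values")
    mean = float(v.mean())
    if np.ptp(v) == 0.0:  # degenerate sample: CI collapses to the mean
        return mean, mean, mean
    from scipy.stats import bootstrap as _bootstrap
    rng = np.random.default_rng(seed)
    res = _bootstrap((v,), np.mean, n_resamples=n_boot,
                     confidence_level=level, method="percentile",
                     random_state=rng)
    return mean, float(res.confidence_interval.low), \
        float(res.confidence_interval.high)


def _existing_rows(reuse: Optional[pd.DataFrame], condition: Dict,
                   mode: str, n_instances: int):
    """Instance rows of a completed (condition, mode) ensemble from an
    earlier sweep table, or None if the ensemble is incomplete."""
    if reuse is None or reuse.empty:
        return None
    sel = reuse[reuse["mode"].astype(str) == mode]
    for key, val in condition.items():
        if key not in sel.columns:
            return None
        sel = sel[sel[key].astype(str) == str(val)]
    if len(sel) != n_instances or \
            sorted(sel["instance"]) != list(range(n_instances)):
        return None
    return sel.sort_values("instance")


def sweep(parameter_grid: Dict[str, Sequence], n_instances: int,
          master_seed: int, modes: Sequence[str] = ("spatial",),
          config: Optional[SimulationConfig] = None,
          reuse_instances: Optional[pd.DataFrame] = None,
          progress=None) -> SweepTable:
    """Full-factorial sweep over named parameters and modes.

    Every condition runs the same instance seeds (paired design).
    Returns a SweepTable with one row per (condition, mode, instance)
    plus per-condition aggregates: mean richness with a bootstrap 95%
    CI, mean presence-only richness, mean Shannon index, and the count
    of failed instances (excluded from the means).  Pass an earlier
    instance table as ``reuse_instances`` to skip ensembles whose rows
    are already complete (resume); determinism makes the combined
    result identical to a fresh run.
    """
    for m in modes:
        if m not in _MODES:
            raise ParameterError(f"unknown mode {m!r}")
    names = list(parameter_grid)
    if any(len(parameter_grid[n]) == 0 for n in names):
        raise ParameterError("empty value list in parameter grid")
    # validate parameter names before running anything
    _split_condition({n: parameter_grid[n][0] for n in names})
    combos = list(itertools.product(*(parameter_grid[n] for n in names)))
    inst_rows, agg_rows = [], []
    for combo in combos:
        condition = dict(zip(names, combo))
        for mode in modes:
            cached = _existing_rows(reuse_instances, condition, mode,
                                    n_instances)
            if cached is not None:
                err = cached["error"].fillna("").astype(str) \
                    if "error" in cached else pd.Series([""] * len(cached))
                outcomes = [InstanceOutcome(
                    instance=int(r.instance), seed=(),
                    richness=int(r.richness),
                    richness_present=int(r.richness_present),
                    shannon=float(r.shannon),
                    survivors=frozenset(
                        int(s) for s in str(r.survivors).split(";")
                        if s not in ("", "nan")),
                    generations=float("nan"),
                    error=(e or None))
                    for r, e in zip(cached.itertuples(), err)]
            else:
                outcomes = run_ensemble(condition, n_instances, master_seed,
                                        mode=mode, config=config)
            ok = [o for o in outcomes if o.error is None]
            for o in outcomes:
                inst_rows.append({**condition, "mode": mode,
                                  "instance": o.instance,
                                  "richness": o.richness,
                                  "richness_present": o.richness_present,
                                  "shannon": o.shannon,
                                  "survivors": ";".join(map(str, sorted(o.survivors))),
                                  "error": o.error or ""})
            rich = [o.richness for o in ok]
            mean, lo, hi = (bootstrap_ci(rich, seed=master_seed)
                            if len(rich) >= 2 else
                            (float(np.mean(rich)) if rich else float("nan"),)
                            * 3)
            agg_rows.append({**condition, "mode": mode,
                             "mean_richness": mean,
                             "ci_lower": lo, "ci_upper": hi,
                             "mean_richness_present":
                                 float(np.mean([o.richness_present
                                                for o in ok]))
                                 if ok else float("nan"),
                             "mean_shannon":
                                 float(np.mean([o.shannon for o in ok]))
                                 if ok else float("nan"),
                             "n_instances": len(ok),
                             "n_failed": len(outcomes) - len(ok)})
            if progress is not None:
                progress(condition, mode)
    return SweepTable(instances=pd.DataFrame(inst_rows),
                      aggregates=pd.DataFrame(agg_rows))


def shuffle_experiment(network: InteractionNetwork, n_shuffles: int,
                       seed: int, config: Optional[SimulationConfig] = None,
                       grid=None, mode: str = "spatial") -> ShuffleResult:
    """Rerun one network with shuffled initial block positions.

    Runs the identity arrangement as baseline plus ``n_shuffles``
    random permutations of the species blocks, keeping the network
    itself fixed; reports richness per arrangement.
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    cfg = config or SimulationConfig()
    base = run_enrichment(network, cfg, grid=grid, mode=mode)
    rng = np.random.default_rng(seed)
    richness, perms = [], []
    for _ in range(n_shuffles):
        perm = tuple(int(i) for i in rng.permutation(network.n_species))
        res = run_enrichment(network, cfg, grid=grid,
                             initial_permutation=perm, mode=mode)
        richness.append(res.richness)
        perms.append(perm)
    return ShuffleResult(baseline_richness=base.richness,
                         richness=richness, permutations=perms)
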