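"""Configuration files, run manifests and result serialization.

Configs are YAML mappings with two optional sections, ``simulation``
(SimulationConfig fields) and ``network`` (network-generation
parameters).  Omitted keys take the standard defaults; unknown keys or
out-of-range values raise a validation error naming the offending keys.
"""

from __future__ import annotations

import datetime
import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from ._exceptions import ConfigurationError
from .config import SimulationConfig
from .dynamics import Trajectory
from .enrichment import EnrichmentResult

__all__ = [
    "load_config", "validate_config", "default_network_params",
    "write_manifest", "save_result", "save_trajectory", "load_trajectory",
]

_NETWORK_DEFAULTS = dict(n_species=10, n_mediators=5, qp=0.5, qc=0.5,
                         fac_ratio=0.5, beta0=0.1, alpha0=0.15, rint0=0.2,
                         r0_range=(0.1, 0.2))


def default_network_params() -> Dict:
    return dict(_NETWORK_DEFAULTS)


def validate_config(data: Optional[dict]) -> Tuple[SimulationConfig, Dict]:
    """Validate a parsed config mapping; returns (SimulationConfig,
    network-parameter dict) with defaults filled in."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = [k for k in data if k not in ("simulation", "network")]
    if unknown:
        raise ConfigurationError(
            f"unknown config sections: {', '.join(sorted(unknown))}",
            keys=unknown)
    sim_over = data.get("simulation") or {}
    net_over = data.get("network") or {}
    config = SimulationConfig().replace(**sim_over)  # raises naming keys
    bad = [k for k in net_over if k not in _NETWORK_DEFAULTS]
    if bad:
        raise ConfigurationError(
            f"unknown network parameters: {', '.join(sorted(bad))}",
            keys=bad)
    net = dict(_NETWORK_DEFAULTS)
    net.update(net_over)
    if isinstance(net["r0_range"], list):
        net["r0_range"] = tuple(net["r0_range"])
    return config, net


def load_config(path=None) -> Tuple[SimulationConfig, Dict]:
    """Load a YAML config file; a missing or empty file yields the
    standard defaults."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate_config(data)


def dump_config(config: SimulationConfig, net_params: Dict, path) -> None:
    payload = {"simulation": config.to_dict(),
               "network": {**net_params,
                           "r0_range": list(net_params["r0_range"])}}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_manifest(output_dir, *, config: SimulationConfig,
                   net_params: Dict, seed, outputs: Dict[str, str],
                   extra: Optional[Dict] = None) -> Path:
    """Write a RunManifest JSON sufficient to reproduce the run."""
    output_dir = Path(output_dir)
    manifest = {
        "medspace_version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "python": platform.python_version(),
        "seed": seed,
        "simulation": config.to_dict(),
        "network": {**net_params,
                    "r0_range": list(net_params["r0_range"])},
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    path = output_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def save_result(result: EnrichmentResult, output_dir,
                stem: str = "enrichment") -> Dict[str, str]:
    """Write an EnrichmentResult as JSON summary + per-round CSV."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    json_path = output_dir / f"{stem}.json"
    csv_path = output_dir / f"{stem}_rounds.csv"
    with open(json_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
    result.abundance_table().to_csv(csv_path, index=False)
    return {"summary": str(json_path), "rounds": str(csv_path)}


def save_trajectory(traj: Trajectory, path, *, config=None,
                    network=None) -> None:
    """Write trajectory snapshots to a chunked HDF5 container."""
    import h5py
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=traj.times)
        h5.create_dataset("S", data=traj.S, chunks=True)
        h5.create_dataset("C", data=traj.C, chunks=True)
        h5.attrs["medspace_version"] = __version__
        if config is not None:
            h5.attrs["config"] = json.dumps(config.to_dict())
        if network is not None:
            h5.attrs["network"] = network.to_json()


def load_trajectory(path) -> Trajectory:
    import h5py
    with h5py.File(path, "r") as h5:
        return Trajectory(times=np.asarray(h5["time"]),
                          S=np.asarray(h5["S"]),
                          C=np.asarray(h5["C"]))
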