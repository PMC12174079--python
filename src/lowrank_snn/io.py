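"""Configuration files, result serialization, fixtures, and seed handling.

Conventions: spike trains go to CSV (interoperable), dense traces to
compressed NPZ, summaries to JSON, and every experiment directory receives a
``manifest.json`` written last (atomic completion marker) that echoes the
resolved configuration and inventories the files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .params import BiophysicalParameters, ParameterError
from .connectivity import (ConnectivityConfig, ConnectivitySet,
                           LowRankStructure, assemble_connectivity)
from .simulation import ReadoutConfig, SimulationConfig

log = logging.getLogger("lowrank_snn")

__all__ = [
    "ExperimentConfig", "ConfigError", "load_config", "dump_config",
    "config_hash", "make_fixture", "write_results", "spawn_seeds",
]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "params": BiophysicalParameters,
    "connectivity": ConnectivityConfig,
    "simulation": SimulationConfig,
    "readout": ReadoutConfig,
}


@dataclass
class ExperimentConfig:
    params: BiophysicalParameters = field(default_factory=BiophysicalParameters)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    experiment: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        return {
            **{name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS},
            "experiment": dict(self.experiment),
            "seed": self.seed,
            "outdir": self.outdir,
        }


def _build_section(name: str, payload: dict):
    cls = _SECTIONS[name]
    fields = set(cls.__dataclass_fields__)
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    try:
        return cls(**payload)
    except (TypeError, ValueError, ParameterError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def load_config(path) -> ExperimentConfig:
    """Read a YAML experiment config; omitted fields take the model defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(_SECTIONS) | {"experiment", "seed", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name in _SECTIONS:
        payload = raw.get(name) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, payload)
    return ExperimentConfig(
        experiment=raw.get("experiment") or {},
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "results")),
        **kwargs,
    )


def dump_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def spawn_seeds(master_seed: int, n: int, stream: int = 0):
    """Counter-based seed derivation: adding streams/trials never perturbs
    earlier draws."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(stream,))
    return ss.spawn(n)


FIXTURE_KINDS = ("two_neuron", "five_neuron_ring", "gamma_small")


def make_fixture(kind: str, seed: int = 0, outdir=None):
    """Deterministic tiny networks for unit tests.

    two_neuron: one E->E synapse of weight 0.5 (neuron 0 -> neuron 1), one
    silent inhibitory cell.  five_neuron_ring: five excitatory neurons in a
    directed ring of weight 0.5.  gamma_small: a 200-neuron network
    (N_E=160, N_I=40) preserving the gamma operating point's block means.
    Returns (ConnectivitySet, BiophysicalParameters); with ``outdir`` the
    bundle (connectivity NPZ + config YAML) is also written to disk.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected {FIXTURE_KINDS}")
    cfg = ConnectivityConfig()
    if kind == "two_neuron":
        params = BiophysicalParameters(N_E=2, N_I=1)
        lr = LowRankStructure(m=np.array([1.0, 0.0]), n=np.array([0.0, 1.0]),
                              sigma_lr=cfg.sigma_lr)
        conn = ConnectivitySet(
            J_EE=np.array([[0.0, 0.0], [0.5, 0.0]]),
            J_EI=np.zeros((2, 1)), J_IE=np.zeros((1, 2)), J_II=np.zeros((1, 1)),
            lowrank=lr, config=cfg)
    elif kind == "five_neuron_ring":
        params = BiophysicalParameters(N_E=5, N_I=1)
        J = np.zeros((5, 5))
        for i in range(5):
            J[(i + 1) % 5, i] = 0.5
        lr = LowRankStructure(m=np.eye(5)[0], n=np.eye(5)[1], sigma_lr=cfg.sigma_lr)
        conn = ConnectivitySet(J_EE=J, J_EI=np.zeros((5, 1)),
                               J_IE=np.zeros((1, 5)), J_II=np.zeros((1, 1)),
                               lowrank=lr, config=cfg)
    else:  # gamma_small
        params = BiophysicalParameters(N_E=160, N_I=40)
        conn = assemble_connectivity(cfg, params.N_E, params.N_I,
                                     np.random.default_rng(seed))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        conn.save_npz(outdir / f"{kind}_connectivity.npz")
        exp = ExperimentConfig(params=params, connectivity=cfg,
                               experiment={"fixture": kind}, seed=seed,
                               outdir=str(outdir))
        dump_config(exp, outdir / f"{kind}_config.yaml")
    return conn, params


def _default_json(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(outdir, experiment: str, cfg: ExperimentConfig,
                  artifacts: Optional[Dict[str, object]] = None,
                  seeds=None) -> Path:
    """Write artifacts and the manifest (last, as completion marker).

    Artifact dispatch by type: pandas DataFrame -> CSV, dict of arrays /
    ndarray -> NPZ, everything JSON-serializable -> JSON.
    """
    import pandas as pd
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in (artifacts or {}).items():
        if isinstance(obj, pd.DataFrame):
            fn = outdir / f"{name}.csv"
            obj.to_csv(fn, index=False)
        elif isinstance(obj, np.ndarray):
            fn = outdir / f"{name}.npz"
            np.savez_compressed(fn, **{name: obj})
        elif isinstance(obj, dict) and obj and all(
                isinstance(v, np.ndarray) for v in obj.values()):
            fn = outdir / f"{name}.npz"
            np.savez_compressed(fn, **obj)
        else:
            fn = outdir / f"{name}.json"
            fn.write_text(json.dumps(obj, indent=2, default=_default_json))
        files.append(fn.name)
    dump_config(cfg, outdir / "config.yaml")
    files.append("config.yaml")
    manifest = dict(
        experiment=experiment,
        package_version=_package_version(),
        config_hash=config_hash(cfg),
        files=sorted(files),
        seeds=[int(s) for s in np.atleast_1d(seeds)] if seeds is not None else [cfg.seed],
    )
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=_default_json))
    log.info("wrote %d artifact(s) to %s", len(files), outdir)
    return mpath


def _package_version() -> str:
    try:
        from importlib.metadata import version
        return version("lowrank-snn")
    except Exception:
        return "unknown"
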