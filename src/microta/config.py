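"""Configuration files, validation, and run manifests.

Simulation configs are flat YAML key/value files; every key is optional and
defaults to the base-model parameterization (k_a = 4.2 /min, k_b = k_u =
0.1, lambda_max = ln 2 / 30 /min, alpha = 0.1, dt = 0.5 min, onset at 100
min, end at 250 min).  Unknown keys are rejected so typos cannot silently
fall back to defaults.

Every run can write a manifest alongside its outputs recording the fully
resolved configuration, the seed, the package version, wall times, and the
emitted files with checksums; re-running from a manifest's config and seed
reproduces stochastic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from .kinetics import GrowthLaw, RateParameters
from .population import SimulationConfig

__all__ = ["load_config", "config_to_dict", "config_from_dict",
           "save_config", "RunManifest", "write_manifest", "load_manifest"]

_RATE_KEYS = {"k_t", "k_a", "k_b", "k_u", "d_a", "k_on", "k_off"}
_LAW_KEYS = {"lambda_max", "alpha"}
_TOP_KEYS = {"dt", "t_onset", "t_end", "n_replicates", "seed", "variant",
             "initial_antitoxin", "population_cap", "record",
             "arrest_cutoff_per_hour"}


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a flat mapping."""
    unknown = set(data) - _RATE_KEYS - _LAW_KEYS - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        rates = RateParameters(**{k: v for k, v in data.items()
                                  if k in _RATE_KEYS})
        law = GrowthLaw(**{k: v for k, v in data.items() if k in _LAW_KEYS})
        return SimulationConfig(rates=rates, law=law,
                                **{k: v for k, v in data.items()
                                   if k in _TOP_KEYS})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a config back to the plain key/value form (round-trips)."""
    out = dataclasses.asdict(config.rates)
    out.update(dataclasses.asdict(config.law))
    for key in sorted(_TOP_KEYS):
        out[key] = getattr(config, key)
    return out


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML key/value config file.

    An empty file yields the full default (base-model) configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a key/value mapping")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to a run's outputs."""

    config: dict
    seed: int
    version: str
    started: float
    finished: float
    outputs: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(out_dir, config: SimulationConfig, seed: int,
                   outputs: Sequence[str], started: float,
                   finished: Optional[float] = None) -> Path:
    """Write ``manifest.json`` into ``out_dir`` listing every output file."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in outputs:
        p = out_dir / name
        entries.append({"file": name, "sha256": _sha256(p),
                        "bytes": p.stat().st_size})
    manifest = RunManifest(config=config_to_dict(config), seed=int(seed),
                           version=__version__, started=started,
                           finished=finished if finished is not None
                           else time.time(), outputs=entries)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest.to_dict(), indent=2, default=str))
    return path


def load_manifest(path) -> RunManifest:
    """Load a manifest; a manifest without a seed is rejected (no replay)."""
    data = json.loads(Path(path).read_text())
    if data.get("seed") is None:
        raise ValueError("manifest has no seed; run cannot be replayed")
    return RunManifest(**data)
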