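"""Configuration files, result serialization and run provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from apraxim.battery import PerformanceMatrix, ClinicalProfile
from apraxim.lesions import LesionSpec
from apraxim.world import ConfigurationError, WorldConfig

__all__ = [
    "load_experiment_config",
    "config_hash",
    "matrices_to_frame",
    "write_results_csv",
    "read_results_csv",
    "write_profile_json",
]

_RESULT_COLUMNS = ["lesion_site", "severity", "task", "n_trials", "accuracy", "seed"]


def load_experiment_config(path: str | Path) -> dict:
    """Parse a YAML experiment config into world/lesion/battery pieces.

    Recognized keys: ``world`` (WorldConfig fields), ``lesions`` (list of
    ``{site, severity}``) and ``battery`` (``n_trials``, ``seed``).
    Unknown keys raise, naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"world", "lesions", "battery"}
    for key in raw:
        if key not in known:
            raise ConfigurationError(f"unknown config key {key!r}")
    world_kwargs = raw.get("world", {}) or {}
    valid = {f.name for f in dataclasses.fields(WorldConfig)}
    for key in world_kwargs:
        if key not in valid:
            raise ConfigurationError(f"unknown world config key {key!r}")
    world = WorldConfig(**world_kwargs)
    lesions = [LesionSpec(item["site"], float(item.get("severity", 1.0)))
               for item in raw.get("lesions", []) or []]
    battery = {"n_trials": int(raw.get("battery", {}).get("n_trials", 200)),
               "seed": int(raw.get("battery", {}).get("seed", 0))}
    return {"world": world, "lesions": lesions, "battery": battery}


def config_hash(world: WorldConfig, battery: dict) -> str:
    """Stable hash of the run configuration, for the provenance log."""
    payload = json.dumps(
        {"world": dataclasses.asdict(world), "battery": battery}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def matrices_to_frame(matrices: list[PerformanceMatrix]) -> pd.DataFrame:
    rows = []
    for m in matrices:
        site = m.lesion.site.value if m.lesion is not None else "intact"
        severity = m.lesion.severity if m.lesion is not None else 0.0
        for task, acc in m.accuracies.items():
            rows.append({"lesion_site": site, "severity": severity, "task": task,
                         "n_trials": m.n_trials, "accuracy": acc, "seed": m.seed})
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results_csv(matrices: list[PerformanceMatrix], path: str | Path) -> None:
    matrices_to_frame(matrices).to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profile_json(profiles: dict[str, ClinicalProfile], path: str | Path) -> None:
    payload = {
        site: {
            "label": p.label,
            "impaired": p.impaired,
            "spared": p.spared,
            "accuracies": p.accuracies,
        }
        for site, p in profiles.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
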