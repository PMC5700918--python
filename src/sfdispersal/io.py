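"""Readers, writers and run manifests.

All tabular outputs are tidy CSVs with fixed column sets so that every file
the package writes can be re-read losslessly by the package's own readers.
Configuration files are YAML mappings mirroring the dataclass fields.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ibm import ScenarioConfig, TransitionRates, RESULT_COLUMNS, SCENARIO_IDS
from .synthetic import (BIOASSAY_COLUMNS, TRACK_COLUMNS, BioassayDesign,
                        BioassayParams)


# ---------------------------------------------------------------------------
# Bioassay / track tables
# ---------------------------------------------------------------------------

def write_bioassay_csv(records: pd.DataFrame, path: str | Path) -> None:
    records[BIOASSAY_COLUMNS].to_csv(path, index=False)


def read_bioassay_csv(path: str | Path) -> pd.DataFrame:
    from .stats import validate_bioassay

    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty bioassay table")
    validate_bioassay(df)
    return df[BIOASSAY_COLUMNS]


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks[TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: track table missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty track table")
    bad = df.index[(df[TRACK_COLUMNS[2:]] < 0).any(axis=1)].tolist()
    if bad:
        raise ValueError(f"{path}: negative endpoints in rows {bad}")
    return df[TRACK_COLUMNS]


def write_results_csv(results: pd.DataFrame, path: str | Path) -> None:
    results[RESULT_COLUMNS].to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: results table missing columns {missing}")
    return df[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key: value mapping")
    return cfg


def design_from_config(cfg: dict) -> BioassayDesign:
    kw = {k: cfg[k] for k in ("n_blocks", "larvae_per_plant") if k in cfg}
    for k in ("strains", "varieties", "intervals_h"):
        if k in cfg:
            kw[k] = tuple(cfg[k])
    return BioassayDesign(**kw)


def params_from_config(cfg: dict) -> BioassayParams:
    kw = {}
    if "survival_logit" in cfg:
        kw["survival_logit"] = {s: tuple(v) for s, v in cfg["survival_logit"].items()}
    for name in ("on_plant_prob", "fed_given_on_prob", "fed_given_off_prob"):
        if name in cfg:
            # YAML keys "SS,6" -> tuple keys
            table = {}
            for key, v in cfg[name].items():
                a, b = (x.strip() for x in str(key).split(","))
                table[(a, int(b) if b.isdigit() else b)] = float(v)
            kw[name] = table
    if "seed" in cfg:
        kw["seed"] = cfg["seed"]
    return BioassayParams(**kw)


def scenario_from_config(cfg: dict, scenario: str | None = None,
                         seed: int | None = None) -> ScenarioConfig:
    kw = dict(cfg)
    rates = kw.pop("rates", None)
    if rates is not None:
        kw["rates"] = TransitionRates(**rates)
    if scenario is not None:
        from .ibm import _BATTERY_SPEC

        if scenario not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario {scenario!r}; choose from {list(SCENARIO_IDS)}")
        dom, frac = _BATTERY_SPEC[scenario]
        kw.update(scenario=scenario, dominant=dom, contamination=frac)
    if seed is not None:
        kw["seed"] = seed
    return ScenarioConfig(**kw)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(out_dir: str | Path, command: str, config: dict,
                   seed: int | None, outputs: list[str]) -> Path:
    """Record what a run did: command, config snapshot, master seed, package
    version, timestamp and the files written.  Re-running with the recorded
    config and seed reproduces the CSV payloads byte-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if hasattr(obj, "__dataclass_fields__"):
            return _clean(asdict(obj))
        return obj

    manifest = {
        "command": command,
        "config": _clean(config),
        "seed": seed,
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": outputs,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
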