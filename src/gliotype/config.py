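"""YAML pipeline configuration: schema, defaults and fail-fast validation."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["ConfigError", "load_pipeline_config", "config_hash", "DEFAULTS"]


class ConfigError(Exception):
    """Invalid pipeline configuration (exit code 2)."""


#: section -> {key: default}; None means required-if-section-present
DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_samples": 400,
        "n_genes": 2000,
        "n_subtypes": 4,
        "subtype_prevalence": [0.40, 0.25, 0.20, 0.15],
        "n_informative_genes": 200,
        "effect_size": 2.0,
        "censoring_rate": 0.30,
    },
    "input": {
        "expression": None,
        "clinical": None,
        "mutations": None,
        "purity": None,
    },
    "dbu": {
        "n_iterations": 100,
        "genes_per_iteration": 500,
        "n_neighbors": 5,
        "min_dist": 0.0,
        "metric": "manhattan",
        "min_points": 25,
        "eps": "auto",
        "expected_groups": "auto",
        "ambiguity_threshold": 0.70,
        "subcluster": True,
    },
    "signature": {
        "n_select": 40,
        "curated": [],
        "n_groups": 6,
        "candidate_pool": None,
        "step": 5,
    },
    "dictionary": {
        "n_models": 200,
        "step": 5,
        "cv_folds": 3,
        "floor": 0.95,
    },
    "ensemble": {
        "n_folds": 4,
    },
    "characterize": {
        "compare": None,  # "truth" (simulated cohorts) or a labels TSV path
        "reference_group": None,
    },
}

_TOP_KEYS = {"seed", "out_dir", *DEFAULTS.keys()}


def _check_keys(section: str, block: dict) -> None:
    allowed = set(DEFAULTS[section])
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")


def load_pipeline_config(path: str | Path) -> dict:
    """Load and validate a pipeline YAML; returns config with defaults filled."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "simulate" in raw and "input" in raw:
        raise ConfigError("give either 'simulate' or 'input', not both")
    if "simulate" not in raw and "input" not in raw:
        raise ConfigError("one of 'simulate' or 'input' is required")

    cfg: dict = {
        "seed": raw.get("seed", 0),
        "out_dir": raw.get("out_dir", "gliotype_out"),
    }
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")

    for section, defaults in DEFAULTS.items():
        if section in ("simulate", "input") and section not in raw:
            continue
        block = raw.get(section, {}) or {}
        if not isinstance(block, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        _check_keys(section, block)
        cfg[section] = {**defaults, **block}

    if "input" in cfg:
        for key in ("expression", "clinical"):
            if not cfg["input"].get(key):
                raise ConfigError(f"input.{key} is required when using 'input'")
        for key, value in cfg["input"].items():
            if value is not None and not Path(value).exists():
                raise ConfigError(f"input.{key} does not exist: {value}")
    compare = cfg["characterize"].get("compare")
    if compare not in (None, "truth") and not Path(compare).exists():
        raise ConfigError(f"characterize.compare file does not exist: {compare}")
    if "input" in cfg and compare == "truth":
        raise ConfigError("characterize.compare='truth' requires a simulated cohort")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
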