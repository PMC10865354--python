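"""YAML pipeline configuration: schema, defaults and validation.

The config file defines the pipeline architecture — search mode and
schedule, the parameter value ranges to explore, the matching-sphere
perturbation settings, the significance level and the backend — in the
spirit of a dockopt_config.yaml.  Validation is strict: unknown keys are
rejected, and all defaults are materialized explicitly into the effective
config that gets saved next to the results, so a run is fully described
by that one file.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "save_config", "parameter_pool"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "criterion": "normalized_logauc",
    "search": {
        "mode": "beam",  # beam | grid
        "top_fraction": 0.2,
        "max_beam_width": 5,
        "zoom_factor": 2.0,
        "n_steps": 3,
        "early_stopping": {"enabled": False, "patience": 2, "min_delta": 0.0},
        # optional nested step-sequence declaration (list of phase mappings,
        # possibly embedding {"sequence": [...], "iterate": k}); overrides
        # the single-run n_steps schedule when set
        "sequence": None,
    },
    # value pools: {"low","high","n"} for an evenly spaced numeric range,
    # {"values": [...]} for an explicit numeric pool, {"choices": [...]} for
    # categorical values.
    "parameters": {
        "electrostatic_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 4},
        "desolvation_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 4},
    },
    "matching_spheres_perturbation": {
        "enabled": True,
        "radius": 0.4,
        "counts_per_step": [10, 25, 50],
    },
    "significance": {"p_value": 0.01, "null_reps": 100_000},
    "backend": {
        "name": "oracle",
        "oracle": {
            "sigma": 0.5,
            "signal": 5.0,
            "noise_sd": 1.0,
            "charge_offset": 0.0,
            # null => hidden optimum drawn from the master seed within the
            # parameter bounds; set explicitly to pin it.
            "theta_opt": None,
            # null => hotspots at the base matching-sphere centers
            "hotspots": None,
        },
    },
    "executor": {"workers": 1, "retries": 0},
    "report": {"top_k": 3},
    "paths": {"sphere_file": None},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults and path not in ("parameters",):
            raise ValueError(f"unknown config key: {here!r}")
        if (
            isinstance(value, dict)
            and isinstance(defaults.get(key), dict)
            and path != "parameters"
            and key != "parameters"
        ):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _validate(cfg: dict) -> None:
    mode = cfg["search"]["mode"]
    if mode not in ("beam", "grid"):
        raise ValueError(f"search.mode must be 'beam' or 'grid', got {mode!r}")
    if not 0 < cfg["search"]["top_fraction"] <= 1:
        raise ValueError("search.top_fraction must be in (0, 1]")
    if cfg["search"]["n_steps"] < 1:
        raise ValueError("search.n_steps must be >= 1")
    if cfg["search"]["sequence"] is not None:
        from screenopt.search import flatten_sequence

        flatten_sequence(cfg["search"]["sequence"])  # depth/shape validation
    if not cfg["parameters"]:
        raise ValueError("at least one searchable parameter is required")
    for name, spec in cfg["parameters"].items():
        parameter_pool(name, spec)
    pert = cfg["matching_spheres_perturbation"]
    if pert["radius"] < 0:
        raise ValueError("matching_spheres_perturbation.radius must be >= 0")
    if len(pert["counts_per_step"]) < 1:
        raise ValueError("matching_spheres_perturbation.counts_per_step must be non-empty")
    if not 0 < cfg["significance"]["p_value"] <= 1:
        raise ValueError("significance.p_value must be in (0, 1]")


def parameter_pool(name: str, spec) -> tuple[str, list]:
    """Normalize one parameter spec to ('numeric'|'categorical', pool list)."""
    if isinstance(spec, list):
        return "numeric", list(spec)
    if not isinstance(spec, dict):
        raise ValueError(f"parameter {name!r}: spec must be a list or mapping")
    if "choices" in spec:
        if not spec["choices"]:
            raise ValueError(f"parameter {name!r}: empty choices")
        return "categorical", list(spec["choices"])
    if "values" in spec:
        if not spec["values"]:
            raise ValueError(f"parameter {name!r}: empty values")
        return "numeric", [float(v) for v in spec["values"]]
    if {"low", "high", "n"} <= set(spec):
        n = int(spec["n"])
        if n < 1 or spec["high"] < spec["low"]:
            raise ValueError(f"parameter {name!r}: invalid range spec")
        import numpy as np

        return "numeric", np.linspace(spec["low"], spec["high"], n).tolist()
    raise ValueError(
        f"parameter {name!r}: expected 'values', 'choices' or 'low'/'high'/'n', got {sorted(spec)}"
    )


def load_config(source: str | Path | dict | None = None) -> dict:
    """Load and validate a config, materializing every default explicitly."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    _validate(cfg)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    """Write the effective (fully materialized) config as YAML."""
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
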