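"""Run-configuration loading and validation.

A run config is a YAML mapping with the simulator parameters (grid,
design, endmember band models, scatter), the preprocessing variant, the
regression model, the repeat count, the evaluation ranges and one master
seed. The packaged ``config/default.yaml`` holds the study defaults.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .errors import ValidationError
from .grid import WavenumberGrid
from .preprocess import PREPROCESSING_VARIANTS
from .synth import Band, EndmemberModel, ScatterParams

__all__ = [
    "load_config",
    "default_config",
    "grid_from_config",
    "endmember_from_config",
    "scatter_from_config",
]

_MODELS = ("svm_linear", "pls")


def default_config() -> dict:
    """The packaged default run configuration."""
    ref = importlib.resources.files("nutshell") / "config" / "default.yaml"
    return validate_config(yaml.safe_load(ref.read_text()))


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a YAML run config; None gives the default."""
    if path is None:
        return default_config()
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    for key in ("seed", "grid", "design", "endmembers", "scatter",
                "preprocessing", "model", "n_repeats", "evaluation"):
        if key not in cfg:
            raise ValidationError(f"config missing required key {key!r}")
    if not isinstance(cfg["seed"], int):
        raise ValidationError("config seed must be an integer")
    if cfg["preprocessing"] not in PREPROCESSING_VARIANTS:
        raise ValidationError(
            f"preprocessing must be one of {PREPROCESSING_VARIANTS}")
    if cfg["model"] not in _MODELS:
        raise ValidationError(f"model must be one of {_MODELS}")
    for role in ("nutmeg", "shell"):
        if role not in cfg["endmembers"]:
            raise ValidationError(f"endmembers config missing {role!r}")
    return cfg


def grid_from_config(cfg: dict) -> WavenumberGrid:
    g = cfg["grid"]
    return WavenumberGrid(start=float(g["start"]), stop=float(g["stop"]),
                          step=float(g["step"]))


def endmember_from_config(cfg: dict, role: str) -> EndmemberModel:
    e = cfg["endmembers"][role]
    bands = tuple(Band(center=float(b["center"]), width=float(b["width"]),
                       amplitude=float(b["amplitude"])) for b in e["bands"])
    return EndmemberModel(
        role=role, bands=bands,
        baseline_offset=float(e.get("baseline_offset", 0.0)),
        baseline_slope=float(e.get("baseline_slope", 0.0)),
        population_sd=float(e.get("population_sd", 0.0)))


def scatter_from_config(cfg: dict) -> ScatterParams:
    s = cfg["scatter"]
    return ScatterParams(sigma_b=float(s.get("sigma_b", 0.0)),
                         sigma_a=float(s.get("sigma_a", 0.0)),
                         sigma_eps=float(s.get("sigma_eps", 0.0)),
                         replicates=int(s.get("replicates", 5)))
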