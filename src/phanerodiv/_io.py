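"""YAML round-tripping for model and decay parameter files."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .engine import ModelParams
from .transects import DecayParams

_PARAM_KEYS = {
    "ode_step_myr": "ode_step",
    "model": "model_kind",
}


def load_model_params(path: str | Path) -> ModelParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    for k, v in raw.items():
        k = _PARAM_KEYS.get(k, k)
        if isinstance(v, list):
            v = tuple(v)
        kw[k] = v
    return ModelParams(**kw)


def save_model_params(params: ModelParams, path: str | Path) -> None:
    d = dataclasses.asdict(params)
    d["temp_quantiles"] = list(d["temp_quantiles"])
    d["poc_quantiles"] = list(d["poc_quantiles"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_decay_params(path: str | Path) -> DecayParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DecayParams(**raw)


def save_decay_params(params: DecayParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh)
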