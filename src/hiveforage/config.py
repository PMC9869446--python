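"""Configuration handling: named parameter sets for model runs.

A config is a flat mapping with the conventional parameter names
``T, N, K, m, alpha, beta, s, q, r, survival`` (plus the optional
``initial_stores``), readable from YAML or JSON.  ``steps`` is accepted as
an alias of ``T`` — they are one and the same horizon parameter — and a
config giving both with different values is rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .colony import ColonyParams
from .learning import LearningCurveParams

__all__ = ["DEFAULTS", "params_from_dict", "load_config", "echo_config"]

#: Default parameter values of the foraging model.
DEFAULTS: dict[str, float] = {
    "T": 100,
    "N": 100,
    "K": 100.0,
    "m": 10.0,
    "alpha": 0.45,
    "beta": 10.0,
    "s": 50.0,
    "q": 30.0,
    "r": 0.0,
    "survival": 1.0,
    "initial_stores": 0.0,
}

_COLONY_KEYS = {"N", "r", "q", "T", "survival", "initial_stores"}
_LEARNING_KEYS = {"K", "m", "alpha", "beta", "s"}


def params_from_dict(cfg: dict) -> tuple[ColonyParams, LearningCurveParams]:
    """Build validated parameter objects from a flat config mapping."""
    cfg = dict(cfg)
    if "steps" in cfg:
        steps = cfg.pop("steps")
        if "T" in cfg and cfg["T"] != steps:
            raise ValueError(
                f"'T' ({cfg['T']}) and its alias 'steps' ({steps}) disagree"
            )
        cfg.setdefault("T", steps)
    unknown = set(cfg) - _COLONY_KEYS - _LEARNING_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULTS, **cfg}
    cp = ColonyParams(
        N=int(merged["N"]),
        r=float(merged["r"]),
        q=float(merged["q"]),
        T=int(merged["T"]),
        survival=float(merged["survival"]),
        initial_stores=float(merged["initial_stores"]),
    )
    lc = LearningCurveParams(
        K=float(merged["K"]),
        m=float(merged["m"]),
        alpha=float(merged["alpha"]),
        beta=float(merged["beta"]),
        s=float(merged["s"]),
    )
    return cp, lc


def load_config(path) -> tuple[ColonyParams, LearningCurveParams]:
    """Read a YAML or JSON config file into parameter objects."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return params_from_dict(cfg)


def echo_config(cp: ColonyParams, lc: LearningCurveParams, outdir) -> Path:
    """Write the resolved parameter set to ``outdir/config.json`` for provenance."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {
        "T": cp.T,
        "N": cp.N,
        "K": lc.K,
        "m": lc.m,
        "alpha": lc.alpha,
        "beta": lc.beta,
        "s": lc.s,
        "q": cp.q,
        "r": cp.r,
        "survival": cp.survival,
        "initial_stores": cp.initial_stores,
    }
    path = out / "config.json"
    path.write_text(json.dumps(cfg, indent=2) + "\n")
    return path
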