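"""YAML configuration loading for pipeline hyperparameters.

A config file holds optional ``gat``, ``sae``, ``rwr``, ``features`` and
``cv`` sections whose keys map 1:1 onto the corresponding parameter
dataclasses, e.g.::

    gat:
      embed_dim: 128
      lr: 0.01
    sae:
      hidden_dim: 32
      beta: 0.1
    rwr:
      restart_prob: 0.1
    features:
      standardize: false
    cv:
      n_folds: 5
      n_repeats: 10

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .evaluation import CVConfig
from .gat import GATParams
from .sae import SAEParams
from .similarity import RWRParams

__all__ = ["PipelineConfig", "load_config"]

# accepted aliases per section (config key -> dataclass field)
_ALIASES = {
    "gat": {"lr": "learning_rate", "slope": "leaky_relu_slope", "l": "embed_dim"},
    "sae": {"lr": "learning_rate", "beta": "penalty_weight", "rho": "sparsity_target",
            "k": "hidden_dim"},
    "rwr": {"phi": "restart_prob"},
    "cv": {},
}


@dataclass
class PipelineConfig:
    gat: GATParams = field(default_factory=GATParams)
    sae: SAEParams = field(default_factory=SAEParams)
    rwr: RWRParams = field(default_factory=RWRParams)
    cv: CVConfig = field(default_factory=CVConfig)
    standardize_features: bool = False


def _build(section: str, cls, raw: dict):
    kwargs = {}
    aliases = _ALIASES[section]
    valid = set(cls.__dataclass_fields__)
    for key, value in raw.items():
        name = aliases.get(key, key)
        if name not in valid:
            raise KeyError(f"unknown config key {section}.{key}")
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Parse a YAML config file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = {"gat", "sae", "rwr", "cv", "features"}
    extra = set(raw) - known
    if extra:
        raise KeyError(f"unknown config sections: {sorted(extra)}")
    features = raw.get("features", {}) or {}
    bad = set(features) - {"standardize"}
    if bad:
        raise KeyError(f"unknown config keys: features.{sorted(bad)}")
    return PipelineConfig(
        gat=_build("gat", GATParams, raw.get("gat", {}) or {}),
        sae=_build("sae", SAEParams, raw.get("sae", {}) or {}),
        rwr=_build("rwr", RWRParams, raw.get("rwr", {}) or {}),
        cv=_build("cv", CVConfig, raw.get("cv", {}) or {}),
        standardize_features=bool(features.get("standardize", False)),
    )
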