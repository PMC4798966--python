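"""Configuration loading, seed management, manifests and tabular writers.

Every stochastic run in the toolkit is reproducible from its manifest:
one global seed is expanded into per-component child streams through
``numpy``'s SeedSequence spawning, keyed by a stable label, so enabling
one mechanism never perturbs another's random stream.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_game import AssortmentScheme
from .toxin import ToxinState
from .games import StrategyProfile
from .mito import (
    MechanismConfig,
    constant,
    linear_fecundity,
    logistic_apoptosis,
    step_apoptosis,
)

__all__ = [
    "load_config",
    "rng_for",
    "child_seed",
    "RunManifest",
    "write_results",
    "ConfigError",
]


class ConfigError(ValueError):
    """Schema violation in a run configuration, with a field-level message."""


def child_seed(seed: int, label: str) -> int:
    """Derive a per-component seed (< 2**31) from a global seed and label."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(label.encode()),))
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int | None, label: str) -> np.random.Generator:
    """Seeded generator for one named component of a run."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(child_seed(seed, label))


# --------------------------------------------------------------------------
# model configurations

_RATE_MAPS = {
    "constant": lambda p: constant(float(p["value"])),
    "linear_fecundity": lambda p: linear_fecundity(float(p["max_offspring"])),
    "logistic_apoptosis": lambda p: logistic_apoptosis(
        float(p.get("h50", 0.5)), float(p.get("slope", 10.0))
    ),
    "step_apoptosis": lambda p: step_apoptosis(float(p["threshold"])),
}


def _build_map(spec: Any, field_name: str):
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        return constant(float(spec))
    if isinstance(spec, dict) and spec.get("kind") in _RATE_MAPS:
        try:
            return _RATE_MAPS[spec["kind"]](spec)
        except KeyError as e:
            raise ConfigError(f"{field_name}: missing parameter {e} for kind {spec['kind']!r}")
    raise ConfigError(
        f"{field_name}: expected a number or a mapping with kind in {sorted(_RATE_MAPS)}"
    )


def _require(params: dict, field_name: str, typ, default=None):
    if field_name not in params:
        if default is not None:
            return default
        raise ConfigError(f"missing required field {field_name!r}")
    try:
        return typ(params[field_name])
    except (TypeError, ValueError):
        raise ConfigError(f"field {field_name!r}: cannot interpret {params[field_name]!r} as {typ.__name__}")


def _build_group_game(p: dict) -> dict:
    scheme = AssortmentScheme(
        scheme=p.get("scheme", "random"),
        group_size=_require(p, "group_size", int, 6),
        cooperator_counts=tuple(p["cooperator_counts"]) if "cooperator_counts" in p else None,
    )
    return {
        "initial_cooperators": _require(p, "initial_cooperators", int),
        "initial_cheaters": _require(p, "initial_cheaters", int),
        "scheme": scheme,
        "n_generations": _require(p, "n_generations", int, 1),
        "culling_threshold": float(p["culling_threshold"]) if "culling_threshold" in p else None,
        "max_population": int(p["max_population"]) if "max_population" in p else None,
    }


def _build_toxin(p: dict) -> dict:
    state = ToxinState(
        cooperators=_require(p, "cooperators", float),
        cheaters=_require(p, "cheaters", float),
        suicide_fraction=_require(p, "suicide_fraction", float, 0.1),
        kill_coefficient=_require(p, "kill_coefficient", float, 2.0),
        density_threshold=_require(p, "density_threshold", float, 250.0),
        growth_cost=_require(p, "growth_cost", float, 0.0),
    )
    return {"state": state, "n_episodes": _require(p, "n_episodes", int, 1)}


def _build_ptft(p: dict) -> dict:
    groups = p.get("groups")
    if not groups:
        raise ConfigError("missing required field 'groups' (list of lists of strategies)")
    profile = StrategyProfile(
        groups=tuple(tuple(g) for g in groups),
        rounds=_require(p, "rounds", int, 10),
        benefit=_require(p, "benefit", float, 3.0),
        cost=_require(p, "cost", float, 1.0),
    )
    return {"profile": profile, "replicates": _require(p, "replicates", int, 1)}


def _build_mito(p: dict) -> dict:
    kwargs = {}
    scalar_fields = [
        "replication_advantage",
        "import_selectivity",
        "segregation_bias",
        "mitophagy_selectivity",
        "mitophagy_rate",
    ]
    int_fields = [
        "bottleneck_size",
        "mtdna_per_mito",
        "mitos_per_cell",
        "cells_per_organism",
        "max_organisms",
    ]
    for f in scalar_fields:
        if f in p:
            kwargs[f] = float(p[f])
    for f in int_fields:
        if f in p:
            kwargs[f] = int(p[f])
    if "bottleneck_sampling" in p:
        kwargs["bottleneck_sampling"] = str(p["bottleneck_sampling"])
    for f in ("mito_fitness", "apoptosis_rule", "organism_fecundity"):
        if f in p:
            kwargs[f] = _build_map(p[f], f)
    try:
        config = MechanismConfig(**kwargs)
    except ValueError as e:
        raise ConfigError(str(e))
    return {
        "config": config,
        "n_generations": _require(p, "n_generations", int, 10),
        "initial_h": _require(p, "initial_h", float, 0.3),
    }


_BUILDERS = {
    "group_game": _build_group_game,
    "toxin": _build_toxin,
    "ptft": _build_ptft,
    "mito": _build_mito,
}


def load_config(path) -> tuple[str, dict]:
    """Load and validate a YAML/JSON model configuration.

    The file must carry a top-level ``model`` key naming one of
    ``group_game | toxin | ptft | mito``; all range invariants of the
    target module are enforced at load time with field-level messages.
    Returns ``(model_name, validated_kwargs)``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "model" not in raw:
        raise ConfigError("config must be a mapping with a 'model' key")
    model = raw["model"]
    if model not in _BUILDERS:
        raise ConfigError(f"unknown model {model!r}; expected one of {sorted(_BUILDERS)}")
    params = {k: v for k, v in raw.items() if k != "model"}
    try:
        return model, _BUILDERS[model](params)
    except ValueError as e:
        raise ConfigError(str(e)) from e


# --------------------------------------------------------------------------
# manifests and writers


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a run bit-for-bit."""

    model: str
    parameters: dict
    seed: int | None
    version: str = ""
    annotations: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.version:
            self.version = __version__

    def write(self, path) -> None:
        def default(o):
            if callable(o):
                return getattr(o, "__name__", repr(o))
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return str(o)
            return str(o)

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=default)


def write_results(records, path, format: str = "csv") -> Path:
    """Write tabular results (DataFrame or list of dicts) as CSV/TSV/JSON.

    An empty record list yields a header-only file where headers are
    known.  Numeric values are written at full precision.
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif format == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
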