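"""Run configuration: one YAML document covering every pipeline stage.

Defaults follow the acquisition and analysis parameters the pipeline is
built around — 1000 Hz sampling, 250 ms windows stepped by 100 ms, the
{VAR, RMS, MIN} feature set, and a 64/64 stratified split.  Unknown keys
are rejected by name so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .controller import ControlState
from .errors import ConfigError
from .evaluate import SplitSpec
from .features import DEFAULT_FEATURES, FEATURE_REGISTRY, WindowSpec
from .preprocess import FilterSpec
from .synth import SynthParams

log = logging.getLogger("myograsp.config")


@dataclass
class RunConfig:
    """Effective configuration for every stage, with global seed and log level."""

    synth: SynthParams = field(default_factory=SynthParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    features: tuple = DEFAULT_FEATURES
    lda: dict = field(default_factory=lambda: {"ridge_eps": None})
    eval: SplitSpec = field(default_factory=SplitSpec)
    controller: ControlState = field(default_factory=ControlState)
    kinematics: dict = field(default_factory=lambda: {"geometry": None})
    seed: int = 0
    log_level: str = "INFO"


_SECTION_TYPES = {
    "synth": SynthParams,
    "filter": FilterSpec,
    "window": WindowSpec,
    "eval": SplitSpec,
    "controller": ControlState,
}
_DICT_SECTIONS = {"lda": {"ridge_eps", "n_components"},
                  "kinematics": {"geometry", "driven"}}


def _build_section(name: str, cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) under '{name}': {sorted(unknown)}"
        )
    try:
        return cls(**overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{name}': {exc}") from exc


def load_config(path=None, text: str | None = None) -> RunConfig:
    """Load a YAML config; missing keys take the documented defaults.

    Raises :class:`ConfigError` naming the offending key path for
    unknown keys or out-of-range values.
    """
    if text is None:
        if path is None:
            doc = {}
        else:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
    else:
        doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")

    known_top = (set(_SECTION_TYPES) | set(_DICT_SECTIONS)
                 | {"features", "seed", "log_level"})
    unknown = set(doc) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        overrides = doc.get(name, {}) or {}
        if not isinstance(overrides, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(name, cls, overrides)
    for name, valid in _DICT_SECTIONS.items():
        overrides = doc.get(name, {}) or {}
        unknown = set(overrides) - valid
        if unknown:
            raise ConfigError(f"unknown key(s) under '{name}': {sorted(unknown)}")
        base = RunConfig.__dataclass_fields__[name].default_factory()
        base.update(overrides)
        kwargs[name] = base

    features = tuple(doc.get("features", DEFAULT_FEATURES))
    bad = [f for f in features if f not in FEATURE_REGISTRY]
    if bad:
        raise ConfigError(f"unknown feature(s) under 'features': {bad}")
    kwargs["features"] = features
    kwargs["seed"] = int(doc.get("seed", 0))
    level = str(doc.get("log_level", "INFO")).upper()
    if level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"invalid log_level: {level}")
    kwargs["log_level"] = level

    cfg = RunConfig(**kwargs)
    log.debug("effective config: %s", cfg)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    """Stage-tagged structured logging for the CLI."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
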