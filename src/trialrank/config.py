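"""Algorithm configuration, loadable from YAML.

All tunable coefficients of the valuation and propagation machinery live
here so that a single config object threads through the whole pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .trials import RVTable, SurrogacyClass, ValidationError, default_rv_table

__all__ = ["SplitRule", "PropagationConfig", "AlgorithmConfig", "load_config"]


class SplitRule(enum.Enum):
    """How a propagated value delta is divided among multiple targets."""

    EQUAL = "equal"
    PROPORTIONAL = "proportional"


@dataclass(frozen=True)
class PropagationConfig:
    """Single-generation value propagation settings.

    fraction
        Share of a node's newly incurred value change passed on to the
        regimens it previously beat (losses) or lost to (gains); in [0, 1].
    refresh_enabled
        Whether edges through which value is passed get their effective age
        reduced by one half-life (doubling their aging coefficient, capped).
    split_rule
        EQUAL shares, or PROPORTIONAL to the magnitude of the qualifying
        prior edge's contribution.
    """

    fraction: float = 0.5
    refresh_enabled: bool = True
    split_rule: SplitRule = SplitRule.EQUAL

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValidationError(
                f"propagation fraction must be in [0, 1], got {self.fraction}"
            )


@dataclass(frozen=True)
class AlgorithmConfig:
    """Coefficients of the vertex valuation formula and its diagnostics."""

    half_life_years: float = 10.0
    p_truncation: float = 0.001  # P values below this are truncated
    sig_weight_cap: float = 3.0  # = -log10(p_truncation) by default
    near_zero_epsilon: float = 0.5  # |value| <= eps -> "insufficient evidence"
    rv_table: RVTable = field(default_factory=default_rv_table)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)

    def __post_init__(self) -> None:
        if not self.half_life_years > 0:
            raise ValidationError(
                f"half_life_years must be > 0, got {self.half_life_years}"
            )

    def with_rv_table(self, rv_table: RVTable) -> "AlgorithmConfig":
        return replace(self, rv_table=rv_table)


def load_config(path: str | Path | None = None) -> AlgorithmConfig:
    """Build an :class:`AlgorithmConfig` from a YAML file (or defaults).

    Recognized keys: ``half_life_years``, ``p_truncation``,
    ``sig_weight_cap``, ``near_zero_epsilon``, ``rv_overrides`` (mapping of
    endpoint name -> class name and/or class name -> weight),
    ``propagation`` (``fraction``, ``refresh_enabled``, ``split_rule``).
    """
    if path is None:
        return AlgorithmConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    rv_table = default_rv_table()
    overrides = raw.pop("rv_overrides", None)
    if overrides:
        classes = dict(rv_table.classes)
        weights = dict(rv_table.weights)
        for key, value in overrides.items():
            key_upper = str(key).upper()
            if key_upper in SurrogacyClass.__members__:
                weights[SurrogacyClass[key_upper]] = float(value)
            else:
                classes[str(key)] = SurrogacyClass[str(value).upper()]
        rv_table = RVTable(classes=classes, weights=weights)

    prop_raw = raw.pop("propagation", {}) or {}
    if "split_rule" in prop_raw:
        prop_raw["split_rule"] = SplitRule(str(prop_raw["split_rule"]).lower())
    propagation = PropagationConfig(**prop_raw)

    return AlgorithmConfig(rv_table=rv_table, propagation=propagation, **raw)
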