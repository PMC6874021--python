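"""Ranking, the straw-man diagnostic, and the RV sensitivity analysis.

The straw-man diagnostic is the Pearson correlation between vertex value
and vertex size (total patients studied under the regimen): a significant
negative correlation means the most-studied regimens are systematically
the most negatively valued — the signature of new trials picking weak or
outdated comparators.  Propagation and refresh should attenuate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .config import AlgorithmConfig
from .propagation import evaluate_with_propagation
from .trials import TrialComparison, ValidationError
from .valuation import NetworkState, evaluate_network

__all__ = [
    "RankedRegimen",
    "CorrelationResult",
    "SensitivityReport",
    "rank_regimens",
    "value_size_correlation",
    "sensitivity_rv",
    "compare_rankings",
]

DEFAULT_PERTURBATIONS = (-0.20, -0.10, -0.05, 0.05, 0.10, 0.20)


@dataclass(frozen=True)
class RankedRegimen:
    regimen: str
    value: float
    size: int
    interpretation: str  # "recommendable" | "contraindicated" | "insufficient"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with a Fisher-z 95% CI and a two-sided t-test P value."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass(frozen=True)
class SensitivityReport:
    """Rank stability under uniform multiplicative RV perturbations."""

    perturbations: tuple[float, ...]
    baseline_ranking: tuple[str, ...]
    rankings: dict[float, tuple[str, ...]]
    baseline_values: dict[str, float]
    values: dict[float, dict[str, float]]
    rank_order_stable: bool
    signs_preserved: bool


def _interpret(value: float, epsilon: float) -> str:
    if value > epsilon:
        return "recommendable"
    if value < -epsilon:
        return "contraindicated"
    return "insufficient"


def rank_regimens(
    state: NetworkState, epsilon: float | None = None
) -> list[RankedRegimen]:
    """Rank regimens by descending value; ties broken alphabetically.

    A positively valued vertex is recommendable, a negatively valued one
    contraindicated; values within ``epsilon`` of zero (default 0.5) read
    as insufficient evidence.
    """
    if not state.sizes:
        raise ValidationError("cannot rank an empty network state")
    eps = 0.5 if epsilon is None else epsilon
    values = state.values
    order = sorted(values, key=lambda r: (-values[r], r))
    return [
        RankedRegimen(
            regimen=r,
            value=values[r],
            size=state.sizes[r],
            interpretation=_interpret(values[r], eps),
        )
        for r in order
    ]


def value_size_correlation(state: NetworkState) -> CorrelationResult:
    """Pearson correlation of vertex value against vertex size.

    The 95% CI uses the Fisher z-transform with standard error
    1/sqrt(n - 3); the P value is the two-sided t test with n - 2 degrees
    of freedom (the classical Pearson test).
    """
    values = state.values
    regimens = sorted(values)
    x = np.array([values[r] for r in regimens], dtype=float)
    y = np.array([state.sizes[r] for r in regimens], dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 vertices for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in value or size")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:  # degenerate: Fisher z is infinite
        ci_low = ci_high = r
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3) if n > 3 else float("inf")
        zcrit = stats.norm.ppf(0.975)
        ci_low = math.tanh(z - zcrit * se)
        ci_high = math.tanh(z + zcrit * se)
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, p_value=float(p), n=n)


def _pipeline(
    trials: Sequence[TrialComparison],
    eval_year: int,
    config: AlgorithmConfig,
    propagate: bool,
) -> NetworkState:
    if propagate:
        return evaluate_with_propagation(trials, eval_year, config)
    return evaluate_network(trials, eval_year, config)


def sensitivity_rv(
    trials: Sequence[TrialComparison],
    eval_year: int,
    config: AlgorithmConfig | None = None,
    perturbations: Iterable[float] = DEFAULT_PERTURBATIONS,
    propagate: bool = True,
) -> SensitivityReport:
    """Re-run the full pipeline with every RV scaled by (1 + delta).

    For each perturbation the entire valuation (including propagation if
    enabled) is recomputed and the ranking recorded.  ``rank_order_stable``
    is true iff every perturbed ranking equals the baseline;
    ``signs_preserved`` iff no regimen's value changes sign.  Scaling is
    multiplicative on all classes simultaneously, capped at 1.0 (RV is a
    relative weight whose defining maximum is 1).
    """
    config = config or AlgorithmConfig()
    perturbations = tuple(perturbations)
    for d in perturbations:
        if d <= -1.0:
            raise ValidationError(f"perturbation must be > -100%, got {d:+.0%}")

    def run(cfg: AlgorithmConfig) -> tuple[tuple[str, ...], dict[str, float]]:
        state = _pipeline(trials, eval_year, cfg, propagate)
        ranking = tuple(r.regimen for r in rank_regimens(state, config.near_zero_epsilon))
        return ranking, state.values

    baseline_ranking, baseline_values = run(config)
    rankings: dict[float, tuple[str, ...]] = {}
    values: dict[float, dict[str, float]] = {}
    stable = True
    signs_ok = True
    for d in perturbations:
        cfg = config.with_rv_table(config.rv_table.scaled(1.0 + d))
        ranking, vals = run(cfg)
        rankings[d] = ranking
        values[d] = vals
        if ranking != baseline_ranking:
            stable = False
        for reg, v in vals.items():
            if math.copysign(1.0, v) != math.copysign(1.0, baseline_values[reg]) and (
                v != 0 or baseline_values[reg] != 0
            ):
                signs_ok = False
    return SensitivityReport(
        perturbations=perturbations,
        baseline_ranking=baseline_ranking,
        rankings=rankings,
        baseline_values=baseline_values,
        values=values,
        rank_order_stable=stable,
        signs_preserved=signs_ok,
    )


def compare_rankings(
    a: Sequence[str], b: Sequence[str]
) -> tuple[bool, float]:
    """Exact-order equality flag plus Kendall rank correlation of two rankings."""
    if set(a) != set(b):
        raise ValidationError("rankings cover different regimen sets")
    a = list(a)
    b = list(b)
    pos_b = {reg: i for i, reg in enumerate(b)}
    tau, _ = stats.kendalltau(range(len(a)), [pos_b[reg] for reg in a])
    return a == b, float(tau)
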