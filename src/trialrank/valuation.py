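"""Vertex valuation of a treatment-regimen evidence network.

Each pairwise comparison contributes one signed *edge* to the network.  The
magnitude of an edge's contribution is the product of five factors:

    sig_weight  x  RV  x  E  x  log10(N)  x  aging

where ``sig_weight = min(-log10(P), 3)`` is the strength of evidence (P
values below .001 truncated), ``RV`` is the relative value of the selected
endpoint's surrogacy class, ``E >= 1`` is the effect-size coefficient
(a ratio effect and its reciprocal map to the same E), ``N`` is the total
number of patients in the comparison, and ``aging = 2**(-age/half_life)``
discounts older evidence.  The favored arm receives ``+magnitude``, its
opponent ``-magnitude``.  A vertex's value is the sum of its incident
signed contributions; it is deliberately not normalized, so magnitudes
remain comparable across the network.  Positive values read as
"recommendable", negative as "contraindicated", near-zero as "insufficient
evidence".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .config import AlgorithmConfig
from .trials import (
    EffectMeasure,
    FavoredArm,
    TrialComparison,
    ValidationError,
    select_outcome,
)

__all__ = [
    "EdgeContribution",
    "NetworkState",
    "significance_weight",
    "effect_coefficient",
    "aging_coefficient",
    "reference_year",
    "edge_contribution",
    "evaluate_network",
]


def significance_weight(p: float, cap: float = 3.0) -> float:
    """Strength-of-evidence weight ``min(-log10(p), cap)``.

    Very small P values are hard to interpret, so the weight is capped
    (default 3, i.e. P values below .001 are truncated to .001).
    """
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p must be in (0, 1], got {p}")
    return min(-math.log10(p), cap)


def effect_coefficient(effect_value: float) -> float:
    """Unsigned effect-size coefficient ``E = max(x, 1/x) >= 1``.

    A reported ratio effect (HR, OR, median ratio, ...) is folded so that
    an effect and its reciprocal are equivalent: HR = 0.5 gives E = 2.
    The caller assigns +E to the favored arm and -E to the other.
    """
    if not effect_value > 0:
        raise ValidationError(f"effect_value must be > 0, got {effect_value}")
    return max(effect_value, 1.0 / effect_value)


def aging_coefficient(reference_year: int, eval_year: int, half_life: float) -> float:
    """Exponential evidence-aging factor ``2**(-(eval-ref)/half_life)``.

    Equals 1 at publication and halves every ``half_life`` years.
    """
    if eval_year < reference_year:
        raise ValidationError(
            f"eval_year {eval_year} precedes reference_year {reference_year}"
        )
    if not half_life > 0:
        raise ValidationError(f"half_life must be > 0, got {half_life}")
    return 2.0 ** (-(eval_year - reference_year) / half_life)


def reference_year(trial: TrialComparison, eval_year: int) -> int:
    """Aging reference: latest of pub_year and any interim update <= eval_year."""
    years = [trial.pub_year] + [y for y in trial.update_years if y <= eval_year]
    return max(years)


@dataclass(frozen=True)
class EdgeContribution:
    """One comparison's signed contribution to its two regimen vertices.

    ``winner``/``loser`` are None for draws (noninferiority or an effect of
    exactly 1), in which case ``magnitude`` is 0.  The edge still connects
    ``regimen_a``/``regimen_b`` for sizing and topology purposes.
    """

    trial_id: str
    year: int
    regimen_a: str
    regimen_b: str
    n_total: int
    winner: str | None
    loser: str | None
    sig_weight: float
    rv: float
    e_magnitude: float
    log_n: float
    aging: float
    effective_age: float
    endpoint_class: object  # SurrogacyClass; kept loose to avoid import cycle noise
    magnitude: float

    def signed_contribution(self, regimen: str) -> float:
        """+magnitude for the winner, -magnitude for the loser, else 0."""
        if regimen == self.winner:
            return self.magnitude
        if regimen == self.loser:
            return -self.magnitude
        return 0.0

    @property
    def contribution(self) -> float:
        """Signed contribution from the winner's perspective."""
        return self.magnitude


def edge_contribution(
    trial: TrialComparison, eval_year: int, config: AlgorithmConfig
) -> EdgeContribution:
    """Evaluate one comparison's edge at ``eval_year``.

    The outcome entering the product is the one chosen by
    :func:`trialrank.trials.select_outcome`.  Noninferiority outcomes and
    outcomes favoring neither arm contribute zero (the comparison is a
    draw) but keep the edge in the network.
    """
    if trial.pub_year > eval_year:
        raise ValidationError(
            f"trial {trial.trial_id!r} published {trial.pub_year}, "
            f"after eval_year {eval_year}"
        )
    outcome = select_outcome(trial)
    ref = reference_year(trial, eval_year)
    age = float(eval_year - ref)
    aging = aging_coefficient(ref, eval_year, config.half_life_years)
    log_n = math.log10(trial.n_total)

    p = max(outcome.p_value, config.p_truncation)
    sig = significance_weight(p, cap=config.sig_weight_cap)
    e_mag = effect_coefficient(outcome.effect_value)
    # RV resolved from the live config table so sensitivity perturbations
    # reach the formula even though outcomes cache the load-time weight
    rv = config.rv_table.weights.get(outcome.endpoint_class, outcome.rv)

    is_draw = (
        outcome.effect_measure is EffectMeasure.NONINFERIORITY
        or outcome.favored_arm is FavoredArm.NONE
    )
    if is_draw:
        winner = loser = None
        magnitude = 0.0
    else:
        winner = trial.regimen_a if outcome.favored_arm is FavoredArm.A else trial.regimen_b
        loser = trial.regimen_b if winner == trial.regimen_a else trial.regimen_a
        magnitude = sig * rv * e_mag * log_n * aging

    return EdgeContribution(
        trial_id=trial.trial_id,
        year=trial.pub_year,
        regimen_a=trial.regimen_a,
        regimen_b=trial.regimen_b,
        n_total=trial.n_total,
        winner=winner,
        loser=loser,
        sig_weight=sig,
        rv=rv,
        e_magnitude=e_mag,
        log_n=log_n,
        aging=aging,
        effective_age=age,
        endpoint_class=outcome.endpoint_class,
        magnitude=magnitude,
    )


@dataclass(frozen=True)
class NetworkState:
    """Regimen vertices with values, sizes, and dated signed edges.

    ``adjustments`` records vertex-level value deltas introduced by
    propagation, kept separate from the edge decomposition so the zero-sum
    edge audit stays intact.  A vertex's value is the sum of its incident
    signed edge contributions plus its adjustment.
    """

    eval_year: int
    edges: tuple[EdgeContribution, ...]
    sizes: dict[str, int]
    adjustments: dict[str, float] = field(default_factory=dict)

    @property
    def regimens(self) -> list[str]:
        return sorted(self.sizes)

    @property
    def values(self) -> dict[str, float]:
        vals = {r: self.adjustments.get(r, 0.0) for r in self.sizes}
        for e in self.edges:
            if e.winner is not None:
                vals[e.winner] += e.magnitude
                vals[e.loser] -= e.magnitude
        return vals

    def value(self, regimen: str) -> float:
        return self.values[regimen]

    def size(self, regimen: str) -> int:
        return self.sizes[regimen]

    def with_edges(self, edges: Sequence[EdgeContribution]) -> "NetworkState":
        return replace(self, edges=tuple(edges))

    def with_adjustments(self, adjustments: dict[str, float]) -> "NetworkState":
        return replace(self, adjustments=dict(adjustments))


def evaluate_network(
    trials: Iterable[TrialComparison], eval_year: int, config: AlgorithmConfig | None = None
) -> NetworkState:
    """Pre-propagation valuation of the whole network at ``eval_year``.

    Only trials published by ``eval_year`` enter.  A vertex's size is the
    total number of patients studied under the regimen, i.e. the sum of
    ``n_total`` over all its eligible comparisons.
    """
    config = config or AlgorithmConfig()
    eligible = [t for t in trials if t.pub_year <= eval_year]
    if not eligible:
        raise ValidationError(f"no trials published by eval_year {eval_year}")
    edges = tuple(edge_contribution(t, eval_year, config) for t in eligible)
    sizes: dict[str, int] = {}
    for t in eligible:
        for r in (t.regimen_a, t.regimen_b):
            sizes[r] = sizes.get(r, 0) + t.n_total
    return NetworkState(eval_year=eval_year, edges=edges, sizes=sizes)
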