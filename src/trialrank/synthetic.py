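"""Synthetic RCT comparison streams with controllable straw-man structure.

The real trial networks this tool targets are assembled from decades of
published RCTs.  To make the whole pipeline — including the value-vs-size
bias diagnostic and its amelioration by propagation — testable without any
external data, this module simulates a multi-decade stream of two-arm
trials with the structural features that produce the straw-man effect:

* regimens enter the field over calendar time, each debuting as the
  experimental arm of its first trial;
* new trials preferentially pick the currently most-studied regimen as
  comparator (with probability ``strawman_intensity``); in those biased
  comparisons the newer arm usually wins — the standard is used as
  comparator *because* it is established yet beatable — while comparisons
  against an unbiasedly chosen comparator are a coin flip;
* endpoint surrogacy degrades over calendar time, from overall survival
  toward response-rate style endpoints;
* P values are generated from a two-sided test of the log effect with
  standard error proportional to 1/sqrt(n), so significance, effect size
  and sample size covary realistically.

The heavily used standard therefore accrues a large size and a pile of
losses — a negative value-size correlation — while the null generator
(uniform comparator choice) produces none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trials import (
    EffectMeasure,
    FavoredArm,
    OutcomeRecord,
    RVTable,
    SurrogacyClass,
    TrialComparison,
    ValidationError,
    default_rv_table,
)

__all__ = ["ScenarioConfig", "generate_strawman", "generate_null"]

_ENDPOINT_BY_CLASS = {
    SurrogacyClass.STRONG: "overall survival",
    SurrogacyClass.INTERMEDIATE: "progression-free survival",
    SurrogacyClass.WEAK: "overall response rate",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the simulated trial stream.

    n_regimens
        Number of distinct regimens entering over the study period.
    start_year, end_year
        Calendar span of the stream (inclusive).
    trials_per_year
        Two-arm comparisons published each year.
    strawman_intensity
        Probability that a trial picks the currently most-studied regimen
        as comparator instead of a uniformly random existing one.
    newcomer_win_prob
        Probability the more recently introduced arm is favored in a
        comparison whose comparator was picked through the straw-man
        channel; unbiased comparisons are 50/50.
    endpoint_drift
        Per-decade probability increment that a trial's primary endpoint
        has drifted from overall survival toward surrogate endpoints.
    effect_log_mean, effect_log_sd
        Location/spread of the winner's log effect ratio (a hazard-ratio
        style effect below 1; default median HR 0.70).
    n_log_median, n_log_sd
        Log-normal location/spread of per-trial patient totals (default
        median 300 patients).
    se_scale
        Standard error of the log effect is ``se_scale / sqrt(n_total)``.
    seed
        Seed for the stream's random generator; same seed, same stream.
    """

    n_regimens: int = 20
    start_year: int = 1990
    end_year: int = 2020
    trials_per_year: int = 4
    strawman_intensity: float = 0.8
    newcomer_win_prob: float = 0.8
    endpoint_drift: float = 0.25
    effect_log_mean: float = math.log(0.70)
    effect_log_sd: float = 0.2
    n_log_median: float = 300.0
    n_log_sd: float = 0.5
    se_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("strawman_intensity", "newcomer_win_prob", "endpoint_drift"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.end_year <= self.start_year:
            raise ValidationError("end_year must exceed start_year")
        if self.n_regimens < 2:
            raise ValidationError("need at least 2 regimens")
        if self.trials_per_year < 1:
            raise ValidationError("trials_per_year must be >= 1")


def _debut_years(config: ScenarioConfig) -> list[int]:
    """Entry year per regimen: the first two at start, the rest spread over
    the first ~80% of the span so latecomers still accrue trials."""
    span = config.end_year - config.start_year
    last_entry = config.start_year + max(1, int(round(0.8 * span)))
    entries = np.linspace(config.start_year, last_entry, config.n_regimens)
    years = [int(round(y)) for y in entries]
    years[1] = years[0]  # the debut trial needs an incumbent opponent
    return years


def _sample_endpoint_class(
    rng: np.random.Generator, year: int, config: ScenarioConfig
) -> SurrogacyClass:
    decades = (year - config.start_year) / 10.0
    p_drift = min(config.endpoint_drift * decades, 1.0)
    if rng.random() < p_drift:
        return SurrogacyClass.WEAK if rng.random() < 0.7 else SurrogacyClass.INTERMEDIATE
    return SurrogacyClass.STRONG


def _make_trial(
    trial_id: str,
    year: int,
    experimental: str,
    comparator: str,
    exp_is_newer: bool,
    p_win_newer: float,
    rng: np.random.Generator,
    config: ScenarioConfig,
    rv_table: RVTable,
) -> TrialComparison:
    n_total = int(
        max(40, round(config.n_log_median * math.exp(rng.normal(0.0, config.n_log_sd))))
    )
    if n_total % 2:
        n_total += 1

    # winner's effect ratio < 1 (hazard-ratio convention: smaller favors it)
    log_hr = -abs(rng.normal(config.effect_log_mean, config.effect_log_sd))
    hr = math.exp(log_hr)
    newer_wins = rng.random() < p_win_newer
    # regimen_a = experimental arm, regimen_b = comparator arm
    favored = FavoredArm.A if newer_wins == exp_is_newer else FavoredArm.B

    se = config.se_scale / math.sqrt(n_total)
    z = abs(log_hr) / se
    p = float(np.clip(2.0 * stats.norm.sf(z), 1e-12, 1.0))

    cls = _sample_endpoint_class(rng, year, config)
    endpoint = _ENDPOINT_BY_CLASS[cls]
    outcomes = [
        OutcomeRecord(
            endpoint_name=endpoint,
            endpoint_class=cls,
            rv=rv_table.weights[cls],
            p_value=p,
            effect_measure=EffectMeasure.HAZARD_RATIO,
            effect_value=hr,
            is_primary=True,
            favored_arm=favored,
        )
    ]
    # occasionally a surrogate-primary trial also reports overall survival
    if cls is not SurrogacyClass.STRONG and rng.random() < 0.2:
        os_p = float(np.clip(p * math.exp(rng.normal(1.0, 0.8)), 1e-12, 1.0))
        outcomes.append(
            OutcomeRecord(
                endpoint_name=_ENDPOINT_BY_CLASS[SurrogacyClass.STRONG],
                endpoint_class=SurrogacyClass.STRONG,
                rv=rv_table.weights[SurrogacyClass.STRONG],
                p_value=os_p,
                effect_measure=EffectMeasure.HAZARD_RATIO,
                effect_value=float(np.clip(hr * math.exp(rng.normal(0.0, 0.1)), 1e-6, None)),
                is_primary=False,
                favored_arm=favored,
            )
        )
    return TrialComparison(
        trial_id=trial_id,
        pub_year=year,
        regimen_a=experimental,
        regimen_b=comparator,
        n_total=n_total,
        outcomes=tuple(outcomes),
    )


def _generate(config: ScenarioConfig, intensity: float) -> list[TrialComparison]:
    rng = np.random.default_rng(config.seed)
    rv_table = default_rv_table()
    regimens = [f"R{i + 1:02d}" for i in range(config.n_regimens)]
    debut_sched = dict(zip(regimens, _debut_years(config)))

    patients: dict[str, int] = {r: 0 for r in regimens}
    introduced: list[str] = []
    queue = sorted(regimens, key=lambda r: (debut_sched[r], r))  # debut order
    debut_actual: dict[str, int] = {}

    trials: list[TrialComparison] = []
    counter = 0
    for year in range(config.start_year, config.end_year + 1):
        for _ in range(config.trials_per_year):
            counter += 1
            trial_id = f"T{counter:04d}"
            if not introduced:
                # the stream opens with the first two regimens facing off
                first, second = queue.pop(0), queue.pop(0)
                introduced.extend([first, second])
                debut_actual[first] = debut_actual[second] = year
                p_win = config.newcomer_win_prob if rng.random() < intensity else 0.5
                trial = _make_trial(
                    trial_id, year, second, first, True, p_win, rng, config, rv_table
                )
                trials.append(trial)
                for arm in (first, second):
                    patients[arm] += trial.n_total
                continue
            if queue and debut_sched[queue[0]] <= year:
                # a debutant enters as the experimental arm of its first trial
                newer = queue.pop(0)
                introduced.append(newer)
                debut_actual[newer] = year
            else:
                # experimental arm: a recently introduced regimen
                recent = [r for r in introduced if year - debut_actual[r] <= 10]
                pool = recent if len(recent) >= 2 else introduced
                newer = pool[rng.integers(len(pool))]

            others = [r for r in introduced if r != newer]
            if rng.random() < intensity:
                comparator = max(others, key=lambda r: (patients[r], -debut_actual[r], r))
                p_win = config.newcomer_win_prob
            else:
                comparator = others[rng.integers(len(others))]
                p_win = 0.5
            exp_is_newer = (debut_actual[newer], newer) >= (
                debut_actual[comparator], comparator
            )
            trial = _make_trial(
                trial_id, year, newer, comparator, exp_is_newer, p_win, rng, config, rv_table
            )
            trials.append(trial)
            patients[newer] += trial.n_total
            patients[comparator] += trial.n_total
    return trials


def generate_strawman(config: ScenarioConfig | None = None) -> list[TrialComparison]:
    """Generate a trial stream with comparator selection bias.

    With probability ``strawman_intensity`` each trial uses the currently
    most-studied regimen (largest cumulative patient count) as comparator,
    so a standard-of-care vertex accrues size and losses simultaneously.
    """
    config = config or ScenarioConfig()
    return _generate(config, config.strawman_intensity)


def generate_null(config: ScenarioConfig | None = None) -> list[TrialComparison]:
    """Negative control: identical machinery with uniform comparator choice."""
    config = config or ScenarioConfig()
    return _generate(config, 0.0)
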