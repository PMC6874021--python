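import pytest

from trialrank import (
    AlgorithmConfig,
    EffectMeasure,
    FavoredArm,
    OutcomeRecord,
    SurrogacyClass,
    TrialComparison,
    default_rv_table,
)

_ENDPOINTS = {
    SurrogacyClass.STRONG: "overall survival",
    SurrogacyClass.INTERMEDIATE: "progression-free survival",
    SurrogacyClass.WEAK: "overall response rate",
}


@pytest.fixture
def rv_table():
    return default_rv_table()


@pytest.fixture
def config():
    return AlgorithmConfig()


@pytest.fixture
def make_outcome(rv_table):
    """Factory for valid outcome records with sensible defaults."""

    def _make(
        cls=SurrogacyClass.STRONG,
        p=0.01,
        effect=0.5,
        measure=EffectMeasure.HAZARD_RATIO,
        primary=True,
        favored=FavoredArm.A,
        endpoint=None,
    ):
        return OutcomeRecord(
            endpoint_name=endpoint or _ENDPOINTS[cls],
            endpoint_class=cls,
            rv=rv_table.weights[cls],
            p_value=p,
            effect_measure=measure,
            effect_value=effect,
            is_primary=primary,
            favored_arm=favored,
        )

    return _make


@pytest.fixture
def make_trial(make_outcome):
    """Factory for single-outcome two-arm comparisons."""

    def _make(
        trial_id="T1",
        year=2010,
        a="A",
        b="B",
        n=100,
        outcomes=None,
        updates=(),
        **outcome_kwargs,
    ):
        if outcomes is None:
            outcomes = (make_outcome(**outcome_kwargs),)
        return TrialComparison(
            trial_id=trial_id,
            pub_year=year,
            regimen_a=a,
            regimen_b=b,
            n_total=n,
            outcomes=tuple(outcomes),
            update_years=tuple(updates),
        )

    return _make
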