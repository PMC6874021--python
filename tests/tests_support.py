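"""Shared random-fixture builders for the test suite."""

import numpy as np

from trialrank import (
    EffectMeasure,
    FavoredArm,
    OutcomeRecord,
    SurrogacyClass,
    TrialComparison,
    default_rv_table,
)

_RV = default_rv_table()
_ENDPOINTS = {
    SurrogacyClass.STRONG: "overall survival",
    SurrogacyClass.INTERMEDIATE: "progression-free survival",
    SurrogacyClass.WEAK: "overall response rate",
}


def random_trials(seed: int, max_trials: int = 30, n_regimens: int = 8):
    """A small random but always-valid comparison list (draws included)."""
    rng = np.random.default_rng(seed)
    regimens = [f"R{i}" for i in range(n_regimens)]
    n_trials = int(rng.integers(1, max_trials + 1))
    trials = []
    for i in range(n_trials):
        a, b = rng.choice(regimens, size=2, replace=False)
        year = int(rng.integers(1990, 2021))
        cls = SurrogacyClass(int(rng.integers(0, 3)))
        draw_kind = rng.random()
        if draw_kind < 0.1:  # noninferiority
            measure, effect, favored = (
                EffectMeasure.NONINFERIORITY,
                float(rng.uniform(0.8, 1.2)),
                FavoredArm.NONE,
            )
        elif draw_kind < 0.15:  # exact-unity effect
            measure, effect, favored = (
                EffectMeasure.HAZARD_RATIO,
                1.0,
                FavoredArm.NONE,
            )
        else:
            measure = EffectMeasure.HAZARD_RATIO
            effect = float(np.exp(rng.normal(-0.3, 0.4)))
            if effect == 1.0:
                effect = 0.9
            favored = FavoredArm.A if rng.random() < 0.5 else FavoredArm.B
        outcome = OutcomeRecord(
            endpoint_name=_ENDPOINTS[cls],
            endpoint_class=cls,
            rv=_RV.weights[cls],
            p_value=float(rng.uniform(1e-5, 1.0)),
            effect_measure=measure,
            effect_value=effect,
            is_primary=True,
            favored_arm=favored,
        )
        updates = ()
        if rng.random() < 0.2:
            updates = (year + int(rng.integers(1, 10)),)
        trials.append(
            TrialComparison(
                trial_id=f"S{seed}-T{i}",
                pub_year=year,
                regimen_a=str(a),
                regimen_b=str(b),
                n_total=int(rng.integers(40, 2000)),
                outcomes=(outcome,),
                update_years=updates,
            )
        )
    return trials
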