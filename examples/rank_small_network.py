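"""Value and rank a tiny hand-built evidence network.

Two trials: a 2003 trial in which the standard beat an older regimen, and
a 2010 trial in which a newcomer beat the standard.  Ranking is by the
vertex value — the sum over incident comparisons of
significance weight x relative value x effect coefficient x log10(N) x aging.
"""

from trialrank import (
    EffectMeasure,
    FavoredArm,
    OutcomeRecord,
    TrialComparison,
    default_rv_table,
    evaluate_network,
    rank_regimens,
)

rv = default_rv_table()


def os_outcome(p, hr):
    return OutcomeRecord(
        endpoint_name="overall survival",
        endpoint_class=rv.class_for("overall survival"),
        rv=rv.rv_for("overall survival"),
        p_value=p,
        effect_measure=EffectMeasure.HAZARD_RATIO,
        effect_value=hr,
        is_primary=True,
        favored_arm=FavoredArm.A,
    )


trials = [
    TrialComparison("STANDARD-VS-OLD", 2003, "standard", "older-regimen", 1000,
                    (os_outcome(0.001, 0.5),)),
    TrialComparison("NEW-VS-STANDARD", 2010, "newcomer", "standard", 500,
                    (os_outcome(0.007, 0.6),)),
]

state = evaluate_network(trials, eval_year=2016)
print(f"{'regimen':<16}{'value':>9}  {'size':>6}  interpretation")
for row in rank_regimens(state):
    print(f"{row.regimen:<16}{row.value:>9.2f}  {row.size:>6d}  {row.interpretation}")
print()
print("A positive value reads as recommendable, a negative one as")
print("contraindicated; the standard's wins and losses partially cancel.")
print(f"Total network value (always 0 by construction): "
      f"{sum(state.values.values()):+.2e}")
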