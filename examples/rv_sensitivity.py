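"""Check rank stability under perturbation of the endpoint weights.

The relative value (RV) of an endpoint's surrogacy class (1.0 strong,
0.8 intermediate, 0.7 weak by default) is an empirically chosen weight;
this example rescales all RVs by +-5/10/20% and reports whether the
ranking or any value's sign moves.
"""

from trialrank import ScenarioConfig, generate_strawman, sensitivity_rv

cfg = ScenarioConfig(seed=42, n_regimens=8, start_year=2000, end_year=2016)
trials = generate_strawman(cfg)

report = sensitivity_rv(trials, cfg.end_year, propagate=True)
print("baseline ranking:", " > ".join(report.baseline_ranking))
for d in report.perturbations:
    changed = report.rankings[d] != report.baseline_ranking
    print(f"  RV {d:+5.0%}: ranking {'CHANGED' if changed else 'unchanged'}")
print("rank order stable:   ", report.rank_order_stable)
print("value signs preserved:", report.signs_preserved)
print()
print("A stable rank order means the ranking is not an artifact of the")
print("precise surrogacy weights; adjacent regimens that swap under")
print("perturbation have evidence too close to call apart.")
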