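# trialrank

Valuation, ranking, and visualization of treatment regimens in temporal
networks of randomized-controlled-trial (RCT) comparisons — with a
built-in diagnostic for, and amelioration of, the *straw-man effect*:
the bias by which new interventions look good because they are trialled
against comparatively ineffective or outdated comparators.

The package is aimed at evidence-synthesis and comparative-effectiveness
researchers who work with decades-long streams of pairwise RCT results
(the motivating settings are oncology treatment lines, where mixed
endpoints and strong temporality defeat standard network meta-analysis),
and at methodologists who want a reproducible sandbox for comparator-
selection bias.

## The model

Each two-arm comparison is a dated, signed edge between two regimen
vertices. A regimen's **vertex value** is the sum over its `m` incident
comparisons of

```
v = Σ_y  −log10(P_y) · RV_y · E_y · log10(N_y) · f(α_y)
```

where, for the *y*-th comparison,

- `−log10(P)` is the strength of evidence, capped at 3 (P values below
  .001 are truncated);
- `RV` is the **relative value** of the selected endpoint's surrogacy
  class: 1.0 for strong endpoints (overall survival), 0.8 for
  intermediate (progression-free/event-free survival), 0.7 for weak
  (response rates). One endpoint per comparison is selected: the
  least-surrogate primary, replaced by a strictly less-surrogate
  secondary if the primary was met (P ≤ .05) and the secondary reached
  P ≤ .10;
- `E = max(x, 1/x) ≥ 1` folds the reported ratio effect (HR, OR, median
  ratio): HR = 0.5 gives the winner +2 and the loser −2;
- `log10(N)` weights the comparison by its total patients;
- `f(α) = 2^(−α / half-life)` discounts evidence of age α (default
  half-life 10 years; interim updates reset the clock).

Values are deliberately unnormalized; positive reads as *recommendable*,
negative as *contraindicated*, near zero as *insufficient evidence*.

**Straw-man diagnostic.** If new trials preferentially use the
most-studied standard as a (losing) comparator, the largest vertices end
up the most negatively valued: a significant negative Pearson
correlation between vertex value and vertex size (total patients
studied). **Value propagation** counters it: when a node loses value to
newly published evidence, a fraction (default 0.5) of that loss is
passed one generation back to the regimens it had previously beaten
(symmetrically for gains), and each propagated-through comparison is
**refreshed** — its effective age reduced by one half-life. An RV
sensitivity analysis (±5/10/20%) checks that rankings are not artifacts
of the surrogacy weights.

## Worked example

```python
from trialrank import (EffectMeasure, FavoredArm, OutcomeRecord,
                       TrialComparison, default_rv_table,
                       evaluate_network, rank_regimens)

rv = default_rv_table()
os = lambda p, hr: OutcomeRecord(
    "overall survival", rv.class_for("overall survival"),
    rv.rv_for("overall survival"), p, EffectMeasure.HAZARD_RATIO,
    hr, True, FavoredArm.A)

trials = [
    TrialComparison("STANDARD-VS-OLD", 2003, "standard", "older-regimen",
                    1000, (os(0.001, 0.5),)),
    TrialComparison("NEW-VS-STANDARD", 2010, "newcomer", "standard",
                    500, (os(0.007, 0.6),)),
]
for row in rank_regimens(evaluate_network(trials, eval_year=2016)):
    print(f"{row.regimen:<16}{row.value:>9.2f}  {row.size:>6d}  {row.interpretation}")
```

prints

```
newcomer             6.40     500  recommendable
standard             0.92    1500  recommendable
older-regimen       -7.31    1000  contraindicated
```

The standard's 2003 win (+18 when fresh, decayed to +7.31 by 2016) and
its 2010 loss (−9.69 when fresh, decayed to −6.40) nearly cancel; the
newcomer holds the mirror-image of that loss as a gain; the old
regimen carries only a decayed loss. All vertex values always sum to
zero. The scripts in `examples/` walk through the other capabilities
(straw-man diagnostic on simulated streams, RV sensitivity, rendering),
and the `trialrank` CLI (`simulate`, `rank`, `correlate`, `sensitivity`,
`render`) exposes the same pipeline from the shell.

## Data formats

Trials load from CSV (one outcome per row, trial fields repeated;
columns `trial_id, pub_year, update_years, regimen_a, regimen_b,
n_total, endpoint, p_value, effect_measure, effect_value, is_primary,
favored_arm`) or an equivalent nested JSON. Endpoint-class and weight
overrides, the half-life, and propagation settings load from YAML.
Networks export to SVG/PNG and GraphML.

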