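# Methods

## The valuation model

An evidence network has one vertex per treatment regimen and one edge
per published two-arm RCT comparison. Evaluated at calendar year `Y`,
the edge for comparison *y* carries a magnitude

```
|c_y| = min(−log10 P_y, 3) · RV_y · max(x_y, 1/x_y) · log10 N_y · 2^(−α_y / h)
```

and contributes `+|c_y|` to the favored arm and `−|c_y|` to the other.
A vertex's value is the sum over its incident edges; a vertex's size is
the total number of patients over all its comparisons published by `Y`.
Because every edge is antisymmetric, the total network value is exactly
zero — a cheap global audit that the tests assert to 1e−9 relative
tolerance.

Components and assumptions:

- **Strength of evidence** `min(−log10 P, 3)`: P values below .001 are
  truncated because finer significance is not interpretable across
  heterogeneous decades-old trial reports. The cap and the truncation
  point are configurable (`sig_weight_cap`, `p_truncation`) but should
  be moved together.
- **Endpoint selection and relative value (RV).** Exactly one outcome
  per comparison enters the formula. Among predefined primary endpoints
  the least-surrogate one is taken (surrogacy order: overall survival
  < progression/event-free survival < response-rate style markers; ties
  among equally surrogate primaries break by lower P, then input
  order). If that primary was met (P ≤ .05) and a strictly
  less-surrogate secondary reached marginal significance (P ≤ .10), the
  secondary substitutes; an unmet primary is used regardless of
  secondaries. RV defaults: strong 1.0, intermediate 0.8, weak 0.7;
  the endpoint-name → class map and the class weights are user-
  overridable (YAML `rv_overrides`), since real corpora carry many
  endpoint labels. Valuation resolves the class weight from the live
  configuration (not from the loaded record), so sensitivity
  perturbations reach the formula.
- **Effect coefficient** `E = max(x, 1/x)`: a ratio effect and its
  reciprocal are the same evidence seen from the two arms; E is
  assigned `+` to the favored arm. Effects reported as significant
  point estimates are expected pre-converted to a ratio by the user
  (the ratio of the reported point estimates); no internal conversion
  is attempted. Noninferiority results, and results favoring neither
  arm, contribute zero but keep the edge in the network (it still
  counts toward vertex size and topology).
- **Aging** `2^(−α/h)`: evidence halves in weight every `h` years
  (default `h = 10`, chosen so that a typical oncology treatment
  generation — roughly a decade — loses half its force as the next one
  arrives; the form makes a one-half-life refresh exactly a doubling).
  The age reference is the latest interim update not after the
  evaluation year, so updated trials age from their re-publication.
- Values are **not normalized**: magnitudes carry meaning (how much
  net evidence), so no per-network rescaling is applied, and rankings
  from differently sized networks are not directly comparable.

Interpretation: value > ε is *recommendable*, < −ε *contraindicated*,
within ±ε *insufficient evidence*. ε defaults to 0.5 — half a "unit" of
the weakest meaningful edge (a P = .10, E ≈ 1, N ≈ 100, fresh, weak-
endpoint comparison contributes ≈ 1.6) — and is configurable
(`near_zero_epsilon`).

## Propagation and refresh

A purely pairwise valuation penalizes heavily studied standards: every
newer challenger that beats the standard drags it down, while the
regimens the standard itself displaced keep their old, decayed losses —
the straw-man signature. The countermeasure is single-generation value
propagation, replayed over the publication timeline in ascending year
order:

1. For each year, every node's value delta attributable to that year's
   new edges (valued as of the evaluation year, i.e. after aging)
   becomes one event; events within a year are processed in node-id
   order for determinism.
2. A node *losing* value passes `fraction` (default 0.5) of the loss to
   the losers of its strictly earlier winning edges; a node *gaining*
   value passes the same fraction of the gain to the winners of its
   strictly earlier losing edges. The node's own change shrinks by the
   transferred amount. Multiple targets split equally by default, or
   proportionally to the qualifying edge's magnitude
   (`split_rule: proportional`).
3. Each propagated-through edge is *refreshed*: its effective age drops
   by one half-life (floored at zero), its aging coefficient at most
   doubles (capped at 1), and its contribution is revalued. Only the
   edges through which value passed are refreshed — the propagation
   path, not the whole node.

Transfers are recorded as vertex-level adjustments separate from the
edge decomposition, so the per-edge audit trail survives propagation. A
transfer is zero-sum and a refreshed edge still contributes ±c
symmetrically, so the total network value remains zero with or without
refresh. With `fraction: 0` and refresh disabled, the replay reduces
bit-identically to the plain valuation.

Two deliberate semantics, where the mechanism admits more than one
faithful reading: event deltas use edge contributions **as valued at
the evaluation year** (not at their publication year), which makes the
final state an exact decomposition (edges + adjustments) at the cost of
propagated amounts being already-decayed; and propagation is strictly
single-generation — a transfer received by a node never re-propagates.

## Diagnostics

- **Value-size correlation**: Pearson r over vertices of (value, total
  patients), with a two-sided P from the t statistic on n−2 degrees of
  freedom and a 95% CI from the Fisher z-transform with standard error
  `1/√(n−3)`. Requires ≥ 3 vertices and nonzero variance in both
  coordinates. A significantly negative r flags the straw-man pattern;
  re-running with propagation should attenuate it.
- **RV sensitivity**: all class weights are rescaled by 1+δ for
  δ ∈ {±5%, ±10%, ±20%} (capped at 1.0, since RV is a relative weight
  whose defining maximum is the strong class at 1.0), the full pipeline
  re-runs, and the report flags whether the rank order and every
  value's sign survived. Rank ties break alphabetically throughout.
- **Ranking comparison**: exact-order flag plus Kendall's τ.

## The synthetic trial-stream generator

The generator exists so the bias diagnostic and its amelioration are
testable end-to-end with no external data. It emulates the structural
story of a multi-decade treatment line:

- 20 regimens (default) enter over 1990–2020, the first two in an
  opening face-off, later ones debuting as the experimental arm of
  their first trial, spread over the first ~80% of the span;
- 4 trials per year; per-trial patient totals log-normal with median
  300 (SD 0.5 on the log scale, floored at 40) — typical phase-III
  oncology scale;
- with probability `strawman_intensity` (default 0.8) a trial's
  comparator is the currently most-studied regimen, and the newer arm
  wins with `newcomer_win_prob` (default 0.8); otherwise the comparator
  is uniform among existing regimens and the result is a coin flip.
  Coupling the newcomer advantage to the biased channel is the
  generative reading of the straw-man story — the standard is chosen
  *because* it is established yet beatable — and it makes the null
  stream (intensity 0) a genuine negative control in which value is
  uncorrelated with regimen age;
- the winner's effect is a hazard-ratio-like ratio, log-normal with
  median 0.70 (SD 0.2), and the P value is the two-sided normal test of
  the log effect with standard error `2/√N`, so significance, effect
  size, and sample size covary as they do in practice;
- the primary endpoint's surrogacy degrades over calendar time: the
  probability of a surrogate primary rises by 0.25 per decade (70/30
  weak vs intermediate when it does), echoing the drift toward
  surrogate endpoints as prognosis improves; one in five surrogate-
  primary trials also reports a secondary overall-survival outcome.

Everything is driven by one seeded generator; identical configurations
give identical streams.

What the generator does **not** model — and therefore what passing
tests do not establish about real corpora: latent regimen efficacy and
true effect heterogeneity, publication bias and unpublished trials,
multi-arm trials, noninferiority designs, interim updates, crossover,
or real endpoint vocabularies. The simulation study (200 seeds: median
pre-propagation r < −0.3, |r| attenuated by propagation in ≥ 80% of
seeds, null median |r| ≤ 0.15) demonstrates that the pipeline detects
and ameliorates the bias *it plants*; real-data correlations depend on
supplement-level trial details and the actual decay parameters.

## Numerical and design notes

- log base 10 throughout (both the P and N terms).
- A `favored_arm` of NONE with an effect different from 1 is rejected
  at load time (except noninferiority) rather than silently zeroed.
- The Fisher CI degenerates at |r| = 1, where the CI collapses to the
  point; with n = 3 the CI is the full interval.
- Vertex sizes count each comparison's `n_total` once per incident
  regimen; unreported arms of multi-arm trials contribute nothing.
- Layout is networkx's seeded spring layout; a singleton network is
  pinned to the origin. Node *area* (not radius) scales with patients
  to avoid perceptual exaggeration; opacity fades linearly to 0.25 at
  three half-lives of the vertex's newest incident evidence; node color
  is a divergent red-white-blue scale symmetric about zero; edge color
  encodes the endpoint class (weak surrogates blue).
- Test problem sizes (200-seed simulation study, 1,000 zero-sum
  fixtures, ≤ 5-trial oracle instances) were chosen as the smallest
  sizes at which the stochastic contracts are stable; the whole suite
  runs in well under a minute.

## Known limitations

- The propagation fraction and the half-life are empirical knobs; no
  fitting procedure is provided.
- Each trial is its own edge: no meta-analytic pooling of repeated
  comparisons of the same pair.
- Point-estimate effects require user-side conversion to ratios.
- Reproducing published valuations for a specific disease setting
  requires that setting's full trial tables and decay parameters; the
  package ships none.
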