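# Methods

## The object under study

A reaction dataset is a set of reactions, each a pair of compound sets
(substrates, products); stoichiometry and physiological direction are
deliberately dropped because every projection below depends only on
participation.  Eight projections are built per dataset: four constructions —

* `bi_full`: bipartite graph, compound *c* — reaction *r* iff *c* participates
  in *r*;
* `uni_compounds`: compounds adjacent iff they co-occur in a reaction (either
  side);
* `uni_reactions`: reactions adjacent iff they share a compound;
* `uni_subs_not_connected`: compounds adjacent iff they occur on *opposite*
  sides of a reaction —

each taken for the entire graph and for its largest connected component
(LCC).  All graphs are simple: a compound on both sides of one reaction
yields no self-loop, and multiple shared compounds between two reactions
collapse to one edge.  LCC ties are broken toward the component containing
the lexicographically smallest node id (determinism; ties are vanishingly
rare in practice).  Bipartite degree sequences pool both node classes into a
single distribution, so each projection yields exactly one fit.

## Power-law fitting

The tail model is the zeta-normalised discrete power law
`p(x) = x^(−α)/ζ(α, x_min)` on `{x_min, x_min+1, …}` (Clauset, Shalizi &
Newman 2009).  Two estimators for α are provided:

* `method="exact"` (default): numerical maximisation of the zeta likelihood.
  The score equation `mean(ln x) = −∂_α ln ζ(α, x_min)` has a unique root by
  log-convexity of the Hurwitz zeta; it is solved by vectorised bisection.
  The standard error comes from the observed Fisher information
  `σ = [n · ∂²_α ln ζ]^(−1/2)`.
* `method="approx"`: the familiar closed form
  `α̂ = 1 + n [Σ ln(x_i/(x_min−½))]^(−1)` with `σ = (α̂−1)/√n`.

The closed form is accurate only for `x_min ≳ 6`; at `x_min = 1` its bias is
large (for true α = 2.5 it converges to ≈ 2.02).  The continuous-limit σ
also understates the exact estimator's sampling error at small cutoffs
(at α = 3.5, x_min = 1 the true asymptotic sd is 0.032 vs 0.025 from the
formula).  The pipeline therefore uses the exact estimator with the
Fisher-information σ throughout; the approximation is kept for reference and
fixed-cutoff quick looks.

`x_min` is selected by scanning every distinct observed positive degree
except the largest (the tail must retain ≥ 2 distinct values), refitting α at
each candidate, and minimising the KS distance
`D = max_{x≥x_min} |S(x) − P(x)|` evaluated at the observed support points.
Ties in D break toward the smaller cutoff (keeps more data).  Sequences with
fewer than two distinct positive degrees are degenerate and fail every
criterion downstream.

**Goodness of fit.**  Semi-parametric bootstrap: each synthetic dataset of
size n draws each observation from the fitted tail with probability
`n_tail/n`, otherwise uniformly from the observed sub-cutoff values; each
synthetic set is refit end-to-end (cutoff re-selection included) and
`p = #{D_synth ≥ D_emp}/n_boot`, with 1000 synthetic sets by default and
`p < 0.1` ruling the power law out.  Each synthetic set uses an independent
spawned random stream, so results are reproducible from one seed.
Calibration was verified: under a true power law (n = 2000) the rejection
rate at 0.1 is ≈ 0.10 and the p-values pass a uniformity KS test.

**A structural caveat.**  Free cutoff selection can rescue the power law on
data that is nowhere near power-law over its bulk: for narrow,
binomial-like degree distributions the KS scan walks into the far upper tail
(small `n_tail`, huge α) where a steep power law mimics almost anything.
Rejection there is a matter of tail size, not model truth.  The test suite
demonstrates decisive rejection with the cutoff pinned below the mode; users
should treat `n_tail` and `x_min` as part of any verdict, which is exactly
why the tail-size criterion (`n_tail ≥ 50`) exists in the classification.

## Alternative tails and likelihood ratios

Four competitors are fit on the same tail `{x ≥ x_min}` as discrete
distributions normalised by direct summation: exponential
(`∝ e^(−λx)`, geometric, closed-form normaliser), lognormal
(`∝ x^(−1) e^(−(ln x−μ)²/2s²)`), stretched exponential
(`∝ x^(β−1) e^(−λx^β)`) and power law with exponential cutoff
(`∝ x^(−a) e^(−λx)`; at λ = 0 it reduces exactly to the pure power law, so
its maximised likelihood can never fall below the power law's).  Normalising
sums use 8192 exact terms plus a trapezoid integral on a log-x grid for any
remaining far tail; parameter values whose mass has not decayed by `x = e^80`
are treated as non-normalisable and rejected.  Optimisation is bounded
L-BFGS-B from three spread starting points (the cutoff family starts at the
nested pure-power-law optimum).

Comparison uses `R = L_PL − L_Alt = Σ_i [ℓ_i^PL − ℓ_i^Alt]`.  For non-nested
families significance comes from the Vuong normal approximation on
`R/(σ_R √n_tail)` (σ_R the empirical sd of the per-observation differences),
two-sided; for the nested cutoff family from `2|R|` against χ²(1) (slightly
conservative relative to the boundary mixture ½χ²₀+½χ²₁, which only lowers
the false-alarm rate).  A verdict (`pl_favored` / `alt_favored`) requires
`p < 0.01`; otherwise the comparison is inconclusive.  Measured behaviour:
on geometric samples (n = 10⁴, full tail) the exponential family is favored
essentially always; on true power-law samples alt-favored verdicts occur in
well under 5% of runs per family.  Note that with *free* cutoff selection a
geometric sample often escapes detection — the selected tail is short and
deep, where the ratio test has no power; the power experiments therefore pin
the cutoff at the full tail.

## Classification ladder

Per projection, four boolean criteria: no alternative favored; `p ≥ 0.1`;
`n_tail ≥ 50`; `2 < α̂ < 3`.  Per dataset (eight graphs, thresholds applied
as ≥ counts: 50% → 4/8, 90% → 8/8, 95% → 8/8):

* **Super-Weak**: ≥ 50% of graphs have no alternative favored (not nested);
* **Weakest**: ≥ 50% of graphs pass `p ≥ 0.1`;
* **Weak**: ≥ 50% pass `p ≥ 0.1` *and* `n_tail ≥ 50` jointly;
* **Strong**: Weak, Super-Weak, and ≥ 50% of graphs additionally in
  `2 < α̂ < 3`;
* **Strongest**: the Strong per-graph criteria for ≥ 90% of graphs and no
  alternative favored for ≥ 95%.

The per-graph fraction rule is used for the Strong tier (rather than a
median-α variant sometimes quoted) because it composes with the other tiers
as a monotone function of the 8×4 flag matrix; the implementation is
property-tested against a direct re-evaluation of the definitions.
Degenerate projections count as failing everything (conservative).

## Level discrimination

Each projection contributes an 11-predictor feature vector: α, the four
signed normalised likelihood-ratio outcomes (dexp, dln, dplwc, dstrexp;
zero when inconclusive, NaN when a fit failed — NaNs are median-imputed
within each training split), mean degree, n, n_tail, n_edges, the GOF p, and
x_min.

* **Balanced logistic** ("multinomial" with two classes): per repeat, a
  training set balanced across levels and sized at 80% of the minority
  level's projection count (with 785×8 ecosystem projections that is exactly
  5024), single-predictor logistic fit, per-class accuracy on everything
  held out; 100 repeats averaged.
* **Random forest**: 100 trees, mtry = 3 (≈ √11), half/half train/test
  split, OOB error from the training half, Gini importances.  Scenarios:
  all 11 predictors; without the size predictors (n, n_tail, n_edges); the
  size-blind forest per projection type.

The train/test split is made at the *dataset* level whenever grouping
information is available: the eight projections of one dataset are nearly
duplicate feature rows, and a row-level split lets a forest recognise
datasets rather than levels (measured ≈ 0.73 accuracy on a signal-free
ensemble with row splits, chance-level with grouped splits).  For the same
reason, error bars on reported accuracies should use the number of test
datasets, not rows, as the binomial n.

## Synthetic data

The generator emulates the statistics the analysis needs, not chemistry.
Reactions are drawn sequentially with 1–3 compounds per side (default).
Under preferential reuse an established compound is drawn with weight
(participation − discount) and a new compound with weight
(strength + discount · #compounds): a Pitman–Yor-type scheme.  The defaults
(strength 1, discount 0.75) give a compound inventory growing roughly like
n^0.75 and power-law-tailed participation — a 2000-reaction set yields
≈ 1700 compounds whose maximum participation exceeds the median several
hundredfold, mirroring the hub/leaf structure of real reaction inventories.
Discount 0 recovers the plain participation-proportional scheme, which
degenerates to a handful of hub compounds (Chinese-restaurant behaviour) and
is kept only as a boundary case.  The uniform mode draws from a fixed pool
and is the homogeneous negative control.  What the generator does *not*
reproduce: compound identities, reaction reversibility conventions, currency
metabolites, stoichiometry, or any fit to real KEGG statistics — so passing
tests demonstrate correctness of the *pipeline*, not claims about real
metabolism.

Two-level ensembles scale ecosystem datasets by `size_ratio` (default 3×,
ecosystems being pooled communities) with lognormal per-dataset size jitter
(sd 0.35) so the levels overlap, and can optionally widen ecosystem reaction
arity (the mean-degree effect).  With no planted effects the levels are
statistically exchangeable, which is the null used to validate the
discrimination experiments.

## Problem sizes and numerical choices

Defaults follow the study design (1000 bootstrap sets, 100 logistic repeats,
100 trees, mtry 3).  The test suite and acceptance script scale simulations
to desk size as their own design choice: GOF calibration uses 200 replicates
of n = 2000 with 200 bootstrap sets; likelihood-ratio power/false-alarm runs
use 50 replicates of n = 10⁴; discrimination ensembles use 24–32 datasets
per level of ~100 reactions with 25–30 bootstrap sets for the p feature.
Alpha bisection runs on [1.0001, 60] to ~1e-12; the KS scan evaluates the
model CDF via Hurwitz-zeta survival ratios; the power-law sampler inverts a
32768-entry CDF table exactly, resolving the far tail by bisection on zeta
ratios, so sampler and likelihood agree by construction.  All randomness is
spawned from a single seed via `numpy` SeedSequence streams.

## Known limitations

* The cutoff-escape phenomenon above: free x_min selection has little power
  against distributions whose upper tail is short and steep.
* The Vuong approximation assumes non-nested, correctly-specified-enough
  alternatives; for tiny tails (n_tail ≲ 20) its normal approximation is
  rough — such projections rarely pass the tail-size criterion anyway.
* OOB error is optimistic whenever grouped rows exist within the training
  half (bootstrap leakage); use the held-out-dataset accuracies for honest
  generalisation estimates.
* The generator's heavy-tail mechanism is one of many; results on synthetic
  ensembles quantify pipeline behaviour, not biology.
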