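# Methods

This note documents the models and procedures implemented in `dartiso`, the
assumptions behind them, the tunable parameters, and the design choices made
where more than one reasonable implementation exists.

## Spectral representation

A DART-ToF analysis of one sample yields one centroided spectrum per
Orifice-1 voltage (30, 60, 90 V via function switching). Spectra are reduced
to 0.025 Da m/z bins named for their upper limit, with a left-open,
right-closed convention: the 109.050 bin covers (109.025, 109.050], and a
centroid exactly on a boundary belongs to the bin named after it. Binning
uses a 1e-6 relative tolerance so boundary values are not pushed into the
next bin by floating-point error.

* **Background subtraction** operates on binned representations (centroid
  m/z values never match exactly between a sample and its solvent blank) and
  clamps at zero: negative ion abundances are physically meaningless.
* **Centroid floor** — peaks below 120 counts are dropped; the floor is
  inclusive (a 120-count peak is kept), reading the threshold as the minimum
  reportable value.
* **Multiple centroids in one bin are summed** (ion current is additive);
  the maximum is available via the same code path if ever needed, but
  summation is the default because it conserves total ion current — the
  assembly step is checked by exactly that conservation law.
* Wide-table columns are named `<bin upper, 3 decimals>_<voltage>V`, e.g.
  `109.050_30V`. CSV round trips are bit-exact (`%.17g` on write,
  `float_precision="round_trip"` on read).

## Variable selection and normalisation

Selection works on a temporary percent-of-base-peak scale. The retention
rule is: *keep a bin if at least `min_spectra` spectra (default 50, pooled
over all samples and voltages) reach the percent threshold* (default 0.3%).
The grammatical inverse — discard a bin when `min_spectra` spectra fail the
threshold — would retain almost nothing at a 10% threshold, but is available
via `SelectionConfig(reading="count_failing")` for comparison. Candidate
bins are then refined per voltage with the same rule restricted to that
voltage's spectra, since a fragment can be abundant at one collision energy
and absent at another. Raising the percent threshold never adds a bin
(monotonicity is property-tested), and the base-peak scale never leaks into
downstream values.

Both normalisations act per sample and per voltage, over the finally
selected bins only:

* *ion current*: x_i / Σ_j x_j — rows sum to 1 per voltage;
* *vector length*: x_i / √(Σ_j x_j²) — rows are unit vectors per voltage.

All-zero voltage segments stay all-zero with a warning rather than erroring,
so degraded samples flow through to the classifiers and show up in the
inconclusive statistics where they belong.

## Multiway ANOVA

Each selected variable is screened with a three-factor ANOVA (isomer ×
week × volume) with all interactions. Sums of squares are sequential
(Type I), computed for all variables at once by projecting the response
matrix onto the growing sequence of design subspaces (SVD-based orthonormal
bases, so the redundant dummy columns are harmless). The synthetic design is
balanced, so SS types coincide; unbalanced input triggers a warning that the
sequential decomposition is order-dependent. Factors with a single level are
skipped. The implementation is cross-checked against `statsmodels`'
`anova_lm` in the test suite and reproduces a uniform null p-value
distribution under zero class effect. Raw p-values are reported without
multiple-testing correction: the workflow's decision logic never consumes
these p-values, they are descriptive.

## Welch (univariate) classifier

A test triplicate (one card's three replicates of one compound) is compared
to each candidate isomer's training rows with an unequal-variance t test at
every variable (Welch–Satterthwaite degrees of freedom, two-sided p). A
variable is *indistinguishable* when the test fails to reject at the
replicate's confidence level; the boundary case p = α counts as a rejection.
When both groups have zero variance — reachable on noiseless synthetic
data — the convention is p = 1 for equal means and p = 0 otherwise.

The replicate harness draws, per replicate, a confidence level uniformly
in [90, 99.999]% and one of the two normalisations at random, runs
leave-one-card-out (optionally restricted to same-day cards), and counts
indistinguishable bins per candidate class. Each triplicate contributes one
positive comparison (against its true isomer) and two negatives. ROC curves
sweep integer count thresholds 0..p+1; replicate curves are averaged
pointwise in (FPR, TPR), and a pooled curve over all replicates'
comparisons is emitted as well, since it is not obvious which of the two a
given report prefers. The decision rule assigns the max-count class only
when its margin over the runner-up exceeds `min_difference`; ties are
inconclusive. Per-replicate RNG substreams derive from the master seed by
replicate counter, so any single replicate is reproducible in isolation.

## LDA

Classical equal-covariance Gaussian discriminant analysis with equal priors
(an unknown seized sample carries no prior information about its isomer):
class means, pooled within-class covariance with denominator N − K,
posteriors by Bayes' rule, likelihood ratio = highest / second-highest
posterior, reported as *indicative only* because no calibration is
performed. Discriminant axes are computed in the whitened within-class
space, giving per-variable scaling coefficients whose absolute size ranks
each bin's influence on each axis.

Two guards handle degeneracy:

* variables whose pooled within-class variance falls below 1.0e-8 are
  removed before fitting and recorded on the model;
* the pooled covariance is *structurally* singular whenever ion-current
  normalisation is used, because every voltage segment sums to one — a hard
  linear constraint — and likewise under duplicated variables. Null
  within-class directions along which the class means do not differ are
  projected out with a collinearity warning; this matches how the classical
  R implementation of LDA behaves on the same tables, and a hard error here
  would make LDA unusable on the workflow's own default data. A null
  direction along which the means *do* differ (infinite apparent
  separation, the signature of too many variables for too few samples)
  raises an explicit error recommending a smaller variable set, e.g. a
  higher percent-abundance threshold, rather than silently regularising.

## Random forest

500 unpruned CART trees (Gini splits, minimum node size 1), each grown on a
bootstrap resample of the training-set size, with ⌊√p⌋ (minimum 1) candidate
variables at each split. Tree induction is delegated to scikit-learn's
`DecisionTreeClassifier`; the bootstrap is drawn in-package so per-tree bag
membership is an explicit, inspectable array — out-of-bag vote profiles,
the OOB fraction (≈ (1 − 1/n)ⁿ → e⁻¹, verified), and permutation importance
all read it directly.

* **Vote profiles** — per sample, the proportion of voting trees assigning
  each isomer; OOB profiles use only trees whose bootstrap excluded the
  sample. A sample in every bootstrap (vanishingly rare) is flagged.
* **Permutation importance (MDA)** — shuffle one variable's values among
  samples, re-classify the OOB samples with plain argmax, record the drop in
  accuracy; default 5 shuffles averaged (a single pass is available for
  literal mode; the identity permutation gives exactly 0). Argmax ties
  resolve to the first class for the accuracy bookkeeping only.
* **Elimination curve** — at each step, a stratified 12-fold
  cross-validated error is recorded, importance is (re-)ranked, and the top
  ⌈p/2⌉ variables are kept, down to a single variable. Re-ranking at each
  step is the default; reusing the initial ranking is available, since the
  original procedure's choice is not specified at this level of detail.
* **Triplicate rules** — *all-match* (all three argmax classes agree; the
  mean of the three top proportions meets the threshold), *majority* (at
  least two agree; mean of the agreeing proportions) and *highest* (the
  single best sample speaks). An argmax tie within one replicate counts as
  no clear assignment — a conservative forensic choice.

## Decision framework

All classifiers end in the same rule: report the argmax class iff its score
meets the acceptance threshold, swept 0.50–0.95 in 0.05 steps; ties are
inconclusive. The conclusive boundary is score ≥ threshold, so a unanimous
0.50 vote is conclusive at the 0.50 threshold and rate tables can be fully
conclusive in their first row. Because thresholds are applied after the
models are fitted, a rising threshold can only convert conclusions into
inconclusives — never flip a class — and success/error rates are
non-increasing while the inconclusive rate is non-decreasing (property
tested). Rate tables report success (correct conclusive), error (wrong
conclusive) and inconclusive fractions, which sum to one.

Validation harnesses: leave-one-card-out (the card is the exchangeable unit;
its nine analyses leave training together, so replicate correlation cannot
leak), per-day leave-one-card-out (training restricted to same-day cards;
"day" equals "week" in the default design, where each weekly session is a
single day), and stratified 80/20 splits (288 samples give a 58-sample test
set by ceiling rounding).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design exactly: 3 isomer classes,
8 weeks × 4 cards × 3 replicates = 96 analyses per compound (288 per set);
each card carries a triplicate of every isomer; two cards per week at 3 µL
and two at 6 µL; three voltages per analysis.

Ion abundances are multiplicative (lognormal effects throughout — ambient
ionisation intensities are positive and right-skewed):

```
abundance(s, f) = exp( μ_f + class_offset(c(s), f)
                       + sens_f · log V(vol(s))
                       + load_f · W_week(s) + U_week(s),f
                       + ε_{s,f} )
```

* `μ_f` — mean log abundance of catalogue fragment f (exp(11.8) ≈ 1.3e5
  counts for the protonated molecule at 30 V).
* `class_offset` — per-fragment class contrasts. The protonated molecule
  carries no class effect at any voltage (positional isomers share [M+H]+;
  these bins are the negative control for ANOVA and importance tests);
  the discriminating signal lives in is-CID fragments, several of them
  low-abundance bins near the selection threshold — recovering their
  importance is one of the package's acceptance checks.
* `W_week` — a weekly factor shared across fragments (per-fragment loading
  `load_f` ∈ [0.3, 1]); it is what makes variables positively correlated
  and what the accumulating weekly means stabilise over, `sd = 0.30`.
* `U_{week,f}` — idiosyncratic per-(fragment, week) drift, `sd = 0.25`.
* `V(vol)` — deposition-volume factor (1.0 / 1.9 / 2.6 for 3/6/10 µL; the
  response saturates, so doubling volume does not double signal), raised to
  a per-fragment sensitivity in [0.85, 1.15] so volume alters the relative
  composition and survives normalisation for about half the bins.
* `ε` — per-peak noise, `sd = 0.35` on the log scale, scaled per class by
  (1.0, 1.4, 0.75): the isomers fragment with different reproducibility
  (ortho-effect rearrangement pathways are the most variable). These
  genuinely unequal class covariances are what the equal-covariance LDA
  model mis-specifies and the forest tolerates — the mechanism behind the
  observed classifier ordering.
* Centroid m/z jitter is uniform ±5 mDa, and every catalogue mass sits at
  least 5 mDa inside its bin, so a fragment always maps to one stable bin;
  moving masses toward a boundary deliberately exercises bin splitting.
* Six "junk" peaks per spectrum sit just above the 120-count floor but
  below any percent-abundance threshold, exercising the selection step.

The catalogue combines 17 named fragments with 48 deterministic minor ions
(a fixed internal constant, not a run seed), because real DART spectra carry
dozens of reproducible minor peaks; about a third of the minor ions carry a
small class effect. After default selection this yields p ≈ 65 variables
for n = 288 samples — wide enough that LDA's covariance estimation is
genuinely strained, which is the regime the workflow is designed to probe.

The external batch reuses the fragment catalogue with a tenfold intensity
scale (a concentration change), per-card drift at 1.5× the weekly scale
(the cards were run on scattered days), and its own volume rule (three
10 µL cards, then 3 µL cards; 11 cards × 9 analyses = 99 samples = 33
triplicates).

**Not modelled:** chemically real fragment formulas, isotope patterns,
profile-mode peak shapes (spectra are generated post-centroiding), mass-axis
calibration drift, mixtures and cutting agents, and instrument-to-instrument
transfer. Passing tests therefore show that the *pipeline* recovers the
structure this model injects under realistic noise and batch drift — not
that any particular real isomer pair is separable on a given instrument.

## Numerical choices and degenerate inputs

* Fixed default seed 20210317, recorded in every run's JSON sidecar and
  manifest; all RNG flows from `numpy.random.default_rng` with derived
  substreams, so reruns are byte-identical.
* Welch zero-variance convention as above; indistinguishability boundary
  p > α.
* Normalisation invariants hold to 1e-12; posteriors sum to 1 within 1e-12.
* LDA variance tolerance 1.0e-8 (per variable); structural-null cutoff at
  1e-10 of the largest within-class eigenvalue.
* Argmax ties anywhere in the decision framework are inconclusive.
* Problem sizes in the test suite and acceptance script: the full 288-sample
  design for the end-to-end checks; 500 trees for headline forest numbers
  and 100–300 trees for multi-seed Monte Carlo loops and the elimination
  curve, which leaves every Monte Carlo comparison comfortably clear of its
  assertion band while keeping runs short.

## Known limitations

* The LDA likelihood ratios are uncalibrated by construction and flagged
  as indicative; do not report them as evidential LRs.
* The Welch classifier's counts ignore inter-bin correlation, which the
  heat maps show is substantial; this is inherent to the method.
* Sequential ANOVA on unbalanced designs is order-dependent (warned).
* The synthetic generator's week drift is stationary across classes; it
  does not model class × week interactions beyond what the shared and
  idiosyncratic drift induce through normalisation.
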