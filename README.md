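# dartiso

Chemometric differentiation of positional ring isomers of novel psychoactive
substances (NPS) from multi-voltage DART-ToF mass spectra.

## The problem

Positional ring isomers — compounds that differ only in where a single
substituent sits on an aromatic ring (ortho/meta/para, or 2-/3-/4-) — are a
long-standing headache for forensic drug laboratories, and they can fall
under different levels of legal control. DART-ToF with in-source
collision-induced dissociation (is-CID) is fast and needs no chromatography,
but ambient ionisation makes spectra of such isomers visually
indistinguishable: the differences are small shifts in fragment-ion
abundance, buried under considerable run-to-run variation. `dartiso`
implements a complete chemometric workflow that extracts those latent
differences and turns them into conclusive-or-inconclusive forensic calls:

1. **Binning** — centroided spectra from three Orifice-1 voltages
   (30/60/90 V) are placed into 0.025 Da m/z bins (named for their upper
   limit) after background subtraction and a 120-count centroid floor, giving
   one wide table with a `(bin, voltage)` column per variable.
2. **Variable selection** — each spectrum is temporarily scaled to a 100%
   base peak; a bin is retained when at least `min_spectra` spectra reach the
   percent-abundance threshold, then refined per voltage. Raw abundances pass
   through; the percent scale is used only here.
3. **Normalisation** — per sample and per voltage, either *ion current*
   (divide by the summed abundance of the selected bins, x_i / Σx) or
   *vector length* (divide by the Euclidean norm, x_i / ‖x‖).
4. **Screening** — a per-bin multiway ANOVA over isomer × week × deposition
   volume with all interactions, plus weekly/accumulating profiles and
   variable correlation maps.
5. **Classifiers** — three families sharing one decision framework:
   * **Welch** — a per-bin unequal-variance t test compares a test
     triplicate to each candidate isomer; indistinguishable bins are counted
     and fed to ROC sweeps or a max-count margin rule.
   * **LDA** — equal-prior linear discriminant analysis; posterior
     probabilities, top-two likelihood ratios (indicative only) and
     scaling-coefficient influence.
   * **Random forest** — 500 unpruned trees, mtry = ⌊√p⌋, out-of-bag (OOB)
     vote proportions, permutation importance (mean decrease in accuracy),
     and a 12-fold cross-validated halving elimination curve.
6. **Decisions** — the top score (vote proportion or posterior) is compared
   to thresholds swept 0.50–0.95 in 0.05 steps: the argmax class is reported
   only when its score meets the threshold, otherwise *inconclusive*.
   Raising the threshold can only turn a call inconclusive, never flip it.
   Triplicate rules (all-match / majority / highest) combine one card's
   three replicates into a single conclusion.

Validation harnesses include leave-one-card-out (one QuickStrip card's worth
of data per fold), stratified 80/20 splits, same-day-restricted training and
application of a trained forest to an external batch acquired under shifted
conditions.

Because no instrument data ship with the workflow, `dartiso.synthetic`
generates centroided spectra with the study's full design — 3 isomers ×
8 weeks × 4 cards × 3 replicates (96 analyses per compound, 288 per isomer
set), two deposition volumes, week-level batch drift that stabilises as data
accumulate, class effects carried partly by low-abundance fragments, and an
11-card external validation batch — so every stage is testable end to end.

## Worked example

```python
from dartiso import (DesignConfig, default_model, generate_design, simulate_spectra,
                     apply_abundance_floor, assemble_table, SelectionConfig,
                     select_bins, refine_per_voltage, normalize,
                     ForestConfig, fit_forest, oob_vote_profiles, rate_table)
from dartiso.forest import oob_error

design = generate_design(DesignConfig())
spectra = [apply_abundance_floor(s) for s in simulate_spectra(design, default_model(), seed=1)]
binned = assemble_table(spectra, design)
sel = SelectionConfig(pct_threshold=0.3, min_spectra=50)
variables = refine_per_voltage(binned, select_bins(binned, sel), sel)
table = normalize(binned, variables, "ion_current")

forest = fit_forest(table.values, table.metadata["isomer"], ForestConfig(n_trees=500, seed=1))
votes = oob_vote_profiles(forest)
scored = [(table.metadata.loc[s, "isomer"], row[list(forest.classes)].to_dict())
          for s, row in votes.iterrows()]
rates = rate_table(scored, thresholds=[0.50, 0.70, 0.90])

print(f"{len(variables)} variables selected; OOB error {oob_error(forest):.2%}")
print(rates.round(3))
```

prints

```
65 variables selected; OOB error 0.69%
           success  inconclusive  error
threshold
0.5          0.969         0.031    0.0
0.7          0.691         0.309    0.0
0.9          0.097         0.903    0.0
```

65 `(bin, voltage)` variables survive the 0.3%/50-spectra selection. The
forest misclassifies 0.69% of samples by plain OOB argmax; with the decision
framework the error rate is 0% at every threshold — raising the threshold
converts successes into inconclusives (3.1% at 0.50, 90.3% at 0.90) rather
than into errors, which is exactly the trade a forensic reporting rule wants.

The same workflow is available from the shell:

```bash
dartiso run --seed 1 --outdir out/          # full pipeline, all CSV outputs
dartiso simulate --seed 1 --outdir sim/     # just the synthetic spectra
dartiso rf --seed 1 --outdir out/           # forest + external batch + rates
```

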