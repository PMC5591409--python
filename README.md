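# nmrmetab

Chemometric analysis of serum ¹H-NMR metabolomic profiles, built for the
kind of clinical study that asks whether healthy controls (C), drug-responder
(R) and drug-resistant (NR) epilepsy patients can be discriminated from their
blood-serum metabolite fingerprint. It covers the full workflow those studies
run:

1. **Binning** — each frequency-domain spectrum is divided into consecutive
   0.04-ppm buckets over 0.6–8.6 ppm, the residual-water (4.64–5.2 ppm) and
   noise (5.28–6.6 ppm) regions are excluded, and bucket areas are normalized
   to percent of total area.
2. **Pareto scaling and PCA screening** — x′ⱼ = (xⱼ − x̄ⱼ)/√sⱼ; Hotelling-T²
   limits flag (report-only) potential outlier sera.
3. **OPLS-DA** — a two-class orthogonal projections to latent structures
   model ("1P + 1O": one predictive + one orthogonal component) with
   R²X/R²Y (goodness of fit) and 7-fold cross-validated Q² = 1 − PRESS/SS
   (goodness of prediction).
4. **Validation** — label-permutation testing (default n = 500) with
   R²/Q²-vs-r intercept diagnostics, and CV-ANOVA
   F = ((SS − PRESS)/A)/(PRESS/(N − 1 − A)).
5. **Biomarker selection** — S-plot (per-bucket covariance p1 and correlation
   p(corr)1 with the predictive score) joint with VIP ≥ 1 thresholds, and
   chemical-shift mapping of selected buckets to metabolites.
6. **Quantification and univariate confirmation** — targeted integration of a
   designated multiplet per metabolite against the TSP internal standard
   (0.507 mM, 9 protons, δ = 0.0 ppm): conc = (A_m/n_m)/(A_ref/9) × 0.507 mM,
   followed by Mann–Whitney U tests per group pair with Holm–Bonferroni
   correction.

Because cohort studies rarely deposit raw spectra, the package ships a
first-class **synthetic cohort simulator**: Lorentzian multiplets with
binomial line ratios at 499 MHz, per-class concentration distributions for
the discriminant serum metabolites (ketone bodies, lactate, glucose, citrate,
scyllo-inositol, …), truncated-normal sampling, chemical-shift jitter,
baseline, residual-water hump and noise — with a ground-truth table, so every
stage is testable end to end by parameter recovery.

## Worked example

```python
import numpy as np
from nmrmetab import *

library = build_default_library()
spectra, truth = simulate_cohort(CohortDesign(35, 18, 17, seed=7), library)
grid = build_bin_grid(0.6, 8.6, 0.04, [(4.64, 5.2), (5.28, 6.6)])
matrix = assemble_bin_matrix(
    [normalize_percent(bin_spectrum(s, grid)) for s in spectra], grid
)
print(f"{matrix.n_samples} samples x {matrix.n_bins} bins")

results = OPLSDA(matrix.subset(("C", "NR")), classes=("C", "NR"), n_orth=1).fit()
print(results.summary())
perm = results.permutation_test(n_perm=500, seed=7)
print(f"R2 intercept {perm.r2_intercept:.3f}   Q2 intercept {perm.q2_intercept:.3f}   "
      f"P(Q2_perm >= Q2) {perm.p_q2:.4g}")
print(f"CV-ANOVA p = {results.cv_anova().p:.3g}")

sel = select_discriminants(results.s_plot(), results.vip(), classes=("C", "NR"))
mapped = map_bins_to_metabolites(sel, grid, library)
named = mapped[mapped.metabolites != "unassigned"]
print("discriminant buckets ->", sorted(set(";".join(named.metabolites).split(";"))))

conc = quantify_cohort(spectra, library)
lac = conc[conc.metabolite == "lactate"]
for g in ("C", "R", "NR"):
    v = lac.loc[lac.group == g, "conc_mM"]
    print(f"lactate {g:>2}: {v.mean():.2f} +/- {v.std(ddof=1):.2f} mM")
```

prints

```
70 samples x 153 bins
OPLS-DA summary
===============
comparison:   C vs NR  (n = 35 vs 17)
components:   1P + 1O
R2X(cum):     0.395
R2Y(cum):     0.965
Q2(cum):      0.938
R2 intercept 0.291   Q2 intercept -0.385   P(Q2_perm >= Q2) 0.001996
CV-ANOVA p = 2.72e-30
discriminant buckets -> ['2-OH-butyrate', '2-OH-valerate', 'acetate', 'acetoacetate', 'acetone', 'alanine', 'glucose', 'glutamate', 'lactate', 'scyllo-inositol']
lactate  C: 1.89 +/- 0.04 mM
lactate  R: 1.72 +/- 0.05 mM
lactate NR: 1.15 +/- 0.05 mM
```

Reading this: the 70-subject cohort bins into 153 retained buckets; the
control vs non-responder OPLS-DA separates the classes strongly (high
cross-validated Q², negative Q² permutation intercept, tiny CV-ANOVA p);
the S-plot/VIP selection finds buckets belonging to the ketone bodies,
lactate, glucose and the overlapping 0.92-ppm 2-hydroxy-acid pair; and the
TSP-referenced quantification recovers the per-class lactate levels the
simulator drew them from. On synthetic cohorts the separation is cleaner
than a real serum study would show — see `docs/methods.md` for what the
simulator does and does not emulate.

The same workflow is scriptable from the shell:

```sh
nmrmetab simulate --design 35,18,17 --seed 7 --out run/
nmrmetab bin --manifest run/manifest.tsv --out run/matrix.tsv
nmrmetab fit --matrix run/matrix.tsv --classes C,NR --orth 1 --out run/C_vs_NR
nmrmetab run --out full_run/          # whole pipeline from one config
```

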