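# Methods

This note records the models, conventions and numerical choices behind
`nmrmetab`, in the order the pipeline applies them, together with the design
decisions that were genuinely open and the limitations a user should know.

## Synthetic serum spectra

**Signal model.** A spectrum is a sum over metabolites of first-order
multiplets. A multiplet with multiplicity m has m Lorentzian lines spaced
J/ν₀ ppm apart (ν₀ the spectrometer frequency, default 499 MHz) with
binomial intensity ratios (1 — 1:1 — 1:2:1 — …). The Lorentzian is the
natural lineshape of an exponentially decaying FID; Gaussian/Voigt
refinements add nothing for pipeline testing. Default half-width at
half-maximum is 1.0 Hz (≈ 0.002 ppm at 499 MHz; glucose ring lines use
1.5 Hz to mimic the unresolved envelope). Each metabolite's total integrated
area is concentration × proton count, with one common response factor for
all species including the TSP reference — the assumption that also underlies
internal-standard quantification.

**Chemical shifts** are standard serum reference values (lactate doublet
1.33/quartet 4.11; acetate 1.92; acetone 2.23; acetoacetate 2.27; citrate AB
2.54/2.66; 3-OH-butyrate doublet 1.20; scyllo-inositol 3.35; glucose ring
envelope 3.2–3.9 plus anomeric doublet 5.23; alanine 1.48; choline 3.20;
glutamate 2.08/2.35; the overlapping 2-OH-butyrate and 2-OH-valerate
triplets both at 0.92). They are implementation defaults, editable in
`src/nmrmetab/data/serum_library.yaml`, not measured values.

**Concentrations.** Per-class (C/R/NR) normal distributions truncated at
zero (rejection sampling; only mean ± SD are published, so the simplest
non-negative law is used). Eight metabolites carry published per-class
means/SDs (`source: paper` in the library file). For the four metabolites
whose table was never printed (choline, alanine, glutamate, the 2-OH acids),
defaults in the 0.05–0.3 mM range ordered C < R < NR — the reported
direction of change — stand in and are flagged `source: default`. Note a
consequence of truncation: when the mean is below ~2 SD (acetone in
controls: 0.0008 ± 0.001 mM), the realized mean exceeds the nominal mean by
σφ(μ/σ)/Φ(μ/σ); the sampling tests therefore check against the analytic
truncated-normal mean, which coincides with the nominal mean whenever
μ ≥ 2σ (all quantification-anchor cases).

**Artifacts.** Per-sample, per-metabolite chemical-shift jitter
(SD 0.003 ppm, small against the 0.04-ppm bucket) emulates pH/ionic-strength
shifts; TSP, being the referencing standard, is never jittered. A broad
Lorentzian "residual water" hump sits at 4.79 ppm (15 Hz linewidth, peak
height 0.2 × the TSP peak) — inside the excluded 4.64–5.2 ppm window, so
default preprocessing removes it. White noise with SD a fraction of the
analytic TSP peak height (default 0.002, a high-SNR averaged acquisition);
an optional polynomial baseline defaults to zero since real spectra are
baseline-corrected before analysis. The output grid is 16,384 points over
−0.5…9.5 ppm (≈ 3 points per half-width; trapezoidal integration of a
Lorentzian on such a grid is accurate far beyond the 1% the tests demand).
Synthesis is frequency-domain only — no FID simulation, no second-order
coupling, no lipoprotein broad signals — so passing tests certify the
statistical machinery, not robustness to phasing or alignment errors that
real serum spectra can carry.

## Preprocessing

Buckets are left-closed/right-open intervals of exact width laid from the
low edge; a bucket overlapping an excluded interval **in any part** is
dropped whole (the conservative convention; edge-touching within a 1e-9
relative tolerance is not an overlap). The standard grid — 0.6–8.6 ppm,
0.04-ppm buckets, exclusions [4.64, 5.2) and [5.28, 6.6) — retains 153
buckets, since both exclusion windows land exactly on bucket edges
(200 − 14 − 33). Bucket values are trapezoidal integrals with linear
interpolation at edges between grid points; negative intensities (noise)
integrate as-is — clipping would bias areas — and only a non-positive total
area marks a sample unusable. Normalization divides by total area ×100
(percent of total), suppressing dilution differences between sera.

## Multivariate models

**Pareto scaling** divides each centered column by √s (s the n−1 sample
SD); zero-variance columns are centered only and flagged. Cross-validation
refits the scaler on each training split — scaling with held-out rows
included would leak.

**PCA** is computed by SVD of the scaled matrix (NIPALS retained only as a
test cross-check). Explained fractions are per-component score sums of
squares over the total. The Hotelling T² screen flags samples with
T² > A(N²−1)/(N(N−A))·F₁₋α(A, N−A) at α = 0.05; flags are reported, never
acted on.

**OPLS-DA.** Class membership is coded 0/1 (SIMCA's two-class behaviour)
and centered. The orthogonal filter iterates: w ∝ Xᵀy normalized; t = Xw,
p = Xᵀt/(tᵀt), w_o = p − (wᵀp)w normalized, t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o),
X ← X − t_o p_oᵀ; then one predictive component on the filtered matrix.
With n_orth = 0 this reduces exactly to one-component NIPALS PLS1 (tested to
1e-10). Default component specification is 1P + 1O. R²Y = 1 − ‖y − tc‖²/‖y‖²;
R²X(cum) accumulates ‖t pᵀ‖²/‖X₀‖² over all components. If no y-orthogonal
variation remains, the filter stops early rather than extracting noise.

**Cross-validation.** Seven folds (the default of the software this kind of
study is analysed with), assigned deterministically: samples ordered by
(class, id) take folds 0,1,2,… cyclically — seed-free and class-balanced.
Each fold rescales and refits from scratch; Q² = 1 − PRESS/SS with SS the
total corrected y sum of squares. Q² ≤ R²Y is an enforced test invariant.

## Validation

**Permutation test.** y is shuffled n_perm times (uniform draws, duplicates
allowed — the permutation space is astronomically larger than 500); each
refit uses the identical specification and cross-validation. Following the
convention that the validate plot is evaluated on the corresponding PLS-DA
model, refits default to PLS-DA with the same total component count
(``mode="oplsda"`` refits the OPLS-DA itself). r is the absolute Pearson
correlation between permuted and original centered y. Least-squares lines of
R²Y-vs-r and Q²-vs-r are fitted over all permuted records plus the
unpermuted anchor at r = 1; intercepts at r = 0 are the overfitting
diagnostics, and empirical p-values use the add-one rule. The reported (not
enforced) pass heuristic is R² intercept < 0.4 and Q² intercept < 0.05; with
few samples and many buckets the R² half fails routinely even for valid
models, which is informative, not an error.

**CV-ANOVA.** F = ((SS − PRESS)/A)/(PRESS/(N − 1 − A)) with A the total
component count, p from the upper tail of F(A, N−1−A); PRESS > SS yields a
negative F, reported as p = 1. The F reference distribution is approximate:
null simulations at the pipeline's own dimensionality (N = 50 samples × 153
buckets) put the empirical size at α = 0.05 inside the 99% binomial band,
but at low dimensionality (tens of columns) the test runs conservative
(size ≪ α). That behaviour is inherent to CV-ANOVA, not an implementation
artifact.

## Biomarker selection and quantification

The S-plot pairs p1 = cov(t, xⱼ) with p(corr)1 = corr(t, xⱼ) on the same
Pareto-scaled matrix the model was fitted to. VIPⱼ = √(J·Σₐ wₐⱼ²SSYₐ/ΣₐSSYₐ)
over all components; orthogonal components explain no y variance so they
enter only through weight normalization (a predictive-only variant is
available via a flag since OPLS VIP conventions vary). Mean squared VIP is 1
by construction. Selection requires |p(corr)1| ≥ 0.5 **and** VIP ≥ 1 —
conventional defaults, configurable. Selected buckets are annotated with
every library metabolite owning a line within 0.02 ppm; multi-hit buckets
(the 0.92-ppm pair) are flagged ambiguous, no-hit buckets "unassigned".

**Targeted quantification** replaces proprietary spectral-library
deconvolution with integration of one designated, well-isolated multiplet
per metabolite (designation stored in the library file):
conc = (A_m/n_m)/(A_ref/9) × 0.507 mM. The baseline under each window is a
chord through the mean intensity of 0.005-ppm flanking segments just outside
the window (averaging flank points rather than using the two endpoint
samples keeps the chord noise down). Because a finite window truncates
Lorentzian tails — and the chord removes part of the signal's own wings —
areas are divided by the analytic capture fraction of the designated line
pattern within its window (computed from the library's multiplet geometry
and linewidth, including the chord term). This removes the systematic
window-truncation bias for any window width; without it, narrow windows
(acetone's, hemmed in by acetoacetate 0.04 ppm away) read up to ~15% low.
The correction can be disabled to obtain the plain area ratio. Negative
areas clip to zero with a warning; a non-positive TSP area is an error. The
overlapping 0.92-ppm 2-hydroxy-acid pair is quantified as a combined signal
with an explicit overlap warning, mirroring studies that decline to report
those species separately; glucose is quantified at its isolated anomeric
doublet rather than the crowded ring envelope.

**Univariate confirmation.** Mann–Whitney U (U = min(U₁, U₂), midrank ties)
with exact enumeration p-values for tie-free samples of total size ≤ 12 and
the tie-and-continuity-corrected normal approximation otherwise (delegated
to scipy; the test suite re-derives the exact branch by full enumeration).
Holm–Bonferroni adjustment (statsmodels) is applied per comparison across
the metabolites tested in that comparison — the family the per-comparison
reporting implies — not pooled over comparisons.

## Pipeline determinism and problem sizes

Every stage writes tab-separated intermediates; the report is regenerated
from them, so a run is byte-reproducible from (config, seed) and re-entrant.
The test suite and the acceptance script keep simulations at desk scale:
cohorts of 22–70 spectra for model fitting, 100 spectra per group for
quantification round trips, 100–500 label permutations, and 500–1000
repetitions for the type-I-error simulations — sizes chosen so the full
suite completes in a few minutes while keeping binomial test bands tight
enough to be meaningful.

## Known limitations

- Frequency-domain synthesis cannot exercise phasing, baseline-correction or
  alignment failures; results on real spectra depend on that upstream care.
- The published bucket count for this grid is 159; the stated range, width
  and exclusions yield 153 under any whole-bucket convention. The grid is
  fully configurable; the discrepancy is recorded rather than resolved.
- Synthetic cohorts separate more cleanly than real sera (no drug
  metabolites, lipoproteins, or correlated physiological variation), so
  absolute R²/Q² values here exceed what a real cohort shows; the tests
  assert qualitative recovery, not equality with any published model fit.
- CV-ANOVA p-values at low matrix dimensionality are conservative (above).
- Exact fold partitioning and component auto-selection rules of commercial
  chemometrics software are proprietary; cross-validated quantities are
  reproducible within this package, not against that software.
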