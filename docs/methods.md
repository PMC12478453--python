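# Methods

`seraman` turns point-scanned serum Raman maps into a ratiometric
metabolite peak table and runs the cohort statistics used in serum
biomarker studies. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic cohorts do and do
not establish about real data.

## Spectral model and preprocessing chain

A measured point spectrum is modelled as

    I(ν) = B(ν) + Σ_k a_k · φ(ν − ν_k) + ε(ν) + spikes,

with `B` a smooth, strictly positive fluorescence background several
times larger than the bands, `φ` a narrow line shape (FWHM ≈ 8 cm⁻¹),
`a_k` the band amplitudes at the 40 panel positions (621–1682 cm⁻¹),
`ε` white channel noise, and sporadic cosmic-ray spikes of 1–3 channels.
The processing chain, applied per sample in this order:

1. **Cosmic-ray removal.** Spikes are not reproducible across the
   replicate points of a sample's line map, so a channel of one point is
   flagged when its deviation from the per-channel median across points
   exceeds 8 robust standard deviations. The noise scale is a *pooled*
   MAD over all channels and points: a per-channel MAD over a handful of
   replicates is so variable that it produces false repairs at the
   per-mille level, while the pooled estimate over ~10⁴ deviations is
   stable and uncontaminated by sparse spikes. Flagged runs of at most 3
   channels are repaired by linear interpolation from the flanking
   channels; wider runs are left alone (they are features, not spikes).
   With fewer than 3 replicates a single-spectrum fallback flags large
   residuals against a 5-channel median filter.

2. **Savitzky–Golay smoothing**, 5th-order polynomial over a 17-channel
   frame. Edge channels are handled by fitting the full boundary window
   and evaluating the polynomial at the edge positions, so no data is
   fabricated outside the measured range. The filter is exact on
   signals of polynomial degree ≤ 5 and linear in its input.

3. **Modified-polyfit baseline estimation**, degree 9. The fit-and-clip
   iteration: least-squares fit a polynomial to the working signal,
   replace every working value above the fit by the fit, repeat. Bands
   sit above the background and are flattened out of the working signal;
   the smooth background survives. Numerical choices:
   - the channel axis is rescaled to [−1, 1] (degree-9 fits on raw
     wavenumbers are numerically hostile); the Vandermonde pseudo-inverse
     is computed once per spectrum;
   - the stop rule is sup-norm change of the fit below `tol` (default
     10⁻⁶) times the input's peak-to-peak range. The peak-to-peak
     denominator is shift-invariant, which makes the entire iteration
     exactly equivariant under positive affine intensity maps — the
     property that makes the final peak table invariant to laser power
     and detector offset;
   - hitting the iteration cap (default 100) is recorded in QC and the
     last iterate returned, never raised. With realistic backgrounds the
     fixed point is typically reached near 300 iterations; the iterates
     at 100 and at convergence differ negligibly (≪ noise), so the
     default cap trades a QC warning for a 3× speedup.

4. **SNV normalisation**: (x − mean)/sd per spectrum (sd with one
   degree of freedom), removing multiplicative and additive intensity
   effects. Constant spectra are a hard error.

### Known accuracy limits of the chain

The clip iteration settles slightly *below* the background in peak-free
regions and slightly above it under bands; the residual error scales
with the mean band amplitude, not with the noise. Under the default
amplitude profile it is comparable to the 1% channel noise. Two
consequences, measured and accepted:

- even noiseless spectra lose ~0.5–1% of band height to the baseline
  step (worst near the spectral edges), so band ratios are recoverable
  to a few percent, not exactly;
- bands closer together than the linewidth (1002/1011, 1249/1257,
  992/1002, 1605/1615 cm⁻¹ …) cannot be separated by a windowed
  maximum; the weaker band's value reads the stronger neighbour's
  shoulder. This is a physical resolution limit, not an implementation
  artifact, and recovery contracts are therefore stated for resolved
  bands.

## Ratiometric quantification

Per sample the processed point spectra are averaged (maximising SNR),
each band is quantified as the maximum within ±5 cm⁻¹ of its nominal
position (robust to a few cm⁻¹ of calibration drift), and every value is
divided by the 1448 cm⁻¹ lipid/protein CH-deformation band of the same
sample. The methods literature quotes the reference band as 1447 or
1448 cm⁻¹; with a ±5 cm⁻¹ window the 1 cm⁻¹ discrepancy is immaterial
and 1448 is used as the nominal position.

One design choice needs stating: before the division, the per-spectrum
mean removed by SNV is added back (it is recorded on each processed
spectrum as `snv_offset`). The SNV *scale* cancels in the ratio either
way, but the subtracted mean does not — left in place it shifts
numerator and denominator equally and biases every ratio toward 1 by
roughly the average band mass (~20% for mid-strength bands). Restoring
it makes the ratio a consistent estimator of the band-amplitude ratio
while preserving affine invariance.

## Cohort statistics

- **Volcano**: fold change = ratio of group means on the linear scale;
  p-values from the unpaired two-sided pooled-variance t-test;
  significance at raw p < 0.05 by default, with Benjamini–Hochberg
  behind a flag (fidelity to common practice first, rigor optional).
  Constant features (the denominator column) get p = NaN, never an
  error.
- **Pearson correlation matrices** over shared samples; zero-variance
  features are marked NaN.
- **ROC–AUC** by the Mann–Whitney rank formula with ties credited ½;
  orientation is fixed (no auto-flip below 0.5). 95% CIs by stratified
  percentile bootstrap with 2000 resamples.
- **PCA** with column centring and, by default, unit-variance scaling
  (peak and protein features live on incommensurate scales).
- **PCA–tSNE**: PCA to 10 components, then tSNE to 2D with perplexity
  min(30, (n−1)/3), deterministic for a fixed seed.
- **PCA + linear SVM with leave-one-out CV**: for each held-out sample
  the scaler, the 2-component PCA and the SVM are fit on the remaining
  n−1 samples only; the cost C ∈ [1, 100] is chosen by an *inner*
  leave-one-out on the training fold (ties to the smallest C), so
  hyperparameter selection never sees the held-out sample. A leaky
  variant (single global PCA and C) is available for comparison via
  `nested=False`. Note a known property of leave-one-out under permuted
  balanced labels: the training majority is always the wrong class, so
  null accuracies sit below 0.5 — around 0.35–0.40 for unstructured
  noise cohorts of 16–40 samples, around 0.45 when a clustered cohort's
  labels are permuted. Permutation nulls are therefore read against
  this bias, not against 0.5 exactly.
- **NAR stratification**: complete < 8, partial 8–14 with inclusive
  boundaries, poor > 14. Lower is better.
- **Protein rank metric**: −log10(p) · sign(log2 FC), FC =
  complete/poor ratio of group means; sign(log2 1) ≡ 0 so an exactly
  null fold change is never directional. Differential expression is
  called when the metric rounded to 4 decimals strictly exceeds 1.3010
  (the α = 0.05 line, printed as 1.30): p = 0.05 exactly is *not*
  differential, p = 0.04 is. Set-level enrichment is delegated to
  external tools via the emitted `.rnk` file.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with every draw logged in a ground-truth record:

- band amplitudes = base profile × group effect × lognormal biological
  variation (cv 15% by default, keeping positivity and realistic
  volcano behaviour). The default base profile follows serum practice:
  the 1448 cm⁻¹ reference dominates (1.0), phenylalanine 1002 at 0.6,
  amide/lipid 1657 at 0.45, remaining bands cycling 0.10–0.35;
- pseudo-Voigt (50/50) line shape, FWHM 8 cm⁻¹, typical of serum
  fingerprint bands; Gaussian and Lorentzian selectable;
- background: random positive degree-6 polynomial, 5–20× the reference
  amplitude — inside the degree-9 correction model by construction;
- channel noise sd = 1% of the sample's reference amplitude; cosmic
  spikes at rate 0.05 per point, 20–100× the noise sd, 1–3 channels;
- protein panels linear in the standardized true peak ratios through a
  loading matrix, plus an optional loading on the standardized NAR
  score (so responder classes can carry protein signal of their own),
  shifted positive;
- NAR scores linear in the standardized peak ratios with Gaussian noise,
  truncated at 0; responder classes then derive from the stratification
  rule, guaranteeing consistency. For post-treatment groups the score
  is drawn from an independent latent, modelling the decoupling of the
  serum metabolome from outcome after therapy.

Presets encode the study designs: `pdac-vs-cp` (sugar, tyrosine and
DNA/RNA bands elevated in cancer only; carotenoid and glucose changes
shared with pancreatitis), `larc-response` (glycine/sugar/carotenoid
bands load positively on NAR before treatment), `null` (two identical
groups). Preset effect magnitudes are chosen to reproduce the
qualitative findings — direction and separability — not any particular
printed value, since true patient effect sizes are unpublished.

What passing tests show: the pipeline recovers known amplitude
structure, calibrated error rates and classifier behaviour under the
generative model above. What they do not show: robustness to instrument
drift, wavenumber miscalibration, Mie-scattering baselines, non-white
noise, or any biology — real sera differ from the model in all these
ways.

## Problem sizes

Tests and the acceptance script run scaled-down designs chosen as the
smallest that still measure each property: cohorts of 3–25 samples per
group, 1–8 points per sample (the instrument's 100-point maps are
available via `n_points=100`), coarse SVM cost grids {1, 10, 100}, 100
volcano replicates, 10,000 t-test null replicates, 2000-resample
bootstrap reduced where only determinism is under test. Statistical
tolerances follow the sampling noise at those sizes.
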