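# Methods

## Signal model

All spectra live on a fixed wavelength grid of 380–680 nm in 1 nm steps
(301 points).  The acquisition range is an instrument fact; the 1 nm
sampling is a package choice that keeps every wavelength the analysis
refers to (400, 450, 470, 475, 490, 530, 550, 650 nm) exactly on-grid.
Intensities are dimensionless detector counts; no radiometric calibration
is modelled.

Emission is modelled as a nonnegative linear combination of four
fluorophore bases, each unit-maximum on the grid:

| basis | shape | parameters (default) | role |
|---|---|---|---|
| SHG | Gaussian | center = excitation/2 = 400 nm, σ = 5 nm | collagen second harmonic; marker of intact dermis |
| NADH | Gaussian | peak 450 nm, FWHM 60 nm | metabolic blue fluorescence |
| KERATIN | Gaussian | peak 470 nm, FWHM 80 nm | corneocyte blue-green fluorescence |
| MELANIN | sigmoid + ramp | onset 470 nm, softness 15 nm, ramp 0.15 | pigment tail dominating > 550 nm |

The melanin tail is a logistic sigmoid plus a gentle linear ramp,
normalized to 1 at 680 nm.  The ramp keeps the tail strictly increasing up
to the red edge; a pure sigmoid saturates above ~560 nm, which is both
physically implausible (melanin emission has no in-band plateau) and
numerically fragile — on a saturated stretch the rank ordering used by the
melanoma monotonicity feature is set by noise alone.

No emission lineshapes are published for this instrument, so all widths
are free design parameters.  They were fixed once by a documented
calibration (below) and are exposed in the config file.  FAD is absorbed
into the broad uninformative background rather than modelled separately
(no peak position is available for it at this excitation), and
collagen/elastin fluorescence is omitted — only the collagen SHG line is
kept, since two-photon excitation of an SK rarely reaches the dermis.

## Phenotype templates and their calibration

Each phenotype (SK, CM, nevus, hyperkeratotic skin, healthy forearm, pure
keratin, pure NADH, uninformative background) is a fixed weighted mixture
of the bases times an overall scale.  The constraints the templates must
satisfy are qualitative observations about the three spectral types: the
SK composite must peak at 475 nm although the keratin basis peaks at
470 nm (the melanin tail drags the maximum red-ward); the SK blue band
(450–490 nm) is 10× the nevus blue band (the upper end of the reported
contrast); the CM composite must rise strictly monotonically over
430–650 nm; the nevus composite must be dominated by the SHG line.

The calibration proceeded in one pass, before any acceptance measurement:

1. **SK melanin weight** — with SHG 0.15, NADH 0.20, keratin 1.0 held
   fixed, a 1-D scan over the melanin weight (step 0.01) finds the first
   weight at which the composite argmax over 430–520 nm equals 475 nm on
   both the raw template *and* its span-40 smoothed version.  Result:
   **0.60**, frozen as a constant and re-derived by a test
   (`calibrate_sk_melanin_weight`).
2. **SK overall scale** — set so the SK blue-band mean is exactly 10× the
   nevus blue-band mean: **0.9995**.
3. **Basis widths** — with a keratin FWHM of 70 nm and a shallow melanin
   tail (onset 520, softness 60) no nonnegative mixture can reach a
   475 nm peak while keeping the SK blue/red dominance ≥ 2: a shallow tail
   adds too little slope at 475 nm per unit of red-band mass (verified by
   exhaustive scan over the design grid).  The frozen shapes (keratin FWHM
   80 nm; melanin onset 470, softness 15, ramp 0.15) are the feasible
   corner of that scan with the largest blue/red margin.
4. **Hyperkeratotic template** — keratin 1.0, melanin 0.45, SHG 0.05 and
   NADH 0.02.  The near-zero NADH encodes that terminally differentiated
   corneocytes contain no metabolizing cells; it is also what makes the
   SK-minus-hyperkeratotic difference spectrum peak in the NAD(P)H band
   (430–460 nm) while retaining a positive melanin-band excess.

## Synthetic cohort

A lesion is `n_spectra` (default 300) independent draws.  Each spectrum's
source template is drawn from a per-diagnosis `type_mix`; an independent
Bernoulli(0.05) event replaces it with a low-SNR spectrum (noise around
zero signal).  Noise is Gaussian with σ = noise_level·√(counts + 1), a
Poisson-like surrogate for detector count noise, clipped at zero;
`noise_level` defaults to 1 (Poisson-equivalent) and the counts scale to
2000 counts per unit template intensity.  The detector noise process of
the real instrument is not described anywhere; this surrogate is a
package invention.

Default mixes: SK lesions 70% SK-template / 20% background / 8% nevus /
2% CM; CM lesions 45% CM / 40% background / 15% nevus; nevus lesions
70% nevus / 25% background / 5% SK.  The SK and CM mixes are calibration
choices placing the expected score well below and well above the cut-off;
the nevus mix mirrors the SK structure (real nevi show mostly
nevus-type spectra and score low).  Real per-lesion spectral compositions
are unknown — only aggregate outcomes are reported for patient data — so
these mixes are explicitly synthetic-study conditions, not facts.  Under
them the expected SK score is ≈ 2, below the reported benign means
(≈ 14); matching those means would require assuming per-lesion
compositions the study never printed.

Cohorts default to 28 SK / 5 nevus / 24 CM lesions.  Lesion *i* is seeded
by `SeedSequence([master_seed, i])`, so cohorts are bit-reproducible
across runs and platforms.  Truth labels travel only in spectrum
metadata; the classification path never reads them.

## Preprocessing

*Smoothing* is a centered moving average.  "span = 40" is read as 40 grid
points (40 nm); an even span is symmetrized to the odd 41-point window so
the filter has a well-defined center, and at the edges the window shrinks
symmetrically to the largest centered window that fits.  Two consequences
are worth knowing: (a) total signal is conserved *exactly* for spectra
that vanish within one window of both edges (the suite tests this sharp
form; a blanket "mass preserved to 0.5%" claim fails for nevus-like
spectra whose SHG line sits 20 points from the 380 nm edge), and (b) the
shrinking edge windows inflate smoothed values a few points from the
edges, which lowers the normalized 400 nm band of nevus spectra to ≈ 0.81
— the nevus threshold below accounts for this.

*SNR* is defined as mean(smoothed) / sd(raw − smoothed) within
430–650 nm, with sentinels 0 (all-zero spectrum) and ∞ (zero residual).
The rejection threshold is 3.0.  Definition and threshold are package
choices — the device's criterion is not public — and the generator's
low-SNR contract is defined against them.

*Normalization* divides by the band maximum (default band 380–680 nm),
following the convention used for the reference and difference spectra;
area normalization is not used anywhere.

## Classification

Six features per accepted spectrum, computed on the smoothed,
max-normalized trace: mean intensities over 395–405 nm (SHG), 450–490 nm
(blue) and 550–650 nm (red); the Spearman rank correlation of intensity
with wavelength over 430–650 nm (monotonicity); the argmax wavelength over
430–520 nm; and the SNR carried from preprocessing.

The rule backend applies, in order: nevus (SHG band ≥ 0.7, blue/red < 2,
and SHG band > blue band — the last condition encodes that the signature
is a dominant *line*, so a flat spectrum stays uninformative), SK (SHG
band ≤ 0.4, blue/red ≥ 2, peak in 450–490 nm), melanoma (monotonicity
≥ 0.95 and SHG band ≤ 0.4), else uninformative.  Nevus goes first because
a dominant SHG line is the single clearest discriminator.  Thresholds are
calibrated so each noise-free template is classified correctly with
margin and default-noise perturbations rarely flip a label; all four are
config values.  The decision depends only on normalized features and is
therefore invariant to rescaling the input spectrum.

The surrogate backend is a StandardScaler + linear SVM pipeline trained
on generator truth labels over the first five features (SNR is an
acquisition property, not a type property, and is excluded).  It stands
in for the device's certified SVM, whose feature set and weights are
proprietary; nothing here reproduces the device's decisions.  At default
noise both backends agree on > 90% of generator spectra.

## Unmixing and difference spectra

Unmixing minimizes ‖x − Σ w_b·basis_b‖₂ subject to w ≥ 0 (active-set
NNLS), on smoothed, *unnormalized* spectra so weights keep the counts
scale.  The test suite holds it against an exhaustive lattice oracle on
toy instances and against exact recovery of noise-free compositions.
The difference-spectrum procedure smooths target and reference, rescales
the reference so its full-range maximum equals the target's (the
full-range choice is ours; the sub-band alternative is not specified
anywhere), and subtracts.  Peak localization uses the closed band with
ties broken toward the shorter wavelength.

## Scoring and evaluation

score = 100 · n_malignant / n_classified, where n_classified counts
accepted spectra (uninformative spectra stay in the denominator; low-SNR
rejections leave it), and the excision decision is strict: score > 28.
The linear-in-malignant-count definition with a 0–100 range makes the
reported group scores directly interpretable as percentages; the device's
exact normalization constant is not public, so this reading is an
assumption documented here.  A scan with every spectrum rejected is an
error, not a score of zero.

Cohort evaluation reports per-diagnosis correct/incorrect counts with
percentages recomputed from counts, sensitivity (CM decided malignant)
and specificity (benign decided benign), group mean scores with two-sided
Student-t 95% intervals (omitted for groups of fewer than two lesions,
where the interval is undefined), and a dominant-spectral-type table
(most frequent informative type per lesion; ties or all-uninformative
lesions fall into a no-dominant column).

## Problem sizes and determinism

Default analyses use 300-spectrum lesions and 57-lesion cohorts; the
rejection-rate check uses one 10,000-spectrum scan.  Every random draw
flows from an explicit seed through `numpy.random.Generator`, and the CLI
writes byte-identical outputs for identical config + seed.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of the analysis —
spectral phenotypes, contamination, mixture lesions — not the hardness of
patient data.  Template mixtures at Poisson-like noise are nearly
separable, so the synthetic cohort reaches sensitivity and specificity
near 1.0; the clinical figures (91.7% / 83.0%) come from in vivo spectra
that are not deposited and are *not* reproduced here.  Known limitations:
no Fitzpatrick-type or lesion-geometry effects, no spike/baseline
artifacts, no wavelength-dependent detector response, eumelanin and
pheomelanin share one basis, and the uninformative background is a single
broad shape rather than the heterogeneous residue seen in practice.
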