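# Methods

This note documents the models, numerical choices and limitations behind
`ftirct`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Spectral data model

All spectra live on a strictly decreasing wavenumber axis (the FTIR
plotting convention); readers canonicalize any input orientation to it, so
derivative sign conventions are fixed once. The nominal instrument grid is
4000–750 cm⁻¹ at 4 cm⁻¹ steps, anchored at the high end, which makes
752 cm⁻¹ the lowest grid channel; imaging work uses the 1800–752 cm⁻¹
fingerprint sub-grid (263 channels). Combining data on different grids is
an error — there is deliberately no resampling, because all data this
pipeline targets share one instrument grid and silent interpolation hides
axis bugs.

Exchange formats are wide delimited text for spectral matrices
(`id,meta_*...,<wavenumbers>`) and ENVI (text header + raw float64 binary,
bil/bip/bsq) for hyperspectral cubes. Region crops are inclusive on both
bounds, matching how spectral windows are quoted in the field
("1800 to 920 cm⁻¹").

## Synthetic data generator

**What it emulates.** Pure-component spectra are sums of Gaussian bands.
Band *centers* for collagen type I (1660, 1554, 1456, 1338, 1286, 1236,
1204, 1082, 1060, 1031 cm⁻¹) and chondroitin-4-sulfate (1376, 1228, 1161,
1134, 1072, 1060, 1031, 989, 924 cm⁻¹) follow the published
second-derivative assignment table. Band *shape* is Gaussian — the
simplest lineshape with a closed-form second derivative, which gives the
peak-detection tests an analytic oracle; nothing in the source material
constrains the lineshape. Default FWHM is 16 cm⁻¹ (four grid steps).
Relative *amplitudes* are package defaults chosen once to satisfy the
qualitative constraints on the pure spectra: collagen's strongest band in
the amide I region, C-4-S's strongest in the 1140–985 cm⁻¹ carbohydrate
region. The 1060 cm⁻¹ entry of the C-4-S model carries near-negligible
amplitude (0.05): that band is tabulated with a dual collagen/sulfate
reading but is not a distinct feature of the pure C-4-S spectrum, and at
this amplitude it merges into the 1072/1031 cluster without forming its own
minimum. Bands closer than one FWHM (the 1082/1072/1060/1031 cluster)
merge; the tests only require isolated bands to appear as local maxima.

Mixtures obey Beer–Lambert linearity channel-exactly. Connective tissue is
a collagen/C-4-S binary mixture; the default diet-group compositions are
collagen fraction 0.90 (low starch, LS) and 0.93 (high starch, HS), which
realizes the reported contrast direction (HS relatively collagen-richer)
with the LS group carrying about 40% more GAGs (0.10 vs 0.07).

A third, **synthetic muscle-fiber component** (amide-dominated; no
collagen amide III triplet, no GAG bands) is an acknowledged invention:
muscle-fiber spectra are not characterized by the band table, but
segmentation needs a second class with contrast. The CLI manifest flags it
as synthetic.

**Degradations.** Measured spectra are modeled as
*b·s*(ν) + *a* + *d*₁ν̃ + *d*₂ν̃² + ε(ν) with *b* lognormal
(`exp(N(0, mult_scale_sd))`), polynomial coefficients Gaussian, and ε iid
Gaussian per channel — exactly the distortion family basic EMSC removes,
so parameter recovery is testable to numerical precision. ν̃ is the axis
affinely rescaled to [−1, 1] for polynomial conditioning. Defaults for
replicate groups: `mult_scale_sd = 0.2`, `baseline_coeff_sd =
(0.10, 0.05, 0.02)`, `noise_sd = 0.005` (0.5% of the amide I amplitude) —
a mildly scattering but clean measurement. Degradations are iid across
spectra and pixels; there is no spatially correlated scatter, no water
vapor, no detector nonlinearity, no Mie-type dispersion artifacts. Passing
tests therefore demonstrate correctness of the *algorithmic chain* under
the stated noise model, not robustness to every artifact of real tissue
measurements.

**Tissue images.** Muscle-fiber cells are Voronoi regions of
`n_fiber_seeds` random seed points; a pixel is connective when the gap
between its two nearest-seed distances is at most `seam_width` (an
approximately seam_width-wide band around each Voronoi edge), giving
seam-separated polygonal fibers like transverse muscle sections. Default
geometry 64×64 px at 6.25 μm. Connective pixels draw the binary mixture at
a per-pixel collagen fraction jittered around the nominal composition
(sd 0.05, clipped to [0, 1]); the per-pixel fraction map and label map are
always emitted as ground truth, which is what the correlation-fidelity
tests recover against. Randomness uses one master seed with spawned
independent sub-streams (geometry / composition / one per pixel), so
enlarging an image never perturbs earlier draws and fixed seeds are
bitwise reproducible.

## Preprocessing

**Savitzky–Golay.** Window 9, polynomial order 2, derivative order 2 by
default; derivatives are per cm⁻¹² (scaled by the grid step), and since
the stored order is descending the implementation applies the (−1)^deriv
orientation factor so odd derivatives also come out in wavenumber sense. A
polyorder-2 filter is exact on quadratics and annihilates affine spectra,
which the tests assert at 1e-12. **Edge policy:** the half-window channels
at each end, where a centered window does not fit, are dropped from the
output axis entirely — no padding, no fabricated values, and exclusion
from downstream statistics is structural rather than mask-based.

**EMSC.** Basic variant only: design {1, ν̃, ν̃², *m*} with the reference
*m* the dataset mean (computed per dataset, after differentiation in the
default order); no interferent spectra, no weighting. The per-spectrum fit
is one ordinary least-squares solve; tests pin it to an independent
normal-equations oracle at 1e-10 rms. Corrected spectra are
(*z* − baseline)/*b*. Guards: the reference must not be collinear with the
polynomial terms (rms of its residual after projection ≥ 1e-10), and
|*b*| < 1e-8 is a per-spectrum error naming the offender, never a silent
drop.

**Stage order.** The pipeline fixes crop → derivative → EMSC (reference
built from the derivative spectra) and records the order in its
provenance. Running EMSC first is exposed as `order="emsc-first"` for
sensitivity checks only. One caveat worth stating: with the dataset-mean
reference, rescaling *every* spectrum by a common factor rescales the mean
too, so the corrected set rescales with it — the multiplicative invariance
of EMSC is exact for per-spectrum scatter against a *fixed* reference,
which is how the invariance tests phrase it.

## Chemometrics

**PCA** is SVD on column-mean-centered data. Explained variance is each
singular value's squared share of total centered variance, in percent.
The SVD sign ambiguity is fixed by making each component's
largest-|loading| channel positive. scikit-learn's PCA serves as an
independent cross-check in the tests, not as the implementation.

**Peak detection** operates on second-derivative spectra, where bands are
minima. Interior local minima deeper than 5% of the region's deepest
minimum are kept (the 5% default admits the weak 924 cm⁻¹ band in 90/10
mixtures while rejecting float-level ripples) and refined by fitting a
parabola through the three surrounding channels — necessary because
several tabulated positions (1554, 1338, 1134, …) do not fall on the
4 cm⁻¹ grid anchored at 4000. The refinement error for an isolated
Gaussian band is below 1 cm⁻¹ for FWHM ≥ 12 cm⁻¹, validated against the
analytic second derivative over a sweep of off-grid centers. Assignment
takes the nearest reference band within 4 cm⁻¹ (one grid step); exact
distance ties go to the lower wavenumber. The ambiguous 1060/1031 cm⁻¹
assignments carry both readings rather than a resolved choice.

**GAG marker scan.** Each preprocessed mixture is searched for the three
marker minima in fixed windows (1134: 1120–1150; 989: 974–1004; 924:
910–940 cm⁻¹). Beyond the window-relative prominence rule, a marker must
be deeper than 1% of the spectrum's deepest minimum over its full region:
without this absolute floor, a numerically flat window (pure collagen near
1134 cm⁻¹, where only far Gaussian tails ~1e-11 remain) can contain
"local minima" that pass any relative test. On noiseless mixtures
detection is monotone in the C-4-S fraction, which the suite asserts.

## Imaging

Segmentation scores each pixel against each class as the **maximum**
cosine similarity over that class's patch-mean spectra (max, not
mean-of-means, so one unrepresentative patch cannot drag the class score
down); the pixel takes the argmax class, and an exact tie is labelled
muscle so that ambiguous pixels are discarded rather than quantified —
consistent with the bias-reduction purpose of the muscle-discard step.
For synthetic benchmarks, patches can be auto-drawn from the ground-truth
map (flagged as oracle-assisted in the manifest), standing in for the
manual patch selection done on real images.

Correlation images use Pearson correlation between each connective pixel
spectrum and the preprocessed pure-component spectrum over the analysis
region (default: the full preprocessed fingerprint region, for both
components; configurable). Pearson is affine-invariant per pixel, so the
maps respond to spectral shape, not path length. Pixels constant over the
region are masked and counted, not errors. Group comparison uses 50
shared bins on [−1, 1] with means, medians and the signed HS − LS mean
difference.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design:
64×64×263 cubes for the segmentation benchmarks, 48×48 for the
correlation-fidelity and group-sign checks, 200 spectra for the
least-squares oracle comparisons, 3 replicates per component for the
band-position runs. These sizes put every statistic far above its decision
threshold while keeping the whole suite in seconds. All stochastic steps
are seeded; zero-degradation generation and the whole preprocessing chain
are bitwise deterministic.

## Known limitations

* Band amplitudes (and the muscle model entirely) are plausible synthetic
  choices, not measured quantities; conclusions transfer to real spectra
  only insofar as band positions, not intensities, carry the analysis.
* The degradation model is the EMSC model; real scatter (Mie, dispersion)
  is outside it, so EMSC performance here is an upper bound.
* Explained-variance percentages of the diet-group PCA depend on the
  generator's noise settings and are not comparable to values measured on
  real fish spectra.
* The ENVI reader covers the plain header+raw subset used here (float32/64,
  bil/bip/bsq, wavelength list); vendor binary formats are out of scope.
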