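# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and geometry

Spectra live on an explicit, strictly increasing wavenumber axis; the
default axis has 867 points spanning the 700–1800 cm⁻¹ fingerprint region.
Real CCD sampling is not exactly uniform; the uniform default is a stated
approximation used by the generator. Hyperspectral cubes are row-major
grids with pixel (0, 0) at the top-left and a physical step size in µm;
the default map is 40 × 40 pixels at 2 µm step, i.e. ~1600 spectra over a
~76 µm × 76 µm field. The band catalog carries the eleven prominent
fingerprint bands of prostate-cancer cells with their assignments; the
extraction half-window of 8 cm⁻¹ equals the spectral resolution of the
acquisition this emulates.

Band *intensity* is the maximum within the band window (height, not
area). Height is tolerant to small calibration shifts and is the single
operator shared by the normalization anchor, the statistics tables and
the maps; band area is exposed as an alternative but is not the default.

## Synthetic data

Each pure component (DNA, actin, myosin in its purified-reference and
intracellular forms, lipid, carbohydrate, miscellaneous protein) is a sum
of Lorentzian bands (FWHM 12 cm⁻¹ by default — typical condensed-phase
linewidths; Gaussian and pseudo-Voigt shapes are available). The
intracellular myosin model shifts the purified protein's 1320 and
1670 cm⁻¹ bands to 1336 and 1654 cm⁻¹.

**Group spectra.** A cell spectrum is a weighted sum of components (DNA
weight 1.0 as the internal standard, protein 0.9, actin 0.8, lipid 0.7,
myosin 0.5, carbohydrate 0.4), per-spectrum log-free multiplicative
weight jitter (sd 5%, the variability of selected whole-cell spectra),
a random positive degree-4 polynomial baseline scaled to 20% of the peak
signal (autofluorescence), Gaussian noise (sd 2% of the peak signal, an
SNR-50 condition; SNR here is peak signal over per-channel noise sd), and
Poisson-count single-pixel cosmic spikes (rate 0.02 per spectrum,
amplitude 10–50× the local signal). The tumorigenesis stage effect
multiplies the amplitude of every peak at the staged bands
(1002/1261/1444/1654 cm⁻¹) by 0.7 for the day-(23+10) group and 0.55 for
the day-(23+15) group; the DNA internal standard carries no staged band,
which keeps normalization well-posed. The magnitudes are free parameters
of the emulation (chosen once as clearly detectable at n = 20 without
being trivial); only the direction and the significance structure mirror
the study's findings.

**Cell maps.** Cells are random ellipses; inside each cell one actin-rich
and one myosin-rich elliptical subregion are planted (disjoint). Rich
regions model stress-fiber bundles: a rich pixel is
`(1 − φ) · base cell material + κ · pure component`, with purity
φ ~ U(0.85, 1) and amplitude κ ~ U(2.05, 2.5). High purity reflects how
closely measured fiber-region spectra track the purified reference; the
amplitude floor sits just above the cellular 1444 cm⁻¹ band height
(~2.0 including band tails), so rich pixels are strictly the brightest
pixels of their band in noise-free maps, and the range brackets the level
the reference is scaled to. Non-rich cell pixels receive strong
compositional heterogeneity (sd 35% per component) — subcellular pixels
mix nucleus, droplets and ER and vary far more than whole-cell averages;
without this the synthetic cytoplasm cluster is unrealistically compact.
Background pixels carry only baseline and noise at the cellular signal
scale. All draws flow from a single generator seeded once per call, and
everything drawn (concentrations, baseline coefficients, noise, spike
positions, truth masks) is returned as ground truth.

What the generator does *not* emulate: optics (no PSF/NA modeling, no
photon-budget shot statistics), instrument wavelength-calibration error,
non-uniform CCD sampling, partial-volume mixing at region boundaries
(masks are hard-edged), or spatially correlated biological texture.
Passing tests therefore demonstrate correctness of the algorithms under
idealized mixtures, not performance on any particular instrument's data.

## Preprocessing

Fixed order: crop → despike → baseline → normalize. Spikes corrupt
baseline fits, and normalization must see corrected intensities.

**Despiking.** A point is a spike when it deviates from its 5-point
neighborhood median by more than 8 × 1.4826 × MAD *and* exceeds every
neighbor (cosmic events are strictly positive single-pixel artifacts; the
positivity guard keeps steep band flanks from being clipped, where the
median lags a smooth monotone run). MAD = 0 declares no spike. The outer
half-window is never flagged (reflected edge neighborhoods are
degenerate). Adjacent double spikes need a second pass; replacements are
the neighborhood median. With noisy data the detector has a small
false-positive rate inherent to 4-sample MADs; replacements are then
local medians and benign.

**Baseline.** The default `bandfit` method solves one linear least-squares
problem coupling a degree-4 polynomial with one Lorentzian profile per
catalog band; the common width is scanned over {8…20} cm⁻¹ and up to four
extra profiles are added greedily at the largest positive residual
(e.g. nucleic-acid backbone modes not in the catalog). The baseline is
the polynomial part, so band tails stay in the corrected spectrum. The
motivation: the fingerprint region of a cell is crowded and Lorentzian
tails leave no signal-free channels, so envelope methods (asymmetric
least squares, modified polynomial) systematically eat 6–14% of weak-band
heights, while the joint fit is exact on clean data and unbiased under
noise. ALS (λ = 1e5, p = 0.01, 10 iterations, second-difference penalty)
and an iterative modified polynomial remain available behind the same
contract; when an envelope method is used, the small positive offset it
leaves on noisy spectra is removed by subtracting the 10th percentile of
a band-width-smoothed copy. `bandfit` assumes approximately Lorentzian
bands near the catalog positions — on strongly non-Lorentzian real data
the envelope methods are the safer choice.

**Normalization and flagging.** Spectra are divided by the maximum within
780 ± 5 cm⁻¹, making the DNA-band anchor exactly 1. A spectrum fails when
its anchor is non-positive, or when the anchor of a band-width-smoothed
copy (measured above the spectrum's own median) is below 5× the residual
noise scale (MAD of first differences) — the signature of an empty pixel,
whose post-baseline anchor is positive noise but carries no DNA band.
Failed cube pixels are flagged, never fatal; failed group spectra are
dropped with a logged warning. With `normalize=False` (the mode the
stripe stage uses) the division is skipped and empty pixels are instead
flagged by total smoothed signal below 8× the noise scale.

## Covariance PCA

Observations are spectra, variables are wavenumbers; variables are
mean-centered and never scaled (covariance PCA). The implementation uses
the SVD of the centered matrix; eigenvalues are s²/(n−1), the component
count is min(n−1, p), and eigenvector signs follow the convention that
each loading's largest-magnitude element is positive, making results
deterministic. Degenerate input (zero total variance) yields zero
explained fractions and a flag rather than NaNs. Whether centering is per
wavenumber or per spectrum is ambiguous in common spectroscopy-software
descriptions; per-wavenumber centering is the standard covariance-PCA
reading and is adopted. The published explained-variance figures for the
original instrument data are data-dependent and are not targets; on
synthetic data the first two components separate early from late cultures
whenever the planted effects dominate noise.

## Staging statistics

Band heights per spectrum feed a one-way ANOVA per band (explicit sums of
squares) and all-pairs Tukey HSD using the studentized-range
distribution, with the Tukey–Kramer standard error for unequal n (equal-n
reduces to classic Tukey, matching common statistics packages for
balanced designs). Significance tiers mirror 0.05 / 0.01 / 0.001
annotations. Zero within-group variance with unequal means reports p = 0
with a degeneracy flag. Tukey within band only; no cross-band multiplicity
correction is applied, matching standard practice for per-band histograms.

## Density-peak clustering

Implements clustering by fast search-and-find of density peaks: local
density ρ (Gaussian kernel by default — continuous ρ avoids integer ties
on small maps; the cutoff kernel is available), distance δ to the nearest
denser point (density ties broken by index, so the procedure is fully
deterministic), γ = ρδ, and assignment of each point, in descending
density order, to its nearest denser neighbor's label. The kernel scale
d_c defaults to the 2nd percentile of the *positive* pairwise distances;
zero distances are excluded because coincident points (the digital
stripe's duplicated pixels) would otherwise collapse the percentile.

Center selection: with an explicit k, the top-k points by γ. In automatic
mode a center must first be *separated* — δ > 2 d_c — because a point
whose nearest denser neighbor lies within the kernel scale is the flank
of a denser structure regardless of how large its density makes γ; all
separated candidates become centers (up to 12) unless their sorted δ
sequence contains a drop by ≥ 3×, in which case the list is cut at the
largest such drop. Real centers sit at inter-cluster distances while
stragglers sit just above the eligibility floor, so the δ cliff is the
robust signal; γ mixes density in and legitimately spans orders of
magnitude between clusters of different tightness. Halo (border-density)
demotion is implemented but off by default.

## Reference-stripe identification

The pipeline: scale the pure reference to the average cellular spectrum
via the component's anchor band (1444 cm⁻¹ for actin, 1002 cm⁻¹ for
myosin; flagged pixels excluded from the average) → prepend
⌈width/step⌉ stripe rows (5 µm default → 3 rows at 2 µm step; minimum
one row; every stripe pixel is the scaled reference exactly) → covariance
PCA over all augmented pixels, stripe included → density-peak clustering
of the leading PC scores (6 for actin, 9 for myosin — more components for
myosin, whose discrimination from other proteins is subtler) → the
cluster holding the majority of stripe pixels (a split is logged) → the
mask of image pixels sharing that label. Ten mask pixels drawn uniformly
without replacement under the configured seed are averaged into the
component-like spectrum; stripe pixels are never in the mask nor sampled.
Validation: cosine similarity against the scaled reference and presence
of the component's expected bands (a local maximum within ±8 cm⁻¹ with
prominence above 5% of the spectrum's maximum). An empty mask is a valid
"component not detected" outcome, not an exception.

The stripe stage runs on baseline-corrected but *unnormalized* pixels. A
pure protein reference has no 780 cm⁻¹ DNA band: after per-pixel DNA
normalization every image pixel carries an exact unit anchor peak the
stripe cannot have, an irreducible offset that empirically prevents the
stripe from ever co-clustering with image pixels. Scaling the reference
at the component band is precisely the commensuration step that replaces
DNA normalization in this stage; DNA normalization remains the default
for classification, band statistics and maps.

Myosin identification is intrinsically harder than actin: the stripe
carries the purified reference with its 1320/1670 cm⁻¹ bands, whereas
intracellular myosin is shifted to 1336/1654 cm⁻¹, so the reference sits
farther from the cellular cluster and detection can be partial or fail on
a given map (the band check and similarity report make this visible).

## Maps

Per-pixel band heights (the shared intensity operator), NaN for flagged
pixels, and per-band color bounds computed as the global min/max over all
samples' non-missing pixels so that rendered intensities are directly
comparable across samples. Bounds are order-invariant and emitted
alongside the matrices; PNG export renders missing pixels transparent
with a continuous pseudo-color scale.

## Reproducibility

Generators require an explicit integer seed; one top-level CLI seed fans
out to per-stage sub-seeds drawn in a fixed documented order, so any
stage can be rerun in isolation from the resolved-config echo. The demo
writes a SHA-256 manifest of every artifact; identical seeds give
identical manifests.

## Problem sizes

The test suite and acceptance script run at the study's design scale:
40 × 40 maps, 4 × 20 group spectra, 867-point axes. Replicated checks use
10 seeds for mask recovery, 100 replicates for staging power, 2000 for
the null type-I error, and 20 random matrices / point sets for the PCA
and clustering oracles; small grids (14–20 px) are used only where the
check is about geometry or plumbing rather than statistical performance.
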