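# ramanstage

Label-free Raman hyperspectral imaging analysis for discriminating stages of
prostate-cancer tumorigenesis in bone-mimetic 3D culture models.

Cancer cells grown in 2D, and in sequential 3D cultures where mesenchymal
stem cells first form bone tissue on a nanoclay scaffold (23 days) before
prostate cancer cells are seeded for 5, 10 or 15 days, show progressive
biochemical changes that Raman microscopy can read out without labels:
intensities at the 1002 cm⁻¹ (phenylalanine ring breathing), 1261 cm⁻¹
(amide III), 1444 cm⁻¹ (CH₂ deformation of proteins/lipids) and 1654 cm⁻¹
(amide I) bands fall as tumorigenesis progresses, while the 780 cm⁻¹ DNA
band serves as an internal standard. This package implements the full
analysis pipeline for such data, plus a ground-truthed synthetic-data
generator so every stage is testable without instrument data.

## What it does

- **spectral_core** — wavenumber axes, spectra, grouped spectra,
  hyperspectral cubes (40×40 maps over ~76 µm × 76 µm at 2 µm step,
  867-point fingerprint axis 700–1800 cm⁻¹), the 11-band assignment
  catalog, delimited-text I/O with JSON sidecars.
- **preprocess** — fingerprint cropping, cosmic-ray despiking (windowed
  median/MAD), baseline correction (default: band-targeted joint fit of a
  polynomial baseline with Lorentzian profiles at the catalog bands;
  asymmetric least squares and modified-polynomial also available),
  normalization to the 780 cm⁻¹ DNA band, and empty-pixel flagging.
- **pca** — covariance-matrix PCA (no variable scaling): scores, loadings,
  eigenvalues, explained-variance fractions, with a deterministic sign
  convention.
- **band_stats** — band heights per spectrum, group mean ± SD tables,
  difference spectra, one-way ANOVA with post hoc Tukey HSD
  (studentized-range / Tukey–Kramer) across the four culture groups.
- **dpclust** — density-peak clustering (ρ, δ, γ decision graph; Gaussian
  or cutoff kernel; automatic center selection or explicit k).
- **stripe_id** — the headline technique: a digital stripe of a pure
  reference spectrum (actin or myosin), scaled to the average cellular
  spectrum at an anchor band (1444 cm⁻¹ for actin, 1002 cm⁻¹ for myosin),
  is appended above the image; PCA over all pixels including the stripe,
  density-peak clustering of the leading PC scores (6 for actin, 9 for
  myosin), and co-clustering with the stripe then labels component-rich
  regions. The average of ten randomly sampled component-rich spectra is
  validated against the reference by cosine similarity and band presence.
- **maps** — per-band intensity maps with uniform color bounds across all
  samples of a band, delimited-matrix and PNG export.
- **synthetic_data** — generates the four-group spectra (20 per group) with
  planted stage reductions (×0.7 and ×0.55 at the staged bands for the
  day-(23+10) and day-(23+15) groups), autofluorescence baselines, shot
  noise and cosmic spikes, and cell maps with planted actin/myosin-rich
  fiber regions — every draw recorded as ground truth.

## Worked example

```python
from ramanstage.synthetic_data import SyntheticConfig, simulate_groups, \
    simulate_cube, reference_spectrum
from ramanstage.preprocess import PreprocessConfig, preprocess_all
from ramanstage.band_stats import group_band_table, anova_tukey
from ramanstage.pca import assemble_matrix, fit_pca
from ramanstage.stripe_id import StripeConfig, identify_component

# four culture groups, 20 selected cell spectra each, preprocessed and
# normalized to the 780 cm-1 DNA band
grouped, _ = simulate_groups(SyntheticConfig(seed=1))
processed, report = preprocess_all(grouped)
table = group_band_table(processed)
print(table.summary().pivot(index="band_cm1", columns="group", values="mean"))
```

```
group     2D_PCa  3D_d23+10  3D_d23+15  3D_d23+5
band_cm1
1002       1.730      1.242      0.987     1.764
1261       1.202      0.865      0.691     1.232
1444       1.955      1.402      1.111     2.002
1654       2.028      1.452      1.140     2.076
```

The normalized band intensities drop monotonically from the day-(23+5)
culture to day (23+15) at all four staged bands — the staging signature.
Tukey HSD confirms the day-(23+5) vs day-(23+15) contrasts (q ≈ 31–37,
adjusted p < 10⁻¹⁵ at every band), while 2D vs day-(23+5) shows no
significant change. Covariance PCA of the 80 × 867 matrix puts 79.2% of
the variance in the first two components, which separate early from late
cultures in the score plot.

```python
# reference-stripe identification of actin-rich regions in a cell map
cube, truth = simulate_cube(SyntheticConfig(seed=2))
pcube, _ = preprocess_all(cube, PreprocessConfig(normalize=False))
actin_ref = reference_spectrum("actin", cube.axis)
result = identify_component(
    pcube, StripeConfig(component="actin", reference=actin_ref, seed=7))
print(result.mask.sum(), result.similarity)
```

This run recovers all 81 planted actin-rich pixels (81 found, 81
overlapping, no false positives), the actin-like average spectrum has
cosine similarity 0.999 with the scaled reference, and all four actin
bands (1002, 1261, 1444, 1654 cm⁻¹) are present.

## Command line

```bash
raman-stage demo --seed 0 --out demo_out
```

runs the whole workflow — group simulation, preprocessing, mean/difference
spectra, PCA, band/Tukey tables, per-band maps with shared bounds, and
stripe analysis for actin and myosin on all four samples — and writes a
checksum manifest; identical seeds give identical manifests.
Individual stages are exposed as `raman-stage simulate|preprocess|pca|
bands|map|stripe`.

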