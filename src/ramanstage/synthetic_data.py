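"""Ground-truthed synthetic Raman data.

Emulates the study's acquisition: 40x40 pixel maps over ~76 µm x 76 µm at
2 µm step, 867-point spectra on the 700–1800 cm^-1 fingerprint axis, four
culture groups (2D PCa and three sequential 3D bone-mimetic cultures), 20
selected cell spectra per group, autofluorescence baselines, shot-like
Gaussian noise, rare cosmic-ray spikes, and planted intensity reductions
at the four staged bands (1002/1261/1444/1654 cm^-1) in the later-stage
groups.

Every stochastic quantity is drawn from a single generator seeded once per
call, and all draws are recorded in a :class:`GroundTruth` so downstream
modules can be tested against known truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .spectral_core import (
    GROUP_LABELS,
    STAGED_BAND_CENTERS,
    GroupedSpectra,
    HyperspectralCube,
    Spectrum,
    WavenumberAxis,
)

__all__ = [
    "PeakSpec",
    "ComponentModel",
    "SyntheticConfig",
    "GroundTruth",
    "CubeLayout",
    "default_components",
    "component_spectrum",
    "reference_spectrum",
    "simulate_groups",
    "simulate_cube",
    "procedural_layout",
    "layout_from_masks",
]


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band profile.

    ``shape`` is ``lorentzian`` (default, typical for condensed-phase Raman
    lines), ``gaussian``, or ``pseudo_voigt`` with mixing fraction ``eta``
    (eta=1 is pure Lorentzian).
    """

    center_cm1: float
    fwhm_cm1: float = 12.0
    amplitude: float = 1.0
    shape: str = "lorentzian"
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ValueError("fwhm_cm1 must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.shape not in ("lorentzian", "gaussian", "pseudo_voigt"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Peak profile evaluated on the grid; value at center = amplitude."""
        x = np.asarray(wavenumbers, dtype=float)
        gamma = self.fwhm_cm1 / 2.0
        lor = 1.0 / (1.0 + ((x - self.center_cm1) / gamma) ** 2)
        if self.shape == "lorentzian":
            prof = lor
        else:
            sigma = self.fwhm_cm1 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            gau = np.exp(-0.5 * ((x - self.center_cm1) / sigma) ** 2)
            prof = gau if self.shape == "gaussian" else self.eta * lor + (1 - self.eta) * gau
        return self.amplitude * prof


@dataclass(frozen=True)
class ComponentModel:
    """A pure biochemical component as a sum of band profiles."""

    name: str
    peaks: tuple[PeakSpec, ...]

    def spectrum(self, wavenumbers: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(wavenumbers, dtype=float))
        lo, hi = wavenumbers[0], wavenumbers[-1]
        for peak in self.peaks:
            if not (lo <= peak.center_cm1 <= hi):
                warnings.warn(
                    f"peak at {peak.center_cm1} cm^-1 lies outside the axis "
                    f"[{lo}, {hi}]; only its tail contributes",
                    stacklevel=2,
                )
            out += peak.profile(wavenumbers)
        return out


def _p(center, amp, fwhm=12.0) -> PeakSpec:
    return PeakSpec(center_cm1=center, fwhm_cm1=fwhm, amplitude=amp)


def default_components() -> dict[str, ComponentModel]:
    """Idealized pure-component models built on the catalog band positions.

    ``myosin_reference`` is the purified-protein spectrum (bands at 1320 and
    1670 cm^-1); ``myosin_cellular`` carries the intracellular shifts
    1320→1336 and 1670→1654 cm^-1.
    """
    return {
        "DNA": ComponentModel(
            "DNA", (_p(780, 1.0), _p(1094, 0.35), _p(1336, 0.5))
        ),
        "actin": ComponentModel(
            "actin",
            (_p(935, 0.25), _p(1002, 0.9), _p(1261, 0.6), _p(1444, 1.0), _p(1654, 0.9)),
        ),
        "myosin_reference": ComponentModel(
            "myosin_reference",
            (_p(1002, 0.8), _p(1320, 0.55), _p(1444, 1.0), _p(1670, 0.9)),
        ),
        "myosin_cellular": ComponentModel(
            "myosin_cellular",
            (_p(1002, 0.8), _p(1336, 0.55), _p(1444, 1.0), _p(1654, 0.9)),
        ),
        "lipid": ComponentModel(
            "lipid", (_p(1080, 0.7), _p(1296, 0.8), _p(1444, 1.0))
        ),
        "carbohydrate": ComponentModel(
            "carbohydrate", (_p(850, 0.3), _p(1124, 1.0))
        ),
        "protein_misc": ComponentModel(
            "protein_misc",
            (_p(850, 0.5), _p(935, 0.6), _p(1002, 0.7), _p(1261, 0.8), _p(1654, 1.0)),
        ),
    }


def component_spectrum(model: ComponentModel, axis: WavenumberAxis) -> Spectrum:
    """Noise-free, baseline-free spectrum of a pure component on ``axis``."""
    return Spectrum(axis, model.spectrum(axis.values), {"name": model.name})


def reference_spectrum(name: str, axis: WavenumberAxis | None = None) -> Spectrum:
    """Pure-component reference spectrum by name (e.g. for the digital stripe)."""
    axis = axis or WavenumberAxis.default()
    return component_spectrum(default_components()[name], axis)


#: Base cellular composition: component weight per unit "cell material".
#: DNA is the internal standard (the 780 cm^-1 normalization anchor) and is
#: never modulated by the stage effect.
BASE_CELL_WEIGHTS: dict[str, float] = {
    "DNA": 1.0,
    "protein_misc": 0.9,
    "actin": 0.8,
    "lipid": 0.7,
    "carbohydrate": 0.4,
    "myosin_cellular": 0.5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the acquisition and sampling design: 40x40 maps at
    2 µm step (76 µm x 76 µm fields), 20 selected cell spectra per group,
    and multiplicative reductions of 0.7 / 0.55 at the staged bands for the
    day-(23+10) and day-(23+15) groups.  ``seed`` must be given explicitly.
    """

    seed: int
    rows: int = 40
    cols: int = 40
    step_um: float = 2.0
    axis: WavenumberAxis = field(default_factory=WavenumberAxis.default)
    n_spectra_per_group: int = 20
    group_labels: tuple[str, ...] = GROUP_LABELS
    staged_bands: tuple[float, ...] = STAGED_BAND_CENTERS
    reduction_factors: tuple[tuple[str, float], ...] = (
        ("3D_d23+10", 0.7),
        ("3D_d23+15", 0.55),
    )
    # cube geometry
    n_cells: int = 4
    cell_radius_um: tuple[float, float] = (8.0, 16.0)
    # Component-rich regions are fiber bundles: a pixel there is
    # (1 - purity) * base cell material + amplitude * pure component, with
    # purity and amplitude drawn per pixel.  High purity mirrors how
    # closely actin-like spectra track the pure reference; the amplitude
    # range brackets the typical cellular signal at the component's anchor
    # band (bundle thickness varies within a region).
    # the amplitude floor sits just above the cellular band height (~2.0
    # at 1444 cm^-1 including tails), so rich regions are strictly the
    # brightest pixels at their component band in noise-free maps
    fiber_purity: tuple[float, float] = (0.85, 1.0)
    fiber_amplitude: tuple[float, float] = (2.05, 2.5)
    # nuisance terms
    baseline_degree: int = 4
    baseline_scale: float = 0.2  # relative to the clean signal maximum
    noise_sd: float = 0.02  # Gaussian sd relative to the clean signal maximum
    weight_jitter: float = 0.05  # per-spectrum biological variability
    # Subcellular pixels are far more heterogeneous than whole-cell spectra
    # (nucleus, lipid droplets, ER...): extra per-pixel compositional
    # scatter for non-rich cell pixels in cubes.  Fiber bundles are
    # compositionally homogeneous and keep the base jitter.
    cell_heterogeneity: float = 0.35
    spike_rate: float = 0.02  # expected cosmic spikes per spectrum
    spike_amplitude: tuple[float, float] = (10.0, 50.0)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an explicit integer")
        for name in ("baseline_scale", "noise_sd", "weight_jitter", "spike_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for _, f in self.reduction_factors:
            if not 0 < f <= 1:
                raise ValueError("reduction factors must lie in (0, 1]")

    @property
    def reductions(self) -> dict[str, float]:
        return dict(self.reduction_factors)


@dataclass
class GroundTruth:
    """Everything the generator drew, for testing against known truth."""

    concentrations: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)
    spikes: dict = field(default_factory=dict)
    baseline_coeffs: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    clean: dict = field(default_factory=dict)


@dataclass
class CubeLayout:
    """Per-pixel component concentrations and the planted truth masks."""

    concentrations: dict[str, np.ndarray]
    cell_mask: np.ndarray
    actin_rich: np.ndarray
    myosin_rich: np.ndarray


# ---------------------------------------------------------------------------
# Internal rendering
# ---------------------------------------------------------------------------

def _group_component_matrix(
    config: SyntheticConfig, group: str, components: dict[str, ComponentModel]
) -> tuple[list[str], np.ndarray]:
    """Component spectra with the group's staged-band reduction applied.

    The stage effect multiplies the amplitude of every peak located at a
    staged band by the group's reduction factor; the DNA internal standard
    carries no staged peak and is untouched.
    """
    factor = config.reductions.get(group, 1.0)
    names = list(BASE_CELL_WEIGHTS)
    rows = []
    for name in names:
        model = components[name]
        if factor != 1.0 and name != "DNA":
            peaks = tuple(
                replace(p, amplitude=p.amplitude * factor)
                if p.center_cm1 in config.staged_bands
                else p
                for p in model.peaks
            )
            model = ComponentModel(model.name, peaks)
        rows.append(model.spectrum(config.axis.values))
    return names, np.vstack(rows)


def _random_baseline(
    rng: np.random.Generator, config: SyntheticConfig, signal_max: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """A smooth, positive polynomial baseline and its coefficient vector.

    Coefficients act on the axis rescaled to t in [-1, 1].  The raw random
    polynomial is shifted to be positive and scaled so its peak is
    ``baseline_scale * signal_max``.
    """
    t = np.linspace(-1.0, 1.0, n)
    coeffs = rng.standard_normal(config.baseline_degree + 1)
    raw = np.polynomial.polynomial.polyval(t, coeffs)
    shift = raw.min() - 0.1 * (np.ptp(raw) + 1e-12)
    shifted = raw - shift
    scale = config.baseline_scale * signal_max / max(shifted.max(), 1e-12)
    final = shifted * scale
    final_coeffs = coeffs * scale
    final_coeffs[0] -= shift * scale
    return final, final_coeffs


def _inject_spikes(
    rng: np.random.Generator, config: SyntheticConfig, signal: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    n_spikes = rng.poisson(config.spike_rate)
    out = signal.copy()
    positions: list[int] = []
    if n_spikes > 0:
        idx = rng.choice(signal.size, size=min(n_spikes, signal.size), replace=False)
        lo, hi = config.spike_amplitude
        local = np.maximum(np.abs(signal[idx]), 0.05 * max(signal.max(), 1e-12))
        out[idx] += rng.uniform(lo, hi, size=idx.size) * local
        positions = sorted(int(i) for i in idx)
    return out, positions


def _render(
    rng: np.random.Generator,
    config: SyntheticConfig,
    weights: np.ndarray,
    comp_matrix: np.ndarray,
) -> tuple:
    """signal, clean, baseline, baseline_coeffs, noise, spikes for one spectrum."""
    clean = weights @ comp_matrix
    smax = max(clean.max(), 1e-12)
    if config.baseline_scale > 0:
        baseline, coeffs = _random_baseline(rng, config, smax, clean.size)
    else:
        baseline = np.zeros_like(clean)
        coeffs = np.zeros(config.baseline_degree + 1)
    noise = (
        rng.normal(0.0, config.noise_sd * smax, size=clean.size)
        if config.noise_sd > 0
        else np.zeros_like(clean)
    )
    signal = clean + baseline + noise
    signal, spikes = (
        _inject_spikes(rng, config, signal) if config.spike_rate > 0 else (signal, [])
    )
    return signal, clean, baseline, coeffs, noise, spikes


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def simulate_groups(config: SyntheticConfig) -> tuple[GroupedSpectra, GroundTruth]:
    """Four groups of selected cell spectra with planted stage effects.

    Each spectrum is a jittered mixture of the cellular components (with the
    group's staged-band reduction), plus a random positive polynomial
    baseline, Gaussian noise, and Poisson-count cosmic spikes.  Identical
    seed and config give identical output.
    """
    n = config.n_spectra_per_group
    if n < 2:
        raise ValueError("need at least 2 spectra per group for statistics")
    rng = np.random.default_rng(config.seed)
    components = default_components()
    grouped = GroupedSpectra()
    truth = GroundTruth()
    base_w = np.array(list(BASE_CELL_WEIGHTS.values()))
    for group in config.group_labels:
        names, comp_matrix = _group_component_matrix(config, group, components)
        for i in range(n):
            jitter = (
                1.0 + config.weight_jitter * rng.standard_normal(base_w.size)
                if config.weight_jitter > 0
                else np.ones(base_w.size)
            )
            weights = np.clip(base_w * jitter, 0.0, None)
            signal, clean, baseline, coeffs, noise, spikes = _render(
                rng, config, weights, comp_matrix
            )
            key = (group, i)
            truth.concentrations[key] = dict(zip(names, weights))
            truth.baseline_coeffs[key] = coeffs
            truth.noise[key] = noise
            truth.clean[key] = clean
            truth.spikes[key] = spikes
            grouped.add(
                group, Spectrum(config.axis, signal, {"group": group, "index": i})
            )
    return grouped, truth


def _ellipse_mask(
    rows: int, cols: int, center: tuple[float, float], radii: tuple[float, float], angle: float
) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def procedural_layout(config: SyntheticConfig, rng: np.random.Generator) -> CubeLayout:
    """Random cells as ellipses with interior actin- and myosin-rich blobs.

    Actin-rich and myosin-rich subregions are strongly dominated by their
    component (weight ``rich_weight`` vs the base cellular weights), the way
    stress-fiber bundles dominate the local Raman signal.
    """
    rows, cols = config.rows, config.cols
    r_lo, r_hi = (r / config.step_um for r in config.cell_radius_um)
    if 2 * r_lo > min(rows, cols):
        raise ValueError("cell radius exceeds the grid")
    cell = np.zeros((rows, cols), dtype=bool)
    actin = np.zeros_like(cell)
    myosin = np.zeros_like(cell)
    for _ in range(config.n_cells):
        radii = (rng.uniform(r_lo, r_hi), rng.uniform(r_lo, r_hi))
        center = (
            rng.uniform(radii[0] * 0.7, rows - radii[0] * 0.7),
            rng.uniform(radii[1] * 0.7, cols - radii[1] * 0.7),
        )
        angle = rng.uniform(0, math.pi)
        body = _ellipse_mask(rows, cols, center, radii, angle)
        cell |= body
        for target in (actin, myosin):
            sub_r = (max(radii[0] * 0.4, 1.0), max(radii[1] * 0.4, 1.0))
            off = (
                center[0] + rng.uniform(-0.4, 0.4) * radii[0],
                center[1] + rng.uniform(-0.4, 0.4) * radii[1],
            )
            target |= _ellipse_mask(rows, cols, off, sub_r, rng.uniform(0, math.pi)) & body
    myosin &= ~actin  # rich regions are disjoint by construction
    return _concentrations_from_masks(config, cell, actin, myosin)


def layout_from_masks(
    config: SyntheticConfig,
    cell_mask: np.ndarray,
    actin_rich: np.ndarray | None = None,
    myosin_rich: np.ndarray | None = None,
) -> CubeLayout:
    """Build a layout from explicit boolean masks (planted ground truth)."""
    shape = (config.rows, config.cols)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != shape:
        raise ValueError(f"cell mask shape {cell_mask.shape} != grid {shape}")
    zeros = np.zeros(shape, dtype=bool)
    actin = np.asarray(actin_rich, dtype=bool) if actin_rich is not None else zeros
    myosin = np.asarray(myosin_rich, dtype=bool) if myosin_rich is not None else zeros
    cell_mask = cell_mask | actin | myosin
    return _concentrations_from_masks(config, cell_mask, actin, myosin)


def _concentrations_from_masks(
    config: SyntheticConfig, cell: np.ndarray, actin: np.ndarray, myosin: np.ndarray
) -> CubeLayout:
    # base cellular composition everywhere inside a cell; the fiber-bundle
    # mixing for rich pixels is drawn per pixel at render time
    conc = {name: np.where(cell, w, 0.0) for name, w in BASE_CELL_WEIGHTS.items()}
    return CubeLayout(conc, cell, actin, myosin)


def simulate_cube(
    config: SyntheticConfig, layout: CubeLayout | None = None, sample: str = "2D_PCa"
) -> tuple[HyperspectralCube, GroundTruth]:
    """A hyperspectral cell map with planted component-rich regions.

    Background pixels carry baseline + noise only.  The per-pixel truth
    (concentrations, masks, baselines, spikes, noise) is returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    if layout is None:
        layout = procedural_layout(config, rng)
    components = default_components()
    names, comp_matrix = _group_component_matrix(config, sample, components)
    rows, cols, npt = config.rows, config.cols, config.axis.n_points
    pixels = np.empty((rows, cols, npt))
    truth = GroundTruth(
        masks={
            "cell": layout.cell_mask.copy(),
            "actin_rich": layout.actin_rich.copy(),
            "myosin_rich": layout.myosin_rich.copy(),
        }
    )
    conc_stack = np.stack([layout.concentrations[n] for n in names], axis=-1)
    i_actin = names.index("actin")
    i_myosin = names.index("myosin_cellular")
    # reference signal scale for background baseline/noise: the typical cell
    # signal (the instrument floor does not know whether a pixel holds a cell)
    base_w = np.array(list(BASE_CELL_WEIGHTS.values()))
    cell_ref = float((base_w @ comp_matrix).max())
    for r in range(rows):
        for c in range(cols):
            weights = conc_stack[r, c].copy()
            rich_at = (
                i_actin
                if layout.actin_rich[r, c]
                else i_myosin
                if layout.myosin_rich[r, c]
                else None
            )
            if rich_at is not None:
                purity = rng.uniform(*config.fiber_purity)
                amplitude = rng.uniform(*config.fiber_amplitude)
                weights *= 1.0 - purity
                weights[rich_at] += amplitude
                jitter = config.weight_jitter
            else:
                jitter = max(config.weight_jitter, config.cell_heterogeneity)
            if jitter > 0 and weights.any():
                weights = np.clip(
                    weights * (1.0 + jitter * rng.standard_normal(weights.size)),
                    0.0,
                    None,
                )
            signal, clean, baseline, coeffs, noise, spikes = _render_pixel(
                rng, config, weights, comp_matrix, cell_ref
            )
            pixels[r, c] = signal
            key = (r, c)
            truth.concentrations[key] = dict(zip(names, weights))
            truth.baseline_coeffs[key] = coeffs
            truth.noise[key] = noise
            truth.clean[key] = clean
            truth.spikes[key] = spikes
    cube = HyperspectralCube(
        rows, cols, config.step_um, config.axis, pixels, {"sample": sample}
    )
    truth.masks["concentration_names"] = names
    return cube, truth


def _render_pixel(rng, config, weights, comp_matrix, cell_ref):
    """Render one pixel; background pixels use the typical cell signal scale
    for their baseline and noise amplitudes."""
    clean = weights @ comp_matrix
    smax = clean.max()
    ref = smax if smax > 0 else cell_ref
    if config.baseline_scale > 0:
        baseline, coeffs = _random_baseline(rng, config, ref, clean.size)
    else:
        baseline = np.zeros_like(clean)
        coeffs = np.zeros(config.baseline_degree + 1)
    noise = (
        rng.normal(0.0, config.noise_sd * ref, size=clean.size)
        if config.noise_sd > 0
        else np.zeros_like(clean)
    )
    signal = clean + baseline + noise
    signal, spikes = (
        _inject_spikes(rng, config, signal) if config.spike_rate > 0 else (signal, [])
    )
    return signal, clean, baseline, coeffs, noise, spikes
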