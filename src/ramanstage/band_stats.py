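"""Band-intensity staging statistics.

Band intensities (height = maximum within the band window, the same
operator used by the preprocessing anchor and the maps module) are
extracted per spectrum, summarized per group, and compared across the four
culture groups with one-way ANOVA followed by a post hoc Tukey HSD test
on the studentized-range distribution (Tukey–Kramer for unequal n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .spectral_core import (
    BandDefinition,
    GroupedSpectra,
    Spectrum,
    band_by_center,
    STAGED_BAND_CENTERS,
)

__all__ = [
    "band_intensity",
    "band_area",
    "group_band_table",
    "BandIntensityTable",
    "TukeyResult",
    "anova_tukey",
    "difference_spectrum",
    "mean_sd_spectrum",
    "SIGNIFICANCE_TIERS",
]

#: Significance tiers mirroring */**/*** style annotations.
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001)


def band_intensity(spectrum: Spectrum, band: BandDefinition) -> float:
    """Band height: the maximum intensity within center ± half_window."""
    mask = spectrum.axis.window_mask(band.center_cm1, band.half_window_cm1)
    if not mask.any():
        raise ValueError(
            f"band window {band.center_cm1} ± {band.half_window_cm1} cm^-1 "
            "lies outside the axis"
        )
    return float(spectrum.intensities[mask].max())


def band_area(spectrum: Spectrum, band: BandDefinition) -> float:
    """Band area: trapezoidal integral over the band window (alternative
    intensity operator, not the default)."""
    mask = spectrum.axis.window_mask(band.center_cm1, band.half_window_cm1)
    if mask.sum() < 2:
        raise ValueError("band window too narrow for integration")
    return float(np.trapezoid(spectrum.intensities[mask], spectrum.axis.values[mask]))


@dataclass
class BandIntensityTable:
    """Per-(group, band) intensity samples with mean/SD/n summaries."""

    intensities: dict  # (group label, band center) -> np.ndarray of samples
    groups: tuple[str, ...]
    bands: tuple[BandDefinition, ...]

    def samples(self, group: str, band_center: float) -> np.ndarray:
        return self.intensities[(group, band_center)]

    def summary(self) -> pd.DataFrame:
        records = []
        for band in self.bands:
            for group in self.groups:
                x = self.intensities[(group, band.center_cm1)]
                records.append(
                    {
                        "band_cm1": band.center_cm1,
                        "group": group,
                        "n": x.size,
                        "mean": float(x.mean()),
                        "sd": float(x.std(ddof=1)) if x.size > 1 else np.nan,
                    }
                )
        return pd.DataFrame(records)


def _resolve_bands(bands) -> tuple[BandDefinition, ...]:
    resolved = []
    for b in bands:
        if isinstance(b, BandDefinition):
            resolved.append(b)
        else:
            resolved.append(band_by_center(float(b)))
    return tuple(resolved)


def group_band_table(
    grouped: GroupedSpectra, bands=STAGED_BAND_CENTERS, operator: str = "height"
) -> BandIntensityTable:
    """Extract per-spectrum band intensities for every group x band cell.

    ``bands`` may be band centers (looked up in the catalog) or
    BandDefinition objects.  The default set is the four staged bands of
    the intensity histograms (1002, 1261, 1444, 1654 cm^-1).
    """
    band_defs = _resolve_bands(bands)
    op = band_intensity if operator == "height" else band_area
    table: dict = {}
    for label, spectra in grouped.items():
        if len(spectra) < 2:
            raise ValueError(f"group {label!r} needs >= 2 spectra")
        for band in band_defs:
            table[(label, band.center_cm1)] = np.array(
                [op(s, band) for s in spectra]
            )
    return BandIntensityTable(table, grouped.labels, band_defs)


@dataclass
class TukeyResult:
    """One-way ANOVA per band plus all-pairs Tukey HSD comparisons.

    ``anova`` maps band center -> (F, p); ``pairs`` holds one row per
    (band, group pair) with the mean difference, studentized-range q,
    adjusted p and the significance tier it clears (0.05 / 0.01 / 0.001,
    or NaN when not significant).
    """

    anova: dict
    pairs: pd.DataFrame
    degenerate: bool = False


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, float, int]:
    """F, p, within-group mean square, within df — by sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_x.size - len(groups)
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
        return f, p, ms_within, df_within
    f = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p, float(ms_within), df_within


def _tier(p: float) -> float:
    for threshold in reversed(SIGNIFICANCE_TIERS):
        if p < threshold:
            return threshold
    return float("nan")


def anova_tukey(table: BandIntensityTable) -> TukeyResult:
    """One-way ANOVA per band and Tukey HSD over all group pairs.

    The Tukey q statistic uses the Tukey–Kramer form
    ``q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b))`` (which reduces
    to classic Tukey for balanced designs) with p-values from the
    studentized-range distribution.  Zero within-group variance with
    unequal means is reported as p = 0 with the ``degenerate`` flag.
    """
    if len(table.groups) < 2:
        raise ValueError("Tukey needs at least 2 groups")
    anova: dict = {}
    records = []
    degenerate = False
    k = len(table.groups)
    for band in table.bands:
        groups = [table.samples(g, band.center_cm1) for g in table.groups]
        f, p, msw, dfw = _one_way_anova(groups)
        if msw == 0 and f > 0:
            degenerate = True
        anova[band.center_cm1] = (f, p)
        for (ia, ga), (ib, gb) in combinations(enumerate(table.groups), 2):
            a, b = groups[ia], groups[ib]
            diff = float(a.mean() - b.mean())
            if msw > 0:
                se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, dfw))
            else:
                q = np.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            records.append(
                {
                    "band_cm1": band.center_cm1,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_diff": diff,
                    "q": float(q),
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                    "tier": _tier(p_adj),
                }
            )
    return TukeyResult(anova, pd.DataFrame(records), degenerate)


def mean_sd_spectrum(spectra: list[Spectrum]) -> tuple[Spectrum, Spectrum]:
    """Pointwise mean and sample SD of a group of spectra."""
    if len(spectra) < 2:
        raise ValueError("SD undefined for fewer than 2 spectra")
    axis = spectra[0].axis
    x = np.vstack([s.intensities for s in spectra])
    return (
        Spectrum(axis, x.mean(axis=0), {"stat": "mean"}),
        Spectrum(axis, x.std(axis=0, ddof=1), {"stat": "sd"}),
    )


def difference_spectrum(
    grouped: GroupedSpectra, group_a: str, group_b: str
) -> Spectrum:
    """mean(group_a) - mean(group_b), pointwise."""
    for g in (group_a, group_b):
        if g not in grouped:
            raise KeyError(f"unknown group {g!r}")
    mean_a = grouped.matrix(group_a).mean(axis=0)
    mean_b = grouped.matrix(group_b).mean(axis=0)
    return Spectrum(
        grouped.axis, mean_a - mean_b, {"difference": f"{group_a} - {group_b}"}
    )
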