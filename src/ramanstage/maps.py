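"""Per-band Raman intensity maps with uniform scaling across samples.

A band map holds one band-height value per pixel (the same intensity
operator as :mod:`ramanstage.band_stats`).  When several samples are
rendered for one band, they share color-scale bounds so that
concentration differences are visually comparable, and pixels flagged
during preprocessing are rendered as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .spectral_core import BandDefinition, HyperspectralCube

__all__ = [
    "BandMap",
    "band_map",
    "uniform_scale",
    "save_map_matrix",
    "load_map_matrix",
    "save_map_png",
]

#: Sentinel written for missing pixels in delimited matrices.
MISSING_SENTINEL = "nan"


@dataclass(frozen=True)
class BandMap:
    """A rows x cols matrix of band heights; NaN marks missing pixels."""

    values: np.ndarray
    band: BandDefinition
    step_um: float
    sample: str = ""
    bounds: tuple[float, float] | None = None


def band_map(cube: HyperspectralCube, band: BandDefinition) -> BandMap:
    """Per-pixel band height for a preprocessed cube.

    Pixels flagged by preprocessing (``cube.meta['flagged']``) become NaN.
    """
    mask = cube.axis.window_mask(band.center_cm1, band.half_window_cm1)
    if not mask.any():
        raise ValueError(
            f"band {band.center_cm1} cm^-1 lies outside the cube axis"
        )
    values = cube.pixels[:, :, mask].max(axis=2)
    flagged = cube.meta.get("flagged")
    if flagged is not None:
        values = np.where(np.asarray(flagged, dtype=bool), np.nan, values)
    return BandMap(values, band, cube.step_um, str(cube.meta.get("sample", "")))


def uniform_scale(maps: list[BandMap]) -> list[BandMap]:
    """Attach shared [global min, global max] bounds to maps of one band.

    The bounds are computed over all non-missing pixels of all maps, so
    pseudo-color rendering is directly comparable across samples; the
    result does not depend on the order of the list.
    """
    if not maps:
        return []
    centers = {m.band.center_cm1 for m in maps}
    if len(centers) > 1:
        raise ValueError(f"maps mix bands {sorted(centers)}; uniform scaling is per band")
    stacked = np.concatenate([m.values.ravel() for m in maps])
    finite = stacked[np.isfinite(stacked)]
    if finite.size == 0:
        bounds = (0.0, 1.0)
    else:
        bounds = (float(finite.min()), float(finite.max()))
    return [replace(m, bounds=bounds) for m in maps]


def save_map_matrix(band_map_: BandMap, path, delimiter: str = ",") -> Path:
    """Write the map as a delimited matrix (missing pixels as ``nan``)."""
    path = Path(path)
    np.savetxt(path, band_map_.values, delimiter=delimiter, fmt="%.17g")
    return path


def load_map_matrix(path, delimiter: str = ",") -> np.ndarray:
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)


def save_map_png(band_map_: BandMap, path, cmap: str = "inferno") -> Path:
    """Render the map to PNG with a continuous pseudo-color scale.

    Shared bounds (from :func:`uniform_scale`) clamp the color range;
    missing pixels are transparent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.colors as mcolors
    import matplotlib.image as mimage

    values = band_map_.values
    if band_map_.bounds is not None:
        vmin, vmax = band_map_.bounds
    else:
        finite = values[np.isfinite(values)]
        vmin = float(finite.min()) if finite.size else 0.0
        vmax = float(finite.max()) if finite.size else 1.0
    norm = mcolors.Normalize(vmin=vmin, vmax=vmax)
    rgba = matplotlib.colormaps[cmap](norm(np.nan_to_num(values, nan=vmin)))
    rgba[..., 3] = np.where(np.isfinite(values), 1.0, 0.0)
    path = Path(path)
    mimage.imsave(path, rgba)
    return path
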