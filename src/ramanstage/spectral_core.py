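"""Core data model for Raman spectra: axes, spectra, grouped spectra,
hyperspectral cubes, band definitions, and delimited-text I/O.

All spectra in a collection share one :class:`WavenumberAxis`.  Cubes use
image conventions: pixel ``(0, 0)`` is the top-left corner, the row index
increases downward, and row-major order is used whenever a cube is
flattened to a list of spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FINGERPRINT_RANGE",
    "DEFAULT_N_POINTS",
    "GROUP_LABELS",
    "WavenumberAxis",
    "Spectrum",
    "GroupedSpectra",
    "HyperspectralCube",
    "BandDefinition",
    "BAND_CATALOG",
    "band_by_center",
    "read_spectrum_table",
    "write_spectrum_table",
    "cube_to_table",
    "table_to_cube",
    "write_cube",
    "read_cube",
]

#: Fingerprint region used for all analysis, in cm^-1.
FINGERPRINT_RANGE = (700.0, 1800.0)

#: Number of points of the default (instrument-like) axis.
DEFAULT_N_POINTS = 867

#: Canonical sample labels: 2D prostate-cancer culture and the three
#: sequential 3D bone-mimetic cultures (23 days of MSCs + 5/10/15 days of
#: cancer cells).
GROUP_LABELS = ("2D_PCa", "3D_d23+5", "3D_d23+10", "3D_d23+15")

WAVENUMBER_COLUMN = "wavenumber_cm1"


class AxisError(ValueError):
    """Raised for invalid wavenumber axes (non-monotonic, non-finite)."""


class ParseError(ValueError):
    """Raised for malformed spectrum tables (ragged or non-numeric cells)."""


@dataclass(frozen=True)
class WavenumberAxis:
    """A calibrated, strictly increasing Raman-shift grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise AxisError("axis must be a 1-D array with at least 2 points")
        if not np.all(np.isfinite(values)):
            raise AxisError("axis contains non-finite values")
        if not np.all(np.diff(values) > 0):
            raise AxisError("axis must be strictly increasing")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @classmethod
    def default(cls) -> "WavenumberAxis":
        """The default fingerprint axis: 867 points over [700, 1800] cm^-1.

        The instrument grid is CCD-sampled and not exactly uniform; a
        uniform grid is a stated approximation for synthetic work.
        """
        lo, hi = FINGERPRINT_RANGE
        return cls(np.linspace(lo, hi, DEFAULT_N_POINTS))

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash((self.values.shape, float(self.values[0]), float(self.values[-1])))

    def window_mask(self, center_cm1: float, half_window_cm1: float) -> np.ndarray:
        """Boolean mask of points within ``center ± half_window``."""
        return np.abs(self.values - center_cm1) <= half_window_cm1

    def index_of(self, wavenumber_cm1: float) -> int:
        """Index of the grid point nearest to ``wavenumber_cm1``."""
        return int(np.argmin(np.abs(self.values - wavenumber_cm1)))


@dataclass
class Spectrum:
    """One intensity vector on a shared axis, with free-form metadata.

    ``meta`` may carry a ``group`` label (one of :data:`GROUP_LABELS` or
    free text) and 0-based pixel coordinates ``row``/``col``.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size != self.axis.n_points:
            raise ValueError(
                f"intensities length {arr.size} != axis length {self.axis.n_points}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities contain non-finite values")
        self.intensities = arr

    @property
    def group(self) -> str | None:
        return self.meta.get("group")

    def with_intensities(self, intensities: np.ndarray, **meta) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.axis, intensities, new_meta)


class GroupedSpectra:
    """Ordered per-group collections of spectra sharing one axis.

    Group order is insertion order and is preserved deterministically.
    """

    def __init__(self, groups: Mapping[str, Sequence[Spectrum]] | None = None):
        self._groups: dict[str, list[Spectrum]] = {}
        self._axis: WavenumberAxis | None = None
        if groups:
            for label, spectra in groups.items():
                for s in spectra:
                    self.add(label, s)

    def add(self, label: str, spectrum: Spectrum) -> None:
        if self._axis is None:
            self._axis = spectrum.axis
        elif spectrum.axis != self._axis:
            raise ValueError("all spectra in a GroupedSpectra must share one axis")
        spectrum.meta.setdefault("group", label)
        self._groups.setdefault(label, []).append(spectrum)

    @property
    def axis(self) -> WavenumberAxis:
        if self._axis is None:
            raise ValueError("empty GroupedSpectra has no axis")
        return self._axis

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._groups)

    def __getitem__(self, label: str) -> list[Spectrum]:
        return self._groups[label]

    def __contains__(self, label: str) -> bool:
        return label in self._groups

    def __len__(self) -> int:
        return len(self._groups)

    def items(self) -> Iterator[tuple[str, list[Spectrum]]]:
        return iter(self._groups.items())

    def all_spectra(self) -> list[Spectrum]:
        return [s for spectra in self._groups.values() for s in spectra]

    def matrix(self, label: str) -> np.ndarray:
        """Group intensities stacked as (n_spectra, n_points)."""
        return np.vstack([s.intensities for s in self._groups[label]])

    def map(self, func) -> "GroupedSpectra":
        out = GroupedSpectra()
        for label, spectra in self.items():
            for s in spectra:
                out.add(label, func(s))
        return out


@dataclass
class HyperspectralCube:
    """A rows x cols grid of spectra with a physical step size in µm."""

    rows: int
    cols: int
    step_um: float
    axis: WavenumberAxis
    pixels: np.ndarray  # (rows, cols, n_points)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("cube must have rows >= 1 and cols >= 1")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        arr = np.asarray(self.pixels, dtype=float)
        expected = (self.rows, self.cols, self.axis.n_points)
        if arr.shape != expected:
            raise ValueError(f"pixels shape {arr.shape} != {expected}")
        self.pixels = arr

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (height, width) of the mapped area in µm."""
        return (self.rows * self.step_um, self.cols * self.step_um)

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(
            self.axis,
            self.pixels[row, col],
            {"row": row, "col": col, **self.meta},
        )

    def flat(self) -> np.ndarray:
        """Row-major (n_pixels, n_points) view of the cube."""
        return self.pixels.reshape(self.n_pixels, self.axis.n_points)


@dataclass(frozen=True)
class BandDefinition:
    """A Raman band: nominal center, extraction half-window, assignment."""

    center_cm1: float
    half_window_cm1: float = 8.0
    assignment: str = ""

    def __post_init__(self) -> None:
        lo, hi = FINGERPRINT_RANGE
        if not (lo <= self.center_cm1 <= hi):
            raise ValueError(f"band center {self.center_cm1} outside fingerprint range")
        if self.half_window_cm1 <= 0:
            raise ValueError("half_window_cm1 must be positive")


#: The eleven prominent fingerprint bands of prostate cancer cells, with
#: their tentative biochemical assignments.  The 8 cm^-1 half-window equals
#: the spectral resolution of the acquisition.
BAND_CATALOG: tuple[BandDefinition, ...] = (
    BandDefinition(780, 8.0, "Ring breathing of cytosine and thymine"),
    BandDefinition(850, 8.0, "v(C–C) ring breathing of tyrosine and proline"),
    BandDefinition(935, 8.0, "v(C–C) of α-helix conformation for proteins"),
    BandDefinition(1002, 8.0, "v(C–C) ring breathing of phenylalanine"),
    BandDefinition(1080, 8.0, "v(C–C) of lipids"),
    BandDefinition(1124, 8.0, "v(C–O) in carbohydrates"),
    BandDefinition(1261, 8.0, "amide III δ(N–H) of proteins"),
    BandDefinition(1296, 8.0, "δ(CH2) deformations of lipids and proteins"),
    BandDefinition(1336, 8.0, "CH3CH2 twisting of nucleic acids"),
    BandDefinition(1444, 8.0, "δ(CH2) of proteins and lipids"),
    BandDefinition(1654, 8.0, "amide I v(C=O) of proteins, α-helical conformation"),
)

#: The four bands whose intensities change with tumorigenesis stage.
STAGED_BAND_CENTERS = (1002.0, 1261.0, 1444.0, 1654.0)


def band_by_center(center_cm1: float) -> BandDefinition:
    """Look up a catalog band by its nominal center (exact match)."""
    for band in BAND_CATALOG:
        if band.center_cm1 == center_cm1:
            return band
    raise KeyError(f"no catalog band at {center_cm1} cm^-1")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_spectrum_table(
    path,
    axis: WavenumberAxis,
    spectra: Sequence[Spectrum],
    delimiter: str = ",",
    sidecar: Mapping | None = None,
) -> Path:
    """Write spectra as delimited text: a ``wavenumber_cm1`` column plus one
    column per spectrum.  Values are formatted to 17 significant digits so a
    round trip reproduces them exactly.

    When ``sidecar`` is given (or any spectrum carries a ``group`` label) a
    JSON metadata sidecar is written next to the table.
    """
    path = Path(path)
    for s in spectra:
        if s.axis != axis:
            raise ValueError("all spectra must share the given axis")
    columns: dict[str, np.ndarray] = {WAVENUMBER_COLUMN: axis.values}
    names = []
    for i, s in enumerate(spectra):
        name = str(s.meta.get("name", f"s{i:04d}"))
        columns[name] = s.intensities
        names.append(name)
    df = pd.DataFrame(columns)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")

    meta: dict = dict(sidecar) if sidecar else {}
    groups = [s.meta.get("group") for s in spectra]
    if any(g is not None for g in groups):
        meta.setdefault("groups", groups)
    if meta:
        meta.setdefault("columns", names)
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_spectrum_table(path) -> tuple[WavenumberAxis, list[Spectrum]]:
    """Read a delimited spectrum table (comma or tab separated).

    The first column must be headed ``wavenumber_cm1`` and be strictly
    increasing.  A JSON sidecar ``<path>.meta.json``, when present, supplies
    per-column group labels and grid metadata.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing: the default fast parser is not correctly rounded
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.columns[0] != WAVENUMBER_COLUMN:
        raise ParseError(
            f"first column must be '{WAVENUMBER_COLUMN}', got '{df.columns[0]}'"
        )
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & df[col].notna())[0])
            raise ParseError(
                f"non-numeric cell in column '{col}', data row {row}"
            ) from None
    if df.isna().any().any():
        col = df.columns[int(np.argmax(df.isna().any().values))]
        row = int(np.flatnonzero(df[col].isna())[0])
        raise ParseError(f"missing value (ragged row?) in column '{col}', data row {row}")

    try:
        axis = WavenumberAxis(df[WAVENUMBER_COLUMN].to_numpy())
    except AxisError as exc:
        raise AxisError(f"invalid wavenumber column in {path.name}: {exc}") from None

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    groups = meta.get("groups")

    spectra = []
    for i, col in enumerate(df.columns[1:]):
        smeta: dict = {"name": col}
        if groups is not None and i < len(groups) and groups[i] is not None:
            smeta["group"] = groups[i]
        for key in ("sample", "step_um"):
            if key in meta:
                smeta[key] = meta[key]
        spectra.append(Spectrum(axis, df[col].to_numpy(), smeta))
    return axis, spectra


def cube_to_table(cube: HyperspectralCube) -> tuple[WavenumberAxis, list[Spectrum]]:
    """Flatten a cube to spectra in row-major order, with (row, col) meta."""
    spectra = []
    for r in range(cube.rows):
        for c in range(cube.cols):
            spectra.append(
                Spectrum(
                    cube.axis,
                    cube.pixels[r, c],
                    {"row": r, "col": c, "name": f"r{r:03d}c{c:03d}", **cube.meta},
                )
            )
    return cube.axis, spectra


def table_to_cube(
    axis: WavenumberAxis,
    spectra: Sequence[Spectrum],
    rows: int,
    cols: int,
    step_um: float,
    meta: Mapping | None = None,
) -> HyperspectralCube:
    """Assemble row-major spectra into a cube.  Count must equal rows*cols."""
    if len(spectra) != rows * cols:
        raise ValueError(f"{len(spectra)} spectra cannot fill a {rows}x{cols} grid")
    pixels = np.empty((rows, cols, axis.n_points))
    for i, s in enumerate(spectra):
        if s.axis != axis:
            raise ValueError("all spectra must share the given axis")
        r, c = divmod(i, cols)
        pixels[r, c] = s.intensities
        s.meta.setdefault("row", r)
        s.meta.setdefault("col", c)
    return HyperspectralCube(rows, cols, step_um, axis, pixels, dict(meta or {}))


def write_cube(path, cube: HyperspectralCube, delimiter: str = ",") -> Path:
    """Write a cube as a spectrum table plus a sidecar with grid metadata."""
    axis, spectra = cube_to_table(cube)
    sidecar = {
        "rows": cube.rows,
        "cols": cube.cols,
        "step_um": cube.step_um,
        **{k: v for k, v in cube.meta.items() if isinstance(v, (str, int, float))},
    }
    return write_spectrum_table(path, axis, spectra, delimiter, sidecar=sidecar)


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (requires the sidecar)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"cube sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    axis, spectra = read_spectrum_table(path)
    rows, cols, step = int(meta["rows"]), int(meta["cols"]), float(meta["step_um"])
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("rows", "cols", "step_um", "groups", "columns")
    }
    return table_to_cube(axis, spectra, rows, cols, step, extra)
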