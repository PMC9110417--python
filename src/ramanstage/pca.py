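"""Covariance-matrix PCA over preprocessed spectra.

Observations are spectra and variables are wavenumbers; variables are
mean-centered but never scaled to unit variance (covariance PCA, not
correlation PCA).  Spectroscopy software often stores the matrix
transposed (wavenumbers as rows); that orientation is honored only at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_core import GroupedSpectra, Spectrum

__all__ = ["PCAResult", "assemble_matrix", "fit_pca", "project"]

_DEGENERATE_EPS = 1e-12


@dataclass
class PCAResult:
    """Mean, loadings, scores, eigenvalues and explained-variance fractions.

    ``loadings`` has orthonormal columns (variables x components);
    ``explained_fraction`` is in percent and sums to 100 over all
    components unless the input was degenerate (zero total variance), in
    which case all fractions are 0 and ``degenerate`` is set.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def assemble_matrix(grouped: GroupedSpectra) -> tuple[np.ndarray, list[str]]:
    """Stack grouped spectra into an (observations x variables) matrix.

    Group (insertion) order is preserved; the returned labels give the group
    of each row.  With the study's sampling design (4 groups x 20 selected
    spectra on an 867-point axis) this is an 80 x 867 matrix — the
    transpose of the 867 x 80 storage orientation used by spectroscopy
    packages.
    """
    rows, labels = [], []
    for label, spectra in grouped.items():
        if not spectra:
            raise ValueError(f"group {label!r} is empty")
        for s in spectra:
            rows.append(s.intensities)
            labels.append(label)
    return np.vstack(rows), labels


def fit_pca(matrix: np.ndarray) -> PCAResult:
    """Eigendecomposition of the observation covariance matrix.

    Component count is ``min(n_obs - 1, n_variables)``.  Eigenvector signs
    are fixed by the convention that each loading's largest-magnitude
    element is positive, so results are deterministic.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (observations x variables)")
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = x.mean(axis=0)
    centered = x - mean
    k = min(n - 1, p)
    # SVD of the centered data is the numerically stable route to the
    # covariance eigendecomposition: eigenvalues are s^2 / (n - 1).
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    # deterministic sign convention
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = centered @ loadings
    total = eigenvalues.sum()
    degenerate = bool(total < _DEGENERATE_EPS)
    explained = (
        np.zeros(k) if degenerate else 100.0 * eigenvalues / total
    )
    return PCAResult(mean, loadings, scores, eigenvalues, explained, degenerate)


def project(pca: PCAResult, data) -> np.ndarray:
    """Project spectra (or a raw matrix) onto the fitted components.

    Accepts a Spectrum, a sequence of Spectrum, or an array whose last axis
    matches the training variable count.
    """
    if isinstance(data, Spectrum):
        x = data.intensities[None, :]
    elif isinstance(data, (list, tuple)) and data and isinstance(data[0], Spectrum):
        x = np.vstack([s.intensities for s in data])
    else:
        x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[-1] != pca.mean_spectrum.size:
        raise ValueError(
            f"variable count {x.shape[-1]} != training axis {pca.mean_spectrum.size}"
        )
    return (x - pca.mean_spectrum) @ pca.loadings
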