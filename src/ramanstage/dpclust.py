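"""Density-peak clustering (clustering by fast search and find of density
peaks) over points in PC-score space.

Each point gets a local density rho and a distance delta to the nearest
point of higher density; cluster centers are points where the product
gamma = rho * delta is anomalously large, and every other point inherits
the label of its nearest denser neighbor, walking down the density
ordering.  Density ties are broken by point index (lower index counts as
denser), which makes the procedure fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DPParams",
    "ClusterResult",
    "resolve_dc",
    "local_density",
    "delta_and_neighbor",
    "cluster",
]


@dataclass(frozen=True)
class DPParams:
    """Density-peak clustering parameters.

    ``d_c`` is the kernel distance cutoff; when None it is resolved as the
    ``dc_percentile``-th percentile of all positive pairwise distances (the
    few-percent rule of thumb).  ``n_clusters`` is an explicit center count
    or ``"auto"``: on the decision graph, a center must be *separated* —
    its delta must exceed ``center_min_delta_factor * d_c`` (a point whose
    nearest denser neighbor is within the kernel scale is the flank of a
    denser structure, however large its density makes gamma).  All
    separated candidates become centers (up to 12), unless the candidates'
    sorted deltas contain a decisive drop — a ratio above
    ``center_delta_gap`` — in which case the list is cut at the largest
    such drop.  Real centers sit at inter-cluster distance; stragglers sit
    just above the eligibility floor, so the cliff between the two is the
    robust signal (gamma mixes in density and spans orders of magnitude
    between legitimate clusters of different tightness).
    """

    kernel: str = "gaussian"  # or "cutoff"
    d_c: float | None = None
    dc_percentile: float = 2.0
    n_clusters: int | str = "auto"
    center_min_delta_factor: float = 2.0
    center_delta_gap: float = 3.0
    assign_halo: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "cutoff"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.d_c is not None and self.d_c <= 0:
            raise ValueError("d_c must be positive")
        if isinstance(self.n_clusters, int) and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class ClusterResult:
    """Density-peak quantities and the final assignment.

    ``nn_higher`` is -1 for the global density maximum, which by definition
    has ``delta`` equal to the maximum pairwise distance.
    """

    rho: np.ndarray
    delta: np.ndarray
    nn_higher: np.ndarray
    gamma: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    d_c: float
    halo: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.centers.size)


def resolve_dc(distances: np.ndarray, params: DPParams) -> float:
    """Resolve the cutoff distance: explicit value, or a percentile of the
    positive upper-triangle pairwise distances.

    Zero distances are excluded from the percentile: coincident points
    (e.g. the digital reference stripe's duplicated pixels) would otherwise
    drag the percentile to zero and degenerate the kernel scale.
    """
    if params.d_c is not None:
        return float(params.d_c)
    d = np.asarray(distances)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a square distance matrix over >= 2 points")
    upper = d[np.triu_indices(d.shape[0], k=1)]
    positive = upper[upper > 0]
    if positive.size == 0:
        raise ValueError("degenerate point set: all pairwise distances are zero")
    return float(np.percentile(positive, params.dc_percentile))


def local_density(distances: np.ndarray, d_c: float, kernel: str = "gaussian") -> np.ndarray:
    """Local density rho per point.

    gaussian: rho_i = sum_{j != i} exp(-(d_ij / d_c)^2);
    cutoff:   rho_i = #{j != i : d_ij < d_c}.
    """
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if kernel == "gaussian":
        contrib = np.exp(-((d / d_c) ** 2))
    elif kernel == "cutoff":
        contrib = (d < d_c).astype(float)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return np.where(off, contrib, 0.0).sum(axis=1)


def delta_and_neighbor(
    distances: np.ndarray, rho: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """delta_i = distance to the nearest point of higher (tie-broken by
    index) density; the global density maximum gets the max pairwise
    distance and neighbor -1."""
    d = np.asarray(distances, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n = rho.size
    idx = np.arange(n)
    # "denser" matrix: denser[i, j] True when j outranks i
    denser = (rho[None, :] > rho[:, None]) | (
        (rho[None, :] == rho[:, None]) & (idx[None, :] < idx[:, None])
    )
    masked = np.where(denser, d, np.inf)
    delta = masked.min(axis=1)
    nn = masked.argmin(axis=1)
    top = int(np.lexsort((idx, -rho))[0])
    delta[top] = d[top].max() if n > 1 else 0.0
    nn[top] = -1
    return delta, nn.astype(int)


def _auto_centers(
    gamma: np.ndarray,
    delta: np.ndarray,
    d_c: float,
    min_delta_factor: float,
    delta_gap: float,
) -> np.ndarray:
    """Auto center selection on the decision graph.

    Candidates are delta-separated points (delta > min_delta_factor * d_c),
    ordered by descending delta (ties by gamma, then index).  All
    candidates are kept (capped at 12) unless a delta ratio of at least
    ``delta_gap`` occurs in the sorted list, in which case the list is cut
    at the largest such drop (never below the top two).  Returns center
    indices, sorted.
    """
    eligible = np.flatnonzero(delta > min_delta_factor * d_c)
    if eligible.size == 0:
        eligible = np.array([int(np.argmax(gamma))])
    order = eligible[np.lexsort((eligible, -gamma[eligible], -delta[eligible]))]
    dl = delta[order]
    keep = min(order.size, 12)
    best_k, best_ratio = None, delta_gap
    for k in range(2, keep):
        ratio = dl[k - 1] / dl[k]
        if ratio >= best_ratio:
            best_k, best_ratio = k, ratio
    if best_k is not None:
        keep = best_k
    return np.sort(order[:keep])


def cluster(points: np.ndarray, params: DPParams | None = None) -> ClusterResult:
    """Full density-peak clustering of points under the Euclidean metric.

    Centers are the top-``n_clusters`` points by gamma = rho * delta (ties
    broken by index); remaining points are assigned, in descending density
    order, to the label of their nearest denser neighbor.  With
    ``assign_halo`` set, points whose density falls below their cluster's
    border density are flagged as halo (labels are kept).
    """
    params = params or DPParams()
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = x.shape[0]
    if isinstance(params.n_clusters, int) and params.n_clusters > n:
        raise ValueError("n_clusters cannot exceed the number of points")
    if n == 1:
        return ClusterResult(
            rho=np.zeros(1),
            delta=np.zeros(1),
            nn_higher=np.array([-1]),
            gamma=np.zeros(1),
            centers=np.array([0]),
            labels=np.zeros(1, dtype=int),
            d_c=params.d_c or 1.0,
        )
    d = squareform(pdist(x))
    d_c = resolve_dc(d, params)
    rho = local_density(d, d_c, params.kernel)
    delta, nn = delta_and_neighbor(d, rho)
    gamma = rho * delta
    if params.n_clusters == "auto":
        centers = _auto_centers(
            gamma,
            delta,
            d_c,
            params.center_min_delta_factor,
            params.center_delta_gap,
        )
        k = centers.size
    else:
        k = int(params.n_clusters)
        # top-k gamma, ties broken by index
        order = np.lexsort((np.arange(n), -gamma))
        centers = np.sort(order[:k])
    labels = np.full(n, -1, dtype=int)
    for cid, c in enumerate(centers):
        labels[c] = cid
    for i in np.lexsort((np.arange(n), -rho)):
        if labels[i] < 0:
            labels[i] = labels[nn[i]]
    halo = None
    if params.assign_halo and k > 1:
        halo = np.zeros(n, dtype=bool)
        border_rho = np.zeros(k)
        cross = (labels[:, None] != labels[None, :]) & (d < d_c)
        for cid in range(k):
            members = labels == cid
            pairs = cross[members]
            if pairs.any():
                avg = (rho[members][:, None] + rho[None, :]) / 2.0
                border_rho[cid] = avg[pairs].max()
        halo = rho < border_rho[labels]
    return ClusterResult(rho, delta, nn, gamma, centers, labels, d_c, halo)
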