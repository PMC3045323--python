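"""Hierarchical blocking of the truncated binary DAG matrix.

Rows and columns of the (sources x sinks) binary DAG matrix are reordered
by agglomerative clustering, then a five-step blocking transformation turns
the matrix into a grey-scale picture of latent blocks: row-wise cluster mass
fractions (R), column-wise fractions (C) and their average (Scomb).  A
quality score Q, maximised over a shared dendrogram cutoff, selects the
clustering granularity; a final consolidation pass reclusters the combined
matrix with the Bray-Curtis distance so split bands rejoin their blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

__all__ = [
    "BINARY_MEASURES",
    "DissimilarityConfig",
    "AxisClustering",
    "BlockingResult",
    "binary_dissimilarity",
    "bray_curtis",
    "pairwise_binary",
    "cluster_order",
    "clusters_at_cutoff",
    "block_transform",
    "quality",
    "optimise_blocking",
    "consolidate",
]

#: (a, b) coefficients of the binary dissimilarity family
#: d = (n10 + n01) / (n10 + n01 + a*n11 + b*n00)
BINARY_MEASURES = {
    "matching": (1.0, 1.0),
    "jaccard": (1.0, 0.0),
    "sokal_sneath": (0.5, 0.0),
    "rogers_tanimoto": (0.5, 0.5),
    "dice": (2.0, 0.0),
}

#: range the trial dendrogram cutoffs are restricted to
CUTOFF_RANGE = (0.2, 0.7)
FALLBACK_CUTOFF = 0.45


@dataclass
class DissimilarityConfig:
    """Dissimilarity and linkage choices for the blocking transformation."""

    binary_measure: str = "sokal_sneath"
    linkage: str = "single"
    real_measure: str = "braycurtis"

    @property
    def coefficients(self) -> tuple[float, float]:
        return BINARY_MEASURES[self.binary_measure]


@dataclass
class AxisClustering:
    """Dendrogram over one matrix axis: leaf order plus merge heights."""

    order: np.ndarray  # leaf order, original indices
    heights: np.ndarray  # sorted intercluster merge distances
    Z: np.ndarray | None  # scipy linkage matrix (None for a single vector)


@dataclass
class BlockingResult:
    """Outcome of the blocking transformation at a particular cutoff."""

    row_order: np.ndarray  # original row indices in display order
    col_order: np.ndarray
    row_clusters: list[np.ndarray]  # contiguous position bands in display order
    col_clusters: list[np.ndarray]
    binary: np.ndarray  # reordered binary matrix
    R: np.ndarray
    C: np.ndarray
    Scomb: np.ndarray
    cutoff: float
    Q: float
    white_count: int
    dims: tuple[int, int] = field(default=None)

    def __post_init__(self) -> None:
        if self.dims is None:
            self.dims = self.Scomb.shape


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------


def binary_dissimilarity(u, v, config: DissimilarityConfig | None = None) -> float:
    """Binary vector dissimilarity d = (n10+n01)/(n10+n01 + a*n11 + b*n00).

    Coefficients (a, b) select the named measure (Sokal-Sneath by default).
    Identical vectors give 0; a vanishing denominator (e.g. two all-zero
    vectors under Jaccard) returns 0 by convention.
    """
    a, b = (config or DissimilarityConfig()).coefficients
    u = np.asarray(u, bool)
    v = np.asarray(v, bool)
    n11 = int(np.sum(u & v))
    n00 = int(np.sum(~u & ~v))
    mism = int(np.sum(u != v))
    denom = mism + a * n11 + b * n00
    return mism / denom if denom > 0 else 0.0


def bray_curtis(u, v) -> float:
    """Bray-Curtis distance sum|a-b| / sum|a+b|; 0 when both vectors vanish."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    denom = float(np.abs(u + v).sum())
    return float(np.abs(u - v).sum()) / denom if denom > 0 else 0.0


def pairwise_binary(X: np.ndarray, config: DissimilarityConfig | None = None) -> np.ndarray:
    """Condensed pairwise binary dissimilarities between the rows of X."""
    a, b = (config or DissimilarityConfig()).coefficients
    X = np.asarray(X, float)
    n, L = X.shape
    B = (X != 0).astype(float)
    n11 = B @ B.T
    ones = B.sum(axis=1)
    mism = ones[:, None] + ones[None, :] - 2 * n11
    n00 = L - n11 - mism
    denom = mism + a * n11 + b * n00
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, mism / denom, 0.0)
    iu = np.triu_indices(n, 1)
    return D[iu]


def _pairwise_real(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(np.asarray(X, float), metric="braycurtis")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_order(
    matrix: np.ndarray,
    axis: int = 0,
    config: DissimilarityConfig | None = None,
    real_valued: bool = False,
) -> AxisClustering:
    """Deterministic agglomerative clustering of row (axis=0) or column vectors.

    Returns the dendrogram leaf order and the sorted intercluster merge
    distances.  Binary inputs use the configured binary dissimilarity;
    ``real_valued=True`` switches to the Bray-Curtis distance.
    """
    config = config or DissimilarityConfig()
    X = matrix if axis == 0 else matrix.T
    n = X.shape[0]
    if n == 1:
        return AxisClustering(np.array([0]), np.array([]), None)
    D = _pairwise_real(X) if real_valued else pairwise_binary(X, config)
    D = np.nan_to_num(D, nan=0.0)
    Z = hierarchy.linkage(D, method=config.linkage)
    order = np.asarray(hierarchy.leaves_list(Z))
    return AxisClustering(order, np.sort(Z[:, 2]), Z)


def clusters_at_cutoff(clust: AxisClustering, cutoff: float) -> list[np.ndarray]:
    """Contiguous position bands of the leaf order induced by a distance cutoff.

    Each band is a numpy array of *positions* in ``clust.order`` (not
    original indices); bands partition the axis contiguously because every
    dendrogram subtree occupies a contiguous run of leaves.
    """
    n = len(clust.order)
    if clust.Z is None:
        return [np.arange(n)]
    labels = hierarchy.fcluster(clust.Z, t=cutoff, criterion="distance")
    labels_in_order = labels[clust.order]
    bands = []
    start = 0
    for pos in range(1, n + 1):
        if pos == n or labels_in_order[pos] != labels_in_order[start]:
            bands.append(np.arange(start, pos))
            start = pos
    return bands


# ---------------------------------------------------------------------------
# blocking transformation
# ---------------------------------------------------------------------------


def block_transform(
    binary: np.ndarray,
    row_clusters: list[np.ndarray],
    col_clusters: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the row/column blocking replacement and combine.

    For row i, every element in column cluster Cj is replaced by the fraction
    of the row's nonzero entries falling inside Cj (gaps inside a fully
    occupied cluster fill in to 1); columns are treated symmetrically over
    the row clusters; the combined matrix averages the two.  All-zero
    rows/columns map to zero.
    """
    B = (np.asarray(binary) != 0).astype(float)
    I, J = B.shape
    Mc = np.zeros((J, len(col_clusters)))
    for k, band in enumerate(col_clusters):
        Mc[band, k] = 1.0
    Mr = np.zeros((I, len(row_clusters)))
    for k, band in enumerate(row_clusters):
        Mr[band, k] = 1.0

    row_sums = B.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_rows = np.where(row_sums > 0, (B @ Mc) / row_sums, 0.0)
    R = frac_rows @ Mc.T

    col_sums = B.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_cols = np.where(col_sums > 0, (Mr.T @ B) / col_sums, 0.0)
    C = Mr @ frac_cols

    return R, C, 0.5 * (R + C)


def quality(Scomb: np.ndarray, white_count: int | None = None, dims=None) -> float:
    """Blocking quality Q = (sum(S)/(IJ-W))^2 * (W/IJ).

    The squared factor rewards dark (near-1) block interiors, the second
    rewards compact blocks via the white-cell fraction W/IJ.  An all-white
    matrix scores 0 by convention; Q < 1 always.
    """
    Scomb = np.asarray(Scomb, float)
    I, J = dims if dims is not None else Scomb.shape
    total = I * J
    W = white_count if white_count is not None else int(np.sum(Scomb <= 0))
    if W == total or total == 0:
        return 0.0
    return float((Scomb.sum() / (total - W)) ** 2 * (W / total))


def _trial_cutoffs(row_heights: np.ndarray, col_heights: np.ndarray) -> list[float]:
    merged = np.unique(np.concatenate([row_heights, col_heights]))
    mids = 0.5 * (merged[:-1] + merged[1:]) if merged.size > 1 else np.array([])
    lo, hi = CUTOFF_RANGE
    trials = [float(t) for t in mids if lo <= t <= hi]
    return trials


def _assemble(
    binary: np.ndarray,
    row_clust: AxisClustering,
    col_clust: AxisClustering,
    cutoff: float,
) -> BlockingResult:
    B = binary[np.ix_(row_clust.order, col_clust.order)]
    rcl = clusters_at_cutoff(row_clust, cutoff)
    ccl = clusters_at_cutoff(col_clust, cutoff)
    R, C, S = block_transform(B, rcl, ccl)
    W = int(np.sum(S <= 0))
    return BlockingResult(
        row_order=np.asarray(row_clust.order),
        col_order=np.asarray(col_clust.order),
        row_clusters=rcl,
        col_clusters=ccl,
        binary=B,
        R=R,
        C=C,
        Scomb=S,
        cutoff=cutoff,
        Q=quality(S, W),
        white_count=W,
    )


def optimise_blocking(
    truncated_binary: np.ndarray, config: DissimilarityConfig | None = None
) -> BlockingResult:
    """Search the shared dendrogram cutoff that maximises blocking quality Q.

    Trial cutoffs are midpoints of the merged, sorted row+column intercluster
    distance lists, restricted to [0.2, 0.7]; the same cutoff is applied to
    both dendrograms.  Ties in Q resolve to the smaller cutoff.  All-zero
    rows/columns are dropped (with a warning) before clustering; the stored
    row/col orders index the surviving rows/columns of the input.
    """
    config = config or DissimilarityConfig()
    B = (np.asarray(truncated_binary) != 0).astype(int)
    keep_rows = np.where(B.any(axis=1))[0]
    keep_cols = np.where(B.any(axis=0))[0]
    if len(keep_rows) < B.shape[0] or len(keep_cols) < B.shape[1]:
        warnings.warn(
            f"dropping {B.shape[0] - len(keep_rows)} all-zero rows and "
            f"{B.shape[1] - len(keep_cols)} all-zero columns before clustering"
        )
    B = B[np.ix_(keep_rows, keep_cols)]
    row_clust = cluster_order(B, axis=0, config=config)
    col_clust = cluster_order(B, axis=1, config=config)
    trials = _trial_cutoffs(row_clust.heights, col_clust.heights)
    if not trials:
        warnings.warn("no intercluster merge midpoints in [0.2, 0.7]; using 0.45")
        trials = [FALLBACK_CUTOFF]

    best = None
    for cutoff in sorted(trials):
        res = _assemble(B, row_clust, col_clust, cutoff)
        if best is None or res.Q > best.Q + 1e-15:
            best = res
    # map display orders back to the input matrix's surviving indices
    best.row_order = keep_rows[best.row_order]
    best.col_order = keep_cols[best.col_order]
    return best


def consolidate(
    result: BlockingResult, config: DissimilarityConfig | None = None
) -> BlockingResult:
    """Step 5: recluster the combined matrix (Bray-Curtis) and recompute.

    Rows and columns of Scomb are reordered by hierarchical clustering under
    the Bray-Curtis distance, cluster bands are re-derived at the stored
    cutoff, and R, C, Scomb are recomputed from the binary matrix in the new
    order.  Split bands that belong with a block become contiguous.
    """
    config = config or DissimilarityConfig()
    row_clust = cluster_order(result.Scomb, axis=0, config=config, real_valued=True)
    col_clust = cluster_order(result.Scomb, axis=1, config=config, real_valued=True)
    out = _assemble(result.binary, row_clust, col_clust, result.cutoff)
    out.row_order = np.asarray(result.row_order)[row_clust.order]
    out.col_order = np.asarray(result.col_order)[col_clust.order]
    return out
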