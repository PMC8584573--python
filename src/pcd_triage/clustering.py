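"""Pathogenicity clustering of the predictor-score matrix.

Variants with complete five-score panels are clustered into three classes
(possibly pathogenic / uncertain / possibly benign) by k-means, in two
views: the five-score view (MetaLR, MetaSVM, scaled CADD, REVEL, Condel)
that is also embedded in 2-D by classical multidimensional scaling, and the
two-score REVEL-vs-Condel scatter view. Cluster indices from k-means are
arbitrary, so semantic labels are assigned by descending mean Condel of the
cluster members: highest = pathogenic (red), lowest = benign (green).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .variant_table import CohortTable

__all__ = [
    "ScoreMatrix",
    "ClusterAssignment",
    "MdsEmbedding",
    "SCORE_COLUMNS",
    "CADD_SCALE_DIVISOR",
    "DEFAULT_SEED",
    "build_score_matrix",
    "kmeans",
    "classical_mds",
    "mds_view_cluster",
    "scatter_view_cluster",
    "concordance",
]

SCORE_COLUMNS = ("metalr", "metasvm", "cadd_scaled", "revel", "condel")
#: CADD is divided by 33 so its ~[0, 50] PHRED scale is commensurate with the
#: four unit-range scores in Euclidean distances.
CADD_SCALE_DIVISOR = 33.0
DEFAULT_SEED = 20211030
DEFAULT_RESTARTS = 25

SEMANTIC_LABELS = ("pathogenic", "uncertain", "benign")
LABEL_TO_COLOR = {"pathogenic": "red", "uncertain": "blue", "benign": "green"}


@dataclasses.dataclass
class ScoreMatrix:
    keys: list[tuple[str, str]]  # (gene, cdna_change)
    X: np.ndarray                # n x 5, SCORE_COLUMNS order
    scaling_mode: str

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_score_matrix(table: CohortTable, scaling_mode: str = "cadd_div33") -> ScoreMatrix:
    """Assemble the n x 5 matrix over complete panels, in table order."""
    if scaling_mode not in ("raw", "cadd_div33", "zscore"):
        raise ValueError(f"unknown scaling mode {scaling_mode!r}")
    rows = table.complete_rows()
    if len(rows) < 3:
        raise ValueError(f"need at least 3 complete score panels, got {len(rows)}")
    X = np.array(
        [
            [r.panel.metalr, r.panel.metasvm, r.panel.cadd_phred, r.panel.revel, r.panel.condel]
            for r in rows
        ],
        dtype=float,
    )
    if scaling_mode == "cadd_div33":
        X[:, 2] /= CADD_SCALE_DIVISOR
    elif scaling_mode == "zscore":
        X = (X - X.mean(0)) / X.std(0, ddof=0)
    return ScoreMatrix(keys=[r.record.key for r in rows], X=X, scaling_mode=scaling_mode)


@dataclasses.dataclass
class ClusterAssignment:
    labels: list[str]               # semantic label per row
    centroids: dict[str, np.ndarray]
    wcss: float
    n_restarts: int
    seed: int
    n_iterations: int

    @property
    def colors(self) -> list[str]:
        return [LABEL_TO_COLOR[l] for l in self.labels]

    def sizes(self) -> dict[str, int]:
        return {lab: self.labels.count(lab) for lab in SEMANTIC_LABELS}


def _seed_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding from a random first centre."""
    centroids = [X[rng.integers(len(X))]]
    for _ in range(1, k):
        d2 = cdist(X, np.asarray(centroids), "sqeuclidean").min(axis=1)
        centroids.append(X[int(d2.argmax())])
    return np.asarray(centroids, dtype=float)


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    n = len(X)
    centroids = _seed_centroids(X, k, rng)
    assign = np.full(n, -1)
    prev_wcss = np.inf
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_assign = d2.argmin(axis=1)
        for c in range(k):  # re-seed an emptied centroid at the farthest point
            if not (new_assign == c).any():
                far = int(d2[np.arange(n), new_assign].argmax())
                centroids[c] = X[far]
                d2 = cdist(X, centroids, "sqeuclidean")
                new_assign = d2.argmin(axis=1)
        wcss = float(d2[np.arange(n), new_assign].sum())
        assert wcss <= prev_wcss + 1e-9, "WCSS increased across a Lloyd iteration"
        prev_wcss = wcss
        if np.array_equal(new_assign, assign):
            return assign, centroids, wcss, it
        assign = new_assign
        for c in range(k):
            members = X[assign == c]
            if len(members):  # a duplicate-heavy input can leave a cluster empty
                centroids[c] = members.mean(axis=0)
    d2 = cdist(X, centroids, "sqeuclidean")
    wcss = float(d2[np.arange(n), assign].sum())
    return assign, centroids, wcss, max_iter


def kmeans(
    X: np.ndarray,
    k: int = 3,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    max_iter: int = 300,
    label_values: Sequence[float] | None = None,
) -> ClusterAssignment:
    """Lloyd's k-means, best of ``n_restarts`` by within-cluster sum of squares.

    ``label_values`` (default: the last matrix column, Condel in both score
    views) orders the clusters into semantic labels by descending mean value
    among members.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < k:
        raise ValueError(f"need an n x d matrix with n >= {k}")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(n_restarts):
        assign, centroids, wcss, iters = _lloyd(X, k, rng, max_iter)
        if best is None or wcss < best[0] - 1e-12:
            best = (wcss, assign, centroids, iters)
    wcss, assign, centroids, iters = best
    values = np.asarray(label_values if label_values is not None else X[:, -1], dtype=float)
    means = []
    for c in range(k):
        members = values[assign == c]
        means.append(members.mean() if len(members) else -np.inf)
    order = np.argsort(means)[::-1]  # descending condel -> pathogenic first
    index_to_label = {int(c): SEMANTIC_LABELS[rank] for rank, c in enumerate(order)}
    labels = [index_to_label[int(a)] for a in assign]
    return ClusterAssignment(
        labels=labels,
        centroids={index_to_label[int(c)]: centroids[c].copy() for c in range(k)},
        wcss=wcss,
        n_restarts=n_restarts,
        seed=seed,
        n_iterations=iters,
    )


@dataclasses.dataclass
class MdsEmbedding:
    coords: np.ndarray       # n x 2
    eigenvalues: np.ndarray  # all eigenvalues, descending


def classical_mds(
    X: np.ndarray,
    orient_against: tuple[Sequence[float] | None, Sequence[float] | None] | None = None,
) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling to 2-D.

    Double-centres the squared Euclidean distance matrix, B = -1/2 J D^2 J,
    and takes the top two eigenpairs. Eigenvector signs are arbitrary, so
    when ``orient_against`` supplies per-point values (Condel for axis 1,
    REVEL for axis 2) each axis is flipped to correlate negatively with
    them, placing pathogenic variants at the lower left.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 points")
    D2 = cdist(X, X, "sqeuclidean")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[-1] < -1e-6 * max(eigval[0], 1.0):
        import warnings

        warnings.warn("distance matrix is substantially non-Euclidean", stacklevel=2)
    coords = eigvec[:, :2] * np.sqrt(np.clip(eigval[:2], 0.0, None))
    coords = coords - coords.mean(axis=0)
    if orient_against is not None:
        for axis, values in enumerate(orient_against[:2]):
            if values is None:
                continue
            v = np.asarray(values, dtype=float)
            if coords[:, axis].std() == 0 or v.std() == 0:
                continue
            if np.corrcoef(coords[:, axis], v)[0, 1] > 0:
                coords[:, axis] = -coords[:, axis]
    return MdsEmbedding(coords=coords, eigenvalues=eigval)


def mds_view_cluster(
    table: CohortTable,
    scaling_mode: str = "cadd_div33",
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    cluster_space: str = "scores",
) -> tuple[ClusterAssignment, MdsEmbedding, ScoreMatrix]:
    """Five-score view: k-means plus the classical MDS embedding.

    ``cluster_space='scores'`` clusters the raw (scaled) score matrix;
    ``'mds'`` clusters the 2-D embedding instead. Either way labels follow
    the members' mean Condel.
    """
    matrix = build_score_matrix(table, scaling_mode)
    condel = matrix.X[:, -1]
    revel = matrix.X[:, -2]
    embedding = classical_mds(matrix.X, orient_against=(condel, revel))
    if cluster_space == "scores":
        assignment = kmeans(matrix.X, 3, n_restarts, seed, label_values=condel)
    elif cluster_space == "mds":
        assignment = kmeans(embedding.coords, 3, n_restarts, seed, label_values=condel)
    else:
        raise ValueError(f"unknown cluster space {cluster_space!r}")
    return assignment, embedding, matrix


def scatter_view_cluster(
    table: CohortTable,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
) -> tuple[ClusterAssignment, list[tuple[str, str]]]:
    """Two-score REVEL x Condel view over rows where both are present."""
    rows = [
        r for r in table if r.panel.revel is not None and r.panel.condel is not None
    ]
    if len(rows) < 3:
        raise ValueError("need at least 3 rows with both REVEL and Condel")
    X = np.array([[r.panel.revel, r.panel.condel] for r in rows], dtype=float)
    assignment = kmeans(X, 3, n_restarts, seed, label_values=X[:, 1])
    return assignment, [r.record.key for r in rows]


def concordance(
    predicted: Mapping[tuple, str] | Sequence[str],
    published: Mapping[tuple, str] | Sequence[str],
) -> dict:
    """Adjusted Rand index and confusion counts between two labelings.

    Accepts either key->label mappings (keys must agree; a mismatch raises
    with the symmetric difference) or two aligned label sequences. Predicted
    semantic labels are compared on the color scale (red/blue/green).
    """
    if isinstance(predicted, Mapping) != isinstance(published, Mapping):
        raise TypeError("pass two mappings or two aligned sequences")
    if isinstance(predicted, Mapping):
        diff = set(predicted) ^ set(published)
        if diff:
            raise KeyError(f"variant keys differ between labelings: {sorted(diff)}")
        keys = sorted(predicted)
        pred = [predicted[k] for k in keys]
        pub = [published[k] for k in keys]
    else:
        if len(predicted) != len(published):
            raise ValueError("label sequences differ in length")
        pred, pub = list(predicted), list(published)
    pred = [LABEL_TO_COLOR.get(l, l) for l in pred]
    pub = [LABEL_TO_COLOR.get(l, l) for l in pub]
    ari = float(adjusted_rand_score(pub, pred))
    confusion: dict[str, int] = {}
    for a, b in zip(pred, pub):
        confusion[f"{a}|{b}"] = confusion.get(f"{a}|{b}", 0) + 1
    assert sum(confusion.values()) == len(pred)
    return {"ari": ari, "n": len(pred), "confusion": confusion}
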