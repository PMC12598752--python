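"""Protein-complex detection from predicted interaction scores.

The scored edge list becomes a weighted adjacency matrix; two complementary
smoothed views of that graph are computed — a Markov-cluster flow matrix
(alternating expansion and inflation of the column-stochastic transition
matrix, three fixed iterations) and a topological overlap matrix
(w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) on the elementwise
2.5th power of the adjacency).  The two are blended in fixed proportions
(0.3/0.7 and 0.1/0.9), each blend is clustered by Ward agglomeration on
cosine row distances with a dynamic tree cut, the two clusterings are
unioned into one overlapping cluster set, oversized clusters are re-split,
and heavily overlapping clusters (overlap score strictly above 0.25) are
merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "Adjacency",
    "ClusterSet",
    "build_adjacency",
    "mcl",
    "tom",
    "hybrid_clusters",
    "enforce_max_size",
    "merge_overlapping",
    "ComplexDetector",
    "write_clusters_gmt",
    "write_clusters_long",
]

DEFAULT_WEIGHTINGS = ((0.3, 0.7), (0.1, 0.9))


@dataclass
class Adjacency:
    """Symmetric weighted graph over an ordered protein list."""

    node_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.node_ids)
        if self.W.shape != (n, n):
            raise ValueError("weight matrix shape does not match node count")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero")
        if self.W.min() < 0 or self.W.max() > 1:
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class ClusterSet:
    """Possibly overlapping predicted complexes with provenance tags."""

    clusters: list[frozenset[str]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.clusters = [frozenset(c) for c in self.clusters]
        if not self.provenance:
            self.provenance = [""] * len(self.clusters)
        if len(self.provenance) != len(self.clusters):
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def build_adjacency(
    edges: pd.DataFrame, score_floor: float = 0.5
) -> Adjacency:
    """Scored edge list -> pruned symmetric adjacency.

    Edges with score strictly above ``score_floor`` are kept (duplicate
    a-b / b-a entries collapse to their maximum, with a warning); nodes left
    without any neighbor are removed.  An empty graph is an error.
    """
    req = {"protein_a", "protein_b", "score"}
    if not req <= set(edges.columns):
        raise ValueError(f"edge list must have columns {sorted(req)}")
    s = edges["score"].to_numpy(dtype=float)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    best: dict[tuple[str, str], float] = {}
    dup = False
    for a, b, score in zip(edges["protein_a"], edges["protein_b"], s):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key in best:
            dup = True
            best[key] = max(best[key], score)
        else:
            best[key] = score
    if dup:
        warnings.warn("duplicate edges collapsed to their maximum score")
    kept = {k: v for k, v in best.items() if v > score_floor}
    if not kept:
        raise ValueError("no edges above the score floor; graph is empty")
    nodes = sorted({p for pair in kept for p in pair})
    index = {p: i for i, p in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for (a, b), v in kept.items():
        W[index[a], index[b]] = W[index[b], index[a]] = v
    return Adjacency(nodes, W)


def _column_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("zero column encountered during MCL normalization")
    return M / sums


def mcl(
    A: Adjacency | np.ndarray,
    expansion: int = 2,
    inflation: float = 2.0,
    iterations: int = 3,
    self_loops: bool = True,
) -> np.ndarray:
    """Markov-cluster flow matrix after a fixed number of iterations.

    Self-loops are added once up front (disable with ``self_loops=False``);
    each iteration column-normalizes, raises to the matrix power
    ``expansion``, applies elementwise ``inflation``, and renormalizes.
    There is no convergence test — exactly ``iterations`` rounds run.
    """
    M = A.W.copy() if isinstance(A, Adjacency) else np.array(A, dtype=float)
    if self_loops:
        M = M + np.eye(M.shape[0])
    for _ in range(iterations):
        M = _column_normalize(M)
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M = _column_normalize(M)
    return M


def tom(A: Adjacency | np.ndarray, power: float = 2.5) -> np.ndarray:
    """Topological overlap matrix on the elementwise-powered adjacency.

    With a = A**power (soft thresholding, keeps weights in [0, 1]),
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu:

        w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    The diagonal is set to 1 (self-overlap convention).
    """
    W = A.W if isinstance(A, Adjacency) else np.asarray(A, dtype=float)
    a = np.power(W, power)
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    out = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# dynamic tree cut

def _gap_threshold(heights: np.ndarray) -> float:
    """Cut height at the midpoint of the largest gap between merge heights.

    Only gaps between successive merges are considered (the gap down to the
    zero baseline would cut everything into singletons on unstructured
    data); a dendrogram with a single merge is cut just below it.
    """
    hs = np.sort(heights)
    if len(hs) == 1:
        return float(hs[0] / 2.0)
    gaps = np.diff(hs)
    i = int(np.argmax(gaps))
    return float((hs[i] + hs[i + 1]) / 2.0)


def _split_labels(
    D: np.ndarray, gap_guard: float = 0.0, ref_height: float | None = None
) -> tuple[np.ndarray | None, float]:
    """One round of Ward + largest-gap cut on a condensed-able distance matrix.

    Returns (labels, dendrogram height); labels are None when the dendrogram
    shows no usable gap structure: degenerate (near-zero) heights, a height
    negligible next to ``ref_height`` (the enclosing dendrogram, so tight
    blocks are not shredded during recursion), or — when ``gap_guard`` is
    positive — a dominant gap smaller than that fraction of the tallest
    merge.  The primary cut runs unguarded.
    """
    n = D.shape[0]
    if n < 2:
        return None, 0.0
    Z = linkage(squareform(D, checks=False), method="ward")
    heights = Z[:, 2]
    hmax = float(heights.max())
    if hmax <= 1e-12:
        return None, hmax
    if ref_height is not None and hmax < 0.05 * ref_height:
        return None, hmax
    t = _gap_threshold(heights)
    if gap_guard > 0:
        hs = np.sort(heights)
        if len(hs) < 2 or float(np.diff(hs).max()) < gap_guard * hmax:
            return None, hmax
    labels = fcluster(Z, t=t, criterion="distance")
    if len(np.unique(labels)) < 2:
        return None, hmax
    return labels, hmax


def cut_tree_dynamic(
    D: np.ndarray, min_cluster: int = 3, deep_split: int = 3
) -> list[np.ndarray]:
    """Adaptive dendrogram cut with hybrid small-cluster reassignment.

    A Ward dendrogram of the cosine distance matrix is cut at the midpoint
    of the largest merge-height gap; clusters large enough to carry
    substructure are re-cut recursively up to ``deep_split`` extra levels,
    each recursion requiring its own dominant height gap (at least 30% of
    the local dendrogram height) so homogeneous groups are not shredded.
    Finally, clusters below ``min_cluster`` members are reassigned to the
    retained cluster with the smallest mean distance (the hybrid stage).

    Returns a list of index arrays into the rows of ``D``.
    """
    n = D.shape[0]
    if n < min_cluster:
        raise ValueError(f"need at least {min_cluster} proteins, have {n}")

    def recurse(idx: np.ndarray, depth: int, ref: float) -> list[np.ndarray]:
        if len(idx) < 2 * min_cluster or depth > deep_split:
            return [idx]
        labels, _ = _split_labels(
            D[np.ix_(idx, idx)], gap_guard=0.3, ref_height=ref
        )
        if labels is None:
            return [idx]
        out = []
        for lab in np.unique(labels):
            sub = idx[labels == lab]
            if depth < deep_split and len(sub) < len(idx):
                out.extend(recurse(sub, depth + 1, ref))
            else:
                out.append(sub)
        return out

    top, top_height = _split_labels(D)
    if top is None:
        groups = [np.arange(n)]
    else:
        groups = []
        for lab in np.unique(top):
            groups.extend(recurse(np.flatnonzero(top == lab), 1, top_height))

    big = [g for g in groups if len(g) >= min_cluster]
    small = [g for g in groups if len(g) < min_cluster]
    if not big:
        return [np.arange(n)]
    for g in small:
        # hybrid stage: attach each undersized fragment to its nearest cluster
        mean_d = [D[np.ix_(g, b)].mean() for b in big]
        target = int(np.argmin(mean_d))
        big[target] = np.concatenate([big[target], g])
    return [np.sort(g) for g in big]


def _cosine_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    U = M / safe[:, None]
    D = 1.0 - U @ U.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def hybrid_clusters(
    A_: np.ndarray,
    I_: np.ndarray,
    node_ids: list[str],
    weightings=DEFAULT_WEIGHTINGS,
    min_cluster: int = 3,
    deep_split: int = 3,
) -> ClusterSet:
    """Cluster each blended importance matrix; union the results.

    For every (alpha, beta) weighting, M = alpha*A_ + beta*I_ is row-wise
    cosine-compared, Ward-linked, and dynamically cut.  The clusterings from
    all weightings are pooled into one overlapping :class:`ClusterSet`
    tagged with the weighting that produced each cluster.
    """
    if A_.shape != I_.shape:
        raise ValueError("matrices must share a shape")
    for alpha, beta in weightings:
        if not np.isclose(alpha + beta, 1.0):
            raise ValueError(f"weighting {(alpha, beta)} does not sum to 1")
    clusters, provenance = [], []
    for alpha, beta in weightings:
        M = alpha * A_ + beta * I_
        D = _cosine_rows(M)
        for idx in cut_tree_dynamic(D, min_cluster=min_cluster, deep_split=deep_split):
            if len(idx) >= min_cluster:
                clusters.append(frozenset(node_ids[i] for i in idx))
                provenance.append(f"w{alpha:g}:{beta:g}")
    return ClusterSet(clusters, provenance)


def enforce_max_size(
    C: ClusterSet,
    matrices: dict[str, np.ndarray],
    node_ids: list[str],
    limit: int = 100,
    min_cluster: int = 3,
    deep_split: int = 3,
    max_depth: int = 10,
) -> ClusterSet:
    """Recursively re-split clusters reaching ``limit`` members.

    Each oversized cluster is re-clustered on the submatrix of the blended
    importance matrix that produced it (``matrices`` maps provenance tag to
    matrix); recursion past ``max_depth`` levels raises.
    """
    index = {p: i for i, p in enumerate(node_ids)}

    def split(members: frozenset[str], tag: str, depth: int):
        if len(members) < limit:
            return [(members, tag)]
        if depth >= max_depth:
            raise RuntimeError(
                f"cluster of size {len(members)} could not be split below "
                f"{limit} within {max_depth} levels"
            )
        M = matrices.get(tag)
        if M is None:
            M = next(iter(matrices.values()))
        idx = np.array(sorted(index[p] for p in members))
        D = _cosine_rows(M[np.ix_(idx, idx)])
        parts = cut_tree_dynamic(D, min_cluster=min_cluster, deep_split=deep_split)
        if len(parts) < 2:
            raise RuntimeError(
                f"cluster of size {len(members)} is unsplittable"
            )
        out = []
        for part in parts:
            sub = frozenset(node_ids[idx[i]] for i in part)
            out.extend(split(sub, tag, depth + 1))
        return out

    clusters, provenance = [], []
    for members, tag in zip(C.clusters, C.provenance):
        for sub, subtag in split(members, tag, 0):
            if len(sub) >= min_cluster:
                clusters.append(sub)
                provenance.append(subtag)
    return ClusterSet(clusters, provenance)


def merge_overlapping(C: ClusterSet, threshold: float = 0.25) -> ClusterSet:
    """Iteratively merge the most-overlapping cluster pair.

    The merge score is |X ∩ Y|² / (|X|·|Y|); the highest-scoring pair with a
    score strictly above ``threshold`` is replaced by its union, repeating
    until no pair qualifies.  Exact duplicates (score 1) always merge.  Ties
    break lexicographically on the sorted member tuples, making the result
    order-independent.
    """
    sets = [frozenset(c) for c in C.clusters]
    tags = list(C.provenance)
    while True:
        best = None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = len(sets[i] & sets[j])
                if inter == 0:
                    continue
                score = inter**2 / (len(sets[i]) * len(sets[j]))
                if score <= threshold:
                    continue
                key = (-score, tuple(sorted(sets[i])), tuple(sorted(sets[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            return ClusterSet(sets, tags)
        _, i, j = best
        merged = sets[i] | sets[j]
        tag = tags[i] if tags[i] == tags[j] else f"{tags[i]}+{tags[j]}"
        sets = [s for k, s in enumerate(sets) if k not in (i, j)] + [merged]
        tags = [t for k, t in enumerate(tags) if k not in (i, j)] + [tag]


class ComplexDetector(BaseEstimator, ClusterMixin):
    """End-to-end complex detection estimator over a scored edge list.

    ``fit`` accepts a DataFrame with columns protein_a / protein_b / score
    and exposes ``clusters_`` (a :class:`ClusterSet`) plus the intermediate
    flow (``mcl_``) and topological overlap (``tom_``) matrices.
    """

    def __init__(
        self,
        score_floor: float = 0.5,
        expansion: int = 2,
        inflation: float = 2.0,
        iterations: int = 3,
        tom_power: float = 2.5,
        weightings=DEFAULT_WEIGHTINGS,
        min_cluster: int = 3,
        deep_split: int = 3,
        max_size: int = 100,
        merge_threshold: float = 0.25,
    ):
        self.score_floor = score_floor
        self.expansion = expansion
        self.inflation = inflation
        self.iterations = iterations
        self.tom_power = tom_power
        self.weightings = weightings
        self.min_cluster = min_cluster
        self.deep_split = deep_split
        self.max_size = max_size
        self.merge_threshold = merge_threshold

    def fit(self, X: pd.DataFrame, y=None):
        A = build_adjacency(X, score_floor=self.score_floor)
        self.adjacency_ = A
        self.mcl_ = mcl(
            A,
            expansion=self.expansion,
            inflation=self.inflation,
            iterations=self.iterations,
        )
        self.tom_ = tom(A, power=self.tom_power)
        raw = hybrid_clusters(
            self.mcl_,
            self.tom_,
            A.node_ids,
            weightings=self.weightings,
            min_cluster=self.min_cluster,
            deep_split=self.deep_split,
        )
        matrices = {
            f"w{a:g}:{b:g}": a * self.mcl_ + b * self.tom_
            for a, b in self.weightings
        }
        capped = enforce_max_size(
            raw,
            matrices,
            A.node_ids,
            limit=self.max_size,
            min_cluster=self.min_cluster,
            deep_split=self.deep_split,
        )
        self.clusters_ = merge_overlapping(capped, threshold=self.merge_threshold)
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.clusters_


def write_clusters_gmt(C: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        for i, members in enumerate(C.clusters):
            fh.write("\t".join([f"cluster_{i + 1}", *sorted(members)]) + "\n")


def write_clusters_long(C: ClusterSet, path) -> None:
    rows = [
        (p, f"cluster_{i + 1}")
        for i, members in enumerate(C.clusters)
        for p in sorted(members)
    ]
    pd.DataFrame(rows, columns=["protein", "cluster_id"]).to_csv(
        path, sep="\t", index=False
    )
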