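"""Transductive graph construction over reference and query cells.

The two datasets are embedded jointly by a singular value decomposition of
the cross-dataset cell-cell matrix K = FR FQ^T (both blocks z-scored over
the same selected genes) — the SVD solves the canonical-correlation
objective because singular vectors are the unit-norm maximisers of the
bilinear form. Query components are then warped onto the reference
components with dynamic time warping so the two embeddings share a scale,
and edges are mutual nearest neighbours: reference-query links carry label
information across datasets, query-query links propagate it within the
query set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class CCAEmbedding:
    """Joint low-dimensional coordinates for reference and query cells."""

    ref_coords: np.ndarray  # r x k left singular vectors
    query_coords: np.ndarray  # q x k right singular vectors
    singular_values: np.ndarray  # length-k, non-increasing
    k: int


@dataclass(frozen=True)
class EdgeList:
    """Undirected graph in sparse edge-index form.

    Nodes 0..r-1 are reference cells, r..r+q-1 query cells. Every edge is
    stored in both directions; no self-loops, no duplicates.
    """

    edges: np.ndarray  # (E, 2) int array
    n_nodes: int

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        if edges.size and (edges.min() < 0 or edges.max() >= self.n_nodes):
            raise ValueError("edge indices out of range")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def to_sparse(self) -> sparse.csr_matrix:
        data = np.ones(self.n_edges)
        return sparse.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )

    def write_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t")

    def write_mtx(self, path: str | Path) -> None:
        spio.mmwrite(path, self.to_sparse())


def cca_embed(FR_std: np.ndarray, FQ_std: np.ndarray, k: int = 5) -> CCAEmbedding:
    """Truncated SVD of the r x q cross-dataset matrix K = FR FQ^T.

    Each component's sign is fixed so that the largest-magnitude entry of
    its left singular vector is positive.
    """
    FR_std = np.asarray(FR_std, dtype=float)
    FQ_std = np.asarray(FQ_std, dtype=float)
    if not (np.all(np.isfinite(FR_std)) and np.all(np.isfinite(FQ_std))):
        raise ValueError("inputs must be finite")
    r, q = FR_std.shape[0], FQ_std.shape[0]
    if k > min(r, q):
        raise ValueError(f"k={k} exceeds min(r, q)={min(r, q)}")
    K = FR_std @ FQ_std.T
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    for i in range(k):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    return CCAEmbedding(ref_coords=U, query_coords=V, singular_values=s, k=k)


def _dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Optimal monotone alignment path between sequences a and b.

    Classic dynamic programming with |a_i - b_j| local cost and
    diagonal/up/left steps; ties prefer the diagonal so that identical
    sequences align along the identity.
    """
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = cost[i - 1]
        prev = D[i - 1]
        cur = D[i]
        cur[0] = np.inf
        for j in range(1, m + 1):
            cur[j] = row[j - 1] + min(prev[j - 1], prev[j], cur[j - 1])
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        moves = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
        best = int(np.argmin(moves))  # argmin takes the first -> diagonal on ties
        if best == 0:
            i, j = i - 1, j - 1
        elif best == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return path


def dtw_align(ref_component: np.ndarray, query_component: np.ndarray) -> np.ndarray:
    """Warp a query embedding component onto the reference component.

    Both sequences are sorted and mean-centred for the alignment cost, so
    the warp matches shapes rather than absolute locations (a pure location
    shift between the two distributions is removed exactly). Each sorted
    query value is replaced by the mean of the (uncentred) reference values
    its path step aligns to; the result is mapped back through the query
    sort order, giving a length-q vector whose empirical distribution
    follows the reference component's.
    """
    ref = np.asarray(ref_component, dtype=float)
    qry = np.asarray(query_component, dtype=float)
    if ref.size == 0 or qry.size == 0:
        raise ValueError("components must be non-empty")
    ref_sorted = np.sort(ref, kind="stable")
    order = np.argsort(qry, kind="stable")
    qry_sorted = qry[order]

    path = _dtw_path(qry_sorted - qry_sorted.mean(), ref_sorted - ref_sorted.mean())
    sums = np.zeros(qry.size)
    hits = np.zeros(qry.size)
    for qi, rj in path:
        sums[qi] += ref_sorted[rj]
        hits[qi] += 1
    aligned_sorted = sums / hits
    out = np.empty_like(aligned_sorted)
    out[order] = aligned_sorted
    return out


def mutual_nn_edges(
    A_coords: np.ndarray, B_coords: np.ndarray, k_nn: int = 5
) -> list[tuple[int, int]]:
    """Mutual k-nearest-neighbour pairs between two point sets.

    A pair (a, b) is returned iff b is among the k_nn Euclidean-nearest
    points of B to a AND a is among the k_nn nearest points of A to b.
    When both arguments are the same point set, self-matches are excluded
    before ranking. Distance ties break toward the lower index.
    """
    same = A_coords is B_coords
    A = np.atleast_2d(np.asarray(A_coords, dtype=float))
    B = A if same else np.atleast_2d(np.asarray(B_coords, dtype=float))
    nA, nB = A.shape[0], B.shape[0]
    if k_nn < 1:
        raise ValueError("k_nn must be >= 1")
    limit = min(nA, nB) - 1
    if k_nn > limit:
        raise ValueError(f"k_nn={k_nn} too large for point sets of size {nA}, {nB}")

    d = cdist(A, B)
    if same:
        np.fill_diagonal(d, np.inf)
    # stable argsort -> ties broken by lower index
    a_to_b = np.argsort(d, axis=1, kind="stable")[:, :k_nn]
    b_to_a = np.argsort(d.T, axis=1, kind="stable")[:, :k_nn]

    b_near_a = np.zeros((nA, nB), dtype=bool)
    b_near_a[np.arange(nA)[:, None], a_to_b] = True
    a_near_b = np.zeros((nB, nA), dtype=bool)
    a_near_b[np.arange(nB)[:, None], b_to_a] = True

    mutual = b_near_a & a_near_b.T
    pairs = np.argwhere(mutual)
    return [tuple(p) for p in pairs]


def build_transductive_graph(
    ref_query_pairs, query_query_pairs, r: int, q: int
) -> EdgeList:
    """Assemble reference-query and query-query pairs into one edge list.

    Reference-query pair (i, j) becomes edge (i, r + j); query-query pair
    (i, j) becomes (r + i, r + j). Reverse edges are added, duplicates and
    self-loops removed.
    """
    rows = []
    for i, j in ref_query_pairs:
        if not (0 <= i < r and 0 <= j < q):
            raise ValueError(f"reference-query pair ({i}, {j}) out of range")
        rows.append((i, r + j))
    for i, j in query_query_pairs:
        if not (0 <= i < q and 0 <= j < q):
            raise ValueError(f"query-query pair ({i}, {j}) out of range")
        rows.append((r + i, r + j))
    if rows:
        fwd = np.asarray(rows, dtype=np.int64)
        both = np.vstack([fwd, fwd[:, ::-1]])
        both = both[both[:, 0] != both[:, 1]]
        edges = np.unique(both, axis=0)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return EdgeList(edges=edges, n_nodes=r + q)


def build_graph(
    FR_std: np.ndarray,
    FQ_std: np.ndarray,
    k: int = 5,
    k_nn: int = 5,
    scale_by_singular_values: bool = False,
) -> EdgeList:
    """Full graph construction: SVD embedding, per-component DTW alignment
    of query onto reference, then mutual-kNN edges (reference-query and
    query-query) in the aligned k-dimensional space."""
    emb = cca_embed(FR_std, FQ_std, k=k)
    ref = emb.ref_coords.copy()
    qry = np.column_stack(
        [
            dtw_align(emb.ref_coords[:, i], emb.query_coords[:, i])
            for i in range(emb.k)
        ]
    )
    if scale_by_singular_values:
        ref = ref * emb.singular_values
        qry = qry * emb.singular_values
    rq = mutual_nn_edges(ref, qry, k_nn=k_nn)
    qq = mutual_nn_edges(qry, qry, k_nn=k_nn)
    return build_transductive_graph(rq, qq, r=ref.shape[0], q=qry.shape[0])
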