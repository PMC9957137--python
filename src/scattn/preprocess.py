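"""I/O, reference/query splitting, gene selection, and normalisations.

Two distinct normalisations are used downstream: a per-gene z-score
(applied separately to the reference and query blocks before the
cross-dataset SVD) and a per-cell row normalisation (applied to the
concatenated matrix that feeds the network).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif

from .simulate import CountMatrix, largest_remainder_counts

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an on-disk dataset is malformed."""


def read_dataset(
    counts_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    orientation: str = "cells",
) -> CountMatrix:
    """Read a dataset written as Matrix Market counts + cell/gene tables.

    ``orientation`` declares which axis forms the .mtx rows ("cells" or
    "genes"); the in-memory matrix is always cells x genes. The cells file
    must have a ``cell_id`` column and may carry a ``label`` column.
    """
    if orientation not in ("cells", "genes"):
        raise ValueError("orientation must be 'cells' or 'genes'")
    counts_path, cells_path, genes_path = map(Path, (counts_path, cells_path, genes_path))
    for p in (counts_path, cells_path, genes_path):
        if not p.exists():
            raise FileNotFoundError(p)

    if counts_path.suffix == ".mtx":
        mat = spio.mmread(counts_path)
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
    else:
        mat = np.loadtxt(counts_path, delimiter="\t")
    if orientation == "genes":
        mat = mat.T
    if np.any(mat != np.round(mat)) or np.any(mat < 0):
        raise FormatError(f"{counts_path}: counts must be non-negative integers")
    mat = mat.astype(np.int64)

    cells = pd.read_csv(cells_path, sep="\t")
    genes = pd.read_csv(genes_path, sep="\t")
    if "cell_id" not in cells.columns:
        raise FormatError(f"{cells_path}: missing 'cell_id' column")
    if "gene_id" not in genes.columns:
        raise FormatError(f"{genes_path}: missing 'gene_id' column")
    if len(cells) != mat.shape[0]:
        raise FormatError(
            f"{cells_path}: {len(cells)} cells but matrix has {mat.shape[0]} rows"
        )
    if len(genes) != mat.shape[1]:
        raise FormatError(
            f"{genes_path}: {len(genes)} genes but matrix has {mat.shape[1]} columns"
        )
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"{cells_path}: duplicate cell_id {dup!r}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{genes_path}: duplicate gene_id {dup!r}")

    labels = cells["label"].to_numpy() if "label" in cells.columns else None
    return CountMatrix(
        counts=mat,
        cell_ids=cells["cell_id"].tolist(),
        gene_ids=genes["gene_id"].tolist(),
        labels=labels,
    )


@dataclass(frozen=True)
class ReferenceQuerySplit:
    """Disjoint reference/query cell index sets from a stratified split."""

    reference_indices: np.ndarray
    query_indices: np.ndarray
    p: float

    @property
    def n_reference(self) -> int:
        return self.reference_indices.size

    @property
    def n_query(self) -> int:
        return self.query_indices.size


def _apportion_within_labels(
    label_sizes: np.ndarray, fraction: float, minimum_leftover: int
) -> np.ndarray:
    """Apportion round(fraction * total) cells over labels, largest remainder.

    Each label keeps at least ``minimum_leftover`` cells out of the chosen
    set's complement, and each label contributes at least one cell when its
    quota would round to zero but the fraction is positive.
    """
    total = int(label_sizes.sum())
    target = int(np.floor(fraction * total + 0.5))
    quotas = fraction * label_sizes
    take = np.floor(quotas).astype(int)
    take = np.minimum(take, label_sizes - minimum_leftover)
    remainders = quotas - take
    deficit = target - int(take.sum())
    order = np.argsort(-remainders, kind="stable")
    while deficit > 0:
        progressed = False
        for idx in order:
            if deficit <= 0:
                break
            if label_sizes[idx] - minimum_leftover - take[idx] > 0:
                take[idx] += 1
                deficit -= 1
                progressed = True
        if not progressed:
            break
    return take


def split_reference_query(
    data: CountMatrix, p: float = 0.75, seed: int = 0
) -> ReferenceQuerySplit:
    """Stratified split of labelled cells into reference (fraction p) and query.

    The reference total is round(p * n_cells) exactly, apportioned over
    labels by largest remainder so that each label's reference share is
    within one cell of p times its size; every label keeps at least one
    query cell.
    """
    if data.labels is None:
        raise ValueError("split_reference_query requires per-cell labels")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    labels = np.asarray(data.labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = uniq[counts < 2][0]
        raise ValueError(f"label {small!r} has fewer than 2 cells")

    take = _apportion_within_labels(counts, p, minimum_leftover=1)
    rng = np.random.default_rng(seed)
    ref_parts, query_parts = [], []
    for lab, n_ref in zip(uniq, take):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        ref_parts.append(idx[:n_ref])
        query_parts.append(idx[n_ref:])
    reference = np.sort(np.concatenate(ref_parts))
    query = np.sort(np.concatenate(query_parts))
    return ReferenceQuerySplit(reference_indices=reference, query_indices=query, p=p)


@dataclass(frozen=True)
class GeneSelection:
    """Ranked ANOVA gene selection with Bonferroni-adjusted p-values."""

    selected_indices: np.ndarray
    f_statistics: np.ndarray
    p_values: np.ndarray
    adjusted_p_values: np.ndarray
    m: int


class ANOVAGeneSelector(SelectorMixin, BaseEstimator):
    """Select the most label-discriminative genes by one-way ANOVA.

    For each gene an F statistic over label groups is computed on the
    reference cells; p-values get a Bonferroni adjustment (p x number of
    genes, capped at 1). Genes are ranked by ascending adjusted p, ties by
    descending F then by gene index, and the top ``n_genes`` kept.
    Zero-variance genes receive p = 1 and rank last.

    Parameters
    ----------
    n_genes : int, default=2000
        Number of genes to keep (all genes when fewer are available).
    log1p : bool, default=False
        Apply log1p to counts before the ANOVA.
    """

    def __init__(self, n_genes: int = 2000, log1p: bool = False):
        self.n_genes = n_genes
        self.log1p = log1p

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D matrix")
        if y.shape[0] != X.shape[0]:
            raise ValueError("y must provide one label per cell")
        uniq, counts = np.unique(y, return_counts=True)
        if uniq.size < 2:
            raise ValueError("ANOVA selection needs at least 2 label groups")
        if np.any(counts < 2):
            raise ValueError("every label group needs at least 2 cells")
        if self.log1p:
            X = np.log1p(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant features warn in f_classif
            f_stat, p_val = f_classif(X, y)
        f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.inf)
        p_val = np.nan_to_num(p_val, nan=1.0)
        constant = X.var(axis=0) < 1e-24
        f_stat[constant] = 0.0
        p_val[constant] = 1.0

        g = X.shape[1]
        adjusted = np.minimum(1.0, p_val * g)
        order = np.lexsort((np.arange(g), -f_stat, adjusted))
        m_eff = min(self.n_genes, g)

        self.n_features_in_ = g
        self.f_statistics_ = f_stat
        self.p_values_ = p_val
        self.adjusted_p_values_ = adjusted
        self.ranking_ = order
        self.selected_indices_ = order[:m_eff]
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_indices_] = True
        return mask

    def selection(self) -> GeneSelection:
        return GeneSelection(
            selected_indices=self.selected_indices_.copy(),
            f_statistics=self.f_statistics_.copy(),
            p_values=self.p_values_.copy(),
            adjusted_p_values=self.adjusted_p_values_.copy(),
            m=self.n_genes,
        )


def select_genes_anova(reference: CountMatrix, m: int = 2000) -> GeneSelection:
    """Functional wrapper over :class:`ANOVAGeneSelector` on a CountMatrix."""
    if reference.labels is None:
        raise ValueError("gene selection requires reference labels")
    sel = ANOVAGeneSelector(n_genes=m).fit(reference.counts, reference.labels)
    return sel.selection()


def standardize_genes(F: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-gene z-score: subtract the gene mean, divide by the gene
    standard deviation (ddof=1). Genes with near-zero spread map to zeros."""
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise ValueError("cannot standardize an empty matrix")
    mu = F.mean(axis=0)
    sd = F.std(axis=0, ddof=1) if F.shape[0] > 1 else np.zeros(F.shape[1])
    out = F - mu
    ok = sd > eps
    out[:, ok] /= sd[ok]
    out[:, ~ok] = 0.0
    return out


def feature_normalize(F: np.ndarray) -> np.ndarray:
    """Row normalisation: divide each cell's features by the cell total.

    Equivalent to premultiplying by the diagonal matrix of inverse per-cell
    sums; all-zero rows are left at zero.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("feature_normalize expects non-negative entries")
    totals = F.sum(axis=1)
    out = F.copy()
    nz = totals > 0
    out[nz] /= totals[nz, None]
    return out


@dataclass(frozen=True)
class NodeSplit:
    """Train/validation/test node indices (reference block) plus the
    prediction set (all query nodes), in concatenated-graph coordinates
    where reference nodes come first."""

    train_indices: np.ndarray
    val_indices: np.ndarray
    test_indices: np.ndarray
    prediction_indices: np.ndarray


def make_node_splits(
    split: ReferenceQuerySplit,
    labels: np.ndarray,
    seed: int = 0,
    val_fraction: float = 0.1,
    test_fraction: float = 0.1,
) -> NodeSplit:
    """Stratified 80/10/10 split of reference nodes; prediction = query.

    Indices are in graph-node coordinates: reference nodes occupy
    0..r-1 (in ``split.reference_indices`` order) and query nodes
    r..r+q-1. ``labels`` is the per-cell label vector of the full dataset.
    Validation and test totals are round(fraction * r) exactly, apportioned
    over labels by largest remainder. Labels too small to reach all three
    partitions go entirely to train with a warning.
    """
    labels = np.asarray(labels)
    ref_labels = labels[split.reference_indices]
    r = ref_labels.size
    q = split.query_indices.size
    uniq, counts = np.unique(ref_labels, return_counts=True)

    rng = np.random.default_rng(seed)
    tiny = counts < 3
    if np.any(tiny):
        logger.warning(
            "labels %s have fewer than 3 reference cells; assigned to train only",
            list(uniq[tiny]),
        )
    usable = counts.copy()
    usable[tiny] = 0

    n_val = _apportion_totals(usable, val_fraction)
    n_test = _apportion_totals(usable, test_fraction, reserve=n_val)

    train_parts, val_parts, test_parts = [], [], []
    for i, lab in enumerate(uniq):
        idx = rng.permutation(np.flatnonzero(ref_labels == lab))
        v, t = n_val[i], n_test[i]
        val_parts.append(idx[:v])
        test_parts.append(idx[v : v + t])
        train_parts.append(idx[v + t :])
    return NodeSplit(
        train_indices=np.sort(np.concatenate(train_parts)),
        val_indices=np.sort(np.concatenate(val_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        prediction_indices=np.arange(r, r + q),
    )


def _apportion_totals(
    usable: np.ndarray, fraction: float, reserve: np.ndarray | None = None
) -> np.ndarray:
    """Largest-remainder apportionment of round(fraction * total usable)
    cells over labels, leaving at least one train cell per usable label
    (beyond any already-reserved cells)."""
    total = int(usable.sum())
    target = int(np.floor(fraction * total + 0.5))
    if reserve is None:
        reserve = np.zeros_like(usable)
    room = np.maximum(usable - reserve - 1, 0)
    quotas = fraction * usable
    take = np.minimum(np.floor(quotas).astype(int), room)
    remainders = quotas - take
    deficit = target - int(take.sum())
    order = np.argsort(-remainders, kind="stable")
    while deficit > 0:
        progressed = False
        for idx in order:
            if deficit <= 0:
                break
            if room[idx] - take[idx] > 0:
                take[idx] += 1
                deficit -= 1
                progressed = True
        if not progressed:
            break
    return take
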