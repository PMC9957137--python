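"""Splat-style synthetic scRNA-seq count simulation.

Generates sparse cell x gene count matrices with known cell-type labels so
that the whole annotation pipeline can be exercised without external data.
The generative hierarchy mirrors the splat model: gamma-distributed baseline
gene means, log-normally distributed differential-expression multipliers per
cell type, log-normal library sizes, Poisson sampling, and an independent
logistic dropout whose midpoint is calibrated by bisection to hit a target
zero fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

#: Sentinel dropout midpoint meaning "no dropout applied".
NO_DROPOUT = -np.inf


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the splat-style count simulator.

    Parameters
    ----------
    n_cells, n_genes
        Matrix dimensions (cells are rows).
    group_probs
        Cell-type proportions; must sum to 1. Group sizes are the
        largest-remainder apportionment of ``n_cells`` over these
        proportions, so printed designs like 5/15/35/45% are exact.
    target_sparsity
        Desired fraction of zero entries after dropout, in [0, 1).
        ``None`` disables dropout entirely.
    de_prob
        Probability that a gene is differentially expressed in a group.
    de_factor_location, de_factor_scale
        Log-normal parameters of DE multipliers (inverted with probability
        0.5 for down-regulation).
    mean_shape, mean_rate
        Gamma parameters (shape, rate) of baseline gene means.
    libsize_location, libsize_scale
        Log-normal parameters of expected per-cell library sizes.
    seed
        RNG seed; equal seeds give bit-identical output.
    """

    n_cells: int = 1000
    n_genes: int = 800
    group_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    target_sparsity: float | None = 0.95
    de_prob: float = 0.5
    de_factor_location: float = 1.0
    de_factor_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_location: float = math.log(2e3)
    libsize_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ConfigurationError("n_cells and n_genes must be positive")
        probs = np.asarray(self.group_probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ConfigurationError("group_probs must be a non-empty vector")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("group_probs must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"group_probs must sum to 1 (got {probs.sum()!r})"
            )
        if self.n_cells < probs.size:
            raise ConfigurationError("need at least one cell per group")
        if self.target_sparsity is not None and not (
            0.0 <= self.target_sparsity < 1.0
        ):
            raise ConfigurationError("target_sparsity must be in [0, 1)")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ConfigurationError("de_prob must be in [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_probs)


@dataclass
class CountMatrix:
    """A cells x genes integer count matrix with identifiers and labels."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length must match the number of rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must match the number of columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n_cells,):
                raise ValueError("labels must provide one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (lazy import)."""
        import anndata as ad

        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.labels is not None:
            adata.obs["label"] = pd.Categorical(self.labels)
        return adata


def largest_remainder_counts(total: int, probs: Sequence[float]) -> np.ndarray:
    """Apportion ``total`` items over ``probs`` by largest remainder.

    Guarantees the result sums exactly to ``total``; remainder ties are
    broken by lower index.
    """
    probs = np.asarray(probs, dtype=float)
    quotas = total * probs
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = quotas - base
        # stable sort descending on remainder, ties -> lower index first
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def compute_sparsity(counts: np.ndarray) -> float:
    """Fraction of zero entries in a count matrix."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("cannot compute sparsity of an empty matrix")
    return float(np.count_nonzero(counts == 0) / counts.size)


def _dropout_probability(rates: np.ndarray, midpoint: float) -> np.ndarray:
    """Logistic dropout probability, decreasing in log1p of the Poisson rate.

    Shape is fixed at 1: p_drop = sigmoid(midpoint - log1p(rate)). Larger
    midpoints drop more entries, so realized sparsity is monotone
    non-decreasing in the midpoint.
    """
    if midpoint == NO_DROPOUT:
        return np.zeros_like(rates)
    z = midpoint - np.log1p(rates)
    # numerically stable sigmoid
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def calibrate_dropout(
    config: SimConfig,
    pre_dropout_counts: np.ndarray,
    pre_dropout_means: np.ndarray,
    tol: float = 1e-3,
) -> float:
    """Find the logistic dropout midpoint hitting ``config.target_sparsity``.

    The expected post-dropout zero fraction

        E(x0) = mean( 1[count == 0] + 1[count > 0] * p_drop(rate; x0) )

    is monotone increasing in the midpoint ``x0``, so a bisection converges.
    Returns :data:`NO_DROPOUT` (with a logged warning) when the matrix is
    already at least as sparse as the target.
    """
    target = config.target_sparsity
    if target is None:
        return NO_DROPOUT
    zero_mask = pre_dropout_counts == 0
    base = float(zero_mask.mean())
    if target <= base + 1e-12:
        logger.warning(
            "target sparsity %.3f not above pre-dropout sparsity %.3f; "
            "no dropout applied",
            target,
            base,
        )
        return NO_DROPOUT

    rates = np.asarray(pre_dropout_means, dtype=float)
    nonzero_rates = rates[~zero_mask]
    frac_nonzero = 1.0 - base

    def expected_sparsity(x0: float) -> float:
        return base + frac_nonzero * float(
            _dropout_probability(nonzero_rates, x0).mean()
        )

    log_rates = np.log1p(rates)
    lo = float(log_rates.min()) - 30.0
    hi = float(log_rates.max()) + 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        value = expected_sparsity(mid)
        if abs(value - target) <= tol:
            return mid
        if value < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _group_mean_matrix(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Expected expression proportions, one row per group (groups x genes)."""
    base = rng.gamma(
        shape=config.mean_shape, scale=1.0 / config.mean_rate, size=config.n_genes
    )
    means = np.tile(base, (config.n_groups, 1))
    for g in range(config.n_groups):
        de = rng.random(config.n_genes) < config.de_prob
        factors = rng.lognormal(
            mean=config.de_factor_location,
            sigma=config.de_factor_scale,
            size=config.n_genes,
        )
        down = rng.random(config.n_genes) < 0.5
        factors[down] = 1.0 / factors[down]
        means[g, de] *= factors[de]
    # normalise each group's mean vector to proportions of the library
    return means / means.sum(axis=1, keepdims=True)


def simulate_counts(config: SimConfig) -> CountMatrix:
    """Simulate a labelled scRNA-seq count matrix.

    Group sizes are the deterministic largest-remainder apportionment of
    ``n_cells`` over ``group_probs``; group membership order is shuffled.
    Counts are Poisson draws at rate (library size x group-specific gene
    proportion); dropout then zeroes each entry independently with a
    logistic probability in the log rate, calibrated to the target sparsity.
    """
    rng = np.random.default_rng(config.seed)
    sizes = largest_remainder_counts(config.n_cells, config.group_probs)
    groups = np.repeat(np.arange(config.n_groups), sizes)
    rng.shuffle(groups)

    proportions = _group_mean_matrix(config, rng)
    libsizes = rng.lognormal(
        mean=config.libsize_location, sigma=config.libsize_scale, size=config.n_cells
    )
    rates = libsizes[:, None] * proportions[groups, :]
    counts = rng.poisson(rates)

    if config.target_sparsity is not None:
        midpoint = calibrate_dropout(config, counts, rates)
        if midpoint != NO_DROPOUT:
            p_drop = _dropout_probability(rates, midpoint)
            counts[rng.random(counts.shape) < p_drop] = 0

    width = len(str(config.n_cells))
    gwidth = len(str(config.n_genes))
    cell_ids = [f"Cell{i + 1:0{width}d}" for i in range(config.n_cells)]
    gene_ids = [f"Gene{j + 1:0{gwidth}d}" for j in range(config.n_genes)]
    labels = np.array([f"Group{g + 1}" for g in groups])
    return CountMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, labels=labels)


def write_dataset(
    data: CountMatrix, out_dir: str | Path, orientation: str = "cells"
) -> dict[str, Path]:
    """Write counts to Matrix Market plus ``cells.tsv`` / ``genes.tsv``.

    ``orientation`` selects which axis forms .mtx rows: ``"cells"``
    (default, cells x genes) or ``"genes"`` (genes x cells).
    """
    if orientation not in ("cells", "genes"):
        raise ValueError("orientation must be 'cells' or 'genes'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(data.counts)
    if orientation == "genes":
        mat = mat.T
    paths = {
        "counts": out_dir / "counts.mtx",
        "cells": out_dir / "cells.tsv",
        "genes": out_dir / "genes.tsv",
    }
    spio.mmwrite(paths["counts"], mat, field="integer")
    cells = pd.DataFrame({"cell_id": data.cell_ids})
    if data.labels is not None:
        cells["label"] = data.labels
    cells.to_csv(paths["cells"], sep="\t", index=False)
    pd.DataFrame({"gene_id": data.gene_ids}).to_csv(
        paths["genes"], sep="\t", index=False
    )
    return paths


def high_sparsity_config(**overrides) -> SimConfig:
    """The high-sparsity simulation design (~95% zeros, four equal groups)."""
    base = SimConfig(target_sparsity=0.95)
    return replace(base, **overrides)


def medium_sparsity_config(**overrides) -> SimConfig:
    """The medium-sparsity simulation design (~80% zeros, four equal groups)."""
    base = SimConfig(target_sparsity=0.80)
    return replace(base, **overrides)


def imbalanced_config(**overrides) -> SimConfig:
    """High-sparsity design with imbalanced 5/15/35/45% cell types."""
    base = SimConfig(group_probs=(0.05, 0.15, 0.35, 0.45), target_sparsity=0.95)
    return replace(base, **overrides)
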