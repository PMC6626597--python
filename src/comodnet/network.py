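"""Signed weighted coexpression network construction.

The network is built in three steps: gene-gene Pearson correlation,
soft-threshold signed adjacency a_ij = ((1 + cor_ij)/2)^beta with beta=12
by default, and the topological overlap measure

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   i != j

where L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{j != i} a_ij is the
(intramodular-agnostic) connectivity. The signed adjacency maps strong
negative correlations near zero instead of treating them as strong edges,
so modules group genes that rise and fall together. Gene clustering then
runs on the dissimilarity 1 - TOM.

All matrices are dense; at the few-thousand-gene scale this package
targets, TOM is a single symmetric matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from comodnet.expression import ExpressionMatrix

DEFAULT_BETA = 12


@dataclass
class GeneNetwork:
    """Correlation, adjacency and TOM for one gene set.

    ``correlation``, ``adjacency`` and ``tom`` are symmetric gene x gene
    DataFrames sharing one index; ``connectivity`` is the per-gene sum of
    adjacency to all other genes (diagonal excluded).
    """

    gene_ids: list[str]
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    connectivity: pd.Series
    beta: int = DEFAULT_BETA
    signed: bool = True

    @property
    def tom_dissimilarity(self) -> pd.DataFrame:
        return tom_dissimilarity(self.tom)


def pearson_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation across samples."""
    values = expr.values
    sds = values.std(axis=1)
    if (sds == 0).any():
        bad = [g for g, sd in zip(expr.gene_ids, sds) if sd == 0]
        raise ValueError(f"zero-variance genes (Pearson undefined): {bad[:10]}")
    cor = np.corrcoef(values)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.gene_ids, columns=expr.gene_ids)


def signed_adjacency(correlation, beta: int = DEFAULT_BETA) -> pd.DataFrame | np.ndarray:
    """Soft-threshold signed adjacency ((1 + cor)/2)^beta.

    Monotone nondecreasing in the correlation: cor=-1 -> 0, cor=0 ->
    2^-beta, cor=1 -> 1.
    """
    if beta < 1:
        raise ValueError(f"soft-threshold power beta must be >= 1, got {beta}")
    cor = np.asarray(correlation, dtype=float)
    if np.nanmax(np.abs(cor)) > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    adj = ((1.0 + cor) / 2.0) ** beta
    if isinstance(correlation, pd.DataFrame):
        return pd.DataFrame(adj, index=correlation.index, columns=correlation.columns)
    return adj


def unsigned_adjacency(correlation, beta: int = DEFAULT_BETA):
    """|cor|^beta adjacency; provided for completeness, signed is the default."""
    if beta < 1:
        raise ValueError(f"soft-threshold power beta must be >= 1, got {beta}")
    cor = np.asarray(correlation, dtype=float)
    adj = np.abs(cor) ** beta
    if isinstance(correlation, pd.DataFrame):
        return pd.DataFrame(adj, index=correlation.index, columns=correlation.columns)
    return adj


def _check_adjacency(adj: np.ndarray) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if adj.min() < -1e-12 or adj.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")


def connectivity(adjacency) -> pd.Series | np.ndarray:
    """Per-gene connectivity k_i = sum_{j != i} a_ij."""
    adj = np.asarray(adjacency, dtype=float)
    _check_adjacency(adj)
    k = adj.sum(axis=1) - np.diag(adj)
    if isinstance(adjacency, pd.DataFrame):
        return pd.Series(k, index=adjacency.index, name="connectivity")
    return k


def topological_overlap(adjacency) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    Shared-neighbor sums L and connectivities k exclude the diagonal; the
    TOM diagonal is fixed to 1. The min(k_i, k_j) denominator variant is
    used.
    """
    adj = np.asarray(adjacency, dtype=float)
    _check_adjacency(adj)
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # (a @ a)_ij sums over all u; the u=i and u=j terms vanish because the
    # diagonal of `a` is zero, leaving L_ij = sum_{u != i,j} a_iu a_uj.
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def tom_dissimilarity(tom) -> pd.DataFrame | np.ndarray:
    """1 - TOM, with zero diagonal; the gene clustering distance."""
    arr = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(arr, 0.0)
    if isinstance(tom, pd.DataFrame):
        return pd.DataFrame(arr, index=tom.index, columns=tom.columns)
    return arr


def build_network(
    expr: ExpressionMatrix, beta: int = DEFAULT_BETA, signed: bool = True
) -> GeneNetwork:
    """Run correlation -> adjacency -> TOM and bundle the results."""
    cor = pearson_matrix(expr)
    adj = signed_adjacency(cor, beta) if signed else unsigned_adjacency(cor, beta)
    tom = topological_overlap(adj)
    k = connectivity(adj)
    return GeneNetwork(
        gene_ids=expr.gene_ids,
        correlation=cor,
        adjacency=adj,
        tom=tom,
        connectivity=k,
        beta=beta,
        signed=signed,
    )
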