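"""Module detection: gene dendrogram, adaptive tree cut, eigengenes, merging.

Genes are clustered by average linkage (UPGMA) on topological-overlap
dissimilarity. Modules are branches of that dendrogram found by an
adaptive top-down cut: a merge splits into two candidate modules only when
both sides are large enough and the merge height is separated from the
branches below it by a height gap, and small late-attaching fringes are
left unassigned ("grey"). Each module is summarized by its eigengene
(first right singular vector of the per-gene standardized submatrix) and
modules whose eigengenes are closer than a cut height (default 0.25 on
1 - correlation) are merged iteratively, recomputing eigengenes after
every pass, until no pair remains below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from comodnet.expression import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY = "grey"

# Size-ranked module color sequence; "grey" is reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "tan", "cyan", "purple", "greenyellow", "salmon",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class GeneDendrogram:
    """Average-linkage merge tree over genes (scipy linkage format)."""

    gene_ids: list[str]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ModulePartition:
    """Gene -> module label assignment; unassigned genes carry "grey"."""

    assignment: pd.Series
    min_module_size: int = 30

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype(str)

    @property
    def labels(self) -> list[str]:
        """Non-grey labels, largest module first (ties by first gene id)."""
        sizes = self.module_sizes()
        keys = {
            lab: (-sizes[lab], min(self.members(lab))) for lab in sizes.index
        }
        return sorted(sizes.index, key=keys.__getitem__)

    def module_sizes(self) -> pd.Series:
        counts = self.assignment.value_counts()
        return counts[counts.index != GREY]

    def members(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])

    @property
    def n_modules(self) -> int:
        return int((self.assignment.value_counts().index != GREY).sum())


@dataclass
class EigengeneSet:
    """Module x sample eigengene profiles and variance explained.

    Each eigengene is the unit-norm first right singular vector of the
    module's gene-standardized expression, sign-aligned so it correlates
    positively with the module's mean standardized profile.
    """

    eigengenes: pd.DataFrame
    variance_explained: pd.Series

    @property
    def module_labels(self) -> list[str]:
        return list(self.eigengenes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.eigengenes.columns)


def average_linkage(dissim, gene_ids=None) -> GeneDendrogram:
    """UPGMA tree on a symmetric nonnegative dissimilarity matrix."""
    if isinstance(dissim, pd.DataFrame):
        gene_ids = list(dissim.index) if gene_ids is None else list(gene_ids)
    arr = np.asarray(dissim, dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    if arr.min() < -1e-12:
        raise ValueError("dissimilarity must be nonnegative")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    d = arr.copy()
    np.fill_diagonal(d, 0.0)
    tree = linkage(squareform(d, checks=False), method="average")
    return GeneDendrogram(gene_ids=list(gene_ids), linkage=tree)


def adaptive_cut_height(dendro: GeneDendrogram) -> float:
    """Cut height at the widest gap in the sorted merge-height profile.

    Merges inside a coherent module climb in small increments, while
    joins between modules and late attachments of background genes sit
    near the root, so the sorted heights show a wide quiet band between
    the module tops and the inter-module region. The cut goes through the
    middle of the widest such band in the upper half of the profile
    (below the median lie the dense intra-branch merges of tight
    clusters, whose spacing is uninformative).
    """
    heights = np.sort(dendro.heights)
    if len(heights) == 1:
        return float(heights[0]) / 2.0
    med = float(np.median(heights))
    gaps = np.diff(heights)
    upper = heights[1:] > med
    if not upper.any():
        return float(heights[-1]) / 2.0
    candidates = np.flatnonzero(upper)
    best = candidates[np.argmax(gaps[candidates])]
    return float(heights[best] + heights[best + 1]) / 2.0


def dynamic_tree_cut(
    dendro: GeneDendrogram,
    dissim=None,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> ModulePartition:
    """Adaptive branch cut of the gene dendrogram into modules.

    The dendrogram is cut at :func:`adaptive_cut_height` (or at an
    explicit ``cut_height``); every branch entirely below the cut is a
    candidate module and is kept when it holds at least
    ``min_module_size`` leaves. Genes in smaller branches — isolated
    background genes and fringes that only attach above the cut — stay
    grey.

    ``dissim`` is accepted for signature compatibility with callers that
    hold it; this cut variant uses only the tree shape.
    """
    del dissim
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    n = len(dendro.gene_ids)
    if n < min_module_size:
        raise ValueError(
            f"dendrogram has {n} genes, fewer than min_module_size={min_module_size}"
        )
    if cut_height is None:
        cut_height = adaptive_cut_height(dendro)
    groups = fcluster(dendro.linkage, t=cut_height, criterion="distance")
    assignment = pd.Series(GREY, index=dendro.gene_ids, dtype=object)
    next_label = 1
    for gid, count in zip(*np.unique(groups, return_counts=True)):
        if count >= min_module_size:
            assignment.iloc[np.flatnonzero(groups == gid)] = f"M{next_label}"
            next_label += 1
    part = ModulePartition(assignment=assignment, min_module_size=min_module_size)
    return _relabel_by_size(part)


def _relabel_by_size(partition: ModulePartition) -> ModulePartition:
    mapping = {lab: f"M{i + 1}" for i, lab in enumerate(partition.labels)}
    mapping[GREY] = GREY
    return ModulePartition(
        assignment=partition.assignment.map(mapping),
        min_module_size=partition.min_module_size,
    )


def _standardize_rows(values: np.ndarray, gene_ids, label: str) -> np.ndarray:
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sds.ravel() == 0)
    if flat.size:
        bad = [gene_ids[i] for i in flat[:5]]
        raise ValueError(f"zero-variance genes in module {label}: {bad}")
    return (values - means) / sds


def module_eigengene(
    expr: ExpressionMatrix, partition: ModulePartition
) -> EigengeneSet:
    """First principal component of each module's standardized expression.

    Genes are z-scored across samples; the eigengene is the unit-norm
    first right singular vector, with variance explained
    sigma_1^2 / sum_i sigma_i^2.
    """
    labels = partition.labels
    if not labels:
        raise ValueError("partition has no non-grey modules")
    rows, ve = [], []
    for label in labels:
        members = partition.members(label)
        sub = expr.data.loc[members].to_numpy()
        z = _standardize_rows(sub, members, label)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        if float(np.corrcoef(me, z.mean(axis=0))[0, 1]) < 0:
            me = -me
        rows.append(me)
        ve.append(float(s[0] ** 2 / (s**2).sum()))
    eig = pd.DataFrame(np.vstack(rows), index=labels, columns=expr.sample_ids)
    return EigengeneSet(
        eigengenes=eig, variance_explained=pd.Series(ve, index=labels, name="variance_explained")
    )


def eigengene_dissimilarity(eigengenes: EigengeneSet) -> pd.DataFrame:
    """1 - Pearson correlation between module eigengenes."""
    me = eigengenes.eigengenes.to_numpy()
    cor = np.corrcoef(me)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    d = 1.0 - cor
    np.fill_diagonal(d, 0.0)
    labels = eigengenes.module_labels
    return pd.DataFrame(d, index=labels, columns=labels)


def merge_close_modules(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneSet | None = None,
    cut_height: float = 0.25,
) -> tuple[ModulePartition, EigengeneSet]:
    """Merge modules whose eigengenes are closer than ``cut_height``.

    Eigengenes are clustered by average linkage on 1 - correlation and
    every branch below ``cut_height`` is collapsed into one module; the
    eigengenes are then recomputed and the procedure repeats until no pair
    merges. Termination is guaranteed because the module count strictly
    decreases on every pass.
    """
    if not 0 < cut_height <= 1:
        raise ValueError(f"cut_height must lie in (0, 1], got {cut_height}")
    if eigengenes is None:
        eigengenes = module_eigengene(expr, partition)
    current = partition
    while current.n_modules > 1:
        diss = eigengene_dissimilarity(eigengenes)
        tree = linkage(
            squareform(diss.to_numpy(), checks=False), method="average"
        )
        groups = fcluster(tree, t=cut_height, criterion="distance")
        if len(set(groups)) == len(groups):
            break  # every eigengene in its own branch: nothing below cut_height
        sizes = current.module_sizes()
        mapping: dict[str, str] = {}
        for gid in set(groups):
            members = [diss.index[i] for i in np.flatnonzero(groups == gid)]
            target = max(members, key=lambda lab: (sizes[lab], lab))
            for lab in members:
                mapping[lab] = target
        mapping[GREY] = GREY
        current = ModulePartition(
            assignment=current.assignment.map(mapping),
            min_module_size=current.min_module_size,
        )
        eigengenes = module_eigengene(expr, current)
    current = _relabel_by_size(current)
    eigengenes = module_eigengene(expr, current)
    return current, eigengenes


def assign_colors(partition: ModulePartition) -> ModulePartition:
    """Rename modules by size rank with the conventional color sequence.

    The largest module becomes "turquoise", the second "blue", and so on;
    ties in size break by the lexicographically smallest member gene id.
    "grey" always denotes unassigned genes.
    """
    labels = partition.labels
    mapping = {GREY: GREY}
    for i, lab in enumerate(labels):
        mapping[lab] = (
            MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        )
    return ModulePartition(
        assignment=partition.assignment.map(mapping),
        min_module_size=partition.min_module_size,
    )
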