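"""Module membership (kME), hub genes, hub networks and over-representation.

kME is the Pearson correlation between a gene's expression profile and a
module eigengene, computed for every gene-module pair (members and
non-members alike); hub ranking then restricts to a module's own members.
Hub connection networks are exported in the VisANT plain-text edge format.
Gene-set over-representation uses the hypergeometric upper tail with
Benjamini-Hochberg adjustment, with the analysis gene universe (not the
genome) as background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comodnet.detection import GREY, EigengeneSet, ModulePartition
from comodnet.expression import ExpressionMatrix
from comodnet.network import GeneNetwork

logger = logging.getLogger(__name__)


def compute_kme(expr: ExpressionMatrix, eigengenes: EigengeneSet) -> pd.DataFrame:
    """Gene x module table of correlations with each module eigengene."""
    if list(expr.sample_ids) != list(eigengenes.sample_ids):
        raise ValueError("expression and eigengene sample sets differ")
    x = expr.values
    x = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    if (xn == 0).any():
        bad = [g for g, nz in zip(expr.gene_ids, xn.ravel()) if nz == 0]
        raise ValueError(f"zero-variance genes: {bad[:10]}")
    e = eigengenes.eigengenes.to_numpy()
    e = e - e.mean(axis=1, keepdims=True)
    en = np.linalg.norm(e, axis=1, keepdims=True)
    kme = (x / xn) @ (e / en).T
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr.gene_ids, columns=eigengenes.module_labels)


def top_hub_genes(
    kme: pd.DataFrame,
    partition: ModulePartition,
    module: str,
    n: int = 30,
) -> list[str]:
    """The module's members with the largest kME, best first.

    Ties break lexicographically by gene id; if the module holds fewer
    than ``n`` genes all members are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if module not in kme.columns or module == GREY:
        raise ValueError(f"unknown module {module!r}")
    members = partition.members(module)
    if len(members) < n:
        logger.info("module %s has %d members < n=%d; returning all", module, len(members), n)
    scores = kme.loc[members, module]
    order = sorted(members, key=lambda g: (-scores[g], g))
    return order[:n]


def hub_edge_list(
    network: GeneNetwork,
    hubs: list[str],
    top_edges: int | None = None,
) -> pd.DataFrame:
    """All unordered hub pairs ranked by TOM weight, strongest first.

    ``top_edges=None`` keeps every pair; otherwise the list is truncated
    to the ``top_edges`` heaviest edges.
    """
    missing = [g for g in hubs if g not in network.tom.index]
    if missing:
        raise ValueError(f"hub genes absent from network: {missing}")
    records = []
    for i, a in enumerate(hubs):
        for b in hubs[i + 1 :]:
            records.append((a, b, float(network.tom.at[a, b])))
    edges = pd.DataFrame(records, columns=["gene_a", "gene_b", "weight"])
    edges = edges.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if top_edges is not None:
        edges = edges.iloc[:top_edges].reset_index(drop=True)
    return edges


def write_visant(edges: pd.DataFrame, path, method_id: str = "M0099") -> None:
    """Write edges as VisANT import lines: node_a node_b method weight."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.gene_a}\t{row.gene_b}\t{method_id}\t{row.weight:.6g}\n")


def select_kme_genes(
    kme: pd.DataFrame,
    partition: ModulePartition,
    threshold: float = 0.75,
) -> dict[str, list[str]]:
    """Per module, member genes with kME strictly above ``threshold``.

    This is the gene selection fed to functional-annotation analysis; the
    default 0.75 keeps only genes tightly coupled to the eigengene.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    selected = {}
    for label in partition.labels:
        members = partition.members(label)
        scores = kme.loc[members, label]
        selected[label] = sorted(scores.index[scores > threshold])
    return selected


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, tab-separated members."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {line_no}: expected name, description, genes")
            gene_sets[fields[0]] = {g for g in fields[2:] if g}
    return gene_sets


def hypergeometric_ora(
    selected: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    For a universe of size M with a gene set of size K and a selection of
    size N overlapping in x genes, the p-value is the upper tail
    P(X >= x) of Hypergeometric(M, K, N). BH adjustment runs across the
    tested sets; rows come back sorted by ascending p.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    selected = set(selected)
    if not selected <= set(universe):
        extra = sorted(selected - set(universe))
        raise ValueError(f"selected genes outside the universe: {extra[:10]}")
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & set(universe)
        overlap = len(in_universe & selected)
        # P(X >= overlap) with X ~ Hypergeom(M=m, n=|set|, N=n_sel)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(in_universe), n_sel))
        rows.append((name, len(in_universe), overlap, min(max(p, 0.0), 1.0)))
    table = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values(["p_value", "gene_set"]).reset_index(drop=True)
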