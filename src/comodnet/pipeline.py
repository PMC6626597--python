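"""End-to-end pipeline: files in, module/trait result bundle out.

Stages: load + filter -> sample clustering -> network (correlation,
signed adjacency, TOM) -> dendrogram + adaptive cut -> eigengene merge ->
colors -> kME/hubs -> module-trait grid, time course, BMS gene ranking.
Every artifact is written as TSV (hub networks as VisANT text) with fixed
numeric formatting, and a manifest records parameters, versions and input
checksums, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from comodnet.characterization import (
    compute_kme,
    hub_edge_list,
    select_kme_genes,
    top_hub_genes,
    write_visant,
)
from comodnet.detection import (
    assign_colors,
    average_linkage,
    dynamic_tree_cut,
    merge_close_modules,
    module_eigengene,
)
from comodnet.expression import (
    cluster_samples,
    filter_genes,
    load_expression,
    load_sample_info,
    log_normalize,
)
from comodnet.network import build_network, tom_dissimilarity
from comodnet.traits import (
    build_trait_matrix,
    module_trait_correlation,
    timecourse_summary,
    trait_gene_ranking,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.8g"


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    Defaults follow the analysis conventions this package implements:
    soft-threshold power 12 on a signed network, minimum module size 30,
    eigengene merge height 0.25, 30 hub genes per module, and kME > 0.75
    for annotation gene selection.
    """

    expression: str
    sample_info: str
    output_dir: str
    beta: int = 12
    signed: bool = True
    min_module_size: int = 30
    merge_height: float = 0.25
    n_hubs: int = 30
    kme_threshold: float = 0.75
    baseline_genotype: str = "WT"
    baseline_injury: str = "uninjured"
    min_variance: float = 0.0
    top_n: int | None = None
    log_transform: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage and return the mapping of artifact name to path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    stage = "load"
    try:
        expr = load_expression(config.expression)
        info = load_sample_info(config.sample_info, expr)
        if config.log_transform:
            expr = log_normalize(expr)
        expr = filter_genes(expr, config.min_variance or 1e-12, config.top_n)
        logger.info("loaded %d genes x %d samples", expr.n_genes, expr.n_samples)

        stage = "sample_clustering"
        sc = cluster_samples(expr)
        tree_df = pd.DataFrame(
            sc.linkage_tree, columns=["left", "right", "height", "count"]
        )
        _write_df(tree_df, out / "sample_tree.tsv", "merge")
        (out / "sample_leaf_order.txt").write_text("\n".join(sc.leaf_order) + "\n")
        paths["sample_tree"] = str(out / "sample_tree.tsv")
        paths["sample_leaf_order"] = str(out / "sample_leaf_order.txt")

        stage = "network"
        net = build_network(expr, beta=config.beta, signed=config.signed)

        stage = "module_detection"
        dendro = average_linkage(tom_dissimilarity(net.tom))
        partition = dynamic_tree_cut(
            dendro, min_module_size=config.min_module_size
        )
        n_initial = partition.n_modules
        logger.info("tree cut found %d modules", n_initial)

        stage = "module_merge"
        if partition.n_modules:
            partition, eigengenes = merge_close_modules(
                expr, partition, cut_height=config.merge_height
            )
        else:
            raise RuntimeError("no modules found at this minimum size")
        partition = assign_colors(partition)
        eigengenes = module_eigengene(expr, partition)
        logger.info("%d modules after eigengene merge", partition.n_modules)
        part_df = partition.assignment.rename("module").to_frame()
        part_df.to_csv(out / "modules.tsv", sep="\t", index_label="gene_id")
        _write_df(eigengenes.eigengenes, out / "eigengenes.tsv", "module")
        paths["modules"] = str(out / "modules.tsv")
        paths["eigengenes"] = str(out / "eigengenes.tsv")

        stage = "kme"
        kme = compute_kme(expr, eigengenes)
        _write_df(kme, out / "kme.tsv", "gene_id")
        paths["kme"] = str(out / "kme.tsv")
        hub_tables = []
        for label in partition.labels:
            hubs = top_hub_genes(kme, partition, label, n=config.n_hubs)
            hub_tables.append(
                pd.DataFrame(
                    {"module": label, "rank": range(1, len(hubs) + 1), "gene_id": hubs,
                     "kme": kme.loc[hubs, label].to_numpy()}
                )
            )
            edges = hub_edge_list(net, hubs)
            write_visant(edges, out / f"hub_edges_{label}.visant.txt")
            paths[f"hub_edges_{label}"] = str(out / f"hub_edges_{label}.visant.txt")
        pd.concat(hub_tables).to_csv(
            out / "hub_genes.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        paths["hub_genes"] = str(out / "hub_genes.tsv")
        selection = select_kme_genes(kme, partition, config.kme_threshold)
        with open(out / "kme_selection.tsv", "w") as fh:
            fh.write("module\tgene_id\n")
            for label, genes in selection.items():
                for g in genes:
                    fh.write(f"{label}\t{g}\n")
        paths["kme_selection"] = str(out / "kme_selection.tsv")

        stage = "trait_analysis"
        traits = build_trait_matrix(info)
        keep = [c for c in traits.columns if traits[c].dropna().nunique() > 1]
        dropped = sorted(set(traits.columns) - set(keep))
        if dropped:
            logger.info("dropping constant traits: %s", dropped)
        mt = module_trait_correlation(eigengenes, traits[keep])
        grid = pd.concat(
            {"r": mt.r, "p": mt.p, "q": mt.q}, names=["statistic", "module"]
        )
        grid.to_csv(
            out / "module_trait.tsv",
            sep="\t",
            index_label=["statistic", "module"],
            float_format=FLOAT_FMT,
        )
        paths["module_trait"] = str(out / "module_trait.tsv")

        tc = timecourse_summary(
            expr,
            partition,
            kme,
            info,
            baseline=(config.baseline_genotype, config.baseline_injury),
            n_hubs=config.n_hubs,
        )
        _write_df(tc.timecourse, out / "timecourse.tsv", "module")
        _write_df(tc.group_means, out / "group_means.tsv", "module")
        paths["timecourse"] = str(out / "timecourse.tsv")
        paths["group_means"] = str(out / "group_means.tsv")

        if "bms" in info.columns and info["bms"].notna().sum() >= 6:
            ranking = trait_gene_ranking(expr, info["bms"], info["genotype"])
            pure = ranking[ranking["pure"]]
            _write_df(
                pure[pure["sign"] == "positive"], out / "bms_positive.tsv", "gene_id"
            )
            _write_df(
                pure[pure["sign"] == "negative"], out / "bms_negative.tsv", "gene_id"
            )
            paths["bms_positive"] = str(out / "bms_positive.tsv")
            paths["bms_negative"] = str(out / "bms_negative.tsv")

        stage = "manifest"
        from comodnet import __version__ as pkg_version

        manifest = {
            "comodnet_version": pkg_version,
            "parameters": asdict(config),
            "inputs": {
                "expression": {"path": str(config.expression), "sha256": _sha256(config.expression)},
                "sample_info": {"path": str(config.sample_info), "sha256": _sha256(config.sample_info)},
            },
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "n_modules_initial": n_initial,
            "n_modules_final": partition.n_modules,
            "module_sizes": {
                lab: int(n) for lab, n in partition.module_sizes().items()
            },
            "versions": _library_versions(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = str(out / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
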