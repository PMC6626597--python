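"""Expression matrix I/O, validation, normalization and sample clustering.

The package-wide orientation convention is genes in rows and samples in
columns, both on disk (TSV, first column = gene id, header = sample ids)
and in memory (:class:`ExpressionMatrix` wraps a genes x samples
DataFrame). Values are assumed to be normalized, log-scale expression;
``log_normalize`` provides log2(x + offset) for callers starting from
non-negative linear-scale values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

GENOTYPE_LEVELS = ("WT", "SCID")
INJURY_LEVELS = ("uninjured", "injured")

SAMPLE_INFO_COLUMNS = ("genotype", "injury", "day_post_injury")


@dataclass
class ExpressionMatrix:
    """Validated genes x samples matrix of log-scale expression.

    Parameters
    ----------
    data:
        DataFrame with unique gene ids as the index and unique sample ids
        as the columns; all entries finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = [
                (g, s)
                for g, row in self.data.iterrows()
                for s, v in row.items()
                if not isinstance(v, (int, float, np.number))
            ][:5]
            raise ValueError(f"non-numeric expression values, e.g. at {bad}")
        if np.isnan(values).any():
            genes = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in genes: {genes}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass
class SampleClustering:
    """Sample-level Pearson correlation and average-linkage tree.

    ``linkage_tree`` is a scipy linkage matrix over the samples computed on
    the dissimilarity 1 - correlation; ``leaf_order`` is the dendrogram
    leaf permutation (sample ids left to right).
    """

    correlation: pd.DataFrame
    linkage_tree: np.ndarray
    leaf_order: list[str]


def load_expression(path, *, drop_missing: bool = False) -> ExpressionMatrix:
    """Read a gene-by-sample TSV into a validated :class:`ExpressionMatrix`.

    The file must have a header row of sample ids and one gene per row,
    first column holding the gene id. Rows with missing or non-numeric
    cells are rejected (or dropped when ``drop_missing`` is true).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"expression TSV {path} has no sample columns")
    df = df.apply(pd.to_numeric, errors="coerce")
    if drop_missing and df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        logger.warning("dropping %d genes with missing values: %s", len(bad), bad[:10])
        df = df.dropna()
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV (first column gene id, header sample ids)."""
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def load_sample_info(path, expr: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read sample metadata and validate against an expression matrix.

    Required columns: sample_id, genotype (WT|SCID), injury
    (uninjured|injured), day_post_injury (integer >= 0). Optional: bms,
    a locomotor score in [0, 9] (blank where not measured).
    """
    info = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in ("sample_id", *SAMPLE_INFO_COLUMNS) if c not in info.columns]
    if missing_cols:
        raise ValueError(f"sample info {path} missing columns: {missing_cols}")
    info = info.set_index("sample_id")
    return validate_sample_info(info, expr)


def validate_sample_info(
    info: pd.DataFrame, expr: ExpressionMatrix | None = None
) -> pd.DataFrame:
    if info.index.has_duplicates:
        dups = info.index[info.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    bad_geno = sorted(set(info["genotype"]) - set(GENOTYPE_LEVELS))
    if bad_geno:
        samples = info.index[info["genotype"].isin(bad_geno)].tolist()
        raise ValueError(f"unknown genotype {bad_geno} for samples {samples}")
    bad_inj = sorted(set(info["injury"]) - set(INJURY_LEVELS))
    if bad_inj:
        samples = info.index[info["injury"].isin(bad_inj)].tolist()
        raise ValueError(f"unknown injury level {bad_inj} for samples {samples}")
    info["day_post_injury"] = info["day_post_injury"].astype(int)
    if (info["day_post_injury"] < 0).any():
        samples = info.index[info["day_post_injury"] < 0].tolist()
        raise ValueError(f"negative day_post_injury for samples {samples}")
    if "bms" in info.columns:
        bms = info["bms"].dropna()
        if ((bms < 0) | (bms > 9)).any():
            samples = bms.index[(bms < 0) | (bms > 9)].tolist()
            raise ValueError(f"bms outside [0, 9] for samples {samples}")
    if expr is not None:
        missing = [s for s in expr.sample_ids if s not in info.index]
        if missing:
            raise ValueError(f"metadata missing expression samples: {missing}")
        info = info.loc[expr.sample_ids]
    return info


def write_sample_info(info: pd.DataFrame, path) -> None:
    info.to_csv(path, sep="\t", index_label="sample_id")


def log_normalize(raw: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return log2(x + offset) of a non-negative linear-scale matrix."""
    values = raw.values
    if (values < 0).any():
        genes = raw.data.index[(values < 0).any(axis=1)].tolist()
        raise ValueError(f"negative expression values in genes: {genes}")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(values + offset), index=raw.data.index, columns=raw.data.columns
        )
    )


def filter_genes(
    expr: ExpressionMatrix,
    min_variance: float = 0.0,
    top_n: int | None = None,
) -> ExpressionMatrix:
    """Drop low-variance genes; optionally keep the ``top_n`` most variable.

    Zero-variance genes are always removed when ``min_variance > 0`` or
    ``top_n`` is given; Pearson correlation is undefined for them, so the
    network stage requires this filter (or externally variance-safe input).
    """
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    var = expr.data.var(axis=1, ddof=1)
    keep = var[var >= min_variance] if min_variance > 0 else var
    if top_n is not None:
        if top_n >= len(keep):
            logger.info(
                "top_n=%d >= %d genes after variance filter; keeping all",
                top_n,
                len(keep),
            )
        else:
            keep = keep.sort_values(ascending=False).iloc[:top_n]
    kept_ids = [g for g in expr.gene_ids if g in set(keep.index)]
    return expr.subset_genes(kept_ids)


def cluster_samples(expr: ExpressionMatrix) -> SampleClustering:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    This is the transcriptome-wide sample dendrogram used to check that
    biological groups (e.g. injured vs uninjured) dominate the variance.
    """
    if expr.n_samples < 2:
        raise ValueError("sample clustering needs at least 2 samples")
    values = expr.values
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = [s for s, sd in zip(expr.sample_ids, sds) if sd == 0]
        raise ValueError(f"zero-variance samples: {bad}")
    cor = np.corrcoef(values.T)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    dissim = 1.0 - cor
    np.fill_diagonal(dissim, 0.0)
    tree = linkage(squareform(dissim, checks=False), method="average")
    order = [expr.sample_ids[i] for i in leaves_list(tree)]
    cor_df = pd.DataFrame(cor, index=expr.sample_ids, columns=expr.sample_ids)
    return SampleClustering(correlation=cor_df, linkage_tree=tree, leaf_order=order)
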