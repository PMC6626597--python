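"""Module-trait correlation, hub-gene time courses and trait-gene ranking.

Traits are the experimental design covariates: genotype (WT vs SCID,
where SCID is the immune-deficient *Prkdc* mutant), injury status, day
post-injury, the four one-hot genotype x injury groups, and the BMS
locomotor score (Basso Mouse Scale, 0-9) where measured. Modules are
related to traits by correlating their eigengenes with the trait columns;
time courses summarize each module as the mean expression of its top hub
genes, baseline-normalized to the uninjured wild-type group so the
reference sits exactly at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comodnet.characterization import top_hub_genes
from comodnet.detection import EigengeneSet, ModulePartition
from comodnet.expression import ExpressionMatrix

DESIGN_TRAITS = (
    "genotype_SCID",
    "injured",
    "WT_uninjured",
    "WT_injured",
    "SCID_uninjured",
    "SCID_injured",
    "day_post_injury",
)


@dataclass
class ModuleTraitResult:
    """Module x trait grids of Pearson r, two-sided p, and BH q."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame


@dataclass
class TimeCourseSummary:
    """Hub-gene mean expression per module, baseline-subtracted.

    ``timecourse`` holds module x day means over wild-type injured samples
    (plus day 0 = uninjured wild type); ``group_means`` holds module x
    (genotype, injury) group means. Both are relative to the uninjured
    wild-type baseline, which is therefore identically zero.
    """

    timecourse: pd.DataFrame
    group_means: pd.DataFrame
    baseline: tuple[str, str]
    n_hubs: int


def build_trait_matrix(sample_info: pd.DataFrame) -> pd.DataFrame:
    """Encode the design as numeric traits: binaries, one-hot groups, day, bms."""
    traits = pd.DataFrame(index=sample_info.index)
    geno = sample_info["genotype"]
    inj = sample_info["injury"]
    traits["genotype_SCID"] = (geno == "SCID").astype(float)
    traits["injured"] = (inj == "injured").astype(float)
    for g in ("WT", "SCID"):
        for i in ("uninjured", "injured"):
            traits[f"{g}_{i}"] = ((geno == g) & (inj == i)).astype(float)
    traits["day_post_injury"] = sample_info["day_post_injury"].astype(float)
    if "bms" in sample_info.columns:
        traits["bms"] = sample_info["bms"].astype(float)
    return traits


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def module_trait_correlation(
    eigengenes: EigengeneSet, traits: pd.DataFrame
) -> ModuleTraitResult:
    """Pearson r, t-distribution p and BH q for every module-trait pair.

    p-values use the asymptotic t approximation with n - 2 degrees of
    freedom; BH runs across the whole module x trait grid. Traits with
    missing values are correlated over their observed samples.
    """
    me = eigengenes.eigengenes
    if not set(traits.index) >= set(me.columns):
        missing = sorted(set(me.columns) - set(traits.index))
        raise ValueError(f"traits missing samples: {missing}")
    traits = traits.loc[list(me.columns)]
    const = [c for c in traits.columns if traits[c].dropna().nunique() <= 1]
    if const:
        raise ValueError(f"constant traits (correlation undefined): {const}")
    r = pd.DataFrame(index=me.index, columns=traits.columns, dtype=float)
    p = r.copy()
    for trait in traits.columns:
        tv = traits[trait]
        mask = tv.notna().to_numpy()
        if mask.sum() < 3:
            raise ValueError(f"trait {trait} observed in fewer than 3 samples")
        y = tv.to_numpy(dtype=float)[mask]
        for label in me.index:
            x = me.loc[label].to_numpy()[mask]
            r.at[label, trait], p.at[label, trait] = _pearson_with_p(x, y)
    flat_q = multipletests(p.to_numpy().ravel(), method="fdr_bh")[1]
    q = pd.DataFrame(
        flat_q.reshape(p.shape), index=p.index, columns=p.columns
    )
    return ModuleTraitResult(r=r, p=p, q=q)


def timecourse_summary(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    kme: pd.DataFrame,
    sample_info: pd.DataFrame,
    baseline: tuple[str, str] = ("WT", "uninjured"),
    n_hubs: int = 30,
) -> TimeCourseSummary:
    """Top-hub-gene mean expression per module, by time point and by group.

    Each module is scored per sample as the mean expression of its top
    ``n_hubs`` genes (kME-ranked). The time course averages wild-type
    samples per day post-injury (day 0 = uninjured baseline); the group
    table averages each genotype x injury group. Both subtract the
    baseline group's statistic, so the baseline evaluates to exactly 0.
    """
    sample_info = sample_info.loc[expr.sample_ids]
    geno, inj = baseline
    base_mask = (sample_info["genotype"] == geno) & (sample_info["injury"] == inj)
    if not base_mask.any():
        raise ValueError(f"baseline group {geno}/{inj} has no samples")
    labels = partition.labels
    scores = pd.DataFrame(index=labels, columns=expr.sample_ids, dtype=float)
    for label in labels:
        hubs = top_hub_genes(kme, partition, label, n=n_hubs)
        scores.loc[label] = expr.data.loc[hubs].mean(axis=0)
    base_val = scores.loc[:, base_mask.to_numpy()].mean(axis=1)

    wt = sample_info["genotype"] == geno
    days = sorted(sample_info.loc[wt & (sample_info["injury"] == "injured"), "day_post_injury"].unique())
    tc = pd.DataFrame(index=labels, columns=[0, *days], dtype=float)
    tc[0] = base_val - base_val  # baseline group on itself: exactly zero
    for day in days:
        mask = (wt & (sample_info["injury"] == "injured") & (sample_info["day_post_injury"] == day)).to_numpy()
        if not mask.any():
            raise ValueError(f"no wild-type injured samples at day {day}")
        tc[day] = scores.loc[:, mask].mean(axis=1) - base_val

    groups = []
    for g in ("WT", "SCID"):
        for i in ("uninjured", "injured"):
            mask = ((sample_info["genotype"] == g) & (sample_info["injury"] == i)).to_numpy()
            if mask.any():
                groups.append((f"{g}_{i}", scores.loc[:, mask].mean(axis=1) - base_val))
    gm = pd.DataFrame({name: col for name, col in groups})
    return TimeCourseSummary(
        timecourse=tc, group_means=gm, baseline=baseline, n_hubs=n_hubs
    )


def trait_gene_ranking(
    expr: ExpressionMatrix,
    bms: pd.Series,
    genotype: pd.Series,
) -> pd.DataFrame:
    """Rank genes purely positively or negatively correlated with BMS.

    Genes are correlated with the locomotor score over the pooled samples
    (both genotypes together); a gene is kept only when its correlation
    sign is consistent in the WT subset and in the SCID subset ("purely"
    correlated), which discards genes whose apparent pooled correlation is
    an artifact of the genotype difference. The table carries pooled and
    per-genotype r, a purity flag, and the sign, sorted by |pooled r|
    within each sign.
    """
    bms = bms.dropna()
    samples = [s for s in expr.sample_ids if s in bms.index]
    geno = genotype.loc[samples]
    for g in ("WT", "SCID"):
        if (geno == g).sum() < 3:
            raise ValueError(
                f"genotype {g} has fewer than 3 samples with a BMS score"
            )
    y = bms.loc[samples].to_numpy(dtype=float)
    sub = expr.subset_samples(samples)
    x = sub.values

    def corr_with(mask: np.ndarray) -> np.ndarray:
        xm = x[:, mask]
        ym = y[mask]
        xc = xm - xm.mean(axis=1, keepdims=True)
        yc = ym - ym.mean()
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc) / denom
        return np.clip(np.nan_to_num(r), -1.0, 1.0)

    pooled = corr_with(np.ones(len(samples), dtype=bool))
    r_wt = corr_with((geno == "WT").to_numpy())
    r_scid = corr_with((geno == "SCID").to_numpy())
    sign = np.sign(pooled)
    pure = (np.sign(r_wt) == sign) & (np.sign(r_scid) == sign) & (sign != 0)
    table = pd.DataFrame(
        {
            "r_pooled": pooled,
            "r_WT": r_wt,
            "r_SCID": r_scid,
            "pure": pure,
            "sign": np.where(sign > 0, "positive", np.where(sign < 0, "negative", "zero")),
        },
        index=sub.gene_ids,
    )
    table["abs_r"] = table["r_pooled"].abs()
    table = table.sort_values(["abs_r"], ascending=False, kind="mergesort")
    return table.drop(columns="abs_r")


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qRT-PCR fold change by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference within each condition (the reference is
    a housekeeping gene such as Gapdh); ddCt = dCt_case - dCt_control;
    the fold change is 2 ** -ddCt.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError(f"non-finite Ct values: {cts}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
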