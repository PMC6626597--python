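"""Planted-module expression simulator for the two-genotype injury design.

The generator emulates the study design the analysis assumes: a
six-weeks-post-injury cohort of 10 WT injured, 11 SCID injured, 6 WT
uninjured and 4 SCID uninjured spinal-cord samples (31 in total), plus an
optional 21-sample wild-type time course at days 1, 3, 7, 14, 28 and 42
post-injury. Each planted module m is driven by a latent factor

    f_m(s) = b_geno * [SCID] + b_inj * [injured] + b_day * d(s) + noise,

with d(s) = log1p(day)/log1p(42) for injured samples, and each member
gene is

    g = kme_target * z(f_m) + sqrt(1 - kme_target^2) * eps + baseline,

so kme_target is the population gene-factor correlation. Background
("grey") genes are pure noise. Modules can share latent factors (to plant
sub-modules that should merge) and factors can carry a common component
(factor_base_r). A BMS-like locomotor trait is a weighted sum of module
factors plus noise, affinely rescaled into the instrument's [0, 9] range.

Everything is drawn from a single seeded generator in a fixed order, so a
fixed seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from comodnet.expression import ExpressionMatrix, validate_sample_info, write_expression, write_sample_info

GREY = "grey"

# Latent-factor coefficients (genotype_SCID, injured, day-shape) emulating
# the qualitative behavior of the study's nine modules: two strongly
# injury-induced immune-like programs dampened in SCID, down-regulated
# neurotransmission / transport / energy programs elevated in SCID, and
# assorted intermediate responses.
DEFAULT_EFFECTS = (
    (-1.0, 2.5, -0.5),   # immune response, up with injury, dampened in SCID
    (0.8, -2.5, 0.8),    # neurotransmission/synaptic, down with injury
    (0.0, 1.5, 0.5),
    (-0.5, 1.5, 0.0),
    (0.6, -1.8, 0.5),    # neurotransmitter transport
    (0.0, -1.2, -0.5),
    (0.0, 2.0, -1.0),    # biosynthesis burst early after injury
    (0.6, -1.5, 0.5),    # energy metabolism
    (-0.8, 2.0, -0.8),   # second immune program
)

DEFAULT_MODULE_SIZES = (300, 240, 200, 160, 140, 120, 100, 80, 60)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated study.

    ``factor_assignment`` maps each module to a latent factor index; the
    default identity mapping gives every module its own factor. When
    several modules share a factor, each gets its own sub-factor
    correlated ``within_factor_r`` with the shared one, so their
    eigengenes should merge at the usual 0.25 height while remaining
    separable branches of the gene dendrogram.
    """

    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    kme_target: float | tuple[float, ...] = 0.85
    n_background: int = 200
    effects: tuple[tuple[float, float, float], ...] = DEFAULT_EFFECTS
    factor_assignment: tuple[int, ...] | None = None
    within_factor_r: float = 0.8
    factor_base_r: float = 0.0
    n_wt_injured: int = 10
    n_scid_injured: int = 11
    n_wt_uninjured: int = 6
    n_scid_uninjured: int = 4
    injured_day: int = 42
    include_timecourse: bool = True
    timecourse_days: tuple[int, ...] = (1, 3, 7, 14, 28, 42)
    timecourse_counts: tuple[int, ...] = (4, 4, 4, 3, 3, 3)
    bms_weights: tuple[tuple[str, float], ...] = (("P2", 1.0), ("P1", -1.0))
    bms_noise_sd: float = 0.5
    gene_baseline_mean: float = 8.0
    gene_baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        kmes = self.kme_targets
        if len(kmes) != len(self.module_sizes):
            raise ValueError(
                f"{len(kmes)} kme targets for {len(self.module_sizes)} modules"
            )
        if any(not 0 < k <= 1 for k in kmes):
            raise ValueError("kme_target values must lie in (0, 1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        assign = self.factor_assignments
        if len(assign) != len(self.module_sizes):
            raise ValueError("factor_assignment length must match module_sizes")
        if len(self.effects) != self.n_factors:
            raise ValueError(
                f"{len(self.effects)} effect triples for {self.n_factors} factors"
            )
        if len(self.timecourse_days) != len(self.timecourse_counts):
            raise ValueError("timecourse days and counts differ in length")
        if not 0 < self.within_factor_r <= 1:
            raise ValueError("within_factor_r must lie in (0, 1]")
        if not 0 <= self.factor_base_r < 1:
            raise ValueError("factor_base_r must lie in [0, 1)")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def kme_targets(self) -> tuple[float, ...]:
        if isinstance(self.kme_target, (int, float)):
            return (float(self.kme_target),) * len(self.module_sizes)
        return tuple(float(k) for k in self.kme_target)

    @property
    def factor_assignments(self) -> tuple[int, ...]:
        if self.factor_assignment is None:
            return tuple(range(len(self.module_sizes)))
        return tuple(self.factor_assignment)

    @property
    def n_factors(self) -> int:
        return max(self.factor_assignments) + 1

    @property
    def module_labels(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.n_modules))


@dataclass
class SimulatedBundle:
    """Expression, metadata, planted truth and the latent module factors."""

    expr: ExpressionMatrix
    sample_info: pd.DataFrame
    truth: pd.Series
    factors: pd.DataFrame


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The standard nine-module study-design emulation."""
    return SyntheticSpec(seed=seed, **overrides)


def submodule_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Fourteen sub-modules driven by nine latent factors.

    Five factors each drive two sub-modules (within-factor correlation
    0.85, so the eigengene dissimilarity stays below the 0.25 merge
    height even with sampling noise at around fifty samples) and four
    drive one module each, so eigengene merging should collapse the
    initial partition to nine modules. The factors carry no covariate
    effects but share a mild common component, keeping all pairwise
    eigengene dissimilarities comfortably inside (0.25, 1).
    """
    params = dict(
        module_sizes=(150, 130, 120, 110, 100, 95, 90, 85, 80, 75, 70, 65, 60, 55),
        factor_assignment=(0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 6, 7, 8),
        effects=((0.0, 0.0, 0.0),) * 9,
        within_factor_r=0.85,
        factor_base_r=0.3,
        n_background=150,
        bms_weights=(),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def build_design(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample metadata table for the spec's design (no randomness)."""
    rows = []

    def add(prefix, count, genotype, injury, day, cohort):
        for i in range(count):
            rows.append(
                {
                    "sample_id": f"{prefix}{i + 1:02d}",
                    "genotype": genotype,
                    "injury": injury,
                    "day_post_injury": day,
                    "cohort": cohort,
                }
            )

    add("WTI", spec.n_wt_injured, "WT", "injured", spec.injured_day, "design")
    add("SCI", spec.n_scid_injured, "SCID", "injured", spec.injured_day, "design")
    add("WTU", spec.n_wt_uninjured, "WT", "uninjured", 0, "design")
    add("SCU", spec.n_scid_uninjured, "SCID", "uninjured", 0, "design")
    if spec.include_timecourse:
        for day, count in zip(spec.timecourse_days, spec.timecourse_counts):
            add(f"TCD{day:02d}_", count, "WT", "injured", day, "timecourse")
    info = pd.DataFrame(rows).set_index("sample_id")
    return validate_sample_info(info)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant factor")
    return (x - x.mean()) / sd


def simulate_expression(spec: SyntheticSpec) -> SimulatedBundle:
    """Draw one expression bundle from the spec's generative model.

    Draw order (one seeded stream): shared factor component, latent
    factor noise, sub-factor noise, member-gene noise, background genes,
    per-gene baselines, then the BMS trait.
    """
    rng = np.random.default_rng(spec.seed)
    info = build_design(spec)
    n_samples = len(info)
    scid = (info["genotype"] == "SCID").to_numpy(float)
    injured = (info["injury"] == "injured").to_numpy(float)
    max_day = max(int(info["day_post_injury"].max()), 1)
    dshape = injured * np.log1p(info["day_post_injury"].to_numpy(float)) / np.log1p(max_day)

    shared = rng.standard_normal(n_samples)
    latent = np.empty((spec.n_factors, n_samples))
    for k, (b_geno, b_inj, b_day) in enumerate(spec.effects):
        noise = np.sqrt(spec.factor_base_r) * shared + np.sqrt(
            1.0 - spec.factor_base_r
        ) * rng.standard_normal(n_samples)
        latent[k] = b_geno * scid + b_inj * injured + b_day * dshape + noise

    assign = spec.factor_assignments
    factor_use = {k: assign.count(k) for k in set(assign)}
    module_factors = np.empty((spec.n_modules, n_samples))
    for m, k in enumerate(assign):
        base = _zscore(latent[k])
        if factor_use[k] == 1:
            module_factors[m] = base
        else:
            eta = rng.standard_normal(n_samples)
            sub = np.sqrt(spec.within_factor_r) * base + np.sqrt(
                1.0 - spec.within_factor_r
            ) * eta
            module_factors[m] = _zscore(sub)

    labels = spec.module_labels
    kmes = spec.kme_targets
    blocks, truth_labels, gene_ids = [], [], []
    gene_no = 0
    for m, size in enumerate(spec.module_sizes):
        k = kmes[m]
        eps = rng.standard_normal((size, n_samples))
        blocks.append(k * module_factors[m] + np.sqrt(1.0 - k * k) * eps)
        truth_labels.extend([labels[m]] * size)
        for _ in range(size):
            gene_no += 1
            gene_ids.append(f"g{gene_no:05d}")
    if spec.n_background:
        blocks.append(rng.standard_normal((spec.n_background, n_samples)))
        truth_labels.extend([GREY] * spec.n_background)
        for _ in range(spec.n_background):
            gene_no += 1
            gene_ids.append(f"g{gene_no:05d}")
    values = np.vstack(blocks)
    baselines = rng.normal(spec.gene_baseline_mean, spec.gene_baseline_sd, size=gene_no)
    values = values + baselines[:, None]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=info.index)
    )
    truth = pd.Series(truth_labels, index=gene_ids, name="module")
    factors = pd.DataFrame(module_factors, index=list(labels), columns=info.index)
    info = info.copy()
    if spec.bms_weights:
        info["bms"] = simulate_bms(spec, factors, rng=rng)
    return SimulatedBundle(expr=expr, sample_info=info, truth=truth, factors=factors)


def simulate_bms(
    spec: SyntheticSpec, factors: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.Series:
    """BMS-like locomotor score tied to the weighted module factors.

    The raw score sum_m w_m f_m + noise is affinely rescaled into [0, 9]
    (the instrument's range) over the six-weeks design cohort; time-course
    samples get no score, as in the study the behavioral battery ran on
    the main cohort only. Rescaling plus clipping is a mild nonlinearity
    relative to the latent factors.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    unknown = [lab for lab, _ in spec.bms_weights if lab not in factors.index]
    if unknown:
        raise ValueError(f"bms_weights reference unknown modules: {unknown}")
    raw = np.zeros(factors.shape[1])
    for lab, w in spec.bms_weights:
        raw = raw + w * factors.loc[lab].to_numpy()
    raw = raw + rng.normal(0.0, spec.bms_noise_sd, size=factors.shape[1])
    bms = pd.Series(raw, index=factors.columns, name="bms")
    design = bms.index.str.startswith(("WTI", "SCI", "WTU", "SCU"))
    sub = bms[design]
    span = sub.max() - sub.min()
    if span > 0:
        scaled = 9.0 * (sub - sub.min()) / span
    else:
        scaled = sub * 0.0 + 4.5
    out = pd.Series(np.nan, index=bms.index, name="bms")
    out[design] = scaled.clip(0.0, 9.0).round(2)
    return out


def simulate_trait(
    factors: pd.DataFrame,
    module: str,
    r: float,
    rng: np.random.Generator,
    samples: list[str] | None = None,
) -> pd.Series:
    """Continuous trait with planted correlation ``r`` to one module factor.

    trait = r * z(f_m) + sqrt(1 - r^2) * noise over the chosen samples;
    used for recovery studies of the module-trait correlation analysis.
    """
    if module not in factors.index:
        raise ValueError(f"unknown module {module!r}")
    if not -1 <= r <= 1:
        raise ValueError("planted correlation must lie in [-1, 1]")
    cols = list(factors.columns) if samples is None else list(samples)
    f = _zscore(factors.loc[module, cols].to_numpy(float))
    noise = rng.standard_normal(len(cols))
    return pd.Series(
        r * f + np.sqrt(1.0 - r * r) * noise, index=cols, name=f"trait_{module}"
    )


def write_fixture(bundle: SimulatedBundle, outdir) -> dict[str, str]:
    """Write expression.tsv, samples.tsv and truth.tsv; return the paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(bundle.expr, paths["expression"])
    write_sample_info(bundle.sample_info, paths["samples"])
    bundle.truth.to_frame().to_csv(paths["truth"], sep="\t", index_label="gene_id")
    return {k: str(v) for k, v in paths.items()}
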