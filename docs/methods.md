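# Methods

## Model and procedure

comodnet implements signed weighted coexpression network analysis. The
input is a genes × samples matrix of normalized, log-scale expression;
the pipeline assumes normalization has already happened (a `log2(x + 1)`
helper is provided for callers starting from non-negative linear-scale
values, but the method is agnostic to the unit as long as Pearson
correlation across samples is meaningful). Genes with zero variance are
removed before any correlation is computed, since Pearson correlation is
undefined for them.

**Adjacency.** The gene–gene Pearson correlation matrix is mapped to a
signed adjacency `a_ij = ((1 + cor_ij)/2)^β` with β = 12. The signed
transform sends cor = −1 to 0, cor = 0 to 2^−β, and cor = 1 to 1, so
strongly anticorrelated genes are treated as unconnected rather than as
tightly linked, and modules group genes that move together in the same
direction. β is fixed rather than chosen by a scale-free-fit criterion;
power selection is deliberately out of scope.

**Topological overlap.** Interconnectedness is measured with the standard
topological overlap of the (signed) adjacency,
`TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` for i ≠ j, where
`L_ij = Σ_{u≠i,j} a_iu a_uj` and `k_i = Σ_{j≠i} a_ij`. Conventions: the
adjacency diagonal is excluded from `k` and `L`; the `min(k_i, k_j)`
denominator variant is used; `TOM_ii = 1`; the dissimilarity is
`1 − TOM` with zero diagonal. All matrices are dense; at the few-thousand
gene scale TOM is one symmetric matrix product, and a 2,000-gene TOM
takes a few seconds on one CPU. Blockwise computation for much larger
gene sets is out of scope.

**Gene dendrogram and adaptive cut.** Genes are clustered by average
linkage (UPGMA) on `1 − TOM` via `scipy.cluster.hierarchy.linkage`.
Modules are branches of this dendrogram. The cut height is chosen
adaptively from the merge-height profile: within a coherent module,
UPGMA heights rise in small increments, while inter-module joins and the
late attachments of unassignable background genes crowd in near the
root, so the sorted merge heights show a wide quiet band between the
module tops and the root region. The cut goes through the middle of the
widest gap between consecutive sorted merge heights in the upper half of
the profile (candidates below the median are ignored: they reflect the
dense internal merges of tight branches). Branches below the cut with at
least `min_module_size = 30` leaves become modules; all other genes are
labeled "grey". An explicit cut height can be supplied to override the
adaptive choice. This is a deliberately simple branch-identification
variant: the hybrid refinement that reassigns borderline genes by a
medoid criterion is out of scope, and the minimum module size is a
package default, not a value inherited from any particular study.

The cut exploits a height *band* rather than requiring a gap at each
individual merge. An earlier variant that split recursively whenever a
merge was separated from its children by a fixed gap failed on realistic
data: background genes attach in a dense ramp just below the root, so no
single merge shows a gap even when the band between module tops and the
root region is wide.

**Eigengenes.** Each module's genes are z-scored across samples
(mean 0, SD 1, sample SD with one delta degree of freedom) and the
module eigengene is the first right singular vector of the standardized
submatrix — the module's representative profile, unit-norm over samples.
Its sign is aligned so it correlates non-negatively with the module's
mean standardized expression; without such a convention eigengene and
kME signs would be arbitrary. Variance explained is
`σ₁² / Σ σ_i²`, equivalently the *mean* squared correlation between the
module's genes and the eigengene (first-PC optimality: no other profile
achieves a higher mean squared correlation).

**Merging.** Eigengenes are clustered by average linkage on
`1 − cor(ME_i, ME_j)`; every branch below the merge height (default
0.25, i.e. eigengene correlation above 0.75) collapses into one module,
eigengenes are recomputed, and the procedure repeats until no pair
merges. Termination is guaranteed because the module count strictly
decreases each pass. Merge heights up to 1.0 are accepted (at 1.0 every
pair of positively correlated eigengenes merges). After merging, modules
are renamed by size rank with the conventional color sequence
(turquoise, blue, brown, …), ties broken by the lexicographically
smallest member gene id; "grey" is reserved for unassigned genes.

**kME and hubs.** kME is the Pearson correlation of every gene with
every module eigengene — members and non-members alike, which is the
conventional definition; hub ranking then restricts to the module's own
members, sorted by descending kME with lexicographic tie-breaks. The
top-30 hub list feeds two outputs: a VisANT-format edge list of hub–hub
TOM weights (all pairs by default; a `top_edges` truncation is
available), and the per-module time-course summary. Genes with
kME > 0.75 (strict inequality) are the per-module selection for
over-representation analysis. ORA uses the hypergeometric upper tail
with the analysis gene universe — the post-filter gene list, not the
genome — as background, with Benjamini–Hochberg adjustment across the
tested sets.

## Trait analysis

The design is encoded as numeric traits: binary genotype (SCID = 1) and
injury (injured = 1), four one-hot genotype × injury groups, numeric day
post-injury, and the BMS score where measured. Module–trait association
is the Pearson correlation of each eigengene with each trait, with
two-sided p-values from the t approximation on n − 2 degrees of freedom
and BH adjustment across the whole module × trait grid. Traits with
missing values (BMS is only scored on the behavioral cohort) are
correlated over their observed samples.

The time-course summary scores each module per sample as the mean
expression of its top-30 hub genes, averages within each wild-type
post-injury day and within each genotype × injury group, and subtracts
the uninjured wild-type statistic. Normalization is subtraction in
log-expression space — consistent with plotting the baseline as a flat
line at zero — not division; the baseline group therefore evaluates to
exactly 0, and any constant shift of the input cancels.

The BMS gene ranking correlates every gene with the score over the
pooled genotypes, then applies a purity filter: a gene is kept only when
its correlation carries the same sign within the WT subset and within
the SCID subset as in the pool. This operationalizes "purely positively
or negatively correlated": a gene whose pooled correlation is an
artifact of the genotype difference (positive in one genotype, negative
in the other) is discarded. The filter is one reasonable reading of the
idea; alternatives (e.g. thresholding each subset correlation) would be
stricter.

The `2^−ΔΔCt` helper computes relative qRT-PCR fold change:
ΔCt = Ct_target − Ct_reference per condition, ΔΔCt = ΔCt_case −
ΔCt_control, fold change = 2^−ΔΔCt.

## Synthetic data

The simulator draws, per module m, a latent factor over samples,
`f_m = b_geno·[SCID] + b_inj·[injured] + b_day·d + ε` with ε standard
normal and `d = log1p(day)/log1p(42)` for injured samples — a saturating
time profile, one fixed shape for all modules. Member genes are
`g = kme·z(f_m) + sqrt(1 − kme²)·noise` plus a per-gene baseline offset,
so `kme_target` is the population gene–factor correlation; background
genes are pure noise. The default design emulates the assumed study:
31 six-weeks samples (10 WT-injured, 11 SCID-injured, 6 WT-uninjured,
4 SCID-uninjured) plus 21 wild-type time-course samples at days 1, 3, 7,
14, 28, 42 (counts 4, 4, 4, 3, 3, 3); nine modules of 60–300 genes
(1,400 planted genes), kme_target 0.85, and 200 background genes. The
default effect triples give two injury-induced SCID-dampened immune-like
programs, injury-suppressed SCID-elevated neurotransmission-, transport-
and energy-like programs, and assorted intermediate responses; effect
magnitudes of 1–2.5 against unit factor noise give the clear but not
trivial group separation a strong injury experiment shows.

Modules may share latent factors: each then receives a sub-factor
correlated `within_factor_r` with the shared one. The
`submodule_spec` preset plants 14 sub-modules on 9 factors
(`within_factor_r = 0.85`, chosen so empirical eigengene correlations
stay above 0.75 despite sampling noise at ~50 samples) with a mild
common component across factors (`factor_base_r = 0.3`), so merging at
0.25 should recover nine modules and merging at 1.0 collapses
everything — all pairwise eigengene dissimilarities lie strictly inside
(0.25, 1).

The BMS-like trait is a weighted sum of module factors plus Gaussian
noise, affinely rescaled into the instrument's [0, 9] range over the
behavioral cohort (clipping at the ends is a mild nonlinearity) and
rounded to two decimals; time-course samples get no score. With the
default weights (+1 on the neurotransmission-like module, −1 on the
immune-like module) injured SCID animals outscore injured WT animals on
average, the direction the genotype effects encode.

What the simulator does **not** emulate: count noise and library-size
variation (values are Gaussian in log-space), batch effects, outlier
samples, correlated background genes, and any real gene identity or
annotation. Passing the planted-recovery tests therefore demonstrates
that the pipeline's inference machinery is correct under its own model
assumptions, not that a particular biological dataset would yield any
particular module structure.

All randomness flows from one seeded `numpy` generator in a documented
draw order (shared factor component, factor noise, sub-factor noise,
member-gene noise, background genes, baselines, BMS), so a fixed seed
reproduces a bundle bit for bit.

## Numerical choices and edge cases

- Correlation matrices are symmetrized (`(C + Cᵀ)/2`) and clipped to
  [−1, 1] before use to absorb floating-point asymmetry; unit diagonals
  are set explicitly.
- TOM is clipped to [0, 1] and symmetrized; its diagonal is fixed to 1.
- Zero-variance genes or samples, constant traits, empty baseline
  groups, and modules of zero-variance genes raise errors naming the
  offending entity rather than propagating NaNs.
- `fcluster(..., criterion="distance")` implements "below the cut
  height" as ≤; a tie exactly at a threshold is measure-zero under the
  continuous simulator and is documented rather than special-cased.
- Strict inequality at the kME > 0.75 selection boundary.
- Hub and color ties break lexicographically by gene id so every output
  is deterministic; pipeline TSVs use a fixed float format, making
  reruns byte-identical.
- Tree-cut determinism needs no seed: every stage after simulation is
  deterministic in its inputs.

## Known limitations

- The adaptive cut assumes a visible height band between module tops and
  the root region; on data with a continuum of cluster scales (no clear
  band) it degrades to a single coarse split, where the hybrid dynamic
  cut would do better.
- Unsigned adjacency (`|cor|^β`) is available behind a flag but is not
  exercised by the validation suite.
- The merge loop recomputes eigengenes after every pass; on final
  partitions the minimum eigengene dissimilarity can in principle fall
  slightly below the merge height after the last recomputation, though
  the loop only stops when no pair merges under the recomputed
  eigengenes.
- ORA is a generic hypergeometric test against user-supplied GMT
  collections; it does not ship any annotation database.
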