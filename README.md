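# comodnet

Signed weighted gene coexpression network analysis for bulk transcriptomic
designs with two genotypes, an injury contrast, and a post-injury time
course — the kind of experiment that compares wild-type and
immune-deficient (SCID, *Prkdc* mutant) mice before and after spinal cord
injury and asks which coordinated gene-expression programs differ, how
they evolve over time, and which of them track a behavioral readout such
as the Basso Mouse Scale (BMS) locomotor score.

## What it computes

Starting from a normalized genes × samples expression matrix:

1. **Network.** Pairwise gene Pearson correlations are soft-thresholded
   into a signed adjacency `a_ij = ((1 + cor_ij)/2)^β` (default β = 12),
   so anticorrelated genes get near-zero connection strength. Network
   interconnectedness is measured by the topological overlap

   `TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   with `L_ij = Σ_u a_iu a_uj` and connectivity `k_i = Σ_j a_ij`.
2. **Modules.** Genes are clustered by average linkage on `1 − TOM`; an
   adaptive cut of the dendrogram identifies branches of at least 30
   genes as modules (unassigned genes are "grey"). Each module is
   summarized by its eigengene — the first principal component of its
   standardized expression — and modules whose eigengenes are closer
   than 0.25 (on `1 − cor`) are merged iteratively. Final modules get the
   conventional size-ranked color names (turquoise, blue, brown, …).
3. **Membership and hubs.** kME (the correlation of every gene with every
   module eigengene) ranks intramodular hub genes; the top-30 hub
   connection network is exported in VisANT text format, and genes with
   kME > 0.75 are selected per module for gene-set over-representation
   (hypergeometric test, Benjamini–Hochberg adjustment).
4. **Traits.** Module eigengenes are correlated with the design
   covariates (genotype, injury, day post-injury, group one-hots, BMS)
   with t-based p-values and BH q-values; hub-gene module averages are
   summarized per time point and group, baseline-normalized to the
   uninjured wild-type group (which therefore sits exactly at 0); genes
   purely positively or negatively correlated with BMS in both genotype
   subsets are ranked; a `2^−ΔΔCt` helper supports qRT-PCR validation.

A planted-module simulator (`comodnet.simulate`) generates expression,
metadata, and ground-truth labels with the study's sample design
(10 WT-injured, 11 SCID-injured, 6 WT-uninjured, 4 SCID-uninjured, plus a
21-sample wild-type time course at days 1–42), so the whole pipeline is
testable without any external data.

## Worked example

```python
from comodnet import (default_spec, simulate_expression, write_fixture,
                      PipelineConfig, run_pipeline)

bundle = simulate_expression(default_spec(seed=1))
paths = write_fixture(bundle, "demo/data")
arts = run_pipeline(PipelineConfig(expression=paths["expression"],
                                   sample_info=paths["samples"],
                                   output_dir="demo/out"))
```

or, from a shell, `comodnet simulate --seed 1 --out demo/data` followed by
`comodnet run --expression demo/data/expression.tsv --sample-info
demo/data/samples.tsv --out-dir demo/out`. On the default simulation
(1,600 genes, 52 samples, nine planted modules plus 200 background genes)
the run reports nine modules:

```
modules initial->final: 9 -> 9
sizes: {'turquoise': 301, 'blue': 240, 'brown': 201, 'yellow': 160,
        'red': 120, 'black': 100, 'pink': 80, 'magenta': 60, 'green': 140}
```

`module_trait.tsv` holds the module–trait correlation grid. Here the
turquoise module (planted as an injury-induced, SCID-dampened immune-like
program) correlates +0.66 with injury and −0.84 with the BMS score, while
blue (planted as an injury-suppressed neurotransmission-like program)
shows the mirror pattern (+0.84 with BMS): animals whose
neurotransmission program stays high score better, and a strong immune
program accompanies poor locomotor scores. `timecourse.tsv` gives the
baseline-subtracted hub-gene means per day — turquoise jumps by +1.6–1.9
log-units in the first week and partially resolves, blue drops by −1.6
immediately after injury and recovers toward baseline:

```
module       0     1     3     7    14    28    42
turquoise    0  1.63  1.87  1.72  0.87  0.99  1.39
blue         0 -1.59 -1.31 -1.06 -1.06 -0.99 -0.73
```

`hub_genes.tsv` lists each module's top-30 kME-ranked hub genes, and
`hub_edges_<color>.visant.txt` their strongest TOM connections.

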