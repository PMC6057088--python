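# panelkit

Tools for building and evaluating haplotype reference panels on regionally
structured cohorts: cohort simulation, panel-construction QC,
haplotype-copying genotype imputation with leave-one-out evaluation, and
population-structure / haplotype-sharing analysis. It is aimed at
statistical geneticists who want a small, fully inspectable pipeline for
studying how panel composition, ancestry matching and allele frequency
drive imputation accuracy — on synthetic cohorts whose structure they
control, or on their own phased VCF / hap-legend-sample data.

## What it computes

- **Synthetic cohorts** (`panelkit.simpop`): phased haplotypes for several
  regional subpopulations produced by Wright–Fisher drift from a common
  founder pool (expected pairwise F_ST between regions with branch drifts
  g₁/2N₁ and g₂/2N₂ is their mean), plus planted parent–offspring pairs,
  depth-dependent sequencing-call errors and near-truth array calls.
- **Panel QC** (`panelkit.panel_qc`): per-individual read-depth thresholds
  calibrated to a 99.8% concordance target between sequencing and array
  calls; site filters (call rate ≥ 97%, Hardy–Weinberg exact p ≥ 1e-6,
  MAF ≥ 0.5%); method-of-moments identity-by-descent estimation
  (PI_HAT = P(IBD=1)/2 + P(IBD=2)) and pruning of pairs with
  PI_HAT > 0.125.
- **Imputation** (`panelkit.impute_engine`): the Li & Stephens
  haplotype-copying hidden Markov model — donor states, stay probability
  exp(−ρ) + (1−exp(−ρ))/K per interval, emission 1−ε on allele match —
  with silent untyped sites, per-site rescaling, haploid passes over
  pre-phased targets, and leave-one-out cross-validation that withholds
  both haplotypes of the focal sample.
- **Accuracy evaluation** (`panelkit.eval_pipeline`): per-variant r²
  (squared Pearson correlation of truth genotypes vs dosages), aggregate
  r² per non-reference-allele-frequency bin (pooled over pairs and as a
  per-variant mean), imputation coverage (fraction of variants with
  r² ≥ 0.8), reference-panel comparisons, a Fisher-exact regional
  allele-frequency screen (p < 1e-7), and novel-variant counts (absent
  from the panel, combined allele count ≥ 2).
- **Structure** (`panelkit.popstruct`, `panelkit.coancestry`): windowed LD
  pruning, PCA on standardized genotypes, Weir–Cockerham F_ST
  (genome-wide ratio of sums Σa/Σ(a+b+c)), and ChromoPainter-style
  expected-chunk-count coancestry matrices clustered by average linkage
  with silhouette-selected K.

## Worked example

One simulated chromosome cannot simultaneously look like a whole genome
to every estimator, so the generator exposes the linkage structure as
configuration: imputation wants long shared haplotype blocks
(`ld_coherence=1.0`, small recombination rate), while kinship estimation
wants many quasi-independent markers (`ld_coherence≈0.2`, larger rate).
See `docs/methods.md` for why.

```python
import numpy as np
from panelkit.simpop import RegionSpec, SimulationConfig, simulate_cohort
from panelkit.panel_qc import build_panel, prune_relatives, site_filter
from panelkit.impute_engine import HmmParams, loo_cross_validate
from panelkit.eval_pipeline import aggregate_accuracy

cfg = SimulationConfig(
    n_variants=8000,
    n_founder_haplotypes=400,
    recomb_rate_per_interval=2e-4,   # long shared segments
    regions=[RegionSpec("north", 60, 4, 200), RegionSpec("south", 60, 4, 200)],
    seed=7,
    array_fraction=0.25,
    planted_relative_pairs=0,
    ld_coherence=1.0,
)
cohort = simulate_cohort(cfg)
keep_sites, _ = site_filter(cohort.truth.genotypes())
panel = build_panel(cohort.truth, cohort.truth.samples["sample"].tolist(), keep_sites)
typed = cohort.array_site_mask[keep_sites]
dosages, _ = loo_cross_validate(panel, typed, HmmParams(2e-3, 1e-3))
result = aggregate_accuracy(panel.genotypes(), dosages, panel.alt_freq())
print(result.per_bin[["bin", "n_variants", "r2_pooled", "coverage"]].round(3).to_string(index=False))
```

prints

```
         bin  n_variants  r2_pooled  coverage
   (0,0.005]           0        NaN       NaN
(0.005,0.01]         148      0.357     0.020
 (0.01,0.02]         448      0.201     0.054
 (0.02,0.05]         873      0.788     0.551
  (0.05,0.1]         450      0.961     0.989
   (0.1,0.2]         410      0.968     0.995
   (0.2,0.5]         566      0.955     0.995
     (0.5,1]        2834      0.937     0.670
```

Each row is a panel non-reference-allele-frequency stratum of the
leave-one-out experiment: common variants impute almost perfectly
(pooled r² ≈ 0.96, ~99% of variants above the r² ≥ 0.8 confidence
threshold) while accuracy decays sharply below 5% frequency — with 240
panel haplotypes the rarest strata are singletons and doubletons, for
which a leave-one-out donor set carries little information.

Relatedness pruning runs on a weak-coherence cohort with a planted
parent–offspring pair:

```python
cfg_qc = SimulationConfig(
    n_variants=30000,
    n_founder_haplotypes=400,
    recomb_rate_per_interval=0.01,   # many quasi-independent blocks
    regions=[RegionSpec("north", 40, 2, 200), RegionSpec("south", 40, 10, 200)],
    seed=11,
    array_fraction=0.1,
    planted_relative_pairs=1,
    ld_coherence=0.2,
)
qc_cohort = simulate_cohort(cfg_qc)
prune = prune_relatives(qc_cohort.truth.genotypes())
print("removed:", prune.removed)
```

prints `removed: ['north_rel00']` — exactly the planted offspring
(PI_HAT ≈ 0.5 with each parent; every other pair stays below the 0.125
threshold). Building the panel from the 80 remaining samples and calling
`popstruct.fst_matrix` gives a north–south Weir–Cockerham F_ST of
0.0173, matching the simulated differentiation — branch drifts of
g/2N = 2/400 and 10/400, whose mean 0.015 is what pairwise θ estimates —
within sampling error.

There is also a CLI for file-based workflows — `panelkit simulate | qc |
impute | evaluate | structure | coancestry | screen | run-all` — where
`run-all` executes the whole chain from one YAML config and writes the
panel (hap/legend/sample), QC reports, per-bin accuracy, F_ST matrix and
cluster assignments with a provenance stamp.

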