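# Methods

`panelkit` implements a complete desk-scale analogue of a regional
haplotype-reference-panel study: simulate structured cohorts, apply the
panel-construction QC, impute masked genotypes with a haplotype-copying
model, and quantify accuracy, population structure and haplotype sharing.
This note records the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Synthetic cohorts (`simpop`)

**What it emulates.** Paired sequencing + array genotype data for several
regional subpopulations of one ancestral population, with differentiation
of the magnitude seen between regions of a single country
(F_ST ~ 1e-4 .. 2e-3 between pairs), a small number of cryptic close
relatives, and depth-dependent genotype-calling noise.

**Founders.** Site non-reference frequencies follow a neutral spectrum,
density proportional to 1/x on (1/n_haplotypes, 0.5], with random ref/alt
orientation. Linkage comes from a 20-lineage recombinant mosaic: every
haplotype follows a Markov path over 20 ancestral lineages with switch
probability `recomb_rate_per_interval` per inter-site interval. Alleles
are then dropped onto this structure site by site: the carrier count k is
drawn from the target spectrum (Binomial(n, p) conditioned on
segregating), and the carriers are the k haplotypes whose persistent
lineage-derived keys are nearest a focal point that itself renews at the
recombination scale. Within a block the carrier sets of different sites
are therefore nested by frequency — the local perfect-phylogeny structure
real genealogies produce, and the reason untyped sites are predictable
from typed ones at all. A fraction (1 − `ld_coherence`) of sites instead
receive uniformly random carriers.

**The coherence dial.** A short simulated chromosome cannot present both
faces of a whole genome at once. Nested carrier blocks are what the
copying model exploits, but they also make pairwise identity-by-state
counts fluctuate block-wise, inflating the noise of moment-based kinship
estimates far beyond the genome-wide analogue. Imputation fixtures
therefore run with `ld_coherence = 1.0` and a small per-interval
recombination rate (shared segments span several typed sites), while
relatedness fixtures run with `ld_coherence ≈ 0.2` and a larger rate
(tens of thousands of quasi-independent markers). The default, 0.5, is a
middle ground for end-to-end runs. Real data satisfy both regimes
simultaneously because they have orders of magnitude more sites.

**Drift.** Each region evolves an independent Wright–Fisher population
(no new mutation — every regional variant is a founder variant, which the
novel-variant accounting relies on) for g generations at diploid size N;
expected differentiation per branch is 1 − (1 − 1/2N)^g ≈ g/2N, and the
pairwise Weir–Cockerham θ between two regions estimates the mean of the
two branch drifts. Default regions mirror a 1070/136/39/36 four-region
design with g/2N tuned to the small inter-regional magnitudes above.

**Expansion.** After drift, `expansion_generations` (default 3) rounds of
infinite-population random mating are applied before sampling the cohort:
every ancestor in the expansion pedigree is a fresh individual, generated
lazily, so allele frequencies (hence F_ST) are untouched but no sampled
pair can share an ancestor more recently than `expansion + 1` meioses.
Without this, Wright–Fisher populations of effective size a few hundred to
a few thousand contain many genuine siblings and half-siblings in any
large sample — real cohorts are drawn from census populations orders of
magnitude larger than the drift effective size, and the expansion phase is
the cheap way to represent that. Three generations push incidental
kinship below PI_HAT ~ 0.02, comfortably under the 0.125 pruning
threshold.

**Relatives.** Planted pairs append one offspring built from one
recombinant gamete of each of two existing parents; both (parent,
offspring) relationships are recorded with gamete provenance. Expected
PI_HAT is exactly 0.5.

**Genotyping layers.** Read depth is Poisson(`mean_depth`) per site and
sample; calls below `missing_below` are missing; otherwise the truth
genotype is miscalled (to a uniformly chosen different genotype) with
probability `error_curve(depth)`, a non-increasing function. The default
is a step curve: 5% below depth 8, 0.05% above — no quantitative error
model is published for this kind of data, so the curve is a fixture
choice, and everything downstream treats it as configuration. Array calls
cover a common-variant-biased subset (MAF ≥ 0.05, Bernoulli-thinned to
`array_fraction`) with a depth-independent 1e-3 error: array data are
near-truth, and a zero error rate would make concordance calibration
degenerate.

**Determinism.** One master seed; each stage (founders, drift, relatives,
genotyping, array selection) derives its own stream by a fixed offset, so
identical configurations give bit-identical cohorts and every stage is
independently reproducible.

## Panel QC (`panel_qc`)

*Depth calibration.* For each individual, integer depth thresholds
t = 0, 1, 2, … are scanned; genotypes below t become missing and
concordance is the match fraction at sites called on both platforms (the
denominator is sites non-missing in both — the natural reading where none
is prescribed). The smallest t with concordance ≥ 99.8% is selected;
when no admissible t reaches the target, the maximizing t is returned
with an `attainable=False` flag. Thresholds that leave fewer than
`min_sites` (default 100) comparable sites are inadmissible — tiny
denominators reach any target by chance. The target is applied per
individual.

*Site filters.* A site is excluded iff call rate < 97.0%, Hardy–Weinberg
exact p < 1e-6, or MAF < 0.5% — all strict inequalities. The HWE test is
the standard two-sided conditional exact test: given the allele counts,
the probabilities of all heterozygote counts no more likely than the
observed one are summed.

*Relatedness.* PI_HAT = P(IBD=1)/2 + P(IBD=2) by method of moments from
identity-by-state counts at MAF ≥ 0.05 co-called sites. The expected
IBS-by-IBD probabilities are computed without replacement from the
cohort's observed allele counts (hypergeometric forms rather than the
textbook 2p²q² expressions); with plug-in frequencies estimated from the
same cohort, the naive expectations bias PI_HAT upward by O(1/n). IBD
probabilities are truncated to [0, 1] and renormalized. Even so, the
estimator's sampling noise is material at desk scale: tens of thousands
of sites keep the unrelated-pair distribution safely below the 0.125
threshold, and fixture sizes in the tests are chosen accordingly.

*Pruning.* Pairs with PI_HAT strictly above 0.125 form a graph that is
resolved greedily: remove the sample in the most flagged pairs, breaking
ties by lower call rate and then by lexicographically later label, until
no pair remains. For an isolated pair this is "drop the lower-call-rate
member"; for a planted parent/parent/offspring triad it removes exactly
the offspring, matching the one-sample-per-flagged-family outcome a
per-pair rule cannot guarantee.

## Haplotype-copying imputation (`impute_engine`)

The Li & Stephens model: the hidden state is the donor haplotype being
copied; across each inter-site interval the chain stays with probability
exp(−ρ) + (1 − exp(−ρ))/K and switches to each other donor with
(1 − exp(−ρ))/K. Typed sites emit the observed allele with probability
1 − ε (default ε = 1e-3); untyped sites are silent (emission 1), so one
forward–backward pass handles typed and untyped sites alike — untyped
sites are not interpolated post hoc. The allele-1 probability at any site
is ε + (1 − 2ε) Σ_k γ_k a_k. Forward and backward vectors are rescaled
per site; 1e5-site haplotypes run without underflow.

Targets are imputed haploid (two passes per pre-phased sample; dosage =
sum, typed sites keep the observed genotype). Unphased heterozygous input
is rejected: pre-phasing is a separate concern and both the simulation
and real phased panels provide haplotypes. ρ per interval defaults to the
conventional 4·Ne·r/K; at the simulated scales Ne in the low hundreds
keeps ρ ≪ 1 for typical donor counts. ρ of order the per-meiosis
recombination rate times the drift depth matches the IBD segment scale
the simulation produces; all evaluation fixtures pass ρ explicitly.

Leave-one-out cross-validation removes **both** haplotypes of the focal
sample from the donor set, imputes it from its array-typed alleles, and
restores it — every panel sample is evaluated against a panel that never
contains its own haplotypes.

## Population structure (`popstruct`)

LD pruning removes sites with missingness > 0.1 or MAF < 0.05, then scans
left-to-right dropping the later member of any pair within a sliding
window (default 50 kept sites) whose genotype r² exceeds 0.8. The outcome
depends on site order (documented), never on sample order.

PCA mean-imputes missing genotypes per site, centers at 2p̂ and scales by
√(2p̂(1−p̂)), and eigendecomposes the sample covariance; the sign
convention makes the largest-magnitude score entry positive.

F_ST is the Weir–Cockerham (1984) two-population variance-components
estimator with the observed-heterozygosity term; the genome-wide value is
the ratio of sums Σa / Σ(a+b+c) (ratio of averages, the PLINK
convention), never the mean of per-site ratios. Sites where either
population has fewer than two called samples contribute nothing;
per-site estimates may be negative.

## Coancestry (`coancestry`)

Chromosome painting runs the copying HMM over fully typed haplotypes and
accumulates, per donor, the expected number of contiguous copying
segments: γ at the first site plus the expected switch-entry mass
Σ_m P(state_m = k, state_{m−1} ≠ k). Donors belonging to the recipient's
own individual are excluded. The individual-by-individual chunk matrix is
symmetrized, row-normalized and clustered by average-linkage agglomeration
under correlation distance, with K selected by maximum silhouette over
2..k_max (K = 1 when the best silhouette is below 0.1). This replaces an
MCMC partition sampler deliberately: the deliverable is the cluster
structure, and a deterministic procedure makes the recovery checks exact.
The four-region recovery fixture uses per-branch drift of g/2N ≈
0.025–0.04 — painting at 3,000 sites and 40 individuals per region needs
markedly more signal than the real study's genome-wide haplotypes, where
the same block structure is visible at F_ST ~ 1e-3.

## Evaluation (`eval_pipeline`)

Per-variant accuracy is the squared Pearson correlation between truth
genotypes {0,1,2} and dosages [0,2]; variants whose truth or dosage
vector is constant are undefined and excluded (not zero). Typed sites
never enter accuracy aggregation. Per frequency bin — half-open (lo, hi]
intervals of panel non-reference allele frequency, default edges 0,
0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1 — two aggregates are reported:
pooled r² over all (variant, sample) pairs, and the mean of defined
per-variant r². The published convention is ambiguous between them, so
both are always emitted; pooled is the default headline. Coverage is the
fraction of defined per-variant r² at or above 0.8 (inclusive).

The regional differentiation screen tests each shared segregating site's
2×2 allele-count table with a two-sided Fisher exact test (the smallest-
assumption exact choice at these sample sizes; the source analysis names
no test) and reports sites with p < 1e-7. Novel-variant accounting counts
sites keyed by (contig, position, ref, alt) that are absent from the
panel and have combined alternate-allele count ≥ 2 across the query
cohorts; per-region totals count the novel sites each region carries.

## Fixture scales and what passing means

Everything runs on a single simulated chromosome with tens of thousands
of sites and cohorts of tens to ~1,300 samples — two to five orders of
magnitude below the study scale the pipeline is modeled on. Directional
claims (accuracy falls from common to rare variants; panel augmentation
helps rare variants; ancestry-matched panels beat mismatched ones) are
therefore tested at regional differentiation of g/2N ≈ 0.01, where the
rare-haplotype sharing signal is resolvable with hundred-sample panels;
at the real inter-regional magnitudes (1e-4..2e-3) those contrasts would
need the study's sample and marker counts. Passing these tests shows the
estimators and the machinery behave correctly and in the claimed
directions on data with the modeled structure; it does not calibrate
absolute accuracy for any real cohort. The synthetic data also omit:
genotyping batch effects, a genetic map (recombination is uniform),
indels and multi-allelic sites, allele-frequency ascertainment of real
arrays beyond a MAF floor, and phasing error (truth phase is exact).

## Numerical notes

- HWE exact test: log-gamma arithmetic; ties in the "no more probable"
  rule use a 1e-12 relative tolerance. Agreement with exact rational
  enumeration is at 1e-12 for totals ≤ 200.
- Forward–backward: per-site rescaling; donor posteriors sum to 1 within
  1e-9; equality with exhaustive path enumeration within 1e-10 for K ≤ 3,
  ≤ 6 sites.
- Recombination masks are sampled sparsely (Binomial crossover counts,
  uniform positions, parity by wrap-safe uint8 prefix sums), equivalent to
  independent per-interval switches up to coincident-position draws.
- Pairwise PI_HAT uses float32 indicator mat-muls (exact for counts below
  2^24) and a complete-data fast path for the expectation sums.
- Degenerate inputs: constant genotype matrices are rejected by PCA;
  monomorphic sites contribute nothing to F_ST; empty frequency bins are
  reported with count 0 and undefined r².
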