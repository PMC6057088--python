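"""Forward-time simulation of regionally structured haplotype cohorts.

The generator emulates the statistical structure a multi-region human
sequencing cohort possesses: a shared founder pool with a neutral
frequency spectrum and block-wise linkage, independent Wright–Fisher
drift per region (no new mutation, so every regional variant is a subset
of the founder variants), planted parent–offspring relatives, and a
depth-dependent genotype-calling error layer paired with near-truth
SNP-array calls at a common-variant-biased site subset.

Regional differentiation after ``g`` generations of drift at diploid
size ``N`` is ``F_ST ~ 1 - (1 - 1/2N)^g ~ g/2N``, which is the dial used
to reproduce the magnitude and rank order of real inter-regional
fixation indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, HaplotypePanel
from .errors import EmptyMaskError, InvalidConfigError

#: Number of ancestral lineages in the founder mosaic.
N_SEED_LINEAGES = 20

# Fixed per-stage seed offsets: every pipeline stage draws from its own
# stream so stages are independently reproducible under one master seed.
_STAGE_OFFSET = {
    "founders": 0,
    "drift": 1_000_003,
    "relatives": 2_000_003,
    "genotyping": 3_000_003,
    "array_sites": 4_000_003,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + _STAGE_OFFSET[stage]) % (2**31)


@dataclass
class RegionSpec:
    """Sampling design for one regional subpopulation."""

    name: str
    n_samples: int
    drift_generations: int
    effective_size: int

    def validate(self) -> None:
        if self.n_samples < 1:
            raise InvalidConfigError(f"region {self.name}: n_samples < 1")
        if self.drift_generations < 0:
            raise InvalidConfigError(f"region {self.name}: negative generations")
        if self.effective_size < self.n_samples:
            raise InvalidConfigError(
                f"region {self.name}: effective_size < n_samples"
            )

    @property
    def expected_fst(self) -> float:
        """Closed-form drift expectation 1 - (1 - 1/2N)^g."""
        return 1.0 - (1.0 - 1.0 / (2 * self.effective_size)) ** self.drift_generations


def default_regions() -> list[RegionSpec]:
    """Four-region design mirroring a large north-east cohort plus three
    smaller regional cohorts, with drift tuned to fixation indices of a
    few 1e-4 .. 2e-3 between pairs."""
    return [
        RegionSpec("miyagi", 1070, 1, 5000),
        RegionSpec("iwate", 136, 4, 5000),
        RegionSpec("nagahama", 39, 5, 5000),
        RegionSpec("aki", 36, 15, 5000),
    ]


@dataclass
class DepthErrorModel:
    """Depth-dependent genotype miscall model for sequencing calls.

    ``error_curve`` maps read depth to a per-genotype miscall probability
    and must be non-increasing in depth with values in [0, 0.5]; calls
    below ``missing_below`` are emitted as missing.
    """

    mean_depth: float = 10.0
    error_curve: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    missing_below: int = 1

    def __post_init__(self) -> None:
        if self.error_curve is None:
            self.error_curve = step_error_curve(8, 0.05, 0.0005)

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise InvalidConfigError("mean_depth must be positive")
        if self.missing_below < 0:
            raise InvalidConfigError("missing_below must be >= 0")
        probe = self.error_curve(np.arange(0, 101))
        if probe.min() < 0 or probe.max() > 0.5:
            raise InvalidConfigError("error probabilities must lie in [0, 0.5]")
        if np.any(np.diff(probe) > 1e-12):
            raise InvalidConfigError("error curve must be non-increasing in depth")


def step_error_curve(
    depth_threshold: int, low_depth_error: float, high_depth_error: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Two-level error curve: ``low`` below the depth threshold, ``high`` at
    or above it (the shape used throughout the calibration fixtures)."""

    def curve(depth: np.ndarray) -> np.ndarray:
        depth = np.asarray(depth)
        return np.where(depth < depth_threshold, low_depth_error, high_depth_error)

    return curve


@dataclass
class SimulationConfig:
    n_variants: int = 5000
    n_founder_haplotypes: int = 400
    recomb_rate_per_interval: float = 0.01
    regions: list[RegionSpec] = field(default_factory=default_regions)
    seed: int = 2020
    array_fraction: float = 0.03
    planted_relative_pairs: int = 1
    #: fraction of founder sites whose carriers follow the lineage-key
    #: windows (linked); the rest are assigned uniformly at random.
    ld_coherence: float = 0.5
    #: post-drift generations of infinite-population random mating (all
    #: parents distinct) before the cohort is sampled: differentiation is
    #: untouched (no drift at infinite size) but shared ancestry is pushed
    #: back, so sampled cohorts contain no incidental close relatives.
    expansion_generations: int = 3

    def validate(self) -> None:
        if not 0.0 <= self.ld_coherence <= 1.0:
            raise InvalidConfigError("ld_coherence outside [0, 1]")
        if self.expansion_generations < 0:
            raise InvalidConfigError("expansion_generations must be >= 0")
        if self.n_variants < 2 or self.n_founder_haplotypes < 2:
            raise InvalidConfigError("need >= 2 variants and >= 2 founder haplotypes")
        if self.n_founder_haplotypes % 2:
            raise InvalidConfigError("n_founder_haplotypes must be even")
        if not 0.0 <= self.recomb_rate_per_interval <= 0.5:
            raise InvalidConfigError("recomb rate per interval outside [0, 0.5]")
        if not 0.0 < self.array_fraction < 1.0:
            raise InvalidConfigError("array_fraction outside (0, 1)")
        if self.planted_relative_pairs < 0:
            raise InvalidConfigError("planted_relative_pairs must be >= 0")
        if not self.regions:
            raise InvalidConfigError("at least one region required")
        for r in self.regions:
            r.validate()


@dataclass
class Cohort:
    """Simulated cohort: phased truth plus both genotyping layers."""

    truth: HaplotypePanel
    array_calls: GenotypeMatrix  # restricted to array sites
    ngs_calls: GenotypeMatrix  # all sites, with depth-dependent errors
    depths: np.ndarray  # (n_sites, n_samples) read depth
    array_site_mask: np.ndarray  # bool over all sites
    relative_pairs: list[tuple[str, str, str]]
    provenance: dict


# ---------------------------------------------------------------------------
# founders


def _persistent_values(rng, draw, n_rows: int, n_cols: int, renew_rate: float):
    """Markov-persistent columns: each entry keeps the previous row's value
    and renews (fresh draw) with probability ``renew_rate`` per interval."""
    values = draw((n_rows, n_cols))
    if n_rows == 1:
        return values
    renew = np.empty((n_rows, n_cols), dtype=bool)
    renew[0] = True
    renew[1:] = rng.random((n_rows - 1, n_cols), dtype=np.float32) < renew_rate
    idx = np.where(renew, np.arange(n_rows)[:, None], 0)
    np.maximum.accumulate(idx, axis=0, out=idx)
    return np.take_along_axis(values, idx, axis=0)


def _random_alleles(rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def simulate_founders(config: SimulationConfig) -> HaplotypePanel:
    """Generate the segregating founder haplotype pool.

    Site non-reference frequencies follow a neutral spectrum (density
    proportional to 1/x on ``(1/n_haplotypes, 0.5]``, then random ref/alt
    orientation).  Linkage: each haplotype follows a recombinant mosaic
    path over ``N_SEED_LINEAGES`` ancestral lineages (switch probability
    ``recomb_rate_per_interval`` per inter-site interval) and the carriers
    of each allele are chosen lineage-coherently, so allele sharing decays
    with site distance at the recombination scale while realized carrier
    counts are drawn exactly from the target spectrum (every site
    segregates).
    """
    config.validate()
    m, n_hap = config.n_variants, config.n_founder_haplotypes
    r = max(config.recomb_rate_per_interval, 1e-9)
    rng = np.random.default_rng(stage_seed(config.seed, "founders"))

    paths = _persistent_values(
        rng,
        lambda s: rng.integers(0, N_SEED_LINEAGES, size=s, dtype=np.int8),
        m,
        n_hap,
        r,
    )
    lineage_keys = _persistent_values(
        rng, lambda s: rng.random(s), m, N_SEED_LINEAGES, r
    )
    hap_jitter = _persistent_values(rng, lambda s: rng.random(s), m, n_hap, r)

    # carrier counts from the target SFS, conditioned on segregating
    k = np.zeros(m, dtype=np.int64)
    pending = np.arange(m)
    log_lo, log_hi = np.log(1.0 / n_hap), np.log(0.5)
    while pending.size:
        p = np.exp(rng.uniform(log_lo, log_hi, size=pending.size))
        draw = rng.binomial(n_hap, p)
        ok = (draw >= 1) & (draw <= n_hap - 1)
        k[pending[ok]] = draw[ok]
        pending = pending[~ok]

    # Haplotype keys: lineage key of the mosaic path plus a small jitter,
    # on the unit circle.  Nearby sites share the key layout (linkage) and
    # a persistent focal point (renewing at the recombination scale), so
    # carrier sets within a block are nested by frequency — the local
    # perfect-phylogeny structure real genealogies produce, which is what
    # makes untyped sites predictable from typed ones.  A fraction
    # (1 - ld_coherence) of sites instead get uniformly random carriers,
    # bounding the pairwise-coancestry noise fully clustered carriers
    # would induce.
    keys = np.take_along_axis(lineage_keys, paths.astype(np.intp), axis=1)
    keys = (keys + 0.05 * hap_jitter) % 1.0
    focal = _persistent_values(rng, lambda s: rng.random(s), m, 1, r)
    dist = np.abs(keys - focal)
    dist = np.minimum(dist, 1.0 - dist)
    random_sites = rng.random(m) >= config.ld_coherence
    dist[random_sites] = rng.random((int(random_sites.sum()), n_hap))
    ranks = np.empty((m, n_hap), dtype=np.int32)
    order = np.argsort(dist, axis=1, kind="stable")
    np.put_along_axis(ranks, order, np.arange(n_hap, dtype=np.int32)[None, :], axis=1)
    alleles = (ranks < k[:, None]).astype(np.int8)

    flip = rng.random(m) < 0.5
    alleles[flip] = 1 - alleles[flip]

    ref, alt = _random_alleles(rng, m)
    variants = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(m)],
            "contig": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * 100,
            "ref": ref,
            "alt": alt,
        }
    )
    samples = pd.DataFrame(
        {
            "sample": [f"founder_{i:04d}" for i in range(n_hap // 2)],
            "region": "founders",
        }
    )
    return HaplotypePanel(alleles, variants, samples)


# ---------------------------------------------------------------------------
# drift


def _recombine(rng, h0: np.ndarray, h1: np.ndarray, rate: float) -> np.ndarray:
    """One gamete per column: a recombinant mosaic of the column pair.

    Crossover counts per gamete are Binomial(m - 1, rate) with uniform
    interval positions (equivalent to independent per-interval switches up
    to the negligible chance of coincident draws); the copy phase is the
    crossover-count parity, computed with a wraparound-safe uint8 prefix
    sum so even chromosome-scale gamete blocks stay cheap.
    """
    m, g = h0.shape
    start = rng.integers(0, 2, size=g, dtype=np.int8).astype(bool)
    if m == 1 or rate <= 0:
        return np.where(start[None, :], h1, h0)
    counts = rng.binomial(m - 1, rate, size=g)
    total = int(counts.sum())
    crossings = np.zeros((m, g), dtype=np.uint8)
    if total:
        cols = np.repeat(np.arange(g), counts)
        rows = rng.integers(1, m, size=total)
        np.add.at(crossings, (rows, cols), 1)
    np.cumsum(crossings, axis=0, out=crossings)  # parity survives mod-256 wrap
    phase = (crossings & 1).astype(bool)
    phase ^= start[None, :]
    return np.where(phase, h1, h0)


def _expand(rng, pool: np.ndarray, n_haps_out: int, generations: int, rate: float):
    """Sample ``n_haps_out`` haplotypes after ``generations`` rounds of
    infinite-population random mating rooted in ``pool``.

    Every ancestor in the expansion pedigree is a fresh individual (the
    recent population is treated as unbounded), so sampled cohorts share
    ancestry only through the pool ``generations + 1`` meioses back: no
    incidental siblings or half-siblings, while allele frequencies (and
    hence differentiation) are untouched.
    """
    if generations == 0:
        return pool[:, rng.integers(0, pool.shape[1], size=n_haps_out)].copy()
    count = n_haps_out * (2**generations)
    haps = pool[:, rng.integers(0, pool.shape[1], size=count)].copy()
    while count > n_haps_out:
        haps = _recombine(rng, haps[:, 0::2], haps[:, 1::2], rate)
        count //= 2
    return haps


def drift_split(
    founders: HaplotypePanel,
    regions: Sequence[RegionSpec],
    recomb_rate: float,
    seed: int,
    expansion_generations: int = 3,
) -> HaplotypePanel:
    """Evolve one independent Wright–Fisher population per region.

    Each region starts from a with-replacement draw of ``2 * effective_size``
    founder haplotypes, runs ``drift_generations`` generations of random
    mating with recombination (no new mutation), expands for
    ``expansion_generations`` at unbounded size (see :func:`_expand`), then
    samples ``n_samples`` diploids.  With zero drift generations the
    regional sample is an i.i.d. draw from the founder pool.  Sites fixed
    within a region are retained — they may still segregate elsewhere.
    """
    if not regions:
        raise InvalidConfigError("empty region list")
    for spec in regions:
        spec.validate()
    blocks: list[np.ndarray] = []
    names: list[str] = []
    labels: list[str] = []
    n_founder_haps = founders.n_haplotypes
    for index, spec in enumerate(regions):
        rng = np.random.default_rng([int(seed) % (2**31), index])
        if spec.drift_generations == 0:
            cols = rng.integers(0, n_founder_haps, size=2 * spec.n_samples)
            haps = founders.haplotypes[:, cols].copy()
        else:
            n = spec.effective_size
            pool = founders.haplotypes[
                :, rng.integers(0, n_founder_haps, size=2 * n)
            ].copy()
            for _ in range(spec.drift_generations):
                parents = rng.integers(0, n, size=2 * n)
                pool = _recombine(
                    rng, pool[:, 2 * parents], pool[:, 2 * parents + 1], recomb_rate
                )
            haps = _expand(
                rng, pool, 2 * spec.n_samples, expansion_generations, recomb_rate
            )
        blocks.append(haps)
        names.extend(f"{spec.name}_{i:04d}" for i in range(spec.n_samples))
        labels.extend([spec.name] * spec.n_samples)
    samples = pd.DataFrame({"sample": names, "region": labels})
    return HaplotypePanel(np.hstack(blocks), founders.variants.copy(), samples)


# ---------------------------------------------------------------------------
# relatives


def plant_relatives(
    panel: HaplotypePanel, n_pairs: int, recomb_rate: float, seed: int
) -> tuple[HaplotypePanel, list[tuple[str, str, str]], dict]:
    """Append one offspring per planted pair.

    The offspring receives one recombinant gamete from each of two
    distinct existing parents, so it shares at least one allele identical
    by descent with each parent at every site.  Both (parent, offspring,
    "PO") relationships are recorded, together with gamete provenance
    (which parental haplotype was transmitted at each site).
    """
    if n_pairs < 0:
        raise InvalidConfigError("n_pairs must be >= 0")
    if n_pairs == 0:
        return panel, [], {}
    if panel.n_samples < 2 * n_pairs:
        raise InvalidConfigError("need two unrelated parents per planted pair")
    rng = np.random.default_rng(int(seed) % (2**31))
    parent_idx = rng.choice(panel.n_samples, size=2 * n_pairs, replace=False)
    new_haps = [panel.haplotypes]
    rows = panel.samples.to_dict("records")
    pairs: list[tuple[str, str, str]] = []
    provenance: dict = {}
    m = panel.n_sites
    for j in range(n_pairs):
        a, b = int(parent_idx[2 * j]), int(parent_idx[2 * j + 1])
        name_a = panel.samples["sample"].iat[a]
        name_b = panel.samples["sample"].iat[b]
        child = f"{panel.samples['region'].iat[a]}_rel{j:02d}"
        gametes = []
        phases = []
        for parent in (a, b):
            c0, c1 = panel.sample_columns(parent)
            h0 = panel.haplotypes[:, c0 : c0 + 1]
            h1 = panel.haplotypes[:, c1 : c1 + 1]
            gam = _recombine(rng, h0, h1, recomb_rate)
            # recover which parental haplotype was copied where
            phase = np.where(gam[:, 0] == h1[:, 0], 1, 0)
            phase[h0[:, 0] == h1[:, 0]] = -1  # indistinguishable at IBS-equal sites
            gametes.append(gam)
            phases.append(phase)
        new_haps.append(np.hstack(gametes))
        rows.append({"sample": child, "region": panel.samples["region"].iat[a]})
        pairs.append((name_a, child, "PO"))
        pairs.append((name_b, child, "PO"))
        provenance[child] = {
            "parents": (name_a, name_b),
            "phase_a": phases[0],
            "phase_b": phases[1],
        }
    out = HaplotypePanel(
        np.hstack(new_haps), panel.variants.copy(), pd.DataFrame(rows)
    )
    return out, pairs, provenance


# ---------------------------------------------------------------------------
# genotyping layers


def genotype_with_errors(
    truth: HaplotypePanel,
    model: DepthErrorModel,
    seed: int,
    array_site_mask: np.ndarray,
    array_error: float = 1e-3,
) -> tuple[GenotypeMatrix, np.ndarray, GenotypeMatrix]:
    """Derive NGS-style calls (depth-dependent errors and missingness) and
    near-truth array calls from the truth haplotypes.

    Depth per (site, sample) is Poisson(``mean_depth``); a call is missing
    below ``missing_below`` and otherwise miscalled (to a uniformly chosen
    different genotype) with probability ``error_curve(depth)``.  Array
    calls cover only the array sites with a small depth-independent error.
    """
    model.validate()
    rng = np.random.default_rng(int(seed) % (2**31))
    g_truth = truth.genotypes().genotypes
    m, s = g_truth.shape

    depths = rng.poisson(model.mean_depth, size=(m, s))
    err = model.error_curve(depths)
    miscall = rng.random((m, s)) < err
    shifted = ((g_truth + rng.integers(1, 3, size=(m, s))) % 3).astype(np.int8)
    ngs = np.where(miscall, shifted, g_truth).astype(np.int8)
    ngs[depths < model.missing_below] = MISSING
    ngs_gm = GenotypeMatrix(ngs, truth.variants.copy(), truth.samples.copy())

    array_site_mask = np.asarray(array_site_mask, dtype=bool)
    g_arr = g_truth[array_site_mask].copy()
    arr_miscall = rng.random(g_arr.shape) < array_error
    arr_shift = ((g_arr + rng.integers(1, 3, size=g_arr.shape)) % 3).astype(np.int8)
    g_arr = np.where(arr_miscall, arr_shift, g_arr).astype(np.int8)
    array_gm = GenotypeMatrix(
        g_arr, truth.variants[array_site_mask].copy(), truth.samples.copy()
    )
    return ngs_gm, depths, array_gm


def select_array_sites(
    variants: pd.DataFrame, array_fraction: float, maf_min: float = 0.05, seed: int = 0
) -> np.ndarray:
    """Bernoulli-sample array-typed sites among those with MAF >= ``maf_min``,
    biasing the array toward common variation as genotyping arrays do."""
    if "maf" not in variants.columns:
        raise InvalidConfigError("variant stats must carry a 'maf' column")
    eligible = np.asarray(variants["maf"] >= maf_min)
    if not eligible.any():
        raise EmptyMaskError(f"no site has MAF >= {maf_min}")
    rng = np.random.default_rng(int(seed) % (2**31))
    mask = np.zeros(len(variants), dtype=bool)
    mask[eligible] = rng.random(int(eligible.sum())) < array_fraction
    return mask


# ---------------------------------------------------------------------------
# one-call driver


def simulate_cohort(
    config: SimulationConfig, depth_model: DepthErrorModel | None = None
) -> Cohort:
    """Run every simulation stage under one master seed.

    Identical configs produce bit-identical cohorts: each stage draws from
    a stream derived from the master seed by a fixed offset.
    """
    config.validate()
    model = depth_model or DepthErrorModel()
    founders = simulate_founders(config)
    truth = drift_split(
        founders,
        config.regions,
        config.recomb_rate_per_interval,
        stage_seed(config.seed, "drift"),
        expansion_generations=config.expansion_generations,
    )
    truth, pairs, provenance = plant_relatives(
        truth,
        config.planted_relative_pairs,
        config.recomb_rate_per_interval,
        stage_seed(config.seed, "relatives"),
    )
    from .containers import variant_stats

    stats = variant_stats(truth.genotypes())
    array_mask = select_array_sites(
        stats, config.array_fraction, seed=stage_seed(config.seed, "array_sites")
    )
    ngs, depths, array_calls = genotype_with_errors(
        truth, model, stage_seed(config.seed, "genotyping"), array_mask
    )
    return Cohort(
        truth=truth,
        array_calls=array_calls,
        ngs_calls=ngs,
        depths=depths,
        array_site_mask=array_mask,
        relative_pairs=pairs,
        provenance=provenance,
    )
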