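"""Imputation-accuracy evaluation and regional variant screens.

Headline computations: per-variant and frequency-stratified aggregate
r^2 between true genotypes (0/1/2) and imputed dosages ([0, 2]),
imputation coverage (fraction of variants with r^2 >= 0.8), reference-
panel composition comparisons, a Fisher-exact allele-frequency
differentiation screen between regions, and novel-variant accounting
(variants present in other cohorts but absent from the panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .containers import (
    MISSING,
    DosageMatrix,
    GenotypeMatrix,
    HaplotypePanel,
)
from .errors import InvalidConfigError, SiteMismatchError
from .impute_engine import HmmParams, impute_cohort, loo_cross_validate

DEFAULT_BIN_EDGES = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class FrequencyBinSpec:
    """Half-open (lo, hi] bins over panel non-reference allele frequency."""

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def validate(self) -> None:
        e = np.asarray(self.edges)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise InvalidConfigError("bin edges must be strictly increasing")

    def assign(self, freq: np.ndarray) -> np.ndarray:
        """Bin index per frequency; -1 for frequencies outside (lo0, hiN]."""
        self.validate()
        e = np.asarray(self.edges)
        idx = np.searchsorted(e, freq, side="left") - 1
        idx[(freq <= e[0]) | (freq > e[-1]) | ~np.isfinite(freq)] = -1
        return idx

    def labels(self) -> list[str]:
        return [
            f"({self.edges[i]:g},{self.edges[i + 1]:g}]"
            for i in range(len(self.edges) - 1)
        ]


@dataclass
class EvaluationResult:
    per_variant: pd.DataFrame  # site-level: freq, bin, r2, n_pairs
    per_bin: pd.DataFrame  # bin-level: n_variants, r2_pooled, r2_mean, coverage


@dataclass
class NovelSnpSummary:
    per_region: pd.DataFrame  # region, n_samples, total, per_person
    min_ac: int


def variant_r2(truth: np.ndarray, dosage: np.ndarray) -> float:
    """Squared Pearson correlation of truth genotypes vs dosages.

    Missing truth entries are dropped; returns NaN (undefined — the
    variant is excluded from aggregation, not counted as zero) when fewer
    than two pairs remain or either vector is constant.
    """
    truth = np.asarray(truth, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if truth.shape != dosage.shape:
        raise ValueError("truth and dosage vectors differ in length")
    ok = truth != MISSING
    t, d = truth[ok], dosage[ok]
    if t.size < 2 or np.ptp(t) == 0 or np.ptp(d) == 0:
        return float("nan")
    r = np.corrcoef(t, d)[0, 1]
    return float(r * r)


def _pooled_r2(truth: np.ndarray, dosage: np.ndarray) -> float:
    ok = truth != MISSING
    t, d = truth[ok].astype(float), dosage[ok]
    if t.size < 2 or np.ptp(t) == 0 or np.ptp(d) == 0:
        return float("nan")
    r = np.corrcoef(t, d)[0, 1]
    return float(r * r)


def aggregate_accuracy(
    truth: GenotypeMatrix,
    dosages: DosageMatrix,
    panel_freq: np.ndarray,
    bins: FrequencyBinSpec | None = None,
    coverage_threshold: float = 0.8,
) -> EvaluationResult:
    """Frequency-stratified imputation accuracy.

    Only imputed (untyped) sites enter: typed sites were given, not
    inferred.  Two aggregate modes are reported per bin: ``r2_pooled``
    (one Pearson r^2 over all (variant, sample) pairs in the bin, the
    conventional "aggregate r^2") and ``r2_mean`` (mean of the defined
    per-variant r^2 values).  ``coverage`` is the fraction of variants
    with per-variant r^2 >= ``coverage_threshold`` (inclusive), among
    variants whose r^2 is defined.
    """
    bins = bins or FrequencyBinSpec()
    panel_freq = np.asarray(panel_freq, dtype=float)
    if panel_freq.shape[0] != truth.n_sites:
        raise SiteMismatchError("panel frequency vector does not match sites")
    imputed = ~dosages.typed_mask
    bin_idx = bins.assign(panel_freq)
    r2 = np.full(truth.n_sites, np.nan)
    n_pairs = np.zeros(truth.n_sites, dtype=int)
    for m in np.flatnonzero(imputed):
        r2[m] = variant_r2(truth.genotypes[m], dosages.dosages[m])
        n_pairs[m] = int((truth.genotypes[m] != MISSING).sum())
    per_variant = pd.DataFrame(
        {
            "id": truth.variants["id"],
            "pos": truth.variants["pos"],
            "panel_freq": panel_freq,
            "bin": bin_idx,
            "imputed": imputed,
            "r2": r2,
            "n_pairs": n_pairs,
        }
    )

    rows = []
    labels = bins.labels()
    for b, label in enumerate(labels):
        sel = imputed & (bin_idx == b)
        sites = np.flatnonzero(sel)
        if sites.size:
            t = truth.genotypes[sites].ravel()
            d = dosages.dosages[sites].ravel()
            pooled = _pooled_r2(t, d)
        else:
            pooled = float("nan")
        defined = r2[sites]
        defined = defined[np.isfinite(defined)]
        rows.append(
            {
                "bin": label,
                "lo": bins.edges[b],
                "hi": bins.edges[b + 1],
                "n_variants": int(sites.size),
                "n_defined": int(defined.size),
                "r2_pooled": pooled,
                "r2_mean": float(defined.mean()) if defined.size else float("nan"),
                "coverage": (
                    float((defined >= coverage_threshold).mean())
                    if defined.size
                    else float("nan")
                ),
            }
        )
    return EvaluationResult(per_variant=per_variant, per_bin=pd.DataFrame(rows))


def coverage(per_variant_r2: np.ndarray, threshold: float = 0.8) -> float:
    """Fraction of defined per-variant r^2 values at or above threshold."""
    r2 = np.asarray(per_variant_r2, dtype=float)
    defined = r2[np.isfinite(r2)]
    if defined.size == 0:
        return float("nan")
    return float((defined >= threshold).mean())


def compare_panels(
    base: HaplotypePanel,
    augmented: HaplotypePanel,
    cohorts: dict[str, HaplotypePanel],
    typed_mask: np.ndarray,
    params: HmmParams,
    bins: FrequencyBinSpec | None = None,
) -> pd.DataFrame:
    """Per-cohort, per-bin accuracy under two reference panels.

    Cohorts whose samples are members of a panel are evaluated by
    leave-one-out cross-validation against that panel; external cohorts
    are imputed directly.  Both panels must share the variant grid and the
    typed-site mask; the table reports both panels' aggregate r^2 per bin
    plus the augmented-minus-base delta.
    """
    bins = bins or FrequencyBinSpec()
    if not base.variants["pos"].equals(augmented.variants["pos"]):
        raise SiteMismatchError("base and augmented panels differ in sites")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    rows = []
    for name, cohort in cohorts.items():
        truth = cohort.genotypes()
        per_panel: dict[str, pd.DataFrame] = {}
        for panel_name, panel in (("base", base), ("augmented", augmented)):
            members = set(panel.samples["sample"])
            if set(cohort.samples["sample"]) <= members:
                # leave-one-out inside the full panel, reported for the cohort
                dm_full, _ = loo_cross_validate(panel, typed_mask, params)
                order = [
                    dm_full.samples["sample"].tolist().index(s)
                    for s in cohort.samples["sample"]
                ]
                dm = DosageMatrix(
                    dm_full.dosages[:, order],
                    typed_mask,
                    dm_full.variants,
                    dm_full.samples.iloc[order],
                )
            else:
                dm = impute_cohort(cohort, panel, typed_mask, params)
            truth_here = truth
            res = aggregate_accuracy(truth_here, dm, panel.alt_freq(), bins)
            per_panel[panel_name] = res.per_bin.set_index("bin")
        joined = per_panel["base"][["n_variants", "r2_pooled", "r2_mean"]].join(
            per_panel["augmented"][["r2_pooled", "r2_mean"]],
            lsuffix="_base",
            rsuffix="_augmented",
        )
        joined["delta_pooled"] = (
            joined["r2_pooled_augmented"] - joined["r2_pooled_base"]
        )
        joined["cohort"] = name
        rows.append(joined.reset_index())
    return pd.concat(rows, ignore_index=True)


def diff_snp_screen(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    p_threshold: float = 1e-7,
    region_a: str = "region_a",
    region_b: str = "region_b",
) -> pd.DataFrame:
    """Allele-frequency differentiation screen between two regions.

    For every shared segregating site the 2x2 region-by-allele count
    table is tested with a two-sided Fisher exact test; sites with
    p < ``p_threshold`` are reported with per-region non-reference allele
    frequencies.  Swapping the two regions leaves the p-values unchanged.
    """
    key_a = pd.MultiIndex.from_frame(gm_a.variants[["contig", "pos", "ref", "alt"]])
    key_b = pd.MultiIndex.from_frame(gm_b.variants[["contig", "pos", "ref", "alt"]])
    shared = key_a.intersection(key_b, sort=False)
    ia = key_a.get_indexer(shared)
    ib = key_b.get_indexer(shared)
    records = []
    for sa, sb in zip(ia, ib):
        ga = gm_a.genotypes[sa]
        gb = gm_b.genotypes[sb]
        ca = ga != MISSING
        cb = gb != MISSING
        alt_a = int(ga[ca].sum())
        alt_b = int(gb[cb].sum())
        an_a = 2 * int(ca.sum())
        an_b = 2 * int(cb.sum())
        if an_a == 0 or an_b == 0:
            continue
        if alt_a + alt_b == 0 or alt_a + alt_b == an_a + an_b:
            continue  # monomorphic across both regions
        _, p = fisher_exact(
            [[alt_a, an_a - alt_a], [alt_b, an_b - alt_b]], alternative="two-sided"
        )
        if p < p_threshold:
            row = gm_a.variants.iloc[sa]
            records.append(
                {
                    "id": row["id"],
                    "contig": row["contig"],
                    "pos": row["pos"],
                    f"freq_{region_a}": alt_a / an_a,
                    f"freq_{region_b}": alt_b / an_b,
                    "p": float(p),
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "id",
            "contig",
            "pos",
            f"freq_{region_a}",
            f"freq_{region_b}",
            "p",
        ],
    )


def novel_snp_count(
    panel_variants: pd.DataFrame,
    cohorts: dict[str, GenotypeMatrix],
    min_ac: int = 2,
) -> NovelSnpSummary:
    """Variants present in other cohorts but absent from the panel.

    A site is novel when its (contig, pos, ref, alt) key is not in the
    panel and its combined alt allele count across all cohorts is at
    least ``min_ac``.  Per region, the total counts novel sites carried
    (alt count >= 1) by that region; ``per_person`` divides by the
    region's sample count.
    """
    panel_keys = set(
        map(tuple, panel_variants[["contig", "pos", "ref", "alt"]].itertuples(index=False))
    )
    site_ac: dict[tuple, dict[str, int]] = {}
    region_n = {}
    for region, gm in cohorts.items():
        region_n[region] = gm.n_samples
        g = gm.genotypes
        called = g != MISSING
        ac = np.where(called, g, 0).sum(axis=1)
        keys = list(
            map(
                tuple,
                gm.variants[["contig", "pos", "ref", "alt"]].itertuples(index=False),
            )
        )
        for key, count in zip(keys, ac):
            if key in panel_keys or count == 0:
                continue
            site_ac.setdefault(key, {})[region] = int(count)
    eligible = {
        key: per_region
        for key, per_region in site_ac.items()
        if sum(per_region.values()) >= min_ac
    }
    rows = []
    for region, n in region_n.items():
        total = sum(1 for per_region in eligible.values() if region in per_region)
        rows.append(
            {
                "region": region,
                "n_samples": n,
                "total": total,
                "per_person": total / n,
            }
        )
    return NovelSnpSummary(per_region=pd.DataFrame(rows), min_ac=min_ac)
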