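"""Reference-panel quality control.

Reproduces the standard panel-construction pipeline for a sequenced
cohort paired with array genotypes: per-individual read-depth thresholds
calibrated to a genotype-concordance target (default 99.8%), site-level
filters (call rate >= 97%, HWE exact p >= 1e-6, MAF >= 0.5%), and
removal of cryptic relatives flagged by a method-of-moments identity-by-
descent estimate (PI_HAT > 0.125, the PLINK convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, HaplotypePanel, variant_stats
from .errors import EmptyPanelError, InsufficientDataError, InvalidConfigError


@dataclass
class QcThresholds:
    concordance_target: float = 0.998
    call_rate_min: float = 0.97
    hwe_p_min: float = 1e-6
    maf_min: float = 0.005
    pihat_max: float = 0.125

    def validate(self) -> None:
        for name in ("concordance_target", "call_rate_min", "hwe_p_min", "maf_min", "pihat_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidConfigError(f"{name}={v} outside (0, 1)")


@dataclass
class RelatednessEstimate:
    sample_a: str
    sample_b: str
    ibd0: float
    ibd1: float
    ibd2: float
    pihat: float
    n_sites: int


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one under
    the exact (hypergeometric-type) distribution of genotype counts.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n_minor == 0:
        return 1.0

    lg = math.lgamma
    two_n = 2 * n
    n_major = two_n - n_minor
    base = lg(n + 1) + lg(n_minor + 1) + lg(n_major + 1) - lg(two_n + 1)

    def log_prob(h: int) -> float:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            base
            + h * math.log(2.0)
            - lg(hom_minor + 1)
            - lg(h + 1)
            - lg(hom_major + 1)
        )

    h_obs = n_ab
    hs = range(n_minor % 2, min(n_minor, n_major) + 1, 2)
    logs = {h: log_prob(h) for h in hs}
    p_obs = math.exp(logs[h_obs])
    total = sum(
        math.exp(lp) for lp in logs.values() if math.exp(lp) <= p_obs * (1 + 1e-12)
    )
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# depth-threshold calibration


def _align_sites(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of the shared (contig, pos) sites, in a common order."""
    key_a = pd.MultiIndex.from_frame(a[["contig", "pos"]])
    key_b = pd.MultiIndex.from_frame(b[["contig", "pos"]])
    shared = key_a.intersection(key_b, sort=False)
    ia = key_a.get_indexer(shared)
    ib = key_b.get_indexer(shared)
    return np.asarray(ia), np.asarray(ib)


def calibrate_depth_threshold(
    ngs: GenotypeMatrix,
    depths: np.ndarray,
    array: GenotypeMatrix,
    target: float = 0.998,
    min_sites: int = 100,
) -> pd.DataFrame:
    """Per-individual minimum depth threshold achieving the concordance target.

    For each individual the integer thresholds t = 0, 1, 2, ... are scanned;
    genotypes at sites with depth < t become missing and concordance is the
    match fraction over sites called on both platforms.  The smallest t
    reaching ``target`` is returned; if none does, the concordance-maximizing
    t is returned with ``attainable=False``.
    """
    ia, ib = _align_sites(ngs.variants, array.variants)
    if len(ia) == 0:
        raise InsufficientDataError("no shared sites between NGS and array calls")
    sample_order = array.samples["sample"].tolist()
    ngs_samples = ngs.samples["sample"].tolist()
    rows = []
    for pos_a, s_name in enumerate(sample_order):
        j = ngs_samples.index(s_name)
        g_n = ngs.genotypes[ia, j]
        g_a = array.genotypes[ib, pos_a]
        d = depths[ia, j]
        both = (g_n != MISSING) & (g_a != MISSING)
        if int(both.sum()) < min_sites:
            raise InsufficientDataError(
                f"sample {s_name}: only {int(both.sum())} comparable sites (< {min_sites})"
            )
        d_c = d[both]
        match = (g_n[both] == g_a[both]).astype(np.int64)
        d_max = int(d_c.max())
        tot = np.bincount(d_c, minlength=d_max + 1)
        hit = np.bincount(d_c, weights=match, minlength=d_max + 1)
        # concordance at threshold t = matches among depth >= t
        tot_ge = np.cumsum(tot[::-1])[::-1]
        hit_ge = np.cumsum(hit[::-1])[::-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            conc = np.where(tot_ge > 0, hit_ge / np.maximum(tot_ge, 1), np.nan)
        # a threshold is only admissible while it leaves enough comparable
        # sites; otherwise tiny denominators reach any target by chance
        valid = tot_ge >= min_sites
        reach = valid & (conc >= target)
        if reach.any():
            t = int(np.flatnonzero(reach)[0])
            rows.append((s_name, t, float(conc[t]), True))
        else:
            t = int(np.nanargmax(np.where(valid, conc, -1.0)))
            rows.append((s_name, t, float(conc[t]), False))
    return pd.DataFrame(
        rows, columns=["sample", "threshold", "concordance", "attainable"]
    ).set_index("sample")


# ---------------------------------------------------------------------------
# site filter


def site_filter(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Exclude sites with call rate, HWE p or MAF strictly below threshold.

    Returns the kept-site mask and a per-excluded-site report with the
    first triggering rule (rules checked in the order call_rate, hwe, maf).
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    stats = variant_stats(gm, hwe=True)
    fail_cr = stats["call_rate"].to_numpy() < thresholds.call_rate_min
    fail_hwe = stats["hwe_p"].to_numpy() < thresholds.hwe_p_min
    fail_maf = stats["maf"].to_numpy() < thresholds.maf_min
    keep = ~(fail_cr | fail_hwe | fail_maf)
    reason = np.where(
        fail_cr, "call_rate", np.where(fail_hwe, "hwe", np.where(fail_maf, "maf", ""))
    )
    report = pd.DataFrame(
        {
            "id": gm.variants["id"],
            "pos": gm.variants["pos"],
            "call_rate": stats["call_rate"],
            "hwe_p": stats["hwe_p"],
            "maf": stats["maf"],
            "kept": keep,
            "reason": reason,
        }
    )
    return keep, report


# ---------------------------------------------------------------------------
# relatedness (method-of-moments IBD, PLINK-style)


def _ibs_expectations(ac: np.ndarray, an: np.ndarray) -> dict[str, np.ndarray]:
    """Per-site P(IBS = i | IBD = j) from cohort allele counts.

    Exact without-replacement (hypergeometric) expectations: the pair's
    non-IBD alleles are treated as a simple random sample from the
    cohort's ``an`` observed alleles (``ac`` of them alternate).  This is
    the finite-sample correction of the naive ``2 p^2 q^2``-style terms;
    without it, cohort-estimated frequencies bias PI_HAT upward by
    O(1/n_samples).
    """
    a = ac.astype(np.float64)
    t = an.astype(np.float64)
    r = t - a
    with np.errstate(invalid="ignore", divide="ignore"):
        d0 = t * (t - 1) * (t - 2) * (t - 3)
        e0_ibd0 = 2 * a * (a - 1) * r * (r - 1) / d0
        e2_ibd0 = (
            a * (a - 1) * (a - 2) * (a - 3)
            + r * (r - 1) * (r - 2) * (r - 3)
            + 4 * a * (a - 1) * r * (r - 1)
        ) / d0
        e1_ibd0 = 1.0 - e0_ibd0 - e2_ibd0
        d1 = t * (t - 1)
        e1_ibd1 = 2 * a * r / d1
        e2_ibd1 = (a * (a - 1) + r * (r - 1)) / d1
    return {
        "e0_ibd0": np.nan_to_num(e0_ibd0),
        "e1_ibd0": np.nan_to_num(e1_ibd0),
        "e2_ibd0": np.nan_to_num(e2_ibd0),
        "e1_ibd1": np.nan_to_num(e1_ibd1),
        "e2_ibd1": np.nan_to_num(e2_ibd1),
    }


def estimate_pihat(
    gm: GenotypeMatrix,
    sample_a: str,
    sample_b: str,
    maf_min: float = 0.05,
    min_sites: int = 500,
) -> RelatednessEstimate:
    """PI_HAT for one pair: IBD1/2 + IBD2 from identity-by-state counts.

    Allele frequencies come from the full cohort; sites are restricted to
    MAF >= ``maf_min`` and to calls present in both samples.
    """
    names = gm.samples["sample"].tolist()
    a, b = names.index(sample_a), names.index(sample_b)
    stats = variant_stats(gm)
    keep = (
        (stats["maf"].to_numpy() >= maf_min)
        & np.isfinite(stats["alt_freq"].to_numpy())
        & (stats["an"].to_numpy() >= 4)
    )
    ga = gm.genotypes[keep, a]
    gb = gm.genotypes[keep, b]
    ac = stats["ac"].to_numpy()[keep]
    an = stats["an"].to_numpy()[keep]
    both = (ga != MISSING) & (gb != MISSING)
    if int(both.sum()) < min_sites:
        raise InsufficientDataError(
            f"{int(both.sum())} co-called sites (< {min_sites}) for "
            f"{sample_a} vs {sample_b}"
        )
    ga, gb = ga[both], gb[both]
    ac, an = ac[both], an[both]
    diff = np.abs(ga - gb)
    ibs0 = float((diff == 2).sum())
    ibs2 = float((diff == 0).sum())
    ibs1 = float(len(ga)) - ibs0 - ibs2
    exp = {k: float(v.sum()) for k, v in _ibs_expectations(ac, an).items()}
    p0, p1, p2 = _mom_ibd_sums(ibs0, ibs1, ibs2, exp, float(len(ga)))
    pihat = p1 / 2 + p2
    return RelatednessEstimate(sample_a, sample_b, p0, p1, p2, pihat, int(len(ga)))


def _mom_ibd_sums(
    ibs0: float, ibs1: float, ibs2: float, e: dict[str, float], n: float
) -> tuple[float, float, float]:
    """IBD probabilities from summed observed/expected IBS counts."""
    p0 = ibs0 / e["e0_ibd0"] if e["e0_ibd0"] > 0 else 0.0
    p1 = (ibs1 - p0 * e["e1_ibd0"]) / e["e1_ibd1"] if e["e1_ibd1"] > 0 else 0.0
    p2 = (ibs2 - p0 * e["e2_ibd0"] - p1 * e["e2_ibd1"]) / n if n > 0 else 0.0
    probs = np.clip(np.array([p0, p1, p2]), 0.0, 1.0)
    total = probs.sum()
    if total <= 0:
        return 1.0, 0.0, 0.0
    probs = probs / total
    return float(probs[0]), float(probs[1]), float(probs[2])


def pairwise_pihat(gm: GenotypeMatrix, maf_min: float = 0.05) -> pd.DataFrame:
    """Full PI_HAT matrix, vectorized over pairs via indicator products."""
    stats = variant_stats(gm)
    keep = (
        (stats["maf"].to_numpy() >= maf_min)
        & np.isfinite(stats["alt_freq"].to_numpy())
        & (stats["an"].to_numpy() >= 4)
    )
    g = gm.genotypes[keep]
    # float32 matmuls: exact for counts below 2^24, half the memory
    called = (g != MISSING).astype(np.float32)
    i0 = ((g == 0)).astype(np.float32)
    i1 = ((g == 1)).astype(np.float32)
    i2 = ((g == 2)).astype(np.float32)
    ibs2 = (i0.T @ i0 + i1.T @ i1 + i2.T @ i2).astype(np.float64)
    ibs0 = (i0.T @ i2 + i2.T @ i0).astype(np.float64)
    n_pair = (called.T @ called).astype(np.float64)
    ibs1 = n_pair - ibs2 - ibs0
    exp = _ibs_expectations(stats["ac"].to_numpy()[keep], stats["an"].to_numpy()[keep])
    if bool((g != MISSING).all()):
        # complete data: every pair shares the same expectation sums
        pair_exp = {k: np.full(n_pair.shape, v.sum()) for k, v in exp.items()}
    else:
        pair_exp = {
            k: ((called * v[:, None].astype(np.float32)).T @ called).astype(np.float64)
            for k, v in exp.items()
        }

    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(pair_exp["e0_ibd0"] > 0, ibs0 / pair_exp["e0_ibd0"], 0.0)
        p1 = np.where(
            pair_exp["e1_ibd1"] > 0,
            (ibs1 - p0 * pair_exp["e1_ibd0"]) / pair_exp["e1_ibd1"],
            0.0,
        )
        p2 = np.where(
            n_pair > 0,
            (ibs2 - p0 * pair_exp["e2_ibd0"] - p1 * pair_exp["e2_ibd1"]) / n_pair,
            0.0,
        )
    p0, p1, p2 = (np.clip(x, 0.0, 1.0) for x in (p0, p1, p2))
    total = p0 + p1 + p2
    bad = total <= 0
    total = np.where(bad, 1.0, total)
    pihat = (p1 / 2 + p2) / total
    pihat[bad] = 0.0
    names = gm.samples["sample"].tolist()
    out = pd.DataFrame(pihat, index=names, columns=names)
    np.fill_diagonal(out.values, 0.0)
    return out


@dataclass
class PruneResult:
    kept: list[str]
    removed: list[str]
    removal_reasons: pd.DataFrame  # sample, partner, pihat
    flagged_pairs: pd.DataFrame  # sample_a, sample_b, pihat


def prune_relatives(
    gm: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    maf_min: float = 0.05,
) -> PruneResult:
    """Remove cryptic relatives until no pair has PI_HAT above threshold.

    The flagged-pair graph is resolved greedily: at each step the sample
    in the most flagged pairs is removed (ties broken by lower call rate,
    then by lexicographically later label), which for an isolated flagged
    pair reduces to removing its lower-call-rate member and for a planted
    parent/parent/offspring triad removes only the offspring.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    if gm.n_samples < 2:
        raise InsufficientDataError("need at least two samples")
    mat = pairwise_pihat(gm, maf_min=maf_min)
    names = list(mat.index)
    call_rate = dict(zip(gm.samples["sample"], gm.sample_call_rate()))
    vals = mat.to_numpy()
    iu, ju = np.triu_indices(len(names), k=1)
    above = vals[iu, ju] > thresholds.pihat_max  # strict, matching "> 0.125"
    pairs = [
        (names[i], names[j], float(vals[i, j]))
        for i, j in zip(iu[above], ju[above])
    ]
    flagged = pd.DataFrame(pairs, columns=["sample_a", "sample_b", "pihat"])

    active = set(names)
    live = list(pairs)
    removed: list[str] = []
    reasons = []
    while live:
        degree: dict[str, int] = {}
        for a, b, _ in live:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        # most-flagged first; ties -> lower call rate -> later label
        victim = max(
            degree,
            key=lambda s: (degree[s], -call_rate[s], s),
        )
        partner, top = max(
            ((b if a == victim else a, ph) for a, b, ph in live if victim in (a, b)),
            key=lambda t: t[1],
        )
        removed.append(victim)
        reasons.append((victim, partner, top))
        active.discard(victim)
        live = [t for t in live if victim not in t[:2]]
    kept = [s for s in names if s in active]
    return PruneResult(
        kept=kept,
        removed=removed,
        removal_reasons=pd.DataFrame(reasons, columns=["sample", "partner", "pihat"]),
        flagged_pairs=flagged,
    )


# ---------------------------------------------------------------------------
# panel assembly


def build_panel(
    truth: HaplotypePanel, kept_samples: list[str], kept_sites: np.ndarray
) -> HaplotypePanel:
    """Subset the phased truth to QC-passing samples and sites."""
    names = truth.samples["sample"].tolist()
    idx = [names.index(s) for s in kept_samples if s in names]
    if not idx:
        raise EmptyPanelError("no samples left after QC")
    kept_sites = np.asarray(kept_sites)
    if kept_sites.dtype == bool and not kept_sites.any():
        raise EmptyPanelError("no sites left after QC")
    return truth.subset(sample_idx=np.array(idx), site_idx=kept_sites)
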