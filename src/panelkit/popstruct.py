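"""Population-structure statistics: LD pruning, PCA, Weir–Cockerham F_ST.

The F_ST estimator is the Weir & Cockerham (1984) variance-components
form for two populations, with per-site among-population (a),
among-individual (b) and within-individual (c) components; the
genome-wide estimate is the ratio of sums ``sum(a) / sum(a + b + c)``
(a ratio of averages, not an average of per-site ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, variant_stats
from .errors import DegenerateInputError, InsufficientDataError, InvalidConfigError


@dataclass
class PruneParams:
    max_missing_fraction: float = 0.1
    min_maf: float = 0.05
    max_r2: float = 0.8
    window: int = 50

    def validate(self) -> None:
        if not 0 <= self.max_missing_fraction <= 1:
            raise InvalidConfigError("max_missing_fraction outside [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise InvalidConfigError("min_maf outside [0, 0.5]")
        if not 0 < self.max_r2 <= 1:
            raise InvalidConfigError("max_r2 outside (0, 1]")
        if self.window < 1:
            raise InvalidConfigError("window must be >= 1")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    proportions: np.ndarray  # variance proportion per component


@dataclass
class FstResult:
    a: np.ndarray  # per-site among-population component
    b: np.ndarray
    c: np.ndarray
    per_site: np.ndarray  # may be negative; nan where a+b+c == 0
    genomewide: float


def _imputed_standardized(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing per site; return (imputed matrix, alt freq)."""
    g = g.astype(np.float64)
    miss = g < 0
    g[miss] = np.nan
    mean = np.nanmean(g, axis=1)
    idx = np.where(miss)
    g[idx] = mean[idx[0]]
    return g, mean / 2.0


def ld_prune(gm: GenotypeMatrix, params: PruneParams | None = None) -> np.ndarray:
    """Kept-site mask after missingness, MAF and windowed LD filtering.

    Sites failing missingness (> max) or MAF (< min) go first; the
    remaining sites are scanned left-to-right and a site is dropped if its
    genotype correlation r^2 with any previously kept site within
    ``window`` kept positions exceeds ``max_r2``.  The outcome depends on
    site order (the later of a correlated pair is dropped), not on sample
    order.
    """
    params = params or PruneParams()
    params.validate()
    stats = variant_stats(gm)
    missing_frac = 1.0 - stats["call_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    base = (missing_frac <= params.max_missing_fraction) & (maf >= params.min_maf)
    candidates = np.flatnonzero(base)
    if candidates.size == 0:
        return np.zeros(gm.n_sites, dtype=bool)

    x, _ = _imputed_standardized(gm.genotypes[candidates])
    x -= x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=1))
    keep_local: list[int] = []
    for i in range(len(candidates)):
        if norms[i] == 0:
            continue  # constant after imputation: uninformative
        ok = True
        for j in keep_local[-params.window :]:
            denom = norms[i] * norms[j]
            r = float(x[i] @ x[j]) / denom
            if r * r > params.max_r2:
                ok = False
                break
        if ok:
            keep_local.append(i)
    mask = np.zeros(gm.n_sites, dtype=bool)
    mask[candidates[keep_local]] = True
    return mask


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the standardized genotype matrix.

    Missing entries are mean-imputed per site; each site is centered and
    scaled by ``sqrt(2 p (1 - p))``; the eigendecomposition of the
    sample-by-sample covariance yields scores and variance proportions.
    Sign convention: the largest-magnitude entry of each score vector is
    positive.
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise DegenerateInputError("PCA needs >= 2 samples and >= 2 sites")
    x, p = _imputed_standardized(gm.genotypes)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    informative = scale > 0
    if not informative.any():
        raise DegenerateInputError("all sites are constant")
    z = (x[informative] - 2.0 * p[informative, None]) / scale[informative, None]
    cov = (z.T @ z) / z.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    if total <= 0:
        raise DegenerateInputError("no variance in standardized genotypes")
    k = min(n_components, len(eigval))
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    for j in range(k):
        top = np.argmax(np.abs(scores[:, j]))
        if scores[top, j] < 0:
            scores[:, j] = -scores[:, j]
    frame = pd.DataFrame(
        scores,
        index=gm.samples["sample"],
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(scores=frame, proportions=eigval[:k] / total)


def _pop_site_summaries(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called, alt freq, observed het fraction) for one pop."""
    called = g != MISSING
    n = called.sum(axis=1)
    ac = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / (2.0 * np.maximum(n, 1)), np.nan)
        het = np.where(n > 0, (g == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return n, p, het


def fst_pairwise(
    gm: GenotypeMatrix, pop_a_samples: np.ndarray, pop_b_samples: np.ndarray
) -> FstResult:
    """Weir–Cockerham F_ST between two populations.

    ``pop_*_samples`` are boolean masks or index arrays over the samples
    of ``gm``.  Sites contribute only when each population has >= 2 called
    samples; monomorphic (across both populations) sites add zero to all
    components.
    """
    ga = gm.genotypes[:, np.asarray(pop_a_samples)]
    gb = gm.genotypes[:, np.asarray(pop_b_samples)]
    n1, p1, h1 = _pop_site_summaries(ga)
    n2, p2, h2 = _pop_site_summaries(gb)
    usable = (n1 >= 2) & (n2 >= 2)
    if not usable.any():
        raise InsufficientDataError(
            "a population has < 2 called samples at every site"
        )
    r = 2.0
    n1f, n2f = n1[usable].astype(float), n2[usable].astype(float)
    p1f, p2f = p1[usable], p2[usable]
    h1f, h2f = h1[usable], h2[usable]
    nbar = (n1f + n2f) / r
    nc = (r * nbar - (n1f**2 + n2f**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1f * p1f + n2f * p2f) / (r * nbar)
    s2 = (n1f * (p1f - pbar) ** 2 + n2f * (p2f - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1f * h1f + n2f * h2f) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0

    a_full = np.zeros(gm.n_sites)
    b_full = np.zeros(gm.n_sites)
    c_full = np.zeros(gm.n_sites)
    a_full[usable], b_full[usable], c_full[usable] = a, b, c
    denom = a_full + b_full + c_full
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom != 0, a_full / denom, np.nan)
    total_denom = denom.sum()
    if total_denom == 0:
        raise InsufficientDataError("no polymorphic site contributes to F_ST")
    return FstResult(
        a=a_full,
        b=b_full,
        c=c_full,
        per_site=per_site,
        genomewide=float(a_full.sum() / total_denom),
    )


def fst_matrix(gm: GenotypeMatrix, labels: np.ndarray | None = None) -> pd.DataFrame:
    """Symmetric pairwise genome-wide F_ST matrix over region labels."""
    labels = np.asarray(labels if labels is not None else gm.samples["region"])
    regions = list(pd.unique(labels))
    if len(regions) < 2:
        raise InvalidConfigError("need >= 2 regions for an F_ST matrix")
    out = pd.DataFrame(np.nan, index=regions, columns=regions, dtype=float)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            est = fst_pairwise(gm, labels == ra, labels == rb).genomewide
            out.loc[ra, rb] = est
            out.loc[rb, ra] = est
    return out
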