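"""Haplotype-copying (Li & Stephens) imputation.

A target haplotype is modeled as a mosaic of the ``K`` donor haplotypes
in a phased reference panel.  The hidden state is the donor currently
copied; across each inter-site interval the chain stays with probability
``exp(-rho) + (1 - exp(-rho))/K`` and switches to each other donor with
probability ``(1 - exp(-rho))/K``.  Typed sites emit the observed allele
with probability ``1 - eps`` (miscopy probability ``eps``); untyped sites
are silent states that emit nothing.  Forward–backward posteriors over
donors give per-site allele probabilities, and two haploid passes per
pre-phased sample give diploid dosages in [0, 2].

Leave-one-out cross-validation — impute every panel member against the
panel with both of that member's haplotypes withheld — is the standard
protocol for measuring a panel's imputation accuracy from within.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import MISSING, DosageMatrix, HaplotypePanel
from .errors import (
    InsufficientDataError,
    InvalidConfigError,
    NoDonorsError,
    UnphasedInputError,
)


@dataclass
class HmmParams:
    """Copying-model parameters.

    ``rho_per_interval`` is the expected switch intensity per inter-site
    interval (a scaled recombination rate; the conventional choice is
    ``4 * Ne * r / K``), ``miscopy_epsilon`` the per-site copy-error
    probability.
    """

    rho_per_interval: float = 0.01
    miscopy_epsilon: float = 1e-3

    def validate(self) -> None:
        if self.rho_per_interval < 0:
            raise InvalidConfigError("rho_per_interval must be >= 0")
        if not 0.0 < self.miscopy_epsilon < 0.5:
            raise InvalidConfigError("miscopy_epsilon outside (0, 0.5)")

    @classmethod
    def from_effective_size(
        cls, effective_size: float, recomb_rate: float, n_donors: int,
        miscopy_epsilon: float = 1e-3,
    ) -> "HmmParams":
        """The conventional scaled-recombination parameterization."""
        if n_donors < 1:
            raise NoDonorsError("panel has no donor haplotypes")
        return cls(4.0 * effective_size * recomb_rate / n_donors, miscopy_epsilon)


def forward_backward(
    obs: np.ndarray,
    donors: np.ndarray,
    params: HmmParams,
    return_chunks: bool = False,
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Scaled forward–backward over donor states.

    Parameters
    ----------
    obs:
        Observed alleles per panel site; ``-1`` marks an untyped (silent)
        site.
    donors:
        ``(n_sites, K)`` donor haplotype alleles in {0, 1}.

    Returns
    -------
    gamma:
        ``(n_sites, K)`` donor posteriors (each row sums to 1).
    loglik:
        Log-likelihood of the observed alleles.
    chunks:
        When ``return_chunks``, the expected number of contiguous copying
        segments attributed to each donor (initial state plus switch-entry
        events), else ``None``.
    """
    params.validate()
    obs = np.asarray(obs, dtype=np.int8)
    donors = np.asarray(donors, dtype=np.int8)
    m, k = donors.shape
    if k < 1:
        raise NoDonorsError("panel has no donor haplotypes")
    if obs.shape[0] != m:
        raise InvalidConfigError("observation vector does not match panel sites")
    eps = params.miscopy_epsilon
    stay = math.exp(-params.rho_per_interval)
    switch = (1.0 - stay) / k

    emit = np.ones((m, k))
    typed = obs != MISSING
    emit[typed] = np.where(donors[typed] == obs[typed, None], 1.0 - eps, eps)

    fwd = np.empty((m, k))
    scale = np.empty(m)
    f = emit[0] / k
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for t in range(1, m):
        f = (stay * fwd[t - 1] + switch) * emit[t]
        scale[t] = f.sum()
        fwd[t] = f / scale[t]

    bwd = np.empty((m, k))
    bwd[m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        w = emit[t + 1] * bwd[t + 1]
        bwd[t] = (stay * w + switch * w.sum()) / scale[t + 1]

    gamma = fwd * bwd  # rows sum to 1 under this scaling
    loglik = float(np.log(scale).sum())
    chunks = None
    if return_chunks:
        chunks = gamma[0].copy()
        for t in range(1, m):
            # mass entering donor j at t from a different donor
            chunks += switch * (1.0 - fwd[t - 1]) * emit[t] * bwd[t] / scale[t]
    return gamma, loglik, chunks


def ls_posterior(
    obs: np.ndarray, donors: np.ndarray, params: HmmParams
) -> np.ndarray:
    """Posterior allele-1 probability at every panel site.

    ``P(allele = 1) = eps + (1 - 2 eps) * sum_k gamma_k * a_k`` where
    ``a_k`` is donor ``k``'s allele — the copy-error channel applied to the
    donor-posterior mixture.
    """
    gamma, _, _ = forward_backward(obs, donors, params)
    mean_allele = np.einsum("mk,mk->m", gamma, donors.astype(np.float64))
    eps = params.miscopy_epsilon
    return eps + (1.0 - 2.0 * eps) * mean_allele


def impute_haplotype_pair(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    donors: np.ndarray,
    params: HmmParams,
) -> np.ndarray:
    """Dosage for one pre-phased sample: sum of two haploid passes.

    Typed sites (observed in both haplotypes) keep the observed genotype.
    """
    hap_a = np.asarray(hap_a, dtype=np.int8)
    hap_b = np.asarray(hap_b, dtype=np.int8)
    p_a = ls_posterior(hap_a, donors, params)
    p_b = ls_posterior(hap_b, donors, params)
    dosage = p_a + p_b
    typed = (hap_a != MISSING) & (hap_b != MISSING)
    dosage[typed] = (hap_a + hap_b)[typed].astype(np.float64)
    return np.clip(dosage, 0.0, 2.0)


def impute_genotypes(
    genotypes: np.ndarray, donors: np.ndarray, params: HmmParams
) -> np.ndarray:
    """Impute from unphased diploid observations.

    Only homozygous or missing calls can be used without phase; any
    heterozygous call raises :class:`UnphasedInputError` (pre-phasing is
    deliberately out of scope — simulation provides truth phase and real
    panels arrive phased).
    """
    genotypes = np.asarray(genotypes)
    if np.any(genotypes == 1):
        raise UnphasedInputError(
            "heterozygous diploid input requires pre-phased haplotypes"
        )
    hap = np.where(genotypes == MISSING, MISSING, genotypes // 2).astype(np.int8)
    return impute_haplotype_pair(hap, hap, donors, params)


def mask_to_observed(
    panel: HaplotypePanel, typed_mask: np.ndarray, column: int
) -> np.ndarray:
    """One haplotype column with untyped sites hidden (set to MISSING)."""
    obs = panel.haplotypes[:, column].astype(np.int8).copy()
    obs[~np.asarray(typed_mask, dtype=bool)] = MISSING
    return obs


def loo_cross_validate(
    panel: HaplotypePanel,
    typed_mask: np.ndarray,
    params: HmmParams,
    collect_audit: bool = False,
) -> tuple[DosageMatrix, dict[str, list[str]]]:
    """Leave-one-out imputation of every panel sample.

    Each sample is imputed from its array-site (typed) alleles against
    the panel with BOTH of its haplotypes removed from the donor set, so
    a sample's own haplotypes are never among its donors.
    """
    if panel.n_samples < 2:
        raise InsufficientDataError("leave-one-out needs a panel of >= 2 samples")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    if typed_mask.shape[0] != panel.n_sites:
        raise InvalidConfigError("typed mask length does not match panel sites")
    m, s = panel.n_sites, panel.n_samples
    dosages = np.empty((m, s))
    hap_labels = panel.haplotype_labels()
    audit: dict[str, list[str]] = {}
    all_cols = np.arange(panel.n_haplotypes)
    for i in range(s):
        c0, c1 = panel.sample_columns(i)
        donor_cols = all_cols[(all_cols != c0) & (all_cols != c1)]
        donors = panel.haplotypes[:, donor_cols]
        obs_a = mask_to_observed(panel, typed_mask, c0)
        obs_b = mask_to_observed(panel, typed_mask, c1)
        dosages[:, i] = impute_haplotype_pair(obs_a, obs_b, donors, params)
        if collect_audit:
            audit[panel.samples["sample"].iat[i]] = [
                hap_labels[c] for c in donor_cols
            ]
    dm = DosageMatrix(dosages, typed_mask, panel.variants.copy(), panel.samples.copy())
    return dm, audit


def impute_cohort(
    cohort_panel: HaplotypePanel,
    reference: HaplotypePanel,
    typed_mask: np.ndarray,
    params: HmmParams,
) -> DosageMatrix:
    """Impute every (out-of-panel) cohort sample against a full reference.

    Cohort and reference must share the same variant grid.
    """
    if not cohort_panel.variants["pos"].equals(reference.variants["pos"]):
        from .errors import SiteMismatchError

        raise SiteMismatchError("cohort and reference variant grids differ")
    typed_mask = np.asarray(typed_mask, dtype=bool)
    m, s = cohort_panel.n_sites, cohort_panel.n_samples
    dosages = np.empty((m, s))
    donors = reference.haplotypes
    for i in range(s):
        c0, c1 = cohort_panel.sample_columns(i)
        obs_a = mask_to_observed(cohort_panel, typed_mask, c0)
        obs_b = mask_to_observed(cohort_panel, typed_mask, c1)
        dosages[:, i] = impute_haplotype_pair(obs_a, obs_b, donors, params)
    return DosageMatrix(
        dosages, typed_mask, cohort_panel.variants.copy(), cohort_panel.samples.copy()
    )
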