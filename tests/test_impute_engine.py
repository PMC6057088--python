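"""Haplotype-copying HMM: enumeration equivalence, posteriors, LOO driver."""

import itertools
import math

import numpy as np
import pytest

from panelkit.containers import MISSING
from panelkit.errors import (
    InsufficientDataError,
    NoDonorsError,
    UnphasedInputError,
)
from panelkit.impute_engine import (
    HmmParams,
    forward_backward,
    impute_genotypes,
    impute_haplotype_pair,
    loo_cross_validate,
    ls_posterior,
    mask_to_observed,
)
from tests.conftest import make_panel


def enumerate_posteriors(obs, donors, params):
    """Brute-force donor posteriors and expected chunk counts.

    Sums the joint probability of every donor path explicitly; the HMM
    implementation must match this for small panels.
    """
    donors = np.asarray(donors)
    m, k = donors.shape
    eps = params.miscopy_epsilon
    stay = math.exp(-params.rho_per_interval) + (1 - math.exp(-params.rho_per_interval)) / k
    switch = (1 - math.exp(-params.rho_per_interval)) / k

    def emit(t, state):
        if obs[t] == MISSING:
            return 1.0
        return 1.0 - eps if donors[t, state] == obs[t] else eps

    gamma = np.zeros((m, k))
    chunks = np.zeros(k)
    total = 0.0
    for path in itertools.product(range(k), repeat=m):
        p = emit(0, path[0]) / k
        for t in range(1, m):
            p *= (stay if path[t] == path[t - 1] else switch) * emit(t, path[t])
        total += p
        chunks[path[0]] += p
        for t in range(m):
            gamma[t, path[t]] += p
        for t in range(1, m):
            if path[t] != path[t - 1]:
                chunks[path[t]] += p
    return gamma / total, chunks / total


class TestForwardBackward:
    @pytest.mark.parametrize(
        "m,k,rho,eps,seed",
        [(3, 2, 0.1, 0.01, 0), (5, 3, 0.3, 0.05, 1), (6, 2, 0.02, 0.001, 2)],
    )
    def test_matches_path_enumeration(self, m, k, rho, eps, seed):
        rng = np.random.default_rng(seed)
        donors = rng.integers(0, 2, size=(m, k)).astype(np.int8)
        obs = rng.integers(0, 2, size=m).astype(np.int8)
        obs[rng.random(m) < 0.4] = MISSING  # a mix of typed and silent sites
        params = HmmParams(rho, eps)
        gamma, _, chunks = forward_backward(obs, donors, params, return_chunks=True)
        ref_gamma, ref_chunks = enumerate_posteriors(obs, donors, params)
        assert np.max(np.abs(gamma - ref_gamma)) < 1e-10
        assert np.max(np.abs(chunks - ref_chunks)) < 1e-10

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(3)
        donors = rng.integers(0, 2, size=(200, 20)).astype(np.int8)
        obs = donors[:, 0].copy()
        obs[::3] = MISSING
        gamma, _, _ = forward_backward(obs, donors, HmmParams(0.05, 0.01))
        assert np.max(np.abs(gamma.sum(axis=1) - 1.0)) < 1e-9

    def test_rho_zero_limit_single_donor_weighting(self):
        """As rho -> 0 the chain cannot switch: the posterior reduces to a
        soft assignment over whole-haplotype emission likelihoods."""
        donors = np.array(  # three pairwise-distinct donor haplotypes
            [[0, 1, 1], [1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8
        )
        obs = donors[:, 1].copy()
        params = HmmParams(1e-8, 0.01)
        gamma, _, _ = forward_backward(obs, donors, params)
        ref_gamma, _ = enumerate_posteriors(obs, donors, params)
        assert np.max(np.abs(gamma - ref_gamma)) < 1e-8
        # constant over sites and concentrated on the matching donor
        assert np.max(np.ptp(gamma, axis=0)) < 1e-6
        assert gamma[0, 1] > 0.9

    def test_no_underflow_long_haplotypes(self):
        rng = np.random.default_rng(5)
        m = 100_000
        donors = rng.integers(0, 2, size=(m, 4)).astype(np.int8)
        obs = donors[:, 0].copy()
        gamma, loglik, _ = forward_backward(obs, donors, HmmParams(0.01, 1e-3))
        assert np.isfinite(loglik)
        assert np.all(np.isfinite(gamma))

    def test_empty_panel_rejected(self):
        with pytest.raises(NoDonorsError):
            forward_backward(
                np.array([0, 1], dtype=np.int8),
                np.empty((2, 0), dtype=np.int8),
                HmmParams(0.1, 0.01),
            )


class TestLsPosterior:
    def test_unanimous_panel_closed_form(self):
        """All donors carry allele 1 at an untyped site: the allele-1
        probability is exactly 1 - eps regardless of the posterior."""
        eps = 0.01
        donors = np.ones((4, 5), dtype=np.int8)
        donors[0] = [0, 1, 0, 1, 0]  # one typed site to anchor the chain
        obs = np.array([1, MISSING, MISSING, MISSING], dtype=np.int8)
        probs = ls_posterior(obs, donors, HmmParams(0.1, eps))
        assert probs[1:] == pytest.approx(1.0 - eps, abs=1e-12)

    def test_posterior_concentrates_on_matching_donor(self):
        rng = np.random.default_rng(6)
        m, k = 120, 8
        donors = rng.integers(0, 2, size=(m, k)).astype(np.int8)
        typed = np.zeros(m, dtype=bool)
        typed[rng.choice(m, size=50, replace=False)] = True
        obs = np.where(typed, donors[:, 0], MISSING).astype(np.int8)
        params = HmmParams(1e-3, 1e-4)
        gamma, _, _ = forward_backward(obs, donors, params)
        probs = ls_posterior(obs, donors, params)
        interior = slice(10, m - 10)
        assert np.all(gamma[interior, 0] > 0.99)
        assert np.max(np.abs(probs[interior] - donors[interior, 0])) < 1e-2


class TestImputeSample:
    def test_in_panel_target_recovered(self, two_region_panel):
        panel = two_region_panel
        typed = np.zeros(panel.n_sites, dtype=bool)
        typed[::10] = True
        donors = panel.haplotypes[:, 2:]
        obs_a = mask_to_observed(panel, typed, 0)
        obs_b = mask_to_observed(panel, typed, 1)
        # donors include exact copies of the target's haplotypes? no -
        # use the target itself as a donor to probe the in-panel limit
        donors_with_self = panel.haplotypes
        dosage = impute_haplotype_pair(
            obs_a, obs_b, donors_with_self, HmmParams(1e-4, 1e-4)
        )
        truth = panel.haplotypes[:, 0] + panel.haplotypes[:, 1]
        assert np.max(np.abs(dosage - truth)) < 0.05

    def test_dosage_bounds(self, two_region_panel):
        panel = two_region_panel
        typed = np.zeros(panel.n_sites, dtype=bool)
        typed[::25] = True
        dosage = impute_haplotype_pair(
            mask_to_observed(panel, typed, 0),
            mask_to_observed(panel, typed, 1),
            panel.haplotypes[:, 2:],
            HmmParams(0.05, 0.01),
        )
        assert dosage.min() >= 0.0 and dosage.max() <= 2.0

    def test_typed_sites_pass_through(self, two_region_panel):
        panel = two_region_panel
        typed = np.zeros(panel.n_sites, dtype=bool)
        typed[::7] = True
        dosage = impute_haplotype_pair(
            mask_to_observed(panel, typed, 4),
            mask_to_observed(panel, typed, 5),
            panel.haplotypes[:, 6:],
            HmmParams(0.05, 0.01),
        )
        truth = panel.haplotypes[:, 4] + panel.haplotypes[:, 5]
        assert np.array_equal(dosage[typed], truth[typed].astype(float))

    def test_unphased_heterozygotes_rejected(self, two_region_panel):
        panel = two_region_panel
        geno = panel.genotypes().genotypes[:, 0]
        assert np.any(geno == 1)
        with pytest.raises(UnphasedInputError):
            impute_genotypes(geno, panel.haplotypes[:, 2:], HmmParams(0.05, 0.01))


class TestLooCrossValidate:
    def test_bookkeeping_three_samples(self):
        rng = np.random.default_rng(7)
        haps = rng.integers(0, 2, size=(60, 6)).astype(np.int8)
        haps[0] = [0, 1] * 3  # keep every site polymorphic enough
        panel = make_panel(haps)
        typed = np.zeros(60, dtype=bool)
        typed[::4] = True
        dm, audit = loo_cross_validate(
            panel, typed, HmmParams(0.05, 0.01), collect_audit=True
        )
        assert dm.dosages.shape == (60, 3)
        for name, donors in audit.items():
            assert len(donors) == 4, "both focal haplotypes are withheld"
            assert not any(d.startswith(name + "_h") for d in donors)

    def test_single_sample_panel_rejected(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng.integers(0, 2, size=(30, 2)).astype(np.int8))
        with pytest.raises(InsufficientDataError):
            loo_cross_validate(panel, np.ones(30, bool), HmmParams(0.05, 0.01))

    def test_loo_less_accurate_than_self_included(self, two_region_panel):
        """Removing the target's own haplotypes can only hurt: per-bin
        aggregate accuracy under leave-one-out is below the self-included
        evaluation."""
        from panelkit.eval_pipeline import FrequencyBinSpec, aggregate_accuracy
        from panelkit.impute_engine import impute_cohort

        panel = two_region_panel.subset(sample_idx=np.arange(40))
        typed = np.zeros(panel.n_sites, dtype=bool)
        typed[::8] = True
        params = HmmParams(1e-3, 1e-3)
        loo, _ = loo_cross_validate(panel, typed, params)
        self_inc = impute_cohort(panel, panel, typed, params)
        bins = FrequencyBinSpec((0.0, 0.05, 0.2, 0.5, 1.0))
        truth = panel.genotypes()
        freq = panel.alt_freq()
        res_loo = aggregate_accuracy(truth, loo, freq, bins).per_bin
        res_self = aggregate_accuracy(truth, self_inc, freq, bins).per_bin
        both = (res_loo["n_variants"] >= 5) & res_loo["r2_pooled"].notna()
        assert (
            res_loo.loc[both, "r2_pooled"] <= res_self.loc[both, "r2_pooled"] + 1e-9
        ).all()


def test_frequency_accuracy_gradient(two_region_panel):
    """Common variants impute better than rare ones (pooled r^2)."""
    from panelkit.eval_pipeline import FrequencyBinSpec, aggregate_accuracy

    panel = two_region_panel
    typed = np.zeros(panel.n_sites, dtype=bool)
    rng = np.random.default_rng(10)
    freq = panel.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf >= 0.05)
    typed[rng.choice(eligible, size=int(0.2 * eligible.size), replace=False)] = True
    params = HmmParams(1e-3, 1e-3)
    dm, _ = loo_cross_validate(panel, typed, params)
    bins = FrequencyBinSpec((0.0, 0.01, 0.05, 0.5, 1.0))
    res = aggregate_accuracy(panel.genotypes(), dm, freq, bins).per_bin
    rare = res.iloc[0]["r2_pooled"]
    common = res.iloc[2]["r2_pooled"]
    assert common > rare
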