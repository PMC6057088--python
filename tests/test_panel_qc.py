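"""Panel QC: depth calibration, HWE exact test, site filters, relatedness."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelkit.containers import MISSING, variant_stats
from panelkit.errors import EmptyPanelError, InsufficientDataError
from panelkit.panel_qc import (
    QcThresholds,
    build_panel,
    calibrate_depth_threshold,
    estimate_pihat,
    hwe_exact_test,
    pairwise_pihat,
    prune_relatives,
    site_filter,
)
from tests.conftest import make_gm, make_panel


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exhaustive enumeration with exact rational arithmetic."""
    n = n_aa + n_ab + n_bb
    n_minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n_minor == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        num = (
            Fraction(math.factorial(n))
            * 2**h
            * math.factorial(n_minor)
            * math.factorial(2 * n - n_minor)
        )
        den = (
            math.factorial(hom_min)
            * math.factorial(h)
            * math.factorial(hom_maj)
            * math.factorial(2 * n)
        )
        return num / den

    p_obs = prob(n_ab)
    total = Fraction(0)
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        p = prob(h)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(57, 78, 13), (0, 50, 0), (10, 5, 10), (1, 1, 1), (0, 1, 0), (3, 0, 3)],
    )
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), abs=1e-12
        )

    def test_all_heterozygote_extreme(self):
        assert hwe_exact_test(0, 50, 0) < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=70),
        st.integers(min_value=0, max_value=70),
        st.integers(min_value=0, max_value=60),
    )
    def test_enumeration_agreement_totals_up_to_200(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_oracle(a, h, b), abs=1e-12)


def _calibration_fixture(error_low, error_high, threshold, seed=0, m=8000):
    """One individual with depth-stratified miscalls and error-free array."""
    rng = np.random.default_rng(seed)
    truth = rng.binomial(2, 0.3, size=(m, 1)).astype(np.int8)
    depths = rng.poisson(10.0, size=(m, 1))
    err = np.where(depths < threshold, error_low, error_high)
    flip = rng.random((m, 1)) < err
    shifted = ((truth + rng.integers(1, 3, size=(m, 1))) % 3).astype(np.int8)
    ngs = make_gm(np.where(flip, shifted, truth))
    arr = make_gm(truth)
    return ngs, depths, arr


class TestDepthCalibration:
    def test_error_free_data(self):
        ngs, depths, arr = _calibration_fixture(0.0, 0.0, 8)
        res = calibrate_depth_threshold(ngs, depths, arr)
        row = res.iloc[0]
        assert row["threshold"] == 0
        assert row["concordance"] == 1.0
        assert bool(row["attainable"])

    def test_low_depth_errors_reach_target(self):
        """Miscalls confined to depth < 8 -> a threshold at or below 8
        reaches the 99.8% concordance target."""
        ngs, depths, arr = _calibration_fixture(0.05, 0.0, 8, seed=1)
        res = calibrate_depth_threshold(ngs, depths, arr, target=0.998)
        row = res.iloc[0]
        assert bool(row["attainable"])
        assert row["threshold"] <= 8
        assert row["concordance"] >= 0.998

    def test_depth_independent_error_unattainable(self):
        ngs, depths, arr = _calibration_fixture(0.02, 0.02, 8, seed=2)
        res = calibrate_depth_threshold(ngs, depths, arr, target=0.998)
        row = res.iloc[0]
        assert not bool(row["attainable"])
        assert row["concordance"] == pytest.approx(0.98, abs=0.01)

    def test_concordance_monotone_when_errors_low_depth(self):
        ngs, depths, arr = _calibration_fixture(0.05, 0.0, 8, seed=3)
        ia = np.arange(ngs.n_sites)
        g_n = ngs.genotypes[:, 0]
        g_a = arr.genotypes[:, 0]
        d = depths[:, 0]
        conc = []
        for t in range(0, 9):
            keep = d >= t
            conc.append((g_n[keep] == g_a[keep]).mean())
        # monotone up to per-depth-class sampling noise; the boundary
        # threshold (all erroneous classes removed) is the global optimum
        assert np.all(np.diff(conc) >= -0.003)
        assert conc[8] == max(conc)

    def test_insufficient_overlap_rejected(self):
        ngs, depths, arr = _calibration_fixture(0.0, 0.0, 8, m=50)
        with pytest.raises(InsufficientDataError):
            calibrate_depth_threshold(ngs, depths, arr, min_sites=100)


class TestSiteFilter:
    def _toy(self):
        """10 sites: 2 low call rate, 1 low MAF, 1 HWE-violating, 6 clean."""
        rng = np.random.default_rng(8)
        n = 100
        g = rng.binomial(2, 0.4, size=(10, n)).astype(np.int8)
        g[0, :20] = MISSING  # call rate 0.80
        g[1, :5] = MISSING  # call rate 0.95
        g[2] = 0
        g[2, 0] = 1  # MAF 0.005... exactly? 1/200 = 0.005 -> kept (strict <)
        g[3] = 0  # monomorphic: MAF 0 -> excluded
        g[4] = 1  # all heterozygous -> HWE exact p << 1e-6
        return make_gm(g)

    def test_toy_verdicts(self):
        gm = self._toy()
        keep, report = site_filter(gm, QcThresholds())
        assert not keep[0] and report.loc[0, "reason"] == "call_rate"
        assert not keep[1] and report.loc[1, "reason"] == "call_rate"
        assert keep[2], "MAF exactly at the threshold is kept (strict <)"
        assert not keep[3] and report.loc[3, "reason"] == "maf"
        assert not keep[4] and report.loc[4, "reason"] == "hwe"
        assert keep.sum() == 6

    def test_call_rate_threshold_strict(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.5, size=(1, 100)).astype(np.int8)
        g[0, :4] = MISSING  # call rate 0.96 < 0.97
        keep, report = site_filter(make_gm(g))
        assert not keep[0] and report.loc[0, "reason"] == "call_rate"

    def test_sample_order_invariance(self):
        gm = self._toy()
        keep1, _ = site_filter(gm)
        perm = np.random.default_rng(3).permutation(gm.n_samples)
        keep2, _ = site_filter(gm.subset(sample_idx=perm))
        assert np.array_equal(keep1, keep2)


class TestRelatedness:
    def test_duplicate_sample_limit(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        g = np.hstack([gm.genotypes, gm.genotypes[:, :1]])
        dup = make_gm(g)
        est = estimate_pihat(dup, "test_000", f"test_{gm.n_samples:03d}")
        assert est.pihat >= 0.95

    def test_parent_offspring_near_half(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        parent, child, rel = small_cohort.relative_pairs[0]
        assert rel == "PO"
        est = estimate_pihat(gm, parent, child)
        assert 0.4 <= est.pihat <= 0.6
        assert est.ibd0 + est.ibd1 + est.ibd2 == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_near_zero(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        est = estimate_pihat(gm, "alpha_0003", "alpha_0017")
        assert abs(est.pihat) < 0.1

    def test_insufficient_sites_rejected(self):
        g = np.random.default_rng(0).binomial(2, 0.5, size=(100, 5)).astype(np.int8)
        with pytest.raises(InsufficientDataError):
            estimate_pihat(make_gm(g), "test_000", "test_001")

    def test_matrix_matches_single_pair(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        mat = pairwise_pihat(gm)
        pair = estimate_pihat(gm, "alpha_0001", "alpha_0002")
        assert mat.loc["alpha_0001", "alpha_0002"] == pytest.approx(pair.pihat, abs=1e-9)


class TestPrune:
    def test_planted_pair_removes_exactly_one(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        result = prune_relatives(gm)
        assert len(result.removed) == 1
        assert result.removed[0] == small_cohort.relative_pairs[0][1]

    def test_no_flagged_pairs_no_removal(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        names = gm.samples["sample"].tolist()
        child = small_cohort.relative_pairs[0][1]
        keep = [i for i, s in enumerate(names) if s != child]
        result = prune_relatives(gm.subset(sample_idx=np.array(keep)))
        assert result.removed == []

    def test_boundary_pihat_not_flagged(self):
        """A pair sitting exactly at the threshold survives (strict >)."""
        thresholds = QcThresholds(pihat_max=0.125)
        assert not (0.125 > thresholds.pihat_max)

    def test_no_pair_above_threshold_after_prune(self, small_cohort):
        gm = small_cohort.truth.genotypes()
        result = prune_relatives(gm)
        kept_idx = [
            i
            for i, s in enumerate(gm.samples["sample"])
            if s in set(result.kept)
        ]
        mat = pairwise_pihat(gm.subset(sample_idx=np.array(kept_idx)))
        vals = mat.to_numpy()
        iu, ju = np.triu_indices(len(vals), k=1)
        assert vals[iu, ju].max() <= 0.125 + 1e-12


class TestBuildPanel:
    def test_counts_after_one_removal(self, small_cohort):
        truth = small_cohort.truth
        names = truth.samples["sample"].tolist()
        kept = [s for s in names if s != small_cohort.relative_pairs[0][1]]
        panel = build_panel(truth, kept, np.ones(truth.n_sites, dtype=bool))
        assert panel.n_samples == truth.n_samples - 1
        assert panel.n_haplotypes == 2 * panel.n_samples

    def test_single_sample(self, small_cohort):
        truth = small_cohort.truth
        panel = build_panel(
            truth, [truth.samples["sample"].iat[0]], np.ones(truth.n_sites, bool)
        )
        assert panel.n_haplotypes == 2

    def test_site_removal_consistent(self, small_cohort):
        truth = small_cohort.truth
        mask = np.ones(truth.n_sites, bool)
        mask[:10] = False
        panel = build_panel(truth, truth.samples["sample"].tolist(), mask)
        assert panel.n_sites == truth.n_sites - 10
        assert panel.haplotypes.shape[0] == len(panel.variants)

    def test_empty_selection_rejected(self, small_cohort):
        with pytest.raises(EmptyPanelError):
            build_panel(
                small_cohort.truth, [], np.ones(small_cohort.truth.n_sites, bool)
            )
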