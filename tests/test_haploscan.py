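"""EHH/EHHS decay, iHH integration, iHS and Rsb scans, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import ehh_pairs_oracle, ehhs_pairs_oracle
from selscan import haploscan as hs


def _hap(alleles, positions=None, chrom="1"):
    a = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, a.shape[1] + 1) * 1000
    return hs.HaplotypeMatrix(alleles=a, positions=np.asarray(positions, np.int64),
                              chrom=chrom)


class TestEHH:
    def test_ehh_is_one_at_core(self):
        h = _hap([[0, 1], [0, 0], [1, 1], [1, 0]])
        d = hs.ehh_decay(h, 0, 1)
        assert d.left_ehh[0] == 1.0 and d.right_ehh[0] == 1.0

    def test_three_carriers_one_identical_pair(self):
        # derived carriers extend as {AB, AB, Ab}: EHH = 1/3 one marker out
        h = _hap([[1, 0], [1, 0], [1, 1], [0, 0], [0, 1]])
        d = hs.ehh_decay(h, 0, 1, cutoff=0.0)
        assert d.right_ehh[1] == pytest.approx(1 / 3)

    def test_identical_carriers_reach_chromosome_end(self):
        h = _hap([[1] * 6, [1] * 6, [0, 1, 0, 1, 0, 1]])
        d = hs.ehh_decay(h, 2, 1)
        assert np.all(d.right_ehh == 1.0) and np.all(d.left_ehh == 1.0)
        assert d.truncation == {"left": "chromosome-end", "right": "chromosome-end"}

    def test_gap_truncates_side(self):
        h = _hap([[1, 1, 1], [1, 1, 0], [0, 0, 1]],
                 positions=[1000, 2000, 500_000])
        d = hs.ehh_decay(h, 0, 1, max_gap=200_000)
        assert d.truncation["right"] == "gap"
        assert d.right_pos[-1] == 2000

    def test_insufficient_carriers_raises(self):
        h = _hap([[1, 0], [0, 0], [0, 1]])
        with pytest.raises(hs.InsufficientCarriersError):
            hs.ehh_decay(h, 0, 1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 30))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        m = int(rng.integers(3, 200))
        a = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        core = int(rng.integers(0, m))
        for allele in (0, 1):
            if (a[:, core] == allele).sum() < 2:
                continue
            d = hs.ehh_decay(_hap(a), core, allele, cutoff=0.0)
            for pos, val in zip(d.right_pos, d.right_ehh):
                j = pos // 1000 - 1
                assert val == pytest.approx(ehh_pairs_oracle(a, core, j, allele))
            for pos, val in zip(d.left_pos, d.left_ehh):
                j = pos // 1000 - 1
                assert val == pytest.approx(ehh_pairs_oracle(a, core, j, allele))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 2 ** 30))
    def test_ehhs_matches_pair_oracle_and_is_one_at_core(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=(int(rng.integers(4, 20)),
                                     int(rng.integers(3, 50)))).astype(np.int8)
        core = int(rng.integers(0, a.shape[1]))
        try:
            d = hs.ehh_decay(_hap(a), core, "all", cutoff=0.0)
        except hs.InsufficientCarriersError:
            return
        assert d.right_ehh[0] == 1.0
        for pos, val in zip(d.right_ehh[:0], []):
            pass
        for pos, val in zip(d.right_pos, d.right_ehh):
            j = pos // 1000 - 1
            assert val == pytest.approx(ehhs_pairs_oracle(a, core, j))

    def test_ehh_non_increasing(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, size=(30, 80)).astype(np.int8)
        d = hs.ehh_decay(_hap(a), 40, 1, cutoff=0.0)
        assert np.all(np.diff(d.right_ehh) <= 1e-12)
        assert np.all(np.diff(d.left_ehh) <= 1e-12)


class TestIntegrate:
    def _decay(self, pos, ehh):
        return hs.EHHDecay(core_index=0, core_allele=1,
                           left_pos=np.array([pos[0]]), left_ehh=np.array([1.0]),
                           right_pos=np.asarray(pos), right_ehh=np.asarray(ehh))

    def test_hand_trapezoid(self):
        d = self._decay([0, 1000, 2000], [1.0, 0.5, 0.05])
        assert hs.integrate(d, cutoff=0.05) == pytest.approx(1025.0)

    def test_flat_side_is_rectangle(self):
        d = self._decay([0, 10_000], [1.0, 1.0])
        assert hs.integrate(d) == pytest.approx(10_000.0)

    def test_doubling_distances_doubles_area(self):
        d1 = self._decay([0, 1000, 3000], [1.0, 0.6, 0.2])
        d2 = self._decay([0, 2000, 6000], [1.0, 0.6, 0.2])
        assert hs.integrate(d2) == pytest.approx(2 * hs.integrate(d1))

    def test_below_cutoff_crossing_interpolated(self):
        # crossing between the last two points is integrated to the cutoff level
        d = self._decay([0, 1000, 2000], [1.0, 0.5, 0.0])
        # segment 1: (1+0.5)/2*1000; segment 2 up to crossing at 0.05:
        # fraction (0.5-0.05)/0.5 = 0.9 -> (0.5+0.05)/2 * 900
        assert hs.integrate(d, cutoff=0.05) == pytest.approx(750 + 247.5)

    def test_core_only_decay_is_zero(self):
        d = self._decay([0], [1.0])
        assert hs.integrate(d) == 0.0


class TestIhsScan:
    def test_symmetric_site_has_raw_zero(self):
        # ancestral and derived classes with mirror-identical decay
        a = np.array([[1, 1, 1, 0], [1, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 1]],
                     dtype=np.int8)
        tr = hs.ihs_scan(_hap(a), maf_min=0.0)
        assert tr["raw"].iloc[1] == pytest.approx(0.0)

    def test_bin_standardization_identity(self, sweep_ihs_case):
        tr = sweep_ihs_case
        scored = tr.dropna(subset=["score"])
        bins = np.floor(scored["freq_derived"] / 0.025).astype(int)
        for b, grp in scored.groupby(bins):
            if len(grp) >= 2 and grp["raw"].std() > 0:
                assert grp["score"].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp["score"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_p_is_two_sided_normal(self, sweep_ihs_case):
        scored = sweep_ihs_case.dropna(subset=["score"])
        expect = 2 * stats.norm.sf(np.abs(scored["score"]))
        np.testing.assert_allclose(scored["p"], expect, rtol=1e-12)

    def test_low_maf_sites_flagged_not_scored(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, size=(40, 30)).astype(np.int8)
        a[:, 5] = 0
        a[0, 5] = 1  # freq 1/40 < 0.05
        tr = hs.ihs_scan(_hap(a))
        assert tr["flag"].iloc[5] == "low_maf" and np.isnan(tr["score"].iloc[5])

    def test_invariant_to_haplotype_row_order(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=(20, 40)).astype(np.int8)
        tr1 = hs.ihs_scan(_hap(a), maf_min=0.0)
        perm = rng.permutation(20)
        tr2 = hs.ihs_scan(_hap(a[perm]), maf_min=0.0)
        np.testing.assert_allclose(tr1["raw"], tr2["raw"], equal_nan=True)


class TestRsbScan:
    def test_identical_populations_give_raw_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, size=(16, 40)).astype(np.int8)
        tr = hs.rsb_scan(_hap(a), _hap(a.copy()))
        ok = tr["raw"].notna()
        assert ok.any()
        np.testing.assert_allclose(tr.loc[ok, "raw"], 0.0, atol=1e-12)

    def test_median_standardization_centers_at_zero(self, sweep_rsb):
        scored = sweep_rsb["score"].dropna()
        assert np.median(scored) == pytest.approx(0.0, abs=1e-12)

    def test_swapping_populations_negates_raw(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 2, size=(14, 50)).astype(np.int8)
        b = rng.integers(0, 2, size=(18, 50)).astype(np.int8)
        ab = hs.rsb_scan(_hap(a), _hap(b))
        ba = hs.rsb_scan(_hap(b), _hap(a))
        np.testing.assert_allclose(ab["raw"], -ba["raw"], atol=1e-12, equal_nan=True)

    def test_shared_site_intersection(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 2, size=(10, 6)).astype(np.int8)
        b = rng.integers(0, 2, size=(10, 4)).astype(np.int8)
        ha = _hap(a, positions=[1, 2, 3, 4, 5, 6])
        hb = _hap(b, positions=[2, 3, 4, 9])
        tr = hs.rsb_scan(ha, hb)
        assert tr["pos"].tolist() == [2, 3, 4]

    def test_sweep_rsb_peak_near_planted_locus(self, sweep_study, sweep_rsb):
        sw = sweep_study["truth"].sweeps[0]
        am = sweep_rsb.loc[sweep_rsb["score"].abs().idxmax()]
        assert abs(int(am["pos"]) - sw["pos"]) <= 500_000


class TestThresholds:
    def test_fixed_threshold_is_389(self):
        thr = hs.significance_threshold(method="fixed", p_cutoff=1e-4)
        assert round(thr, 2) == 3.89

    def test_bh_threshold_by_enumeration(self):
        p = [0.001, 0.01, 0.02, 0.9]
        thr = hs.significance_threshold(p, method="bh", alpha=0.05)
        assert thr == pytest.approx(0.02)  # first three rejected

    def test_permutation_threshold_monotone_in_alpha(self):
        rng0 = np.random.default_rng(0)
        base = rng0.normal(size=200)

        def perm(rng):
            return base[rng.permutation(200)][:50]  # subsample max varies

        t05 = hs.significance_threshold(method="max-permutation", alpha=0.05,
                                        B=200, seed=1, perm_scores_fn=perm)
        t20 = hs.significance_threshold(method="max-permutation", alpha=0.20,
                                        B=200, seed=1, perm_scores_fn=perm)
        assert t05 >= t20

    def test_small_B_refused(self):
        with pytest.raises(ValueError, match="B < 100"):
            hs.significance_threshold(method="max-permutation", alpha=0.05,
                                      B=50, seed=1, perm_scores_fn=lambda r: [1.0])
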