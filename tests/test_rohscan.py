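"""ROH detection, consensus pooling, allelic matching and LROH criteria."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dataset
from oracles import roh_oracle
from selscan import genodata as gd
from selscan import rohscan as rs

SMALL = rs.ROHParams(min_snp=20, min_kb=1.0, window_snp=10, window_het_max=1,
                     window_missing_max=0, window_threshold=0.05)


def _one_sample_ds(g, positions=None):
    return make_dataset(np.asarray(g, dtype=np.int8)[None, :], positions=positions)


class TestDetect:
    def test_all_het_individual_has_no_segments(self):
        ds = _one_sample_ds([1] * 300)
        assert rs.detect_roh(ds) == []

    def test_planted_run_recovered_at_exact_span(self):
        # 200 homozygous SNVs spanning 1.5 Mb inside het-dense flanks
        flank = np.ones(150, dtype=np.int8)  # heterozygous flanks
        run = np.full(200, 2)
        g = np.concatenate([flank, run, flank])
        pos = np.concatenate([
            np.arange(150) * 2000 + 1,
            300_000 + np.arange(200) * 7500 + 1,       # 1.49 Mb span
            1_800_000 + np.arange(150) * 2000 + 1,
        ])
        ds = _one_sample_ds(g, positions=pos)
        segs = rs.detect_roh(ds, rs.ROHParams())
        assert len(segs) == 1
        assert segs[0].first_pos == pos[150] and segs[0].last_pos == pos[349]
        assert segs[0].n_snp == 200 and segs[0].n_het == 0

    def test_four_hets_per_window_kill_the_run(self):
        g = np.full(400, 2)
        g[np.arange(0, 400, 12)] = 1  # >3 hets in every 50-SNV window
        ds = _one_sample_ds(g)
        assert rs.detect_roh(ds, rs.ROHParams(min_snp=50)) == []

    def test_short_chromosome_skipped_with_warning(self):
        ds = _one_sample_ds([2] * 10)
        with pytest.warns(UserWarning, match="fewer than"):
            assert rs.detect_roh(ds, rs.ROHParams()) == []

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 2 ** 30))
    def test_matches_window_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(100, 2000))
        # blocks of homozygous and mixed genotype to create runs
        g = rng.choice([0, 1, 2], size=m, p=[0.45, 0.15, 0.4]).astype(np.int8)
        block = rng.integers(0, max(m - 300, 1))
        g[block:block + 300] = rng.choice([0, 2], size=min(300, m - block))
        pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=m, replace=False))
        prm = rs.ROHParams(min_snp=50, min_kb=1.0, window_snp=25, window_het_max=2,
                           window_missing_max=0, window_threshold=0.05)
        ds = _one_sample_ds(g, positions=pos)
        segs = rs.detect_roh(ds, prm)
        oracle = roh_oracle(g.tolist(), pos.tolist(), min_snp=50, min_kb=1.0,
                            window_snp=25, window_het_max=2, window_missing_max=0,
                            window_threshold=0.05)
        assert [(s.first_pos, s.last_pos, s.n_snp) for s in segs] == oracle

    def test_inbred_zone_has_more_roh(self, inbred_study, inbred_segments):
        ds = inbred_study["ds"]
        zones = dict(zip(ds.samples["sample_id"], ds.samples["zone"]))
        sf = rs.segments_frame(inbred_segments)
        sf["zone"] = sf["sample_id"].map(zones)
        sf["length"] = sf["end"] - sf["start"]
        per_zone = sf.groupby("zone")["length"].sum()
        n_per_zone = ds.samples["zone"].value_counts()
        mean_case = per_zone.get("case", 0) / n_per_zone["case"]
        mean_ctrl = per_zone.get("control", 0) / n_per_zone["control"]
        assert mean_case > mean_ctrl

    def test_planted_roh_recovered_at_exact_snv_spans(self, inbred_study, inbred_segments):
        truth = inbred_study["truth"]
        v = inbred_study["ds_qc"].variants
        sf = rs.segments_frame(inbred_segments)
        for p in truth.planted_roh:
            inside = v[(v["chrom"] == p["chrom"]) & (v["pos"] >= p["first_pos"])
                       & (v["pos"] <= p["last_pos"])]
            exp_first, exp_last = inside["pos"].iloc[0], inside["pos"].iloc[-1]
            hit = sf[(sf["sample_id"] == p["sample_id"]) & (sf["chrom"] == p["chrom"])
                     & (sf["start"] == exp_first - 1) & (sf["end"] == exp_last)]
            assert len(hit) == 1, f"planted ROH not exactly recovered: {p}"


class TestPooling:
    def _segment(self, sample, start, end, chrom="1", n_snp=100):
        return rs.ROHSegment(sample_id=sample, chrom=chrom, start=start, end=end,
                             n_snp=n_snp, n_het=0, n_missing=0,
                             first_pos=start + 1, last_pos=end)

    def test_disjoint_segments_form_singleton_pools(self):
        segs = [self._segment("a", 0, 10_000), self._segment("b", 20_000, 30_000)]
        pools = rs.pool_segments(segs)
        assert len(pools) == 2 and all(p.n_members == 1 for p in pools)

    def test_consensus_is_interval_intersection(self):
        segs = [self._segment("a", 10_000, 20_000),
                self._segment("b", 15_000, 30_000),
                self._segment("c", 18_000, 22_000)]
        pools = rs.pool_segments(segs)
        assert len(pools) == 1
        assert (pools[0].consensus_start, pools[0].consensus_end) == (18_000, 20_000)

    def test_pooling_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        segs = [self._segment(f"s{i}", int(s), int(s) + int(l))
                for i, (s, l) in enumerate(zip(rng.integers(0, 10 ** 6, 30),
                                               rng.integers(5000, 50_000, 30)))]
        a = rs.pool_segments(segs)
        b = rs.pool_segments(segs[::-1])
        key = lambda pools: sorted((p.consensus_start, p.consensus_end, p.n_members)
                                   for p in pools)
        assert key(a) == key(b)

    def test_allelic_mismatch_splits_match_groups(self):
        # two members overlapping with 50% genotype concordance -> same pool,
        # different match groups at the 0.95 threshold
        g = np.zeros((2, 40), dtype=np.int8)
        g[1, ::2] = 2  # disagree at every other site
        ds = make_dataset(g, positions=np.arange(1, 41) * 100)
        segs = [self._segment("s0", 0, 4000), self._segment("s1", 0, 4000)]
        pools = rs.pool_segments(segs, ds=ds, match_threshold=0.95)
        assert len(pools) == 1 and len(pools[0].match_groups) == 2

    def test_identical_members_share_a_match_group(self):
        g = np.full((2, 40), 2, dtype=np.int8)
        ds = make_dataset(g, positions=np.arange(1, 41) * 100)
        segs = [self._segment("s0", 0, 4000), self._segment("s1", 0, 4000)]
        pools = rs.pool_segments(segs, ds=ds)
        assert len(pools[0].match_groups) == 1


class TestLROH:
    def _pool(self, members, start, end, pool_id=0):
        segs = [rs.ROHSegment(sample_id=s, chrom="1", start=start, end=end,
                              n_snp=100, n_het=0, n_missing=0,
                              first_pos=start + 1, last_pos=end)
                for s in members]
        return rs.ConsensusPool(pool_id=pool_id, chrom="1", members=segs,
                                consensus_start=start, consensus_end=end)

    def test_mixed_zone_pool_fails_criterion_d(self):
        pool = self._pool(["a", "b"], 0, 50_000)
        zones = {"a": "case", "b": "control"}
        calls = rs.classify_lroh([pool], zones, {"case": 10, "control": 10})
        assert calls[0].passed["d"] is False and not calls[0].passed_all

    def test_small_pool_fails_zone_fraction(self):
        pool = self._pool(["a", "b", "c"], 0, 50_000)
        zones = {s: "case" for s in "abc"}
        calls = rs.classify_lroh([pool], zones, {"case": 100, "control": 100})
        assert calls[0].passed["c"] is False

    def test_short_consensus_fails_length(self):
        pool = self._pool(["a", "b"], 0, 800)
        zones = {"a": "case", "b": "case"}
        calls = rs.classify_lroh([pool], zones, {"case": 10, "control": 10})
        assert calls[0].passed["a"] is False

    def test_qualifying_pool_passes_all(self):
        pool = self._pool(["a", "b"], 0, 50_000)
        zones = {"a": "case", "b": "case"}
        calls = rs.classify_lroh([pool], zones, {"case": 10, "control": 10})
        assert calls[0].passed_all and calls[0].zone == "case"

    def test_empty_zone_rejected(self):
        pool = self._pool(["a"], 0, 50_000)
        with pytest.raises(ValueError):
            rs.classify_lroh([pool], {"a": "case"}, {"case": 0})

    def test_reported_lroh_only_from_inbred_zone(self, inbred_study, inbred_segments):
        ds = inbred_study["ds_qc"]
        zones = dict(zip(ds.samples["sample_id"], ds.samples["zone"]))
        pools = rs.pool_segments(inbred_segments, ds=ds, zones=zones)
        calls = rs.classify_lroh(pools, zones,
                                 ds.samples["zone"].value_counts().to_dict())
        reported = [c for c in calls if c.passed_all]
        assert {c.zone for c in reported} <= {"case"}
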