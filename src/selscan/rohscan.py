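"""Runs of homozygosity: scanning-window detection, pooling, LROH calls.

Detection follows the PLINK 1.9 sliding-window algorithm: windows of
``window_snp`` consecutive SNVs move one SNV at a time; a window passes if
it holds at most ``window_het_max`` heterozygous and ``window_missing_max``
missing calls; each SNV's hit rate is the fraction of passing windows among
the windows containing it; SNVs at or above ``window_threshold`` are
eligible; maximal runs of eligible SNVs (split at gaps over ``max_gap_kb``)
are trimmed to homozygous endpoints and reported if they satisfy the
``min_snp``, ``min_kb`` and density rules.

Overlapping segments are pooled per chromosome by single linkage; the pool
consensus is the intersection of member intervals; members are partitioned
into allelic-match groups at >= 95% homozygous-genotype concordance over the
consensus SNVs.  A pool becomes a landscape-ROH (LROH) call when (a) the
consensus is at least ``min_len_kb`` long, (b) the consensus is covered by
every member segment, (c) the members represent at least ``min_zone_fraction``
of the samples in their climate zone, and (d) all members come from a single
zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset


@dataclass
class ROHParams:
    min_snp: int = 100
    min_kb: float = 1.0
    window_snp: int = 50
    window_het_max: int = 3
    window_missing_max: int = 0
    window_threshold: float = 0.05
    max_gap_kb: float = 1000.0
    density_kb_per_snp: float = 50.0


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start: int      # 0-based half-open span of the first..last SNV of the run
    end: int
    n_snp: int
    n_het: int
    n_missing: int
    first_pos: int  # 1-based position of the first SNV
    last_pos: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusPool:
    pool_id: int
    chrom: str
    members: list            # list[ROHSegment]
    consensus_start: int     # 0-based half-open; start >= end means empty
    consensus_end: int
    match_groups: list = field(default_factory=list)  # list of member index lists
    zones: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class LROHCall:
    pool_id: int
    chrom: str
    zone: str
    consensus_start: int
    consensus_end: int
    n_members: int
    zone_fraction: float
    passed: dict = field(default_factory=dict)  # criterion letter -> bool

    @property
    def passed_all(self) -> bool:
        return all(self.passed.values())


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _segments_one_sample(g: np.ndarray, pos: np.ndarray, chrom: str,
                         sample_id: str, prm: ROHParams) -> list[ROHSegment]:
    m = g.size
    w = prm.window_snp
    if m < w:
        return []
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    passing = ((chet[starts + w] - chet[starts] <= prm.window_het_max)
               & (cmis[starts + w] - cmis[starts] <= prm.window_missing_max))
    cpass = np.concatenate([[0], np.cumsum(passing.astype(np.int64))])
    # windows containing SNV i start in [max(0, i-w+1), min(i, n_win-1)]
    i = np.arange(m)
    w_lo = np.maximum(0, i - w + 1)
    w_hi = np.minimum(i, n_win - 1)
    n_containing = w_hi - w_lo + 1
    n_passing = cpass[w_hi + 1] - cpass[w_lo]
    eligible = (n_passing / n_containing) >= prm.window_threshold

    segments = []
    max_gap_bp = prm.max_gap_kb * 1000.0
    run_start = None
    prev = None
    for idx in range(m + 1):
        in_run = idx < m and eligible[idx]
        if in_run and run_start is not None and pos[idx] - pos[prev] > max_gap_bp:
            _flush_run(segments, g, pos, run_start, prev, chrom, sample_id, prm)
            run_start = idx
        elif in_run and run_start is None:
            run_start = idx
        elif not in_run and run_start is not None:
            _flush_run(segments, g, pos, run_start, prev, chrom, sample_id, prm)
            run_start = None
        if in_run:
            prev = idx
    return segments


def _flush_run(segments, g, pos, lo, hi, chrom, sample_id, prm: ROHParams) -> None:
    # trim endpoints to homozygous, non-missing SNVs
    hom = (g == 0) | (g == 2)
    while lo <= hi and not hom[lo]:
        lo += 1
    while hi >= lo and not hom[hi]:
        hi -= 1
    if hi < lo:
        return
    n_snp = hi - lo + 1
    length_bp = int(pos[hi]) - int(pos[lo]) + 1
    if n_snp < prm.min_snp:
        return
    if length_bp / 1000.0 < prm.min_kb:
        return
    if (length_bp / 1000.0) / n_snp > prm.density_kb_per_snp:
        return
    seg = ROHSegment(
        sample_id=sample_id, chrom=str(chrom),
        start=int(pos[lo]) - 1, end=int(pos[hi]),
        n_snp=n_snp,
        n_het=int((g[lo:hi + 1] == 1).sum()),
        n_missing=int((g[lo:hi + 1] == MISSING).sum()),
        first_pos=int(pos[lo]), last_pos=int(pos[hi]),
    )
    segments.append(seg)


def detect_roh(ds: GenotypeDataset, params: ROHParams | None = None) -> list[ROHSegment]:
    """Per-individual ROH segments over every chromosome of the dataset."""
    prm = params or ROHParams()
    segments: list[ROHSegment] = []
    skipped = 0
    for chrom, sub in ds.variants.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(np.int64)
        if cols.size < prm.window_snp:
            skipped += 1
            continue
        for i in range(ds.n_samples):
            segments.extend(_segments_one_sample(
                ds.genotypes[i, cols], pos, str(chrom),
                str(ds.samples["sample_id"].iloc[i]), prm))
    if skipped:
        warnings.warn(f"skipped {skipped} chromosome(s) with fewer than "
                      f"{prm.window_snp} SNVs")
    return segments


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start, "end": s.end,
        "n_snp": s.n_snp, "n_het": s.n_het, "n_missing": s.n_missing,
    } for s in segments])


# ---------------------------------------------------------------------------
# Pooling and allelic matching
# ---------------------------------------------------------------------------

def _allelic_match_groups(pool_members: list[ROHSegment], ds: GenotypeDataset,
                          c_start: int, c_end: int, threshold: float) -> list[list[int]]:
    sid_to_row = {s: i for i, s in enumerate(ds.samples["sample_id"])}
    chrom = pool_members[0].chrom
    vmask = ((ds.variants["chrom"].astype(str) == chrom)
             & (ds.variants["pos"] > c_start) & (ds.variants["pos"] <= c_end)).to_numpy()
    cols = np.flatnonzero(vmask)
    k = len(pool_members)
    genos = np.stack([ds.genotypes[sid_to_row[m.sample_id], cols] for m in pool_members])
    hom = (genos == 0) | (genos == 2)
    adj = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            both = hom[i] & hom[j]
            if both.sum() == 0:
                same = False
            else:
                same = (genos[i][both] == genos[j][both]).mean() >= threshold
            adj[i, j] = adj[j, i] = same
    # connected components of the match graph
    groups, seen = [], set()
    for i in range(k):
        if i in seen:
            continue
        comp, stack = [], [i]
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        groups.append(sorted(comp))
    return groups


def pool_segments(segments: list[ROHSegment], ds: GenotypeDataset | None = None,
                  match_threshold: float = 0.95,
                  zones: dict | None = None) -> list[ConsensusPool]:
    """Single-linkage overlap pools per chromosome with interval consensus.

    ``ds`` (when given) enables allelic-match grouping over the consensus
    SNVs; ``zones`` maps sample_id -> zone for downstream classification.
    """
    pools: list[ConsensusPool] = []
    pool_id = 0
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.start, s.end, s.sample_id))
        cluster: list[ROHSegment] = []
        cluster_end = None
        for s in segs + [None]:
            if s is not None and cluster and s.start < cluster_end:
                cluster.append(s)
                cluster_end = max(cluster_end, s.end)
            else:
                if cluster:
                    c_start = max(m.start for m in cluster)
                    c_end = min(m.end for m in cluster)
                    pool = ConsensusPool(
                        pool_id=pool_id, chrom=chrom, members=cluster,
                        consensus_start=c_start, consensus_end=c_end,
                        zones=[zones.get(m.sample_id) for m in cluster] if zones else [],
                    )
                    if ds is not None and c_end > c_start and len(cluster) > 1:
                        pool.match_groups = _allelic_match_groups(
                            cluster, ds, c_start, c_end, match_threshold)
                    elif cluster:
                        pool.match_groups = [[i] for i in range(len(cluster))]
                    pools.append(pool)
                    pool_id += 1
                if s is not None:
                    cluster = [s]
                    cluster_end = s.end
    return pools


def classify_lroh(pools: list[ConsensusPool], zones: dict,
                  zone_sizes: dict, min_len_kb: float = 1.0,
                  min_zone_fraction: float = 0.05) -> list[LROHCall]:
    """Landscape-ROH calls: audit flags for criteria (a)-(d) on every pool.

    ``zones`` maps sample_id -> zone; ``zone_sizes`` maps zone -> number of
    samples in that zone.  Only calls passing all four criteria are the
    reported LROH; the returned list carries every pool with a non-empty
    consensus, with per-criterion flags.
    """
    for z, n in zone_sizes.items():
        if n <= 0:
            raise ValueError(f"zone {z!r} has no samples")
    calls: list[LROHCall] = []
    for pool in pools:
        if pool.consensus_end <= pool.consensus_start:
            continue  # emptied by intersection; dropped before classification
        member_zones = [zones[m.sample_id] for m in pool.members]
        uniq = sorted(set(member_zones))
        zone = max(uniq, key=member_zones.count)
        n_samples = len({m.sample_id for m in pool.members})
        length_kb = (pool.consensus_end - pool.consensus_start) / 1000.0
        covered = all(m.start <= pool.consensus_start and m.end >= pool.consensus_end
                      for m in pool.members)
        frac = n_samples / zone_sizes[zone]
        calls.append(LROHCall(
            pool_id=pool.pool_id, chrom=pool.chrom, zone=zone,
            consensus_start=pool.consensus_start, consensus_end=pool.consensus_end,
            n_members=n_samples, zone_fraction=frac,
            passed={
                "a": length_kb >= min_len_kb,
                "b": covered,
                "c": frac >= min_zone_fraction,
                "d": len(uniq) == 1,
            },
        ))
    return calls


_LROH_COLS = ["pool_id", "chrom", "zone", "start", "end", "n_members",
              "zone_fraction", "pass_a", "pass_b", "pass_c", "pass_d", "lroh"]


def lroh_frame(calls: list[LROHCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=_LROH_COLS)
    return pd.DataFrame([{
        "pool_id": c.pool_id, "chrom": c.chrom, "zone": c.zone,
        "start": c.consensus_start, "end": c.consensus_end,
        "n_members": c.n_members, "zone_fraction": c.zone_fraction,
        "pass_a": c.passed["a"], "pass_b": c.passed["b"],
        "pass_c": c.passed["c"], "pass_d": c.passed["d"],
        "lroh": c.passed_all,
    } for c in calls])
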