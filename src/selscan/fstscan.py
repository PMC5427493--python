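"""Per-site fixation-index estimation, overlapping-window averaging, peaks.

The default estimator is Weir & Cockerham's (1984) variance-components
theta-hat for r = 2 populations, computed from per-group sample sizes,
allele frequencies and observed heterozygote frequencies.  Hudson's
estimator is available as a robustness cross-check.  Windows are 100 kb
with a 50 kb step (50% overlap) anchored at coordinate 0 per chromosome;
peaks are local window maxima at or above a threshold (default 0.2) whose
base is the contiguous run of windows above a base level (default: the
genome-wide mean of window means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset


@dataclass
class Peak:
    chrom: str
    apex_start: int
    apex_end: int
    apex_value: float
    base_start: int
    base_end: int


def _group_site_stats(g: np.ndarray):
    """(n_called, alt freq, observed het freq) per site for one group's genotypes."""
    called = g != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    het = np.where(called, g == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def weir_cockerham_components(n1, p1, h1, n2, p2, h2):
    """Vectorized W&C (1984) a, b, c variance components for two populations.

    Arguments are per-site sample sizes (diploids), alt-allele frequencies
    and observed heterozygote frequencies.  Returns ``(a, b, c)``; entries
    are NaN where a group has fewer than 2 called diploids.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                     - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
        c = hbar / 2.0
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(nbar)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def per_site_fst(ds: GenotypeDataset, group_col: str = "zone",
                 estimator: str = "weir-cockerham") -> pd.DataFrame:
    """Per-site F_ST between exactly two groups of ``group_col``.

    Returns ``chrom, pos, a, b, c, theta`` (Weir-Cockerham) or
    ``chrom, pos, theta`` (Hudson).  theta is NaN when the site is
    monomorphic overall or the total variance is non-positive.
    """
    groups = ds.samples[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups in {group_col!r}, got {list(groups)}")
    g1 = ds.genotypes[np.flatnonzero((ds.samples[group_col] == groups[0]).to_numpy())]
    g2 = ds.genotypes[np.flatnonzero((ds.samples[group_col] == groups[1]).to_numpy())]
    n1, p1, h1 = _group_site_stats(g1)
    n2, p2, h2 = _group_site_stats(g2)
    pool = (2 * n1 * p1 + 2 * n2 * p2) / (2 * n1 + 2 * n2)
    mono = ~np.isfinite(pool) | (pool <= 0) | (pool >= 1)
    out = pd.DataFrame({"chrom": ds.variants["chrom"], "pos": ds.variants["pos"]})
    if estimator == "weir-cockerham":
        a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = a + b + c
            theta = np.where(tot > 0, a / tot, np.nan)
        theta[mono] = np.nan
        out["a"], out["b"], out["c"], out["theta"] = a, b, c, theta
    elif estimator == "hudson":
        with np.errstate(invalid="ignore", divide="ignore"):
            num = ((p1 - p2) ** 2
                   - p1 * (1 - p1) / np.maximum(2 * n1 - 1, 1)
                   - p2 * (1 - p2) / np.maximum(2 * n2 - 1, 1))
            den = p1 * (1 - p2) + p2 * (1 - p1)
            theta = np.where(den > 0, num / den, np.nan)
        theta[mono | (n1 < 2) | (n2 < 2)] = np.nan
        out["theta"] = theta
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return out


def sliding_windows(sites: pd.DataFrame, value_col: str = "theta",
                    size: int = 100_000, step: int = 50_000,
                    min_sites: int = 1) -> pd.DataFrame:
    """Mean of ``value_col`` in overlapping windows anchored at 0 per chromosome.

    Windows are 0-based half-open ``[start, start+size)``; a 1-based site at
    ``pos`` falls in windows covering ``pos-1``.  Window starts run from 0 in
    ``step`` increments up to the last scored site.  Windows holding fewer
    than ``min_sites`` non-missing values get ``mean_stat`` NaN.
    """
    if step > size:
        raise ValueError("step larger than window size would leave gaps")
    frames = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy(np.int64) - 1
        vals = sub[value_col].to_numpy(float)
        last = int(pos0.max())
        starts = np.arange(0, last + 1, step, dtype=np.int64)
        n_sites = np.zeros(starts.size, dtype=np.int64)
        sums = np.zeros(starts.size)
        ok = np.isfinite(vals)
        # each site belongs to windows with start in (pos-size, pos]
        for s_idx, start in enumerate(starts):
            inw = (pos0 >= start) & (pos0 < start + size)
            m = inw & ok
            n_sites[s_idx] = int(m.sum())
            sums[s_idx] = vals[m].sum() if m.any() else 0.0
        with np.errstate(invalid="ignore"):
            mean = np.where(n_sites >= max(min_sites, 1), sums / np.maximum(n_sites, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + size,
            "n_sites": n_sites, "mean_stat": mean,
        }))
    return pd.concat(frames, ignore_index=True)


def call_peaks(windows: pd.DataFrame, peak_threshold: float = 0.2,
               base_rule: str = "genomewide-mean") -> list[Peak]:
    """Local-maximum windows at/above ``peak_threshold`` with their bases.

    The base is the maximal contiguous run of windows around the apex whose
    mean stays above the base level: the genome-wide mean of window means
    (default) or half the apex value (``base_rule="half-apex"``).
    Overlapping peak bases on a chromosome are merged, keeping the higher apex.
    """
    if base_rule not in ("genomewide-mean", "half-apex"):
        raise ValueError(f"unknown base_rule {base_rule!r}")
    gw_mean = float(np.nanmean(windows["mean_stat"])) if len(windows) else 0.0
    peaks: list[Peak] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        v = sub["mean_stat"].to_numpy(float)
        n = len(sub)
        for i in range(n):
            if not np.isfinite(v[i]) or v[i] < peak_threshold:
                continue
            left = v[i - 1] if i > 0 and np.isfinite(v[i - 1]) else -np.inf
            right = v[i + 1] if i < n - 1 and np.isfinite(v[i + 1]) else -np.inf
            if v[i] < left or v[i] < right:
                continue  # not a local maximum
            level = gw_mean if base_rule == "genomewide-mean" else v[i] / 2.0
            lo = i
            while lo - 1 >= 0 and np.isfinite(v[lo - 1]) and v[lo - 1] > level:
                lo -= 1
            hi = i
            while hi + 1 < n and np.isfinite(v[hi + 1]) and v[hi + 1] > level:
                hi += 1
            peaks.append(Peak(
                chrom=str(chrom),
                apex_start=int(sub["start"].iloc[i]), apex_end=int(sub["end"].iloc[i]),
                apex_value=float(v[i]),
                base_start=int(sub["start"].iloc[lo]), base_end=int(sub["end"].iloc[hi]),
            ))
    # merge overlapping bases per chromosome, keep the strongest apex
    merged: list[Peak] = []
    for pk in sorted(peaks, key=lambda p: (p.chrom, p.base_start)):
        if merged and merged[-1].chrom == pk.chrom and pk.base_start < merged[-1].base_end:
            prev = merged[-1]
            keep = pk if pk.apex_value > prev.apex_value else prev
            merged[-1] = Peak(chrom=pk.chrom,
                              apex_start=keep.apex_start, apex_end=keep.apex_end,
                              apex_value=keep.apex_value,
                              base_start=min(prev.base_start, pk.base_start),
                              base_end=max(prev.base_end, pk.base_end))
        else:
            merged.append(pk)
    return merged
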