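"""Independent brute-force oracles used to validate the implementations.

Each oracle is written from the textbook definition with plain loops and no
shared code with the package, so agreement is meaningful.
"""

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components, r = 2, scalar per site
# ---------------------------------------------------------------------------

def wc_site_oracle(g1, g2):
    """(a, b, c) from two groups' genotype vectors (alt-dosage, -1 missing)."""
    g1 = [g for g in g1 if g != MISSING]
    g2 = [g for g in g2 if g != MISSING]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return (float("nan"),) * 3
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# EHH by exhaustive pair enumeration
# ---------------------------------------------------------------------------

def ehh_pairs_oracle(alleles, core, target, core_allele):
    """EHH at marker ``target`` for carriers of ``core_allele`` at ``core``:
    identical pairs over the inclusive interval, by checking every pair."""
    carriers = [i for i in range(alleles.shape[0]) if alleles[i, core] == core_allele]
    n = len(carriers)
    if n < 2:
        return float("nan")
    lo, hi = min(core, target), max(core, target)
    same = 0
    for x in range(n):
        for y in range(x + 1, n):
            if all(alleles[carriers[x], j] == alleles[carriers[y], j]
                   for j in range(lo, hi + 1)):
                same += 1
    return same / (n * (n - 1) / 2)


def ehhs_pairs_oracle(alleles, core, target):
    """EHHS at ``target``: all-haplotype identical-pair fraction over the
    interval, normalized by the identical-pair fraction at the core alone."""
    n = alleles.shape[0]
    lo, hi = min(core, target), max(core, target)
    same_interval = same_core = 0
    for x in range(n):
        for y in range(x + 1, n):
            if alleles[x, core] == alleles[y, core]:
                same_core += 1
                if all(alleles[x, j] == alleles[y, j] for j in range(lo, hi + 1)):
                    same_interval += 1
    if same_core == 0:
        return float("nan")
    return same_interval / same_core


# ---------------------------------------------------------------------------
# PLINK-style ROH by explicit window enumeration
# ---------------------------------------------------------------------------

def roh_oracle(g, pos, min_snp=100, min_kb=1.0, window_snp=50, window_het_max=3,
               window_missing_max=0, window_threshold=0.05, max_gap_kb=1000.0,
               density_kb_per_snp=50.0):
    """Segments (first_pos, last_pos, n_snp) for one sample on one chromosome."""
    m = len(g)
    if m < window_snp:
        return []
    passing = []
    for w in range(m - window_snp + 1):
        win = g[w:w + window_snp]
        het = sum(1 for x in win if x == 1)
        mis = sum(1 for x in win if x == MISSING)
        passing.append(het <= window_het_max and mis <= window_missing_max)
    eligible = []
    for i in range(m):
        wins = [w for w in range(max(0, i - window_snp + 1),
                                 min(i, m - window_snp) + 1)]
        rate = sum(passing[w] for w in wins) / len(wins)
        eligible.append(rate >= window_threshold)
    # maximal eligible runs, split at large gaps
    runs, cur = [], None
    prev = None
    for i in range(m + 1):
        inr = i < m and eligible[i]
        if inr and cur is not None and pos[i] - pos[prev] > max_gap_kb * 1000:
            runs.append((cur, prev))
            cur = i
        elif inr and cur is None:
            cur = i
        elif not inr and cur is not None:
            runs.append((cur, prev))
            cur = None
        if inr:
            prev = i
    out = []
    for lo, hi in runs:
        while lo <= hi and g[lo] not in (0, 2):
            lo += 1
        while hi >= lo and g[hi] not in (0, 2):
            hi -= 1
        if hi < lo:
            continue
        n_snp = hi - lo + 1
        length_kb = (pos[hi] - pos[lo] + 1) / 1000
        if (n_snp >= min_snp and length_kb >= min_kb
                and length_kb / n_snp <= density_kb_per_snp):
            out.append((int(pos[lo]), int(pos[hi]), n_snp))
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up and hypergeometric tail
# ---------------------------------------------------------------------------

def bh_oracle(pvals, alpha=0.05):
    """(q-values, rejected) by the literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * alpha / m:
            k_star = k
    rejected = [False] * m
    for k in range(k_star):
        rejected[order[k]] = True
    return q, rejected


def hypergeom_tail_oracle(k, N, K, n):
    """Exact P(X >= k) by summing hypergeometric point masses as fractions."""
    total = Fraction(0)
    denom = comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


# ---------------------------------------------------------------------------
# Window means by naive rescan
# ---------------------------------------------------------------------------

def window_means_oracle(pos, vals, size, step):
    """[(start, n, mean)] for windows anchored at 0 up to the last site."""
    pos0 = [p - 1 for p in pos]
    out = []
    start = 0
    last = max(pos0)
    while start <= last:
        inw = [v for p, v in zip(pos0, vals)
               if start <= p < start + size and not np.isnan(v)]
        out.append((start, len(inw), float(np.mean(inw)) if inw else float("nan")))
        start += step
    return out
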