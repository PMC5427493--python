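"""Candidate regions around hits, gene annotation, gene-set enrichment.

Significant variants become +-``flank`` bp windows (default 2 Mb each side,
clipped at the chromosome start); interval hits (e.g. landscape-ROH) flank
their first/last SNV.  Gene annotation uses the any-overlap rule on 0-based
half-open intervals.  Enrichment is a one-sided hypergeometric upper tail
against user-supplied gene sets (GMT), BH-corrected across sets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .envassoc import bh_adjust

DEFAULT_FLANK = 2_000_000


@dataclass
class Region:
    chrom: str
    start: int   # 0-based half-open
    end: int
    source: str = ""


def hit_windows(hits: pd.DataFrame, flank: int = DEFAULT_FLANK,
                merge: bool = True, source: str = "") -> list[Region]:
    """Regions around hits: ``[pos - flank, pos + flank)`` clipped at 0.

    ``hits`` needs ``chrom`` and either ``pos`` (point hits) or
    ``start``/``end`` columns (interval hits such as LROH, flanked as
    ``[start - flank, end + flank)``).  Overlapping regions on a chromosome
    are merged when ``merge`` is on.
    """
    regions: list[Region] = []
    interval = {"start", "end"}.issubset(hits.columns)
    for _, row in hits.iterrows():
        if interval:
            lo, hi = int(row["start"]) - flank, int(row["end"]) + flank
        else:
            lo, hi = int(row["pos"]) - flank, int(row["pos"]) + flank
        regions.append(Region(chrom=str(row["chrom"]), start=max(lo, 0), end=hi,
                              source=source))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    if not merge:
        return regions
    merged: list[Region] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            merged[-1].end = max(merged[-1].end, r.end)
        else:
            merged.append(Region(r.chrom, r.start, r.end, r.source))
    return merged


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_bed_genes(path) -> pd.DataFrame:
    """Gene models from BED (0-based half-open): chrom, start, end, gene_id[, ., strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({
        "gene_id": df[3].astype(str), "chrom": df[0].astype(str),
        "start": df[1].astype(np.int64), "end": df[2].astype(np.int64),
        "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
    })
    return out


_GFF_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Gene models from GFF3 (1-based closed; converted to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            m = _GFF_ID.search(f[8])
            rows.append({
                "gene_id": m.group(1) if m else f"{f[0]}:{f[3]}-{f[4]}",
                "chrom": f[0], "start": int(f[3]) - 1, "end": int(f[4]),
                "strand": f[6],
            })
    return pd.DataFrame(rows)


def annotate(regions: list[Region], genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each region by >= 1 bp (half-open; strand ignored).

    Returns one row per (region, gene) pair, genes sorted by start within a
    region.  Warns when the chromosome label sets do not intersect cleanly.
    """
    region_chroms = {r.chrom for r in regions}
    gene_chroms = set(genes["chrom"].astype(str))
    missing = region_chroms - gene_chroms
    if missing:
        warnings.warn(f"no gene models on chromosome(s): {sorted(missing)} "
                      f"(gene table covers {sorted(gene_chroms)})")
    rows = []
    for k, r in enumerate(regions):
        sub = genes[genes["chrom"].astype(str) == r.chrom]
        hit = sub[(sub["start"] < r.end) & (sub["end"] > r.start)].sort_values("start")
        for _, g in hit.iterrows():
            rows.append({"region_index": k, "chrom": r.chrom,
                         "region_start": r.start, "region_end": r.end,
                         "gene_id": g["gene_id"],
                         "gene_start": int(g["start"]), "gene_end": int(g["end"])})
    return pd.DataFrame(rows, columns=["region_index", "chrom", "region_start",
                                       "region_end", "gene_id", "gene_start", "gene_end"])


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """GMT gene sets: one set per line (id, description, member genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = set(f[2:])
    return sets


def enrich(gene_list, universe, gene_sets: dict, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_list`` against each set.

    Sets are intersected with ``universe`` first; p = P(X >= k) for a
    hypergeometric draw of n = len(gene_list) from N = len(universe) with
    K_set marked genes.  BH q across sets; ``significant`` flags q <= fdr_alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    n = len(genes)
    N = len(universe)
    rows = []
    for set_id, members in sorted(gene_sets.items()):
        members = set(members) & universe
        K = len(members)
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_id": set_id, "k": k, "n": n, "K_set": K, "N": N, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        q, rej = bh_adjust(table["p"].to_numpy(), alpha=fdr_alpha)
        table["q"] = q
        table["significant"] = table["q"] <= fdr_alpha
    else:
        table["q"] = []
        table["significant"] = []
    return table
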