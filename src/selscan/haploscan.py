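"""Extended-haplotype-homozygosity statistics: EHH/EHHS decay, iHS and Rsb.

EHH at a marker x, for haplotypes carrying a given core allele, is the
probability that two randomly chosen carrier haplotypes are identical at
every site between the core and x (inclusive).  iHS is the standardized
ln-ratio of the integrated EHH (iHH) of the ancestral versus the derived
core allele; Rsb is the standardized ln-ratio between two populations of
the site-wise integrated EHHS (iES), where EHHS pools all haplotypes and
is normalized to 1 at the core.

Haplotypes must be phased, complete (no missing entries) and polarized:
0 = ancestral allele, 1 = derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_FREQ_BIN = 0.025


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes for one chromosome.

    ``alleles`` is ``(2 * n_diploids, n_sites)`` with 0 = ancestral and
    1 = derived; rows ``2i`` and ``2i+1`` belong to diploid ``i``.
    ``positions`` are 1-based bp coordinates, strictly increasing.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    sample_ids: list = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def validate(self) -> None:
        assert self.alleles.ndim == 2
        assert len(self.positions) == self.n_sites
        assert np.all(np.diff(self.positions) > 0), "positions must be strictly increasing"
        assert self.alleles.min() >= 0 and self.alleles.max() <= 1


@dataclass
class EHHDecay:
    core_index: int
    core_allele: object            # 0, 1 or "all"
    left_pos: np.ndarray           # positions from core outward (descending)
    left_ehh: np.ndarray
    right_pos: np.ndarray          # positions from core outward (ascending)
    right_ehh: np.ndarray
    truncation: dict = field(default_factory=dict)  # side -> reason
    n_carriers: int = 0


class InsufficientCarriersError(ValueError):
    pass


def _pair_homozygosity(labels: np.ndarray) -> float:
    """Fraction of haplotype pairs falling in the same partition class."""
    n = labels.size
    if n < 2:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


@njit(cache=True)
def _extend_kernel(alleles, positions, rows, start_labels, core, step,
                   cutoff, max_gap, norm):  # pragma: no cover - exercised via wrapper
    """Partition-refinement walk from the core in one direction.

    Haplotypes in singleton identity classes contribute no pairs and never
    rejoin a class, so they are pruned as the walk proceeds; per-step work
    is linear in the surviving (non-singleton) haplotypes.  Returns
    ``(pos, ehh, n_points, reason)`` with reason 0 = chromosome-end,
    1 = gap, 2 = cutoff.
    """
    n_sites = alleles.shape[1]
    n0 = rows.size
    denom = float(n0 * (n0 - 1))
    max_pts = n_sites + 1
    out_pos = np.empty(max_pts, np.int64)
    out_ehh = np.empty(max_pts, np.float64)

    # compress start labels and drop singleton classes
    lmax = 0
    for i in range(n0):
        if start_labels[i] > lmax:
            lmax = start_labels[i]
    cnt0 = np.zeros(lmax + 1, np.int64)
    for i in range(n0):
        cnt0[start_labels[i]] += 1
    act = np.empty(n0, np.int64)
    labels = np.empty(n0, np.int64)
    remap = np.full(lmax + 1, -1, np.int64)
    n_act = 0
    nxt = 0
    for i in range(n0):
        l = start_labels[i]
        if cnt0[l] > 1:
            if remap[l] < 0:
                remap[l] = nxt
                nxt += 1
            act[n_act] = rows[i]
            labels[n_act] = remap[l]
            n_act += 1

    out_pos[0] = positions[core]
    out_ehh[0] = 1.0
    m = 1
    reason = 0
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= n_sites:
            reason = 0
            break
        gap = positions[jn] - positions[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            reason = 1
            break
        j = jn
        # refine: key = 2*label + allele, counts via dense arrays
        width = 2 * n_act if n_act > 0 else 2
        cnt = np.zeros(width, np.int64)
        keys = np.empty(n_act, np.int64)
        for i in range(n_act):
            k = 2 * labels[i] + alleles[act[i], j]
            keys[i] = k
            cnt[k] += 1
        pairs = 0.0
        for k in range(width):
            c = cnt[k]
            if c > 1:
                pairs += c * (c - 1)
        val = pairs / denom / norm
        # prune singletons, relabel compactly
        remap2 = np.full(width, -1, np.int64)
        nxt = 0
        na = 0
        for i in range(n_act):
            k = keys[i]
            if cnt[k] > 1:
                if remap2[k] < 0:
                    remap2[k] = nxt
                    nxt += 1
                act[na] = act[i]
                labels[na] = remap2[k]
                na += 1
        n_act = na
        out_pos[m] = positions[j]
        out_ehh[m] = val
        m += 1
        if val < cutoff:
            reason = 2
            break
    return out_pos[:m], out_ehh[:m], m, reason


_REASONS = {0: "chromosome-end", 1: "gap", 2: "cutoff"}


def _extend(alleles: np.ndarray, positions: np.ndarray, rows: np.ndarray,
            core: int, step: int, cutoff: float, max_gap: int,
            norm: float, start_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, str]:
    pos, ehh, _, reason = _extend_kernel(
        alleles, positions.astype(np.int64), rows.astype(np.int64),
        start_labels.astype(np.int64), core, step, float(cutoff),
        int(max_gap), float(norm))
    return pos.copy(), ehh.copy(), _REASONS[int(reason)]


def ehh_decay(hap: HaplotypeMatrix, core_index: int, core_allele,
              cutoff: float = DEFAULT_CUTOFF, max_gap: int = DEFAULT_MAX_GAP) -> EHHDecay:
    """EHH (core_allele 0/1) or EHHS (core_allele "all") decay around a core site."""
    alleles = hap.alleles
    if core_allele == "all":
        rows = np.arange(hap.n_haplotypes)
        if rows.size < 2:
            raise InsufficientCarriersError("need at least 2 haplotypes")
        start_labels = alleles[rows, core_index].astype(np.int64)
        core_hom = _pair_homozygosity(start_labels)
        if core_hom <= 0:
            raise InsufficientCarriersError("zero homozygosity at core site")
        norm = core_hom
    else:
        rows = np.flatnonzero(alleles[:, core_index] == core_allele)
        if rows.size < 2:
            raise InsufficientCarriersError(
                f"fewer than 2 carriers of allele {core_allele} at site {core_index}")
        start_labels = np.zeros(rows.size, dtype=np.int64)
        norm = 1.0
    lp, le, lr = _extend(alleles, hap.positions, rows, core_index, -1, cutoff, max_gap,
                         norm, start_labels)
    rp, re_, rr = _extend(alleles, hap.positions, rows, core_index, +1, cutoff, max_gap,
                          norm, start_labels)
    return EHHDecay(core_index=core_index, core_allele=core_allele,
                    left_pos=lp, left_ehh=le, right_pos=rp, right_ehh=re_,
                    truncation={"left": lr, "right": rr}, n_carriers=int(rows.size))


def _side_area(pos: np.ndarray, ehh: np.ndarray, cutoff: float) -> float:
    """Trapezoid area of one decay side over |distance|, clipped at the cutoff
    level with linear interpolation of the crossing point."""
    if pos.size < 2:
        return 0.0
    d = np.abs(pos.astype(np.float64) - float(pos[0]))
    area = 0.0
    for i in range(1, pos.size):
        a, b = ehh[i - 1], ehh[i]
        if b >= cutoff:
            area += 0.5 * (a + b) * (d[i] - d[i - 1])
        else:
            # crossing between i-1 and i: integrate up to the cutoff level
            frac = (a - cutoff) / (a - b) if a > b else 0.0
            area += 0.5 * (a + cutoff) * (d[i] - d[i - 1]) * frac
            break
    return float(area)


def integrate(decay: EHHDecay, cutoff: float = DEFAULT_CUTOFF) -> float:
    """iHH (or iES): summed left+right trapezoid areas, in bp."""
    return (_side_area(decay.left_pos, decay.left_ehh, cutoff)
            + _side_area(decay.right_pos, decay.right_ehh, cutoff))


def _two_sided_p(score: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(score))


def _ihs_raw(hap: HaplotypeMatrix, maf_min: float, cutoff: float,
             max_gap: int) -> pd.DataFrame:
    """Unstandardized per-site ln(iHH_ancestral / iHH_derived) for one chromosome."""
    hap.validate()
    n = hap.n_haplotypes
    freq = hap.alleles.mean(axis=0)
    rows = []
    for j in range(hap.n_sites):
        d = float(freq[j])
        rec = {"chrom": hap.chrom, "pos": int(hap.positions[j]), "freq_derived": d,
               "ihh_a": np.nan, "ihh_d": np.nan, "raw": np.nan,
               "score": np.nan, "p": np.nan, "neglog10p": np.nan, "flag": ""}
        if min(d, 1 - d) < maf_min:
            rec["flag"] = "low_maf"
            rows.append(rec)
            continue
        n_der = int(hap.alleles[:, j].sum())
        if n_der < 2 or n - n_der < 2:
            rec["flag"] = "insufficient_carriers"
            rows.append(rec)
            continue
        dec_a = ehh_decay(hap, j, 0, cutoff, max_gap)
        dec_d = ehh_decay(hap, j, 1, cutoff, max_gap)
        ihh_a = integrate(dec_a, cutoff)
        ihh_d = integrate(dec_d, cutoff)
        rec["ihh_a"], rec["ihh_d"] = ihh_a, ihh_d
        if ihh_a <= 0 or ihh_d <= 0:
            rec["flag"] = "zero_ihh"
            rows.append(rec)
            continue
        rec["raw"] = float(np.log(ihh_a / ihh_d))
        if any(r == "gap" for r in (*dec_a.truncation.values(), *dec_d.truncation.values())):
            rec["flag"] = "truncated"
        rows.append(rec)
    return pd.DataFrame(rows)


def ihs_scan(hap, maf_min: float = 0.05,
             freq_bin_width: float = DEFAULT_FREQ_BIN,
             cutoff: float = DEFAULT_CUTOFF, max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Within-population iHS scan.

    ``hap`` is a single :class:`HaplotypeMatrix` or an iterable of them (one
    per chromosome); standardization pools sites genome-wide, which matters
    whenever one chromosome carries a sweep whose hitchhikers would otherwise
    dominate their own frequency bins.  Returns a per-site frame with columns
    ``chrom, pos, freq_derived, ihh_a, ihh_d, raw, score, p, neglog10p,
    flag``.  Sites failing the MAF/carrier rules are flagged and left
    unscored; raw scores are standardized to mean 0 / SD 1 within
    derived-allele-frequency bins of ``freq_bin_width``.
    """
    haps = [hap] if isinstance(hap, HaplotypeMatrix) else list(hap)
    track = pd.concat([_ihs_raw(h, maf_min, cutoff, max_gap) for h in haps],
                      ignore_index=True)

    scored = track["raw"].notna().to_numpy()
    bins = np.floor(track["freq_derived"].to_numpy() / freq_bin_width).astype(int)
    score = np.full(len(track), np.nan)
    for b in np.unique(bins[scored]):
        m = scored & (bins == b)
        vals = track.loc[m, "raw"].to_numpy()
        if m.sum() >= 2 and np.std(vals) > 0:
            score[m] = (vals - vals.mean()) / np.std(vals)
        else:
            track.loc[m, "flag"] = "unstandardizable"
    track["score"] = score
    ok = np.isfinite(score)
    track.loc[ok, "p"] = _two_sided_p(score[ok])
    track.loc[ok, "neglog10p"] = -np.log10(track.loc[ok, "p"])
    return track


def ies_track(hap: HaplotypeMatrix, cutoff: float = DEFAULT_CUTOFF,
              max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Site-wise integrated EHHS (iES) for one population."""
    hap.validate()
    vals = np.full(hap.n_sites, np.nan)
    for j in range(hap.n_sites):
        try:
            vals[j] = integrate(ehh_decay(hap, j, "all", cutoff, max_gap), cutoff)
        except InsufficientCarriersError:
            pass
    return pd.DataFrame({"chrom": hap.chrom, "pos": hap.positions, "ies": vals})


def rsb_scan(hap_a: HaplotypeMatrix, hap_b: HaplotypeMatrix,
             standardization: str = "median", cutoff: float = DEFAULT_CUTOFF,
             max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Between-population Rsb scan over the shared site set.

    raw = ln(iES_A / iES_B); standardized by subtracting the median (default;
    ``standardization="mean"`` uses the mean) and dividing by the SD.
    """
    if standardization not in ("median", "mean"):
        raise ValueError(f"unknown standardization {standardization!r}")
    common, ia, ib = np.intersect1d(hap_a.positions, hap_b.positions, return_indices=True)
    sub_a = HaplotypeMatrix(hap_a.alleles[:, ia], hap_a.positions[ia], hap_a.chrom)
    sub_b = HaplotypeMatrix(hap_b.alleles[:, ib], hap_b.positions[ib], hap_b.chrom)
    ies_a = ies_track(sub_a, cutoff, max_gap)["ies"].to_numpy()
    ies_b = ies_track(sub_b, cutoff, max_gap)["ies"].to_numpy()
    raw = np.full(common.size, np.nan)
    flag = np.array([""] * common.size, dtype=object)
    ok = np.isfinite(ies_a) & np.isfinite(ies_b) & (ies_a > 0) & (ies_b > 0)
    raw[ok] = np.log(ies_a[ok] / ies_b[ok])
    flag[~ok] = "zero_ies"
    track = pd.DataFrame({"chrom": hap_a.chrom, "pos": common,
                          "ies_a": ies_a, "ies_b": ies_b, "raw": raw,
                          "score": np.nan, "p": np.nan, "flag": flag})
    vals = raw[ok]
    if vals.size >= 2 and np.std(vals) > 0:
        center = np.median(vals) if standardization == "median" else vals.mean()
        score = (raw - center) / np.std(vals)
        track["score"] = np.where(ok, score, np.nan)
        track.loc[ok, "p"] = _two_sided_p(score[ok])
    return track


# ---------------------------------------------------------------------------
# Significance thresholds
# ---------------------------------------------------------------------------

def significance_threshold(values=None, method: str = "fixed", alpha: float = 0.05,
                           p_cutoff: float = 1e-4, B: int = 1000, seed: int | None = None,
                           perm_scores_fn=None):
    """Score/p-value thresholds for calling selected variants.

    * ``fixed``: the |score| threshold equivalent to a two-sided normal
      p-value of ``p_cutoff`` (the operative rule: p <= 1e-4 <-> |score| >= 3.89).
    * ``bh``: Benjamini-Hochberg step-up on ``values`` (p-values); returns the
      largest p(i) <= i*alpha/m, or 0.0 when nothing is rejected.
    * ``max-permutation``: the (1-alpha) quantile of the maximum |score| over
      ``B`` permutation replicates produced by ``perm_scores_fn(rng)``; the
      caller supplies the permutation mechanism (e.g. population-label
      reshuffling for Rsb).  ``B`` below 100 is refused as unstable.
    """
    if method == "fixed":
        return float(stats.norm.isf(p_cutoff / 2.0))
    if method == "bh":
        p = np.sort(np.asarray(values, dtype=float))
        m = p.size
        if m == 0:
            return 0.0
        ok = p <= (np.arange(1, m + 1) * alpha / m)
        return float(p[np.flatnonzero(ok).max()]) if ok.any() else 0.0
    if method == "max-permutation":
        if B < 100:
            raise ValueError("B < 100 gives an unstable quantile; refusing")
        if perm_scores_fn is None:
            raise ValueError("max-permutation requires perm_scores_fn")
        if seed is None:
            raise ValueError("seed is mandatory for permutation thresholds")
        rng = np.random.default_rng(seed)
        maxima = np.empty(B)
        for b in range(B):
            s = np.asarray(perm_scores_fn(rng), dtype=float)
            maxima[b] = np.nanmax(np.abs(s))
        return float(np.quantile(maxima, 1.0 - alpha))
    raise ValueError(f"unknown method {method!r}")


def haplotype_matrices_from_dataset(ds, zone: str | None = None) -> dict:
    """Split a phased :class:`~selscan.genodata.GenotypeDataset` into per-
    chromosome derived-coded :class:`HaplotypeMatrix` objects.

    Polarity comes from the ``ancestral`` column; where it is absent the
    minor allele is treated as derived (sign of iHS only; a warning is
    emitted once).
    """
    import warnings

    if ds.haplotypes is None:
        raise ValueError("dataset carries no haplotypes (unphased input?)")
    if zone is not None:
        idx = np.flatnonzero((ds.samples["zone"] == zone).to_numpy())
        ds = ds.take_samples(idx)
    anc = ds.variants["ancestral"]
    ref = ds.variants["ref"]
    alt = ds.variants["alt"]
    hap = ds.haplotypes.astype(np.int8).copy()
    known = anc.notna().to_numpy() if hasattr(anc, "notna") else np.zeros(len(ref), bool)
    flip = np.zeros(ds.n_variants, dtype=bool)
    flip[known] = (anc[known] == alt[known]).to_numpy()
    if (~known).any():
        warnings.warn("no ancestral allele for some variants; treating the "
                      "minor allele as derived (affects iHS sign only)")
        freq = (hap[:, ~known] == 1).mean(axis=0)
        flip[np.flatnonzero(~known)[freq > 0.5]] = True
    hap[:, flip] = 1 - hap[:, flip]
    out = {}
    for chrom, sub in ds.variants.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        out[str(chrom)] = HaplotypeMatrix(
            alleles=np.ascontiguousarray(hap[:, cols]),
            positions=sub["pos"].to_numpy(np.int64),
            chrom=str(chrom),
            sample_ids=ds.samples["sample_id"].tolist(),
        )
    return out
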