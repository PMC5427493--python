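"""Genotype containers, VCF/PLINK I/O, quality control and GRM-based PCA.

The central container is :class:`GenotypeDataset`: an ``(n_samples, n_variants)``
matrix of alt-allele counts (``-1`` marks a missing call) together with a
variant map and a sample metadata table.  Phased haplotypes, when present in
the source VCF (or produced by the simulator), are carried alongside the
genotype matrix so that haplotype statistics can be computed downstream
without re-reading the file.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_NUCS = ("A", "C", "G", "T")


class QCEmptyError(RuntimeError):
    """Raised when quality control removes every sample or every variant."""


@dataclass
class QCLog:
    """Accounting of a quality-control pass.

    A record removed by several rules is attributed to the first rule in the
    fixed filter order, so ``n_in == n_out + sum(removed)`` on both axes.
    """

    n_variants_in: int = 0
    n_variants_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_variants_by_rule: dict = field(default_factory=dict)
    removed_samples_by_rule: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_variants_out + sum(self.removed_variants_by_rule.values()) == self.n_variants_in
        assert self.n_samples_out + sum(self.removed_samples_by_rule.values()) == self.n_samples_in


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # (k,) descending, non-negative
    eigenvectors: np.ndarray         # (n_samples, k) orthonormal columns
    variance_explained: np.ndarray   # (k,) fractions of total variance
    n_variants_used: int = 0
    n_monomorphic_skipped: int = 0


@dataclass
class GenotypeDataset:
    """Samples x variants allele-count matrix plus variant and sample tables.

    ``genotypes[i, j]`` is the number of copies of the alt allele carried by
    sample ``i`` at variant ``j`` (0/1/2), or ``-1`` for a missing call.
    ``variants`` has columns ``chrom, pos, ref, alt, ancestral`` (``pos`` is
    the 1-based physical coordinate, as in VCF/bim).  ``samples`` has at least
    ``sample_id`` and usually ``subpopulation``, ``zone`` and environmental
    covariate columns.  ``haplotypes``, when not ``None``, is an
    ``(2*n_samples, n_variants)`` int8 matrix of phased alleles (0=ref,
    1=alt, -1=missing); haplotypes ``2i`` and ``2i+1`` belong to sample ``i``.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    haplotypes: np.ndarray | None = None
    phased: bool = False

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        assert self.genotypes.shape == (len(self.samples), len(self.variants))
        if self.haplotypes is not None:
            assert self.haplotypes.shape == (2 * self.n_samples, self.n_variants)

    def take_variants(self, idx: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
            phased=self.phased,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.ravel(np.column_stack([2 * np.asarray(idx), 2 * np.asarray(idx) + 1]))
            hap = self.haplotypes[hap_idx]
        return GenotypeDataset(
            genotypes=self.genotypes[idx, :],
            variants=self.variants,
            samples=self.samples.iloc[idx].reset_index(drop=True),
            haplotypes=hap,
            phased=self.phased,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "vcf", meta: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read a VCF (plain or bgzipped) or a PLINK bed/bim/fam trio.

    ``fmt`` is ``"vcf"`` or ``"plink"``; for PLINK pass the prefix (or any of
    the three file names).  Multi-allelic VCF records are excluded with a
    warning.  ``meta``, when given, is merged onto the sample table by
    ``sample_id``.
    """
    if fmt == "vcf":
        ds = _read_vcf(str(path))
    elif fmt == "plink":
        ds = _read_plink(str(path))
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if meta is not None:
        ds.samples = ds.samples.merge(meta, on="sample_id", how="left")
    ds.validate()
    return ds


def _read_vcf(path: str) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    genos, haps = [], []
    chroms, poss, refs, alts, aas = [], [], [], [], []
    n_multiallelic = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        g = np.full(n, MISSING, dtype=np.int8)
        h = np.full(2 * n, MISSING, dtype=np.int8)
        for i, (a0, a1, phased) in enumerate(v.genotypes):
            if a0 >= 0 and a1 >= 0:
                g[i] = a0 + a1
                h[2 * i] = a0
                h[2 * i + 1] = a1
            if not phased:
                all_phased = False
        genos.append(g)
        haps.append(h)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        aa = v.INFO.get("AA")
        aas.append(aa if aa else None)
    vcf.close()
    if n_multiallelic:
        warnings.warn(f"excluded {n_multiallelic} multi-allelic site(s)")
    if not genos:
        raise ValueError(f"no biallelic records parsed from {path}")
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
         "ref": refs, "alt": alts, "ancestral": aas}
    )
    # rows were assembled per-variant; transpose to samples/haplotypes x variants
    return GenotypeDataset(
        genotypes=np.ascontiguousarray(np.vstack(genos).T).astype(np.int8),
        variants=variants,
        samples=pd.DataFrame({"sample_id": sample_ids}),
        haplotypes=np.ascontiguousarray(np.vstack(haps).T).astype(np.int8),
        phased=all_phased,
    )


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write a plain-text VCF; emits phased GT (``a|b``) when haplotypes exist."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(ds.variants["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.samples["sample_id"].astype(str)) + "\n")
        sep = "|" if (ds.phased and ds.haplotypes is not None) else "/"
        hap = ds.haplotypes
        for j in range(ds.n_variants):
            row = ds.variants.iloc[j]
            aa = row.get("ancestral")
            info = f"AA={aa}" if isinstance(aa, str) and aa else "."
            if hap is not None:
                cells = [
                    "." + sep + "." if hap[2 * i, j] < 0 else f"{hap[2 * i, j]}{sep}{hap[2 * i + 1, j]}"
                    for i in range(ds.n_samples)
                ]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                cells = [code[int(g)] for g in ds.genotypes[:, j]]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                     f"\t.\tPASS\t{info}\tGT\t" + "\t".join(cells) + "\n")


# PLINK .bed 2-bit codes (SNP-major, v1): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# We write A1 = alt and A2 = ref, so alt dosage 2 -> 00, 1 -> 10, 0 -> 11.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(ds: GenotypeDataset, prefix) -> None:
    """Write a bed/bim/fam trio (phase information is not representable)."""
    prefix = str(prefix)
    bim = pd.DataFrame({
        "chrom": ds.variants["chrom"],
        "id": [f"v{j}" for j in range(ds.n_variants)],
        "cm": 0,
        "pos": ds.variants["pos"],
        "a1": ds.variants["alt"],
        "a2": ds.variants["ref"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": ds.samples.get("subpopulation", pd.Series(["0"] * ds.n_samples)),
        "iid": ds.samples["sample_id"],
        "pat": 0, "mat": 0, "sex": 0,
        "pheno": ds.samples["zone"].map({"case": 2, "control": 1}).fillna(-9).astype(int)
        if "zone" in ds.samples else -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    n = ds.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(ds.n_variants):
            codes = np.fromiter(
                (_DOSAGE_TO_CODE[int(g)] for g in ds.genotypes[:, j]), dtype=np.uint8, count=n
            )
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for k in range(4):
                part = codes[k::4]
                packed[: len(part)] |= part << (2 * k)
            fh.write(packed.tobytes())


def _read_plink(prefix: str) -> GenotypeDataset:
    prefix = re.sub(r"\.(bed|bim|fam)$", "", prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed: not a SNP-major PLINK v1 bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * n_bytes:
        raise ValueError(f"{prefix}.bed: truncated (expected {m * n_bytes} body bytes, got {raw.size})")
    raw = raw.reshape(m, n_bytes)
    # sample i lives in byte i//4, bit-pair i%4
    byte_idx = np.arange(n) // 4
    shift = 2 * (np.arange(n) % 4)
    codes = (raw[:, byte_idx] >> shift[None, :]) & 0b11
    geno = _CODE_TO_DOSAGE[codes].T
    variants = pd.DataFrame({
        "chrom": bim["chrom"].astype(str), "pos": bim["pos"].astype(np.int64),
        "ref": bim["a2"], "alt": bim["a1"], "ancestral": None,
    })
    samples = pd.DataFrame({"sample_id": fam["iid"].astype(str),
                            "subpopulation": fam["fid"].astype(str)})
    pheno = fam["pheno"].astype(int)
    if pheno.isin([1, 2]).all():
        samples["zone"] = pheno.map({2: "case", 1: "control"})
    return GenotypeDataset(genotypes=np.ascontiguousarray(geno), variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

_NON_AUTOSOME = {"X", "Y", "MT", "M", "Z", "W", "XY"}


def _is_autosome(label: str) -> bool:
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in _NON_AUTOSOME:
        return False
    return s.isdigit()


def apply_qc(
    ds: GenotypeDataset,
    maf_min: float = 0.05,
    sample_cr: float = 0.99,
    variant_cr: float = 0.99,
    autosomes_only: bool = True,
    drop_duplicate_positions: bool = True,
    dup_policy: str = "keep-first",
) -> tuple[GenotypeDataset, QCLog]:
    """Apply the standard array-QC filters in a fixed, logged order.

    Order: (1) duplicate-position removal, (2) sample call rate, (3) variant
    call rate, (4) MAF on retained samples, (5) autosome restriction.
    Raises :class:`QCEmptyError` if nothing survives.
    """
    if ds.n_samples == 0 or ds.n_variants == 0:
        raise QCEmptyError("dataset empty before QC")
    log = QCLog(
        n_variants_in=ds.n_variants, n_samples_in=ds.n_samples,
        thresholds={"maf_min": maf_min, "sample_callrate_min": sample_cr,
                    "variant_callrate_min": variant_cr, "dup_policy": dup_policy},
    )
    cur = ds

    # 1. duplicate (chrom, pos)
    if drop_duplicate_positions:
        key = cur.variants[["chrom", "pos"]]
        if dup_policy == "keep-first":
            dup = key.duplicated(keep="first").to_numpy()
        elif dup_policy == "drop-all":
            dup = key.duplicated(keep=False).to_numpy()
        else:
            raise ValueError(f"unknown dup_policy: {dup_policy!r}")
        log.removed_variants_by_rule["duplicate_position"] = int(dup.sum())
        cur = cur.take_variants(np.flatnonzero(~dup))

    # 2. sample call rate
    called = cur.genotypes != MISSING
    cr_s = called.mean(axis=1) if cur.n_variants else np.ones(cur.n_samples)
    keep_s = cr_s >= sample_cr
    log.removed_samples_by_rule["sample_callrate"] = int((~keep_s).sum())
    cur = cur.take_samples(np.flatnonzero(keep_s))
    if cur.n_samples == 0:
        raise QCEmptyError("all samples removed during QC (sample call rate)")

    # 3. variant call rate
    called = cur.genotypes != MISSING
    cr_v = called.mean(axis=0)
    keep_v = cr_v >= variant_cr
    log.removed_variants_by_rule["variant_callrate"] = int((~keep_v).sum())
    cur = cur.take_variants(np.flatnonzero(keep_v))

    # 4. MAF on retained samples
    if cur.n_variants:
        g = cur.genotypes
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        denom = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)
        maf = np.fmin(f, 1 - f)
        keep_m = np.nan_to_num(maf, nan=-1.0) >= maf_min
        log.removed_variants_by_rule["maf"] = int((~keep_m).sum())
        cur = cur.take_variants(np.flatnonzero(keep_m))

    # 5. autosomes
    if autosomes_only and cur.n_variants:
        auto = cur.variants["chrom"].map(_is_autosome).to_numpy()
        log.removed_variants_by_rule["non_autosome"] = int((~auto).sum())
        cur = cur.take_variants(np.flatnonzero(auto))
    else:
        log.removed_variants_by_rule.setdefault("non_autosome", 0)

    if cur.n_variants == 0:
        raise QCEmptyError("all variants removed during QC")

    # enforce sorted, strictly increasing positions per chromosome
    order = np.lexsort((cur.variants["pos"].to_numpy(),
                        cur.variants["chrom"].astype(str).to_numpy()))
    if not np.array_equal(order, np.arange(cur.n_variants)):
        cur = cur.take_variants(order)

    log.n_variants_out = cur.n_variants
    log.n_samples_out = cur.n_samples
    log.check()
    return cur, log


def group_allele_freqs(ds: GenotypeDataset, by: str = "zone") -> pd.DataFrame:
    """Per-variant alt-allele frequency and MAF per group of ``by``.

    Frequency is alt-allele count over ``2 x`` non-missing diploids in the
    group; a group with zero non-missing calls at a site gets NaN.
    """
    if by not in ds.samples.columns:
        raise KeyError(f"grouping column {by!r} not in sample table")
    frames = []
    for name, idx in ds.samples.groupby(by, sort=True).indices.items():
        g = ds.genotypes[idx, :]
        called = g != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
        frames.append(pd.DataFrame({
            "chrom": ds.variants["chrom"], "pos": ds.variants["pos"],
            "group": name, "n_called": n_called,
            "freq_alt": f, "maf": np.fmin(f, 1 - f),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# GRM PCA
# ---------------------------------------------------------------------------

def standardized_genotypes(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Variance-standardized genotype matrix ``(x - 2p) / sqrt(2p(1-p))``.

    Missing calls are mean-imputed (0 after centering).  Monomorphic variants
    are dropped; returns ``(Z, used_mask)``.
    """
    g = ds.genotypes.astype(np.float64)
    miss = g == MISSING
    gm = np.where(miss, np.nan, g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(gm, axis=0) / 2.0
    used = np.isfinite(p) & (p > 0) & (p < 1)
    z = (gm[:, used] - 2 * p[used]) / np.sqrt(2 * p[used] * (1 - p[used]))
    z[~np.isfinite(z)] = 0.0
    return z, used


def grm(ds: GenotypeDataset) -> np.ndarray:
    """Variance-standardized genomic relationship matrix ``Z Z' / m``."""
    z, used = standardized_genotypes(ds)
    m = used.sum()
    if m == 0:
        raise ValueError("no polymorphic variants for the relationship matrix")
    return z @ z.T / m


def grm_pca(ds: GenotypeDataset, k: int = 10) -> PCAResult:
    """Top-k eigenpairs of the variance-standardized relationship matrix."""
    if k > ds.n_samples:
        raise ValueError(f"k={k} exceeds n_samples={ds.n_samples}")
    z, used = standardized_genotypes(ds)
    n_mono = int(ds.n_variants - used.sum())
    if n_mono:
        warnings.warn(f"skipped {n_mono} monomorphic variant(s) in PCA")
    A = z @ z.T / max(int(used.sum()), 1)
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    return PCAResult(
        eigenvalues=vals[:k], eigenvectors=vecs[:, :k],
        variance_explained=(vals[:k] / total) if total > 0 else np.zeros(k),
        n_variants_used=int(used.sum()), n_monomorphic_skipped=n_mono,
    )
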