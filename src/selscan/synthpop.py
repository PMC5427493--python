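"""Forward Wright-Fisher simulator for a two-climate-zone study population.

The generator emulates the structure of a diversity-panel study: two
metapopulations ("case" = high ambient temperature, "control" = low ambient
temperature), each made of several subpopulations, diverged by pure drift
from a common founder pool, optionally carrying hard selective sweeps in one
zone, elevated inbreeding (selfing) in one zone, explicitly planted
runs of homozygosity, and an environmentally associated SNP whose allele
frequency tracks a temperature gradient across subpopulations.

Model summary
-------------
* Founders: each site's derived allele drawn at a frequency sampled from the
  neutral site-frequency spectrum (P(count=i) proportional to 1/i), haplotypes
  initialized at linkage equilibrium.  The founder (ancestral) allele defines
  derived-allele polarity for the haplotype statistics.
* Each generation: diploid parents sampled proportional to fitness (additive
  per sweep allele, (1+s) per derived copy, in the sweep's zone only), with
  per-zone selfing probability; gametes recombine with Poisson crossovers at
  ``recomb_rate`` per bp; symmetric recurrent mutation at ``mutation_rate``
  per site per generation.
* Two phases: ``split_generations`` of independent drift per zone, then
  ``subpop_generations`` of independent drift per subpopulation.
* Sweeps enter as a single mutant copy at ``start_gen`` and are re-run from a
  checkpoint (fresh seed) if lost, up to ``max_retries``.

All randomness flows from the single integer ``seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import GenotypeDataset, write_plink, write_vcf
from .haploscan import HaplotypeMatrix

ZONES = ("case", "control")


class SweepLostError(RuntimeError):
    pass


@dataclass
class SweepSpec:
    chrom: int                   # 1-based chromosome index
    pos: int                     # requested bp position (snapped to nearest site)
    s: float                     # selection coefficient per derived copy
    zone: str = "case"
    start_gen: int | None = None  # generation (of the split phase) selection begins
    target_freq: float = 0.8     # selection stops once the allele reaches this
                                 # frequency (controlled incomplete sweep)
    p0: float = 0.0              # founder frequency in the sweep zone; 0 means a
                                 # single mutant copy is introduced at start_gen
    bg_window: int = 1_500_000   # standing carriers share one founder haplotype
                                 # over +-bg_window around the locus (young allele,
                                 # single mutational origin)


@dataclass
class PlantedROH:
    zone: str
    chrom: int
    start: int                   # bp, inclusive of first site at/after this
    end: int                     # bp, inclusive of last site at/before this
    n_carriers: int = 10
    flank_sites: int = 60        # heterozygous delimiter sites on each side


@dataclass
class PlantedEnvSNP:
    chrom: int
    pos: int
    zone: str = "case"
    p_range: tuple = (0.05, 0.95)  # derived-allele frequency across the temp gradient
    covariate: str = "temperature"


@dataclass
class SimConfig:
    seed: int
    n_subpops_per_zone: int = 5
    n_diploids_per_subpop: int = 30
    n_chromosomes: int = 3
    chrom_length: int = 10_000_000
    n_sites: int = 5_000                  # per chromosome
    mutation_rate: float = 1e-6           # per site per generation
    recomb_rate: float = 3e-8             # per bp per generation (~3 cM/Mb)
    split_generations: int = 300
    subpop_generations: int = 20
    sweep_loci: list = field(default_factory=list)       # list[SweepSpec]
    inbreeding_zone_fraction: dict = field(default_factory=dict)  # zone -> selfing prob
    planted_roh: list = field(default_factory=list)      # list[PlantedROH]
    planted_env_snp: PlantedEnvSNP | None = None
    env_means: dict = field(default_factory=lambda: {
        "case": (26.0, 900.0), "control": (7.0, 600.0)})  # (temp degC, precip mm)
    env_subpop_sd: tuple = (4.0, 150.0)   # deterministic spread of subpop means
    env_noise_sd: tuple = (0.5, 25.0)     # individual noise
    max_retries: int = 50

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.mutation_rate, self.recomb_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        for sw in self.sweep_loci:
            if not (0 < sw.pos <= self.chrom_length):
                raise ValueError("sweep position outside chromosome")
            if sw.zone not in ZONES:
                raise ValueError(f"unknown zone {sw.zone!r}")

    @property
    def n_diploids_per_zone(self) -> int:
        return self.n_subpops_per_zone * self.n_diploids_per_subpop


@dataclass
class TruthRecord:
    seed: int
    zone_of_sample: dict
    sweeps: list = field(default_factory=list)       # dicts with realized frequencies
    planted_roh: list = field(default_factory=list)  # per-individual intervals
    planted_env_snp: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self) if dataclasses.is_dataclass(self) else self.__dict__,
                          indent=2, default=str)


# ---------------------------------------------------------------------------
# Core Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while pos.size < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    if pos.size > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos.astype(np.int64)


def _founder_freqs(rng: np.random.Generator, n_sites: int, two_n: int) -> np.ndarray:
    counts = np.arange(1, two_n)
    w = 1.0 / counts
    return counts[rng.choice(len(counts), size=n_sites, p=w / w.sum())] / two_n


def _gametes(rng: np.random.Generator, haps: np.ndarray, parents: np.ndarray,
             positions: np.ndarray, recomb_rate: float, length: int) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid indices) from ``haps`` (2N x S)."""
    n_g = len(parents)
    k = rng.poisson(recomb_rate * length, size=n_g)
    start = rng.integers(0, 2, size=n_g)
    out = haps[2 * parents + start]  # fancy index copies
    for i in np.flatnonzero(k):
        cuts = np.sort(rng.integers(1, length + 1, size=k[i]))
        seg = np.searchsorted(cuts, positions, side="left")  # segment index per site
        use_other = (seg % 2) == 1
        if use_other.any():
            out[i, use_other] = haps[2 * parents[i] + (1 - start[i]), use_other]
    return out


def _mutate(rng: np.random.Generator, haps: np.ndarray, mu: float) -> None:
    n_events = rng.poisson(mu * haps.size)
    if n_events:
        rows = rng.integers(0, haps.shape[0], size=n_events)
        cols = rng.integers(0, haps.shape[1], size=n_events)
        haps[rows, cols] ^= 1


def _next_generation(rng, pops: list[np.ndarray], positions: list[np.ndarray],
                     cfg: SimConfig, fitness: np.ndarray | None, selfing: float) -> list[np.ndarray]:
    """One WF generation for one panmictic unit (list of per-chromosome 2N x S arrays)."""
    n = pops[0].shape[0] // 2
    if fitness is None:
        prob = None
    else:
        prob = fitness / fitness.sum()
    mothers = rng.choice(n, size=n, p=prob)
    fathers = rng.choice(n, size=n, p=prob)
    if selfing > 0:
        self_mask = rng.random(n) < selfing
        fathers = np.where(self_mask, mothers, fathers)
    new_pops = []
    for haps, pos in zip(pops, positions):
        g_m = _gametes(rng, haps, mothers, pos, cfg.recomb_rate, cfg.chrom_length)
        g_f = _gametes(rng, haps, fathers, pos, cfg.recomb_rate, cfg.chrom_length)
        new = np.empty_like(haps)
        new[0::2] = g_m
        new[1::2] = g_f
        _mutate(rng, new, cfg.mutation_rate)
        new_pops.append(new)
    return new_pops


def _zone_fitness(pops: list[np.ndarray], sweeps: list[tuple[int, int, float]]) -> np.ndarray | None:
    """Multiplicative fitness (1+s)^copies over the zone's active sweep sites."""
    if not sweeps:
        return None
    n = pops[0].shape[0] // 2
    w = np.ones(n)
    for chrom_i, site_i, s in sweeps:
        dosage = pops[chrom_i][0::2, site_i].astype(float) + pops[chrom_i][1::2, site_i]
        w *= (1.0 + s) ** dosage
    return w


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> tuple[GenotypeDataset, dict, TruthRecord]:
    """Run the simulation.

    Returns ``(dataset, haplotype_matrices, truth)`` where
    ``haplotype_matrices`` maps chromosome label -> :class:`HaplotypeMatrix`
    over all samples (derived-allele coded, fully phased).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_zone = cfg.n_diploids_per_zone
    two_n = 2 * n_zone * 2  # founder pool = both zones

    positions = [_draw_positions(rng, cfg.chrom_length, cfg.n_sites)
                 for _ in range(cfg.n_chromosomes)]

    # snap sweep/env loci to simulated sites; sweep sites start monomorphic
    sweeps = []
    for sw in cfg.sweep_loci:
        c = sw.chrom - 1
        site = int(np.argmin(np.abs(positions[c] - sw.pos)))
        if sw.start_gen is not None:
            start = sw.start_gen
        else:
            start = 0 if sw.p0 > 0 else max(cfg.split_generations - 60, 0)
        sweeps.append({"spec": sw, "chrom_i": c, "site": site,
                       "pos": int(positions[c][site]), "start_gen": int(start)})
    env_site = None
    if cfg.planted_env_snp is not None:
        c = cfg.planted_env_snp.chrom - 1
        env_site = (c, int(np.argmin(np.abs(positions[c] - cfg.planted_env_snp.pos))))

    freqs = [_founder_freqs(rng, cfg.n_sites, two_n) for _ in range(cfg.n_chromosomes)]
    for swp in sweeps:
        freqs[swp["chrom_i"]][swp["site"]] = 0.0

    # founder haplotypes at linkage equilibrium, split immediately into zones
    zone_pops = {}
    for z in ZONES:
        zone_pops[z] = [
            (rng.random((2 * n_zone, cfg.n_sites)) < f).astype(np.int8)
            for f in freqs
        ]

    # standing sweep variants: private to the sweep zone, carried at founder
    # frequency p0 on a single shared founder background (one origin)
    for swp in sweeps:
        sw = swp["spec"]
        if sw.p0 <= 0:
            continue
        pop = zone_pops[sw.zone][swp["chrom_i"]]
        pos = positions[swp["chrom_i"]]
        n_carriers = max(int(round(sw.p0 * 2 * n_zone)), 1)
        carriers = rng.choice(2 * n_zone, size=n_carriers, replace=False)
        near = np.flatnonzero(np.abs(pos - swp["pos"]) <= sw.bg_window)
        template = pop[carriers[0], near].copy()
        pop[np.ix_(carriers, near)] = template[None, :]
        pop[:, swp["site"]] = 0
        pop[carriers, swp["site"]] = 1
        swp["standing"] = True

    # -------------------- split phase: per-zone drift --------------------
    for z in ZONES:
        selfing = float(cfg.inbreeding_zone_fraction.get(z, 0.0))
        zone_sweeps = [s for s in sweeps if s["spec"].zone == z]
        pops = zone_pops[z]
        gen = 0
        checkpoint = None
        retries = 0
        while gen < cfg.split_generations:
            for swp in zone_sweeps:
                if gen == swp["start_gen"]:
                    if checkpoint is None:
                        checkpoint = ([p.copy() for p in pops], gen)
                    swp["done"] = False
                    if not swp.get("standing", False):
                        hap_row = rng.integers(0, 2 * n_zone)
                        pops[swp["chrom_i"]][hap_row, swp["site"]] = 1
            active = [(s["chrom_i"], s["site"], s["spec"].s)
                      for s in zone_sweeps
                      if gen >= s["start_gen"] and not s.get("done", False)]
            fitness = _zone_fitness(pops, active)
            pops = _next_generation(rng, pops, positions, cfg, fitness, selfing)
            gen += 1
            lost = [s for s in zone_sweeps
                    if gen > s["start_gen"] and pops[s["chrom_i"]][:, s["site"]].sum() == 0]
            if lost:
                retries += 1
                if retries > cfg.max_retries:
                    raise SweepLostError(
                        f"sweep lost in zone {z!r} after {cfg.max_retries} retries")
                pops = [p.copy() for p in checkpoint[0]]
                gen = checkpoint[1]
                for swp in zone_sweeps:
                    swp.pop("done", None)
                continue
            for swp in zone_sweeps:
                if gen > swp["start_gen"] and not swp.get("done", False):
                    freq = pops[swp["chrom_i"]][:, swp["site"]].mean()
                    if freq >= swp["spec"].target_freq:
                        swp["done"] = True
        zone_pops[z] = pops

    # -------------------- subpop phase: per-subpopulation drift ----------
    n_sub = cfg.n_diploids_per_subpop
    for z in ZONES:
        selfing = float(cfg.inbreeding_zone_fraction.get(z, 0.0))
        zone_sweeps = [(s["chrom_i"], s["site"], s["spec"].s)
                       for s in sweeps
                       if s["spec"].zone == z and not s.get("done", False)]
        merged = [np.empty_like(p) for p in zone_pops[z]]
        for k in range(cfg.n_subpops_per_zone):
            rows = slice(2 * k * n_sub, 2 * (k + 1) * n_sub)
            sub = [p[rows].copy() for p in zone_pops[z]]
            for _ in range(cfg.subpop_generations):
                fitness = _zone_fitness(sub, zone_sweeps)
                sub = _next_generation(rng, sub, positions, cfg, fitness, selfing)
            for c in range(cfg.n_chromosomes):
                merged[c][rows] = sub[c]
        zone_pops[z] = merged

    # -------------------- assemble samples -------------------------------
    sample_rows = []
    hap_blocks = [[] for _ in range(cfg.n_chromosomes)]
    temps, precs = [], []
    offsets = (np.linspace(-1.0, 1.0, cfg.n_subpops_per_zone)
               if cfg.n_subpops_per_zone > 1 else np.zeros(1))
    for z in ZONES:
        t_mean, p_mean = cfg.env_means[z]
        for k in range(cfg.n_subpops_per_zone):
            sp = f"{z}_sp{k + 1}"
            t_sub = t_mean + offsets[k] * cfg.env_subpop_sd[0]
            p_sub = p_mean + offsets[k] * cfg.env_subpop_sd[1]
            for i in range(n_sub):
                sample_rows.append({
                    "sample_id": f"{sp}_{i + 1:03d}",
                    "subpopulation": sp, "zone": z,
                })
                temps.append(t_sub + rng.normal(0, cfg.env_noise_sd[0]))
                precs.append(p_sub + rng.normal(0, cfg.env_noise_sd[1]))
        for c in range(cfg.n_chromosomes):
            hap_blocks[c].append(zone_pops[z][c])
    haps_per_chrom = [np.vstack(blocks) for blocks in hap_blocks]
    samples = pd.DataFrame(sample_rows)
    samples["temperature"] = np.round(temps, 3)
    samples["precipitation"] = np.round(precs, 2)
    n_total = len(samples)

    truth = TruthRecord(seed=cfg.seed,
                        zone_of_sample=dict(zip(samples["sample_id"], samples["zone"])))

    # planted environmental SNP: per-sample Bernoulli haplotypes tracking the
    # subpopulation temperature gradient within the target zone
    if env_site is not None:
        c, site = env_site
        pe = cfg.planted_env_snp
        zmask = (samples["zone"] == pe.zone).to_numpy()
        t = samples["temperature"].to_numpy()
        t_z = t[zmask]
        span = t_z.max() - t_z.min()
        frac = (t - t_z.min()) / span if span > 0 else np.full(n_total, 0.5)
        p_i = np.clip(pe.p_range[0] + frac * (pe.p_range[1] - pe.p_range[0]), 0.01, 0.99)
        p_i = np.where(zmask, p_i, 0.5)
        draws = rng.random((n_total, 2)) < p_i[:, None]
        haps_per_chrom[c][0::2, site] = draws[:, 0]
        haps_per_chrom[c][1::2, site] = draws[:, 1]
        truth.planted_env_snp = {
            "chrom": str(pe.chrom), "pos": int(positions[c][site]),
            "site_index": site, "zone": pe.zone, "p_range": list(pe.p_range),
            "covariate": pe.covariate,
        }

    # planted ROH: copy one haplotype over the other across the interval and
    # delimit it with explicitly heterozygous flanking sites (truth markers)
    zone_sample_idx = {z: np.flatnonzero((samples["zone"] == z).to_numpy()) for z in ZONES}
    for pr in cfg.planted_roh:
        c = pr.chrom - 1
        pos = positions[c]
        inside = np.flatnonzero((pos >= pr.start) & (pos <= pr.end))
        if inside.size == 0:
            raise ValueError("planted ROH interval contains no sites")
        first, last = inside[0], inside[-1]
        carriers = rng.choice(zone_sample_idx[pr.zone], size=pr.n_carriers, replace=False)
        lo = max(first - pr.flank_sites, 0)
        hi = min(last + pr.flank_sites, cfg.n_sites - 1)
        for s_i in carriers:
            h = haps_per_chrom[c]
            h[2 * s_i + 1, first:last + 1] = h[2 * s_i, first:last + 1]
            h[2 * s_i, lo:first] = 0
            h[2 * s_i + 1, lo:first] = 1
            h[2 * s_i, last + 1:hi + 1] = 0
            h[2 * s_i + 1, last + 1:hi + 1] = 1
            truth.planted_roh.append({
                "sample_id": samples["sample_id"].iloc[s_i], "chrom": str(pr.chrom),
                "first_pos": int(pos[first]), "last_pos": int(pos[last]),
                "n_sites": int(last - first + 1), "zone": pr.zone,
            })

    # realized sweep frequencies per zone
    zone_rows = {z: np.flatnonzero((samples["zone"] == z).to_numpy()) for z in ZONES}
    for swp in sweeps:
        c, site = swp["chrom_i"], swp["site"]
        col = haps_per_chrom[c][:, site]
        freq = {}
        for z, rows in zone_rows.items():
            hap_rows = np.ravel(np.column_stack([2 * rows, 2 * rows + 1]))
            freq[z] = float(col[hap_rows].mean())
        truth.sweeps.append({
            "chrom": str(swp["spec"].chrom), "pos": swp["pos"], "site_index": site,
            "s": swp["spec"].s, "zone": swp["spec"].zone,
            "start_gen": swp["start_gen"], "final_freq": freq,
        })

    # variant table: derived allele (founder-polarized) is ALT, ancestral is REF
    nuc = np.array(["A", "C", "G", "T"])
    var_frames = []
    for c in range(cfg.n_chromosomes):
        ref_i = rng.integers(0, 4, size=cfg.n_sites)
        alt_i = (ref_i + rng.integers(1, 4, size=cfg.n_sites)) % 4
        var_frames.append(pd.DataFrame({
            "chrom": str(c + 1), "pos": positions[c],
            "ref": nuc[ref_i], "alt": nuc[alt_i], "ancestral": nuc[ref_i],
        }))
    variants = pd.concat(var_frames, ignore_index=True)

    haplotypes = np.hstack(haps_per_chrom)
    genotypes = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    ds = GenotypeDataset(genotypes=genotypes, variants=variants,
                         samples=samples, haplotypes=haplotypes, phased=True)
    ds.validate()

    hap_mats = {
        str(c + 1): HaplotypeMatrix(
            alleles=np.ascontiguousarray(haps_per_chrom[c]),
            positions=positions[c].astype(np.int64),
            chrom=str(c + 1),
            sample_ids=samples["sample_id"].tolist(),
        )
        for c in range(cfg.n_chromosomes)
    }
    return ds, hap_mats, truth


# ---------------------------------------------------------------------------
# Study writer
# ---------------------------------------------------------------------------

def write_study(ds: GenotypeDataset, truth: TruthRecord, out_dir) -> dict:
    """Write VCF + PLINK trio + samples.tsv + truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "study.vcf",
        "plink": out / "study",
        "plink_bed": out / "study.bed",
        "plink_bim": out / "study.bim",
        "plink_fam": out / "study.fam",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(ds, paths["vcf"])
    write_plink(ds, paths["plink"])
    ds.samples.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# Scenario presets (the study conditions used throughout the test suite)
# ---------------------------------------------------------------------------

def neutral_config(seed: int, n_sites: int = 22_000, n_diploids: int = 500,
                   split_generations: int = 50) -> SimConfig:
    """Two panmictic populations drifting apart: the drift-calibration scenario."""
    return SimConfig(seed=seed, n_subpops_per_zone=1, n_diploids_per_subpop=n_diploids,
                     n_chromosomes=3, n_sites=n_sites,
                     split_generations=split_generations, subpop_generations=0)


def sweep_config(seed: int, s: float = 0.15, chrom: int = 2, pos: int = 5_000_000,
                 split_generations: int = 15) -> SimConfig:
    """Study-shaped run with one hard, incomplete sweep in the hot ('case') zone.

    The favored allele is a young standing variant private to the case zone
    (founder frequency 0.1 on one shared haplotype background); selection
    runs from the split and stops when the allele reaches 60% (controlled
    incomplete sweep), so the locus stays at intermediate frequency and
    iHS-scoreable
    while leaving a strong haplotype and differentiation footprint.
    """
    return SimConfig(seed=seed, split_generations=split_generations,
                     subpop_generations=0, n_diploids_per_subpop=60,
                     n_chromosomes=12, n_sites=2_500,
                     sweep_loci=[SweepSpec(chrom=chrom, pos=pos, s=s, zone="case",
                                           p0=0.15, target_freq=0.6,
                                           bg_window=500_000)])


def inbred_config(seed: int, selfing: float = 0.9) -> SimConfig:
    """Selfing in the case zone plus two planted ROH; control zone panmictic."""
    return SimConfig(
        seed=seed, split_generations=50, subpop_generations=10,
        inbreeding_zone_fraction={"case": selfing},
        planted_roh=[
            PlantedROH(zone="case", chrom=1, start=3_000_000, end=4_500_000, n_carriers=12),
            PlantedROH(zone="case", chrom=3, start=6_000_000, end=7_200_000, n_carriers=10),
        ],
    )


def replant_env_snp(ds: GenotypeDataset, env_info: dict, seed: int) -> GenotypeDataset:
    """Re-draw the planted environmental SNP's genotypes with a fresh seed.

    ``env_info`` is the ``planted_env_snp`` entry of a :class:`TruthRecord`
    (or its dict form).  Returns a copy of ``ds`` whose haplotypes and
    genotypes at the planted site are redrawn from the same
    temperature-gradient allele-frequency model; used for power replicates.
    """
    rng = np.random.default_rng(seed)
    j = np.flatnonzero((ds.variants["chrom"].astype(str) == str(env_info["chrom"]))
                       & (ds.variants["pos"] == env_info["pos"]))
    if j.size != 1:
        raise ValueError("planted site not found in dataset (removed by QC?)")
    j = int(j[0])
    zmask = (ds.samples["zone"] == env_info["zone"]).to_numpy()
    t = ds.samples["temperature"].to_numpy(float)
    t_z = t[zmask]
    span = t_z.max() - t_z.min()
    lo, hi = env_info["p_range"]
    frac = (t - t_z.min()) / span if span > 0 else np.full(ds.n_samples, 0.5)
    p_i = np.where(zmask, np.clip(lo + frac * (hi - lo), 0.01, 0.99), 0.5)
    draws = (rng.random((ds.n_samples, 2)) < p_i[:, None]).astype(np.int8)
    out = GenotypeDataset(genotypes=ds.genotypes.copy(), variants=ds.variants,
                          samples=ds.samples,
                          haplotypes=None if ds.haplotypes is None else ds.haplotypes.copy(),
                          phased=ds.phased)
    if out.haplotypes is not None:
        out.haplotypes[0::2, j] = draws[:, 0]
        out.haplotypes[1::2, j] = draws[:, 1]
    out.genotypes[:, j] = draws.sum(axis=1)
    return out


def env_config(seed: int) -> SimConfig:
    """Weak subpopulation structure with a planted temperature-tracking SNP.

    The subpopulation phase is short (one generation) so that within-zone
    structure is present but mild; stronger subpopulation drift confounds
    the subpop-level temperature gradient completely, which no amount of
    genomic-control correction can undo.
    """
    return SimConfig(
        seed=seed, split_generations=30, subpop_generations=1,
        planted_env_snp=PlantedEnvSNP(chrom=2, pos=4_000_000, zone="case"),
    )
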