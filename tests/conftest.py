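"""Shared study fixtures.

The four simulation scenarios (neutral drift calibration, selective sweep,
inbred zone, environmental association) are expensive, so they are built
once per session and shared between the module tests and the acceptance
suite.  Scenario seeds are fixed.
"""

import numpy as np
import pandas as pd
import pytest

from selscan import genodata as gd
from selscan import haploscan as hs
from selscan import synthpop as sp

NEUTRAL_SEED = 1
SWEEP_SEED = 2
INBRED_SEED = 3
ENV_SEED = 4


@pytest.fixture(scope="session")
def neutral_study():
    cfg = sp.neutral_config(seed=NEUTRAL_SEED)
    ds, haps, truth = sp.simulate(cfg)
    ds_qc, _ = gd.apply_qc(ds)
    return {"cfg": cfg, "ds": ds, "ds_qc": ds_qc, "truth": truth}


@pytest.fixture(scope="session")
def neutral_ihs_case(neutral_study):
    mats = hs.haplotype_matrices_from_dataset(neutral_study["ds_qc"], zone="case")
    return hs.ihs_scan(list(mats.values()))


@pytest.fixture(scope="session")
def sweep_study():
    cfg = sp.sweep_config(seed=SWEEP_SEED)
    ds, haps, truth = sp.simulate(cfg)
    ds_qc, _ = gd.apply_qc(ds)
    return {"cfg": cfg, "ds": ds, "ds_qc": ds_qc, "truth": truth}


@pytest.fixture(scope="session")
def sweep_hap_mats(sweep_study):
    return {z: hs.haplotype_matrices_from_dataset(sweep_study["ds_qc"], zone=z)
            for z in ("case", "control")}


@pytest.fixture(scope="session")
def sweep_ihs_case(sweep_hap_mats):
    return hs.ihs_scan(list(sweep_hap_mats["case"].values()))


@pytest.fixture(scope="session")
def sweep_rsb(sweep_study, sweep_hap_mats):
    chrom = sweep_study["truth"].sweeps[0]["chrom"]
    return hs.rsb_scan(sweep_hap_mats["case"][chrom], sweep_hap_mats["control"][chrom])


@pytest.fixture(scope="session")
def inbred_study():
    cfg = sp.inbred_config(seed=INBRED_SEED)
    ds, haps, truth = sp.simulate(cfg)
    ds_qc, _ = gd.apply_qc(ds)
    return {"cfg": cfg, "ds": ds, "ds_qc": ds_qc, "truth": truth}


@pytest.fixture(scope="session")
def inbred_segments(inbred_study):
    from selscan import rohscan as rs

    return rs.detect_roh(inbred_study["ds_qc"])


@pytest.fixture(scope="session")
def env_study():
    cfg = sp.env_config(seed=ENV_SEED)
    ds, haps, truth = sp.simulate(cfg)
    ds_qc, _ = gd.apply_qc(ds)
    return {"cfg": cfg, "ds": ds, "ds_qc": ds_qc, "truth": truth}


# ---------------------------------------------------------------------------
# Small hand-made datasets
# ---------------------------------------------------------------------------

TINY_VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|0\t0|1\t1|1
1\t200\t.\tC\tT\t.\tPASS\tAA=T\tGT\t0|1\t1|1\t.|.
"""

TINY_VCF_TRIALLELIC = TINY_VCF + "2\t300\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/1\n"


@pytest.fixture()
def tiny_vcf(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(TINY_VCF)
    return p


@pytest.fixture()
def tiny_vcf_triallelic(tmp_path):
    p = tmp_path / "tri.vcf"
    p.write_text(TINY_VCF_TRIALLELIC)
    return p


def make_dataset(genotypes, positions=None, chrom="1", sample_meta=None,
                 haplotypes=None):
    """Build a GenotypeDataset from a plain genotype matrix for unit tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if np.isscalar(chrom):
        chroms = [str(chrom)] * m
    else:
        chroms = [str(c) for c in chrom]
    variants = pd.DataFrame({"chrom": chroms, "pos": np.asarray(positions, np.int64),
                             "ref": "A", "alt": "G", "ancestral": "A"})
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    if sample_meta:
        for k, v in sample_meta.items():
            samples[k] = v
    return gd.GenotypeDataset(genotypes=g, variants=variants, samples=samples,
                              haplotypes=haplotypes,
                              phased=haplotypes is not None)
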