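"""End-to-end orchestration: simulate/load -> QC -> PCA -> FST -> iHS -> Rsb
-> ROH/LROH -> environmental association, with a JSON run manifest.

Every stage writes plain TSV/BED/JSON files into the run directory so any
stage can be re-run standalone; the manifest records parameters, seeds and
sha256 checksums of every output.  Re-running an unchanged config reproduces
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envassoc, fstscan, genodata, haploscan, rohscan, synthpop


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_config(seed: int = 1) -> dict:
    return {
        "seed": seed,
        "simulate": {"preset": "sweep"},
        "qc": {"maf_min": 0.05, "sample_cr": 0.99, "variant_cr": 0.99},
        "pca": {"k": 10},
        "fst": {"window": 100_000, "step": 50_000, "peak_threshold": 0.2},
        "ihs": {"maf_min": 0.05, "freq_bin_width": 0.025, "cutoff": 0.05},
        "rsb": {"standardization": "median"},
        "roh": {},
        "lroh": {"min_len_kb": 1.0, "min_zone_fraction": 0.05},
        "envassoc": {"covariate": "temperature", "K": 1, "n_runs": 5},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = _default_config(cfg.get("seed", 1))
    for key, val in cfg.items():
        if isinstance(val, dict) and key in base:
            base[key].update(val)
        else:
            base[key] = val
    return base


def _custom_config(seed: int, **kw) -> synthpop.SimConfig:
    return synthpop.SimConfig(seed=seed, **kw)


_PRESETS = {
    "neutral": synthpop.neutral_config,
    "sweep": synthpop.sweep_config,
    "inbred": synthpop.inbred_config,
    "env": synthpop.env_config,
    "custom": _custom_config,
}


def run(config: dict, out_dir, log=sys.stderr) -> dict:
    """Execute the pipeline described by ``config`` into ``out_dir``.

    Returns the manifest dictionary (also written to ``manifest.json``).
    On stage failure the pipeline halts with the stage name; outputs of
    completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"seed": seed, "config": config, "stages": {}, "checksums": {}}
    stage = "init"

    def _log(msg):
        print(msg, file=log, flush=True)

    def _finish(name, t0, paths):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
        for p in paths:
            manifest["checksums"][Path(p).name] = _sha256(Path(p))
        _log(f"[{name}] done in {manifest['stages'][name]['seconds']}s")

    try:
        # ---------------- inputs ----------------
        stage = "simulate"
        t0 = time.time()
        if "simulate" in config:
            sim_cfg = config["simulate"]
            preset = _PRESETS[sim_cfg.get("preset", "sweep")]
            cfg = preset(seed=seed, **{k: v for k, v in sim_cfg.items() if k != "preset"})
            ds, _, truth = synthpop.simulate(cfg)
            paths = synthpop.write_study(ds, truth, out / "study")
            manifest["stages"]["simulate"] = {"preset": sim_cfg.get("preset", "sweep")}
            _finish(stage, t0, [p for k, p in paths.items() if k != "plink"])
        else:
            meta = pd.read_csv(config["meta"], sep="\t")
            ds = genodata.read_genotypes(config["vcf"], fmt="vcf", meta=meta)

        # ---------------- QC ----------------
        stage = "qc"
        t0 = time.time()
        ds_qc, qclog = genodata.apply_qc(ds, **config.get("qc", {}))
        qc_path = out / "qc_log.json"
        qc_path.write_text(json.dumps(dataclasses.asdict(qclog), indent=2))
        _finish(stage, t0, [qc_path])

        # ---------------- PCA ----------------
        stage = "pca"
        t0 = time.time()
        pca = genodata.grm_pca(ds_qc, k=config["pca"]["k"])
        pca_path = out / "pca.tsv"
        pd.DataFrame(pca.eigenvectors,
                     columns=[f"PC{i + 1}" for i in range(pca.eigenvectors.shape[1])]
                     ).assign(sample_id=ds_qc.samples["sample_id"].to_numpy()
                              ).to_csv(pca_path, sep="\t", index=False)
        _finish(stage, t0, [pca_path])

        # ---------------- FST ----------------
        stage = "fst"
        t0 = time.time()
        fst_cfg = config["fst"]
        sites = fstscan.per_site_fst(ds_qc, "zone")
        wt = fstscan.sliding_windows(sites, size=fst_cfg["window"], step=fst_cfg["step"])
        peaks = fstscan.call_peaks(wt, peak_threshold=fst_cfg["peak_threshold"])
        p_sites = out / "fst_sites.tsv"
        p_win = out / "fst_windows.tsv"
        p_peaks = out / "fst_peaks.bed"
        sites.to_csv(p_sites, sep="\t", index=False)
        wt.to_csv(p_win, sep="\t", index=False)
        with open(p_peaks, "w") as fh:
            for pk in peaks:
                fh.write(f"{pk.chrom}\t{pk.base_start}\t{pk.base_end}\t"
                         f"apex={pk.apex_value:.4f}\n")
        _finish(stage, t0, [p_sites, p_win, p_peaks])

        # ---------------- iHS / Rsb ----------------
        stage = "ihs"
        t0 = time.time()
        ihs_cfg = config["ihs"]
        haps = {z: haploscan.haplotype_matrices_from_dataset(ds_qc, zone=z)
                for z in ("case", "control")}
        ihs_paths = []
        for z, mats in haps.items():
            track = haploscan.ihs_scan(list(mats.values()), maf_min=ihs_cfg["maf_min"],
                                       freq_bin_width=ihs_cfg["freq_bin_width"],
                                       cutoff=ihs_cfg["cutoff"])
            p = out / f"ihs_{z}.tsv"
            track.to_csv(p, sep="\t", index=False)
            ihs_paths.append(p)
        _finish(stage, t0, ihs_paths)

        stage = "rsb"
        t0 = time.time()
        rsb_frames = []
        for chrom in haps["case"]:
            rsb_frames.append(haploscan.rsb_scan(
                haps["case"][chrom], haps["control"][chrom],
                standardization=config["rsb"]["standardization"]))
        p_rsb = out / "rsb.tsv"
        pd.concat(rsb_frames, ignore_index=True).to_csv(p_rsb, sep="\t", index=False)
        _finish(stage, t0, [p_rsb])

        # ---------------- ROH / LROH ----------------
        stage = "roh"
        t0 = time.time()
        prm = rohscan.ROHParams(**config.get("roh", {}))
        segments = rohscan.detect_roh(ds_qc, prm)
        p_seg = out / "roh_segments.tsv"
        rohscan.segments_frame(segments).to_csv(p_seg, sep="\t", index=False)
        zones = dict(zip(ds_qc.samples["sample_id"], ds_qc.samples["zone"]))
        pools = rohscan.pool_segments(segments, ds=ds_qc, zones=zones)
        zone_sizes = ds_qc.samples["zone"].value_counts().to_dict()
        calls = rohscan.classify_lroh(pools, zones, zone_sizes,
                                      **config.get("lroh", {}))
        p_lroh = out / "lroh.tsv"
        rohscan.lroh_frame(calls).to_csv(p_lroh, sep="\t", index=False)
        _finish(stage, t0, [p_seg, p_lroh])

        # ---------------- environmental association ----------------
        stage = "envassoc"
        t0 = time.time()
        ea = config["envassoc"]
        track = envassoc.lfmm_scan(ds_qc, covariate=ea["covariate"], K=ea["K"],
                                   n_runs=ea["n_runs"], seed=seed,
                                   lambda_mode=ea.get("lambda", "computed"))
        p_env = out / "envassoc.tsv"
        track.to_csv(p_env, sep="\t", index=False)
        _finish(stage, t0, [p_env])

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
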