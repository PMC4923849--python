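"""End-to-end orchestration: simulate -> dmr -> meqtl -> enrich -> cohort.

A single YAML config drives the run; one global seed deterministically
spawns per-stage substreams, so each stage can also be reproduced
standalone.  The manifest records parameters, seeds, input checksums and
the headline outputs (DMR count, FDR, ngDMR fraction, enrichment z,
odds-ratio table), and reruns at the same seed are byte-identical apart
from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import dmr as dmr_mod
from . import enrichment as enr_mod
from . import io as io_mod
from . import meqtl as meqtl_mod
from . import simulate as sim_mod
from .core import GenomeLayout

logger = logging.getLogger("stresswgbs")

REQUIRED_KEYS = ("outdir", "seed")

DEFAULT_CONFIG = {
    "outdir": "stresswgbs_run",
    "seed": 0,
    "log_level": "INFO",
    "methylome": {"genome_length": 200_000, "n_per_group": 5, "mean_coverage": 15.0,
                  "n_true_dmrs": 50, "dmr_effect": 0.3},
    "smoothing": {"min_window_bp": 600, "min_window_cpgs": 19},
    "floor_quantile": 0.5,
    "calling": {"t_cutoff": 4.5, "min_cpgs": 3, "min_diff": 0.10, "max_gap_bp": 300},
    "fdr_perms": 20,
    "meqtl": {"n_meqtls": 20, "beta_meqtl": 0.25, "maf": 0.5,
              "window_bp": 5000, "alpha": 0.05},
    "annotations": {"n_intervals": 60, "frac_near_dmrs": 0.8, "interval_len": 500,
                    "n_shuffles": 1000},
    "cohort": {"n_subjects": 443, "or_high": 2.44, "or_medium": 1.39},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} is not a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    missing = [k for k in REQUIRED_KEYS if cfg.get(k) is None]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run every stage and return (and write) the manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO"))))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(int(config["seed"])).spawn(6)]
    manifest: dict = {"seed": int(config["seed"]), "stage_seeds": seeds,
                      "parameters": config, "outputs": {}, "checksums": {}}
    stage = "simulate"
    try:
        mcfg = config["methylome"]
        genome = GenomeLayout(("chr1",), (int(mcfg["genome_length"]),))
        sim = sim_mod.MethylomeSimConfig(
            genome=genome, n_per_group=int(mcfg["n_per_group"]),
            mean_coverage=float(mcfg["mean_coverage"]),
            n_true_dmrs=int(mcfg["n_true_dmrs"]),
            dmr_effect=float(mcfg["dmr_effect"]), seed=seeds[0])
        meth, truth = sim_mod.simulate_methylome(sim)
        geno, truth = sim_mod.simulate_genotypes(
            meth, truth, n_meqtls=int(config["meqtl"]["n_meqtls"]),
            beta_meqtl=float(config["meqtl"]["beta_meqtl"]),
            maf=float(config["meqtl"]["maf"]), seed=seeds[1])
        track = sim_mod.simulate_annotations(
            genome, truth, n_intervals=int(config["annotations"]["n_intervals"]),
            frac_near_dmrs=float(config["annotations"]["frac_near_dmrs"]),
            interval_len=int(config["annotations"]["interval_len"]), seed=seeds[2])
        cohort_cfg = sim_mod.CohortSimConfig(
            n_subjects=int(config["cohort"]["n_subjects"]),
            or_high=float(config["cohort"]["or_high"]),
            or_medium=float(config["cohort"]["or_medium"]), seed=seeds[3])
        cohort_tbl, _ = sim_mod.simulate_cohort(cohort_cfg)

        io_mod.write_genome_layout(genome, outdir / "genome.tsv")
        io_mod.write_methylation(meth, outdir / "counts.tsv")
        io_mod.write_genotypes(geno, outdir / "snps.vcf")
        io_mod.write_intervals(track, outdir / "annotations.bed")
        io_mod.write_cohort(cohort_tbl, outdir / "cohort.csv")
        logger.info("simulated %d CpGs, %d SNPs, %d subjects",
                    meth.n_cpgs, geno.n_variants, len(cohort_tbl))

        stage = "dmr"
        sp = dmr_mod.SmoothParams(**config["smoothing"])
        cp = dmr_mod.DMRCallParams(**config["calling"])
        fq = float(config.get("floor_quantile", 0.75))
        smoothed = dmr_mod.smooth_all(meth, sp)
        track_t = dmr_mod.compute_tstat(smoothed, meth, floor_quantile=fq)
        dmrs = dmr_mod.call_dmrs(track_t, cp)
        fdr = dmr_mod.estimate_fdr(meth, sp, cp, n_perms=int(config["fdr_perms"]),
                                   seed=seeds[4], floor_quantile=fq,
                                   smoothed=smoothed)
        for d in dmrs:
            d.fdr = fdr.fdr
        manifest["outputs"]["n_dmrs"] = len(dmrs)
        manifest["outputs"]["fdr"] = fdr.fdr

        stage = "meqtl"
        mq = meqtl_mod.MeQTLParams(window_bp=int(config["meqtl"]["window_bp"]),
                                   alpha=float(config["meqtl"]["alpha"]))
        dmrs, _, summary = meqtl_mod.classify_dmrs(dmrs, meth, geno, mq)
        io_mod.write_dmrs(dmrs, outdir / "dmrs.bed")
        manifest["outputs"]["n_gdmr"] = summary.n_gdmr
        manifest["outputs"]["ngdmr_fraction"] = summary.ngdmr_fraction

        stage = "enrich"
        ez = enr_mod.enrichment_z(
            dmrs, track, genome,
            enr_mod.ShuffleParams(n_shuffles=int(config["annotations"]["n_shuffles"]),
                                  seed=seeds[5]),
            track_name="annotations")
        manifest["outputs"]["enrichment"] = {
            "track": ez.track_name, "observed": ez.observed_overlap,
            "null_mean": ez.null_mean, "null_sd": ez.null_sd, "z": ez.z,
            "empirical_p": ez.empirical_p}

        stage = "cohort"
        or_high = cohort_mod.contingency_or(cohort_tbl, "persistent_wheeze",
                                            "stress_category", "high", "low")
        or_med = cohort_mod.contingency_or(cohort_tbl, "persistent_wheeze",
                                           "stress_category", "medium", "low")
        manifest["outputs"]["odds_ratios"] = {
            r.comparison: {"or": r.odds_ratio, "ci": [r.ci_low, r.ci_high],
                           "p": r.p_value}
            for r in (or_high, or_med)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(outdir.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["checksums"][p.name] = _sha256(p)
    manifest_with_time = dict(manifest)
    manifest_with_time["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest_with_time, indent=2, sort_keys=True, default=str))
    return manifest_with_time
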