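"""End-to-end orchestration: simulate -> regions -> blocks -> scan -> tag ->
replicate -> meta -> power -> co-occur -> characterize, from one RunConfig,
with deterministic per-stage seeding and a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cooccurrence, downstream, ld, power, regions, replication
from .simulate import (
    SimulationConfig,
    ancestry_frequencies,
    export_cohort,
    simulate_cohort,
    simulate_loop_anchors,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "stage_seed"]

_STAGE_OFFSETS = {
    "simulate": 101, "replication_cohort": 211, "anchors": 307, "blocks": 401,
    "scan": 503, "replicate": 601, "meta": 701, "power": 809, "cooccur": 907,
    "characterize": 1009,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed fan-out of the global seed so toggling stages never shifts streams."""
    return int(global_seed) * 10_000 + _STAGE_OFFSETS[stage]


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    strategies: tuple = ("risk", "linear", "spatial", "enhancer")
    min_maf: float = 0.05
    alpha_bonferroni: float = 0.1
    q_risk: float = 0.1
    q_replication: float = 0.1
    q_meta: float = 0.1
    q_pairs: float = 0.05
    min_patients: int = 15
    flank: int = 500_000
    anchor_window: int = 1_000_000
    n_risk_snps: int = 20
    min_driver_freq: float = 0.05
    seed: int = 0
    out_dir: str = "dqtl_run"

    def __post_init__(self):
        for name in ("alpha_bonferroni", "q_risk", "q_replication", "q_meta", "q_pairs"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {}}

    def record(stage, status, **info):
        manifest["stages"][stage] = {"status": status, **info}

    # --- simulate -----------------------------------------------------------
    cohort = simulate_cohort(config.simulation, seed=stage_seed(config.seed, "simulate"))
    replication_cohort = simulate_cohort(
        config.simulation, seed=stage_seed(config.seed, "replication_cohort"),
        timing_available=False,
    )
    record("simulate", "ok", n_patients=cohort.n_patients,
           n_snps=len(cohort.snp_table), digest=_digest(cohort.snp_table))

    freq = cohort.drivers.mean(axis=0)
    eligible = [d for d in cohort.drivers.columns if freq[d] >= config.min_driver_freq]

    planted = {e.driver_id: e.snp_id for e in config.simulation.planted_effects}
    driver_regions = {d: cohort.driver_region(d) for d in eligible}
    anchors = simulate_loop_anchors(
        cohort.snp_table, driver_regions, planted_snp_ids=planted,
        seed=stage_seed(config.seed, "anchors"),
    )
    record("anchors", "ok", n_pairs=len(anchors))

    # --- scan ---------------------------------------------------------------
    scan_frames = []
    tag_rows = []
    try:
        if "risk" in config.strategies:
            rng = np.random.default_rng(stage_seed(config.seed, "scan"))
            pool = association.maf_filter(cohort.snp_table, config.min_maf)
            k = min(config.n_risk_snps, len(pool))
            risk_snps = sorted(rng.choice(pool["id"], size=k, replace=False))
            df = association.scan_risk(cohort, risk_snps, eligible,
                                       q_threshold=config.q_risk, min_maf=config.min_maf)
            scan_frames.append(df)
        for strategy in ("linear", "spatial", "enhancer"):
            if strategy not in config.strategies:
                continue
            for d in eligible:
                region = driver_regions[d]
                if strategy == "linear":
                    reg = regions.linear_window(region, config.flank)
                elif strategy == "spatial":
                    lin = regions.linear_window(region, config.flank)
                    reg = regions.spatial_regions(region, anchors, exclude=lin)
                else:
                    reg = regions.enhancer_regions(region, anchors)
                snp_ids = regions.snps_in_regions(cohort.snp_table, reg)
                sub = cohort.snp_table[cohort.snp_table["id"].isin(snp_ids)]
                sub = association.maf_filter(sub, config.min_maf)
                if not len(sub):
                    continue
                cols = [cohort._col[s] for s in sub["id"]]
                blocks = ld.gabriel_blocks(cohort.dosage[:, cols], list(sub["id"]))
                df = association.scan_local(cohort, d, strategy, reg, blocks,
                                            alpha=config.alpha_bonferroni,
                                            min_maf=config.min_maf)
                scan_frames.append(df)
                tags = association.select_tag_snps(df, blocks, cohort.snp_table)
                if len(tags):
                    tag_rows.append(tags)
        results = (pd.concat(scan_frames, ignore_index=True)
                   if scan_frames else pd.DataFrame(columns=association.RESULT_COLUMNS))
        record("scan", "ok", n_tests=len(results),
               n_significant=int(results["significant"].sum()) if len(results) else 0)
    except Exception as exc:  # pragma: no cover - fail-and-skip plumbing
        record("scan", "failed", error=str(exc))
        results = pd.DataFrame(columns=association.RESULT_COLUMNS)
        tag_rows = []

    discovered = pd.concat(tag_rows, ignore_index=True) if tag_rows else results.iloc[0:0]
    risk_hits = (results[(results["strategy"] == "risk") & results["significant"]]
                 if len(results) else results)
    discovered = pd.concat([discovered, risk_hits], ignore_index=True)
    discovered = discovered.drop_duplicates(subset=["snp_id", "driver_id"])

    # --- replicate / meta ---------------------------------------------------
    if manifest["stages"]["scan"]["status"] == "ok" and len(discovered):
        rep = replication.test_replication(discovered, replication_cohort,
                                           q_threshold=config.q_replication)
        record("replicate", "ok", n_tested=len(rep),
               n_replicated=int(rep["replicated"].sum()))
        concordant = rep[rep["concordant"]]
        meta_records = {
            f"{r.snp_id}|{r.driver_id}": [
                (r.beta_discovery, r.se_discovery),
                (r.beta_replication, r.se_replication),
            ]
            for r in concordant.itertuples(index=False)
            if np.isfinite(r.se_replication) and r.se_replication > 0
               and np.isfinite(r.se_discovery) and r.se_discovery > 0
        }
        meta = (replication.meta_analyze_set(meta_records, q_threshold=config.q_meta)
                if meta_records else pd.DataFrame())
        record("meta", "ok", n_meta=len(meta))
    else:
        rep = pd.DataFrame()
        meta = pd.DataFrame()
        record("replicate", "skipped")
        record("meta", "skipped")

    # --- power --------------------------------------------------------------
    grid = power.power_grid(
        maf_grid=[0.1, 0.3, 0.5], or_grid=[1.5, 2.0, 3.0],
        freq_grid=[0.05, 0.2, 0.5],
        n_total=cohort.n_patients, alpha=config.alpha_bonferroni / 50,
    )
    record("power", "ok", n_points=len(grid))

    # --- co-occurrence ------------------------------------------------------
    pairs = cooccurrence.pairwise_tests(cohort.drivers, min_patients=config.min_patients,
                                        q_threshold=config.q_pairs)
    record("cooccur", "ok", n_pairs=len(pairs))

    # --- characterize -------------------------------------------------------
    panels = config.simulation.ancestry_panels or {"POP1": 0.01, "POP2": 0.1}
    vaf_table = ancestry_frequencies(cohort.snp_table, panels,
                                     seed=stage_seed(config.seed, "characterize"))
    record("characterize", "ok", n_vaf_rows=len(vaf_table))

    # --- write outputs ------------------------------------------------------
    tables = {
        "associations.tsv": results, "discovered.tsv": discovered,
        "replication.tsv": rep, "meta.tsv": meta, "power_grid.tsv": grid,
        "driver_pairs.tsv": pairs, "population_vaf.tsv": vaf_table,
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = str(path)
    export_paths = export_cohort(cohort, out / "cohort", anchors=anchors)
    manifest["outputs"]["cohort"] = {k: str(v) for k, v in export_paths.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def validate_inputs(paths: dict) -> dict:
    """Cross-check VCF/TSV/BED/BEDPE inputs; returns {'issues': [...], 'ok': bool}."""
    from . import io as io_mod

    issues = []
    dosage = snp_table = samples = None
    if "vcf" in paths:
        try:
            dosage, snp_table, samples = io_mod.read_vcf(paths["vcf"])
        except Exception as exc:
            issues.append(f"vcf: {exc}")
    drivers = None
    if "drivers" in paths:
        try:
            drivers = io_mod.read_tsv_matrix(paths["drivers"])
            if samples is not None:
                extra = [s for s in drivers.index if s not in set(samples)]
                if extra:
                    issues.append(f"drivers: patients absent from VCF: {extra[:10]}")
        except Exception as exc:
            issues.append(f"drivers: {exc}")
    if "covariates" in paths:
        try:
            cov = io_mod.read_tsv_matrix(paths["covariates"])
            if samples is not None:
                extra = [s for s in cov.index if s not in set(samples)]
                if extra:
                    issues.append(f"covariates: patients absent from VCF: {extra[:10]}")
        except Exception as exc:
            issues.append(f"covariates: {exc}")
    if "driver_regions" in paths:
        try:
            reg = io_mod.read_bed(paths["driver_regions"])
            if snp_table is not None:
                chroms = set(snp_table["chrom"])
                missing = sorted(set(reg.intervals["chrom"]) - chroms)
                if missing:
                    issues.append(f"driver_regions: chromosomes absent from VCF: {missing}")
        except Exception as exc:
            issues.append(f"driver_regions: {exc}")
    if "anchors" in paths:
        try:
            io_mod.read_bedpe(paths["anchors"])
        except Exception as exc:
            issues.append(f"anchors: {exc}")
    return {"issues": issues, "ok": not issues}
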