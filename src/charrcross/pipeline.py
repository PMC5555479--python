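"""End-to-end pipeline: simulate/load -> QC -> crossovers -> heterochiasmy -> QTL.

``run_pipeline`` takes a PipelineConfig (either the three input table
paths or a simulation config, never both), runs the stages in fixed
order, and writes a report bundle: qc_report.json, crossovers.tsv,
heterochiasmy.json, scan.tsv + qtl_table.tsv (when traits are present),
and a MANIFEST recording parameters and the seed.  Reruns with the same
config and seed are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from . import qc as cqc
from . import crossovers as cxo
from . import heterochiasmy as chet
from . import qtl as cqtl
from .simulate import SimConfig, simulate_cross

log = logging.getLogger("charrcross")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # exactly one of the two input sources
    map_path: str | None = None
    geno_path: str | None = None
    pheno_path: str | None = None
    sim: SimConfig | None = None
    # QC
    distortion_p: float = 0.01
    sd_k: float = 3.0
    dup_threshold: float = 0.9
    xo_outlier_m: float = 10.0
    max_missing: float | None = None
    exclude_ids: list = field(default_factory=list)
    # correction
    window: float = 50.0
    chaining: str = "gap"
    odd_cluster: str = "collapse_to_one"
    sensitivity_windows: tuple = (50.0, 25.0, 10.0)
    # scan
    n_perm: int = 1000
    alpha_genome: float = 0.05
    alpha_chrom: float = 0.01
    lod_drop: float = 1.5
    sex_p: float = 0.20
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = any([self.map_path, self.geno_path, self.pheno_path])
        if has_paths == (self.sim is not None):
            raise ValueError(
                "supply exactly one of (input table paths, sim config)")
        if has_paths and not (self.map_path and self.geno_path):
            raise ValueError("map_path and geno_path are both required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": [], "complete": False,
                      "parameters": {k: v for k, v in asdict(config).items()
                                     if k != "sim"}}
    _write_manifest(out, manifest)

    stage = "inputs"
    try:
        if config.sim is not None:
            log.info("simulating cross (seed=%d)", config.sim.seed)
            gmap, genotypes, phenotypes, truth = simulate_cross(config.sim)
            cio.write_map(gmap, out / "map.csv")
            cio.write_genotypes(genotypes, out / "geno.csv")
            cio.write_phenotypes(phenotypes, out / "pheno.csv")
            truth.to_json(out / "ground_truth.json")
        else:
            gmap = cio.read_map(config.map_path)
            genotypes = cio.read_genotypes(config.geno_path, gmap)
            phenotypes = (cio.read_phenotypes(config.pheno_path)
                          if config.pheno_path else None)
        manifest["stages"].append(stage)

        stage = "qc"
        raw_counts = cxo.count_obligate(genotypes, gmap)
        report, genotypes, phenotypes = cqc.run_qc(
            genotypes, gmap, phenotypes, raw_counts,
            distortion_p=config.distortion_p, sd_k=config.sd_k,
            dup_threshold=config.dup_threshold,
            xo_outlier_m=config.xo_outlier_m,
            max_missing=config.max_missing,
            exclude_ids=config.exclude_ids)
        qc_dict = report.to_dict()
        qc_dict["raw_crossover_counts"] = {
            "median": float(raw_counts.median()),
            "mean": float(raw_counts.mean()),
        }
        cio.write_summary(qc_dict, out / "qc_report.json")
        manifest["stages"].append(stage)

        stage = "crossovers"
        params = cxo.CorrectionParams(window=config.window,
                                      chaining=config.chaining,
                                      odd_cluster=config.odd_cluster)
        raw_events = cxo.detect_crossovers(genotypes, gmap,
                                           informative_both_only=True)
        events = cxo.apply_correction(raw_events, params)
        cio.write_crossover_table(events, out / "crossovers.tsv")
        manifest["stages"].append(stage)

        stage = "heterochiasmy"
        summary = chet.summarize(events, gmap)
        dist = chet.positional_distribution(events, gmap)
        sens = chet.sensitivity(raw_events, gmap,
                                windows=config.sensitivity_windows,
                                chaining=config.chaining,
                                odd_cluster=config.odd_cluster)
        # centromere calls use a tight window: wide windows collapse mixed
        # clusters to midpoints that misplace the surviving event
        tight = cxo.apply_correction(
            raw_events, cxo.CorrectionParams(window=10.0,
                                             chaining=config.chaining,
                                             odd_cluster=config.odd_cluster))
        centromeres = chet.infer_all_centromeres(tight, gmap)
        het = summary.to_dict()
        het["external20"] = dist.external20
        het["sensitivity"] = sens.to_dict(orient="records")
        het["centromere_calls"] = centromeres.to_dict(orient="records")
        cio.write_summary(het, out / "heterochiasmy.json")
        dist.counts.reset_index().to_csv(out / "positional_bins.tsv",
                                         sep="\t", index=False)
        manifest["stages"].append(stage)

        scans = {}
        if phenotypes is not None and phenotypes.traits:
            stage = "scan"
            rng = np.random.default_rng(config.seed)
            scan_tables, qtl_rows = [], []
            for trait in phenotypes.traits:
                y = phenotypes.trait_values(trait)
                use_sex = cqtl.sex_covariate_screen(y, phenotypes.sex,
                                                    config.sex_p)
                sex = phenotypes.sex if use_sex else None
                res = cqtl.scan_with_thresholds(
                    y, genotypes, gmap, sex,
                    n_perm=config.n_perm,
                    alpha_genome=config.alpha_genome,
                    alpha_chrom=config.alpha_chrom,
                    seed=rng, trait_name=trait)
                t = res.table.copy()
                t.insert(0, "trait", trait)
                scan_tables.append(t)
                scans[trait] = res
                peaks = res.significant_peaks()
                if len(peaks) == 0:
                    continue
                fit = cqtl.fit_multi_qtl(y, genotypes,
                                         list(peaks["marker"]), sex,
                                         trait_name=trait)
                for _, pk in peaks.iterrows():
                    lo, hi = cqtl.support_interval(res, pk["lg"],
                                                   config.lod_drop)
                    qtl_rows.append({
                        "trait": trait, "lg": pk["lg"],
                        "marker": pk["marker"], "pos_cM": pk["pos_cM"],
                        "lod": pk["lod"],
                        "significance": pk["significance"],
                        "ci_lo_cM": lo, "ci_hi_cM": hi,
                        "total_pve": fit.total_pve,
                        "term_pve": fit.per_term_pve.get(pk["marker"]),
                        "sex_covariate": sex is not None,
                        "sex_pve": fit.per_term_pve.get("sex"),
                        "class_means": json.dumps(
                            fit.class_means.get(pk["marker"], {})),
                    })
            cio.write_scan(pd.concat(scan_tables, ignore_index=True),
                           out / "scan.tsv")
            pd.DataFrame(qtl_rows).to_csv(out / "qtl_table.tsv", sep="\t",
                                          index=False)

            # binary sex-trait scan locates the sex-linked lg
            stage = "sex_linkage"
            sex_res = cqtl.sex_linkage_scan(phenotypes.sex, genotypes, gmap)
            g, c, _ = cqtl.permutation_thresholds(
                (phenotypes.sex == "M").astype(float), genotypes, gmap,
                None, n_perm=config.n_perm, seed=rng)
            sex_res.genome_threshold = g
            sex_res.chrom_thresholds = c
            t = sex_res.table.copy()
            t.insert(0, "trait", "sex")
            cio.write_scan(t, out / "sex_linkage_scan.tsv")
            scans["sex"] = sex_res
            manifest["stages"].append(stage)

        manifest["complete"] = True
        _write_manifest(out, manifest)
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc

    return {"out_dir": str(out), "manifest": manifest, "map": gmap,
            "genotypes": genotypes, "phenotypes": phenotypes,
            "events": events, "summary": summary, "scans": scans}


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=1, default=str))
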