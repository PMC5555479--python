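#!/usr/bin/env python
"""Marker and sample quality control.

Chi-square segregation-distortion filter (P <= 0.01), duplicate-sample
check, raw obligate-crossover outlier rule, and single-pass 3-SD
phenotype outlier masking.  Writes results/qc_report.json and the
QC-passed tables under results/qc/.
"""

from pathlib import Path

from charrcross import crossovers as cxo
from charrcross import io as cio
from charrcross import qc as cqc

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    gmap = cio.read_map(DATA / "map.csv")
    geno = cio.read_genotypes(DATA / "geno.csv", gmap)
    pheno = cio.read_phenotypes(DATA / "pheno.csv")

    raw_counts = cxo.count_obligate(geno, gmap)
    report, geno_qc, pheno_qc = cqc.run_qc(geno, gmap, pheno, raw_counts)

    d = report.to_dict()
    d["raw_crossover_counts"] = {"median": float(raw_counts.median()),
                                 "mean": float(raw_counts.mean())}
    cio.write_summary(d, OUT / "qc_report.json")
    (OUT / "qc").mkdir(exist_ok=True)
    cio.write_genotypes(geno_qc, OUT / "qc" / "geno_qc.csv")
    cio.write_phenotypes(pheno_qc, OUT / "qc" / "pheno_qc.csv")

    print(f"segregation distortion removed {len(report.markers_removed)} "
          f"of {geno.codes.shape[1]} markers at P <= 0.01 "
          f"(a Mendelian family, so ~1% by chance)")
    print(f"offspring removed: {report.offspring_removed or 'none'}")
    print(f"raw obligate crossovers per offspring: median "
          f"{raw_counts.median():.0f}, mean {raw_counts.mean():.1f}")
    print(f"phenotype outliers masked: "
          f"{ {t: len(v) for t, v in report.phenotype_outliers.items()} }")


if __name__ == "__main__":
    main()
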