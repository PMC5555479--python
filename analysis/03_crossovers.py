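#!/usr/bin/env python
"""Detect crossovers and correct putative genotyping errors.

Phase switches are detected per offspring per parental haplotype on the
markers informative in both parents (efxeg, hkxhk), then chained into
<= 50 cM clusters: even clusters (no net phase change — the genotyping-
error signature) are removed, odd clusters collapse to one retained
representative.  Writes results/crossovers.tsv with a status column.
"""

from pathlib import Path

from charrcross import crossovers as cxo
from charrcross import io as cio

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    gmap = cio.read_map(OUT / "data" / "map.csv")
    geno = cio.read_genotypes(OUT / "qc" / "geno_qc.csv", gmap)

    raw = cxo.detect_crossovers(geno, gmap, informative_both_only=True)
    corrected = cxo.apply_correction(raw, cxo.CorrectionParams(window=50.0))
    cio.write_crossover_table(corrected, OUT / "crossovers.tsv")

    kept = cxo.retained(corrected)
    removed = cxo.removed_totals(corrected, gmap)
    for parent in ("dam", "sire"):
        r = (raw["parent"] == parent).sum()
        k = (kept["parent"] == parent).sum()
        print(f"{parent}: raw {r}, retained {k}, removed "
              f"{removed[parent]['autosomes']} autosomal + "
              f"{removed[parent]['sex_lg']} on the sex LG")
    print(f"wrote {OUT / 'crossovers.tsv'}")


if __name__ == "__main__":
    main()
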