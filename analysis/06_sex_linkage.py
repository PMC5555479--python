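#!/usr/bin/env python
"""Identify the sex-linked linkage group.

Offspring sex is coded 0/1 and scanned like a quantitative trait.  The
sex LG shows elevated LOD across its whole length (male recombination is
suppressed outside the pseudoautosomal region) with a decline at the
distal pseudoautosomal end.  Writes results/sex_linkage_scan.tsv.
"""

from pathlib import Path

import numpy as np

from charrcross import io as cio
from charrcross import qtl as cqtl

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 11


def main() -> None:
    gmap = cio.read_map(OUT / "data" / "map.csv")
    geno = cio.read_genotypes(OUT / "qc" / "geno_qc.csv", gmap)
    pheno = cio.read_phenotypes(OUT / "qc" / "pheno_qc.csv")

    res = cqtl.sex_linkage_scan(pheno.sex, geno, gmap)
    thr, _, _ = cqtl.permutation_thresholds(
        (pheno.sex == "M").astype(float), geno, gmap, n_perm=1000,
        seed=np.random.default_rng(SEED))
    res.genome_threshold = thr
    cio.write_scan(res.table, OUT / "sex_linkage_scan.tsv")

    peak = res.peak()
    t = res.table.join(gmap.markers["seg_type"], on="marker")
    sex_lg = str(peak["lg"])
    sub = t[(t["lg"] == sex_lg) & t["seg_type"].isin(["efxeg", "hkxhk"])]
    L = gmap.lg_length(sex_lg)
    par = sub[sub["pos_cM"] > 0.8 * L]["lod"].median()
    body = sub[sub["pos_cM"] <= 0.8 * L]["lod"].median()
    print(f"peak on {sex_lg} (simulated sex LG: {gmap.sex_lg}) with LOD "
          f"{peak['lod']:.1f}; genome-wide threshold {thr:.2f}")
    print(f"sire-informative median LOD: {body:.1f} across the LG body "
          f"vs {par:.1f} in the distal 20% — the decline marks the "
          f"pseudoautosomal region")


if __name__ == "__main__":
    main()
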