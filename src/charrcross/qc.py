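"""Marker- and sample-level quality control preceding the analyses.

Filters, in the documented order: (1) chi-square segregation-distortion
test per marker at raw P <= 0.01 (no multiple-testing correction — the
map-building convention for outbred crosses); (2) duplicate-sample check
on pairwise genotype identity; (3) per-offspring obligate-crossover
outlier rule (median + m·MAD on raw counts, operationalizing the ad hoc
removal of grossly error-inflated samples); (4) single-pass 3-SD
phenotype outlier masking per trait.  Every filter is idempotent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneticMap, PhasedGenotypes, PhenotypeTable

# expected Mendelian class ratios per segregation type
EXPECTED = {
    "nnxnp": {"nn": 1, "np": 1},
    "lmxll": {"ll": 1, "lm": 1},
    "hkxhk": {"hh": 1, "hk": 2, "kk": 1},
    "efxeg": {"ee": 1, "ef": 1, "eg": 1, "fg": 1},
}


@dataclass
class SegregationTestResult:
    marker: str
    counts: dict
    expected_ratio: dict
    chi2: float
    df: int
    p_value: float
    removed: bool


@dataclass
class QCReport:
    markers_removed: list[str] = field(default_factory=list)
    offspring_removed: dict = field(default_factory=dict)  # id -> reason
    phenotype_outliers: dict = field(default_factory=dict)  # trait -> ids
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_markers_removed": len(self.markers_removed),
            "markers_removed": self.markers_removed,
            "offspring_removed": self.offspring_removed,
            "phenotype_outliers": self.phenotype_outliers,
            "details": self.details,
        }


def segregation_test(counts: dict, seg_type: str) -> tuple[float, int, float]:
    """Chi-square statistic, df and upper-tail p for observed class counts."""
    expected_ratio = EXPECTED[seg_type]
    classes = list(expected_ratio)
    obs = np.array([counts.get(c, 0) for c in classes], dtype=float)
    total = obs.sum()
    weights = np.array([expected_ratio[c] for c in classes], dtype=float)
    exp = total * weights / weights.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(classes) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def segregation_filter(genotypes: PhasedGenotypes, gmap: GeneticMap,
                       p_threshold: float = 0.01
                       ) -> list[SegregationTestResult]:
    """Test every marker for Mendelian segregation distortion.

    Observed classes are the legal codes for the marker type (the
    ambiguous hkxhk 'hk' het is its own 1:2:1 middle class).  Markers
    with p <= threshold are flagged removed; all-missing markers are
    skipped with a warning and never removed.
    """
    results = []
    seg_types = gmap.markers["seg_type"]
    for marker in genotypes.codes.columns:
        st = seg_types[marker]
        col = genotypes.codes[marker]
        col = col[col != "-"]
        if len(col) < 2:
            import warnings
            warnings.warn(f"marker {marker}: <2 calls, skipped")
            continue
        counts = col.value_counts().to_dict()
        chi2, df, p = segregation_test(counts, st)
        results.append(SegregationTestResult(
            marker=marker, counts=counts, expected_ratio=EXPECTED[st],
            chi2=chi2, df=df, p_value=p, removed=p <= p_threshold))
    return results


def phenotype_outlier_filter(values: pd.Series, k: float = 3.0):
    """Mask values more than k SD from the mean (single pass).

    Returns (masked series, list of removed ids).  Mean and SD are over
    the non-missing values; zero SD removes nothing.
    """
    y = pd.to_numeric(values, errors="coerce")
    ok = y.dropna()
    if len(ok) < 3:
        return y, []
    mu, sd = float(ok.mean()), float(ok.std(ddof=1))
    if sd == 0:
        return y, []
    bad = ok.index[(ok - mu).abs() > k * sd]
    out = y.copy()
    out[bad] = np.nan
    return out, list(bad)


def duplicate_sample_check(genotypes: PhasedGenotypes,
                           threshold: float = 0.9) -> pd.DataFrame:
    """Pairs of offspring whose non-missing calls agree >= threshold."""
    codes = genotypes.codes.to_numpy(dtype=object)
    ids = list(genotypes.codes.index)
    present = codes != "-"
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        both = present[i] & present[j]
        n = int(both.sum())
        if n == 0:
            continue
        prop = float((codes[i, both] == codes[j, both]).mean())
        if prop >= threshold:
            rows.append((ids[i], ids[j], prop, n))
    return pd.DataFrame(rows, columns=["offspring_a", "offspring_b",
                                       "identity", "n_compared"])


def crossover_outlier_filter(counts: pd.Series, m: float = 10.0,
                             exclude_ids=()) -> dict:
    """Flag offspring with grossly inflated raw obligate crossover counts.

    Flags counts above median + m·max(MAD, 1) (the MAD floor keeps a
    degenerate all-equal distribution from flagging everything), plus any
    explicitly excluded ids.  Reports mean/median of the retained counts.
    """
    med = float(counts.median())
    mad = float((counts - med).abs().median())
    cutoff = med + m * max(mad, 1.0)
    flagged = set(counts.index[counts > cutoff]) | (set(exclude_ids)
                                                    & set(counts.index))
    kept = counts[~counts.index.isin(flagged)]
    return {
        "removed": sorted(flagged),
        "cutoff": cutoff,
        "median_retained": float(kept.median()) if len(kept) else None,
        "mean_retained": float(kept.mean()) if len(kept) else None,
    }


def run_qc(genotypes: PhasedGenotypes, gmap: GeneticMap,
           phenotypes: PhenotypeTable | None,
           raw_counts: pd.Series,
           distortion_p: float = 0.01, sd_k: float = 3.0,
           dup_threshold: float = 0.9, xo_outlier_m: float = 10.0,
           max_missing: float | None = None,
           exclude_ids=()) -> tuple[QCReport, PhasedGenotypes,
                                    PhenotypeTable | None]:
    """Apply the full QC battery; returns (report, genotypes, phenotypes)."""
    report = QCReport()

    seg = segregation_filter(genotypes, gmap, distortion_p)
    report.markers_removed = [r.marker for r in seg if r.removed]
    genotypes = genotypes.subset_markers(
        [m for m in genotypes.codes.columns
         if m not in set(report.markers_removed)])

    dup = duplicate_sample_check(genotypes, dup_threshold)
    for _, row in dup.iterrows():
        report.offspring_removed[row["offspring_b"]] = "duplicate"
    report.details["duplicates"] = dup.to_dict(orient="records")

    if max_missing is not None:
        mf = genotypes.missing_fraction()
        for off in mf.index[mf > max_missing]:
            report.offspring_removed.setdefault(off, "missingness")

    xo = crossover_outlier_filter(raw_counts, xo_outlier_m, exclude_ids)
    for off in xo["removed"]:
        report.offspring_removed.setdefault(off, "crossover_outlier")
    report.details["crossover_outliers"] = xo

    drop = list(report.offspring_removed)
    genotypes = genotypes.drop_offspring(drop)
    if phenotypes is not None:
        phenotypes = phenotypes.drop_offspring(drop)
        data = phenotypes.data.copy()
        for trait in phenotypes.traits:
            masked, bad = phenotype_outlier_filter(data[trait], sd_k)
            data[trait] = masked
            if bad:
                report.phenotype_outliers[trait] = [str(b) for b in bad]
        phenotypes = PhenotypeTable(data, dict(phenotypes.transforms))
    return report, genotypes, phenotypes
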