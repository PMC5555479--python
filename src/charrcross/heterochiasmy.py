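"""Sex-stratified recombination summaries from corrected crossover events.

Computes dam/sire crossover totals and female:male ratios overall and per
stratum (fused metacentric vs acrocentric chromosome class; residually
tetraploid vs rediploidized status), positional distributions on a
percent-of-chromosome axis, the fraction of events in the external 20% of
each chromosome, and centromere-end inference for acrocentric linkage
groups from the male crossover distribution (salmonid male crossovers
cluster at the telomere opposite the centromere).

The sex-linked linkage group is excluded from all autosomal totals and
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossovers import (CorrectionParams, PARENTS, apply_correction,
                         removed_totals, retained)
from .io import GeneticMap

EXTERNAL_PCT = 20.0  # closed intervals [0, 20] and [80, 100]


def female_male_ratio(dam_total: float, sire_total: float):
    """(raw quotient, one-decimal rounding) or (None, None) if undefined."""
    if not sire_total:
        return None, None
    r = dam_total / sire_total
    return r, round(r, 1)


def _stratum(events: pd.DataFrame, lgs) -> dict:
    sub = events[events["lg"].isin(set(lgs))]
    dam = int((sub["parent"] == "dam").sum())
    sire = int((sub["parent"] == "sire").sum())
    raw, rounded = female_male_ratio(dam, sire)
    n_lg = len(lgs)
    return {
        "dam": dam,
        "sire": sire,
        "ratio": raw,
        "ratio_1dp": rounded,
        "n_lg": n_lg,
        "dam_mean_per_chr": dam / n_lg if n_lg else None,
        "sire_mean_per_chr": sire / n_lg if n_lg else None,
    }


@dataclass
class CrossoverSummary:
    overall: dict
    per_class: dict
    per_tetraploid: dict
    per_lg: pd.DataFrame
    sex_lg: dict
    removed: dict

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "per_class": self.per_class,
            "per_tetraploid": self.per_tetraploid,
            "per_lg": self.per_lg.reset_index().to_dict(orient="list"),
            "sex_lg": self.sex_lg,
            "removed": self.removed,
        }


def summarize(events: pd.DataFrame, gmap: GeneticMap,
              include_sex_linked_in_class: bool = False) -> CrossoverSummary:
    """Totals, stratified ratios and per-chromosome means.

    ``events`` is a corrected event table; only non-removed events enter
    any count.  Autosomal strata exclude the sex-linked LG unless
    ``include_sex_linked_in_class`` is set.
    """
    kept = retained(events)
    sex_lg = gmap.sex_lg
    groups = gmap.groups
    autosomes = [lg for lg in groups.index if lg != sex_lg]

    overall = _stratum(kept, autosomes)
    per_class = {}
    for cls in ("fused_metacentric", "acrocentric"):
        lgs = [lg for lg in groups.index[groups["lg_class"] == cls]
               if include_sex_linked_in_class or lg != sex_lg]
        per_class[cls] = _stratum(kept, lgs)
    per_tetraploid = {}
    for name, flag in (("tetraploid", True), ("rediploidized", False)):
        lgs = [lg for lg in groups.index[groups["tetraploid"] == flag]
               if lg != sex_lg]
        per_tetraploid[name] = _stratum(kept, lgs)

    per_lg = (
        kept.groupby(["lg", "parent"]).size().unstack(fill_value=0)
        .reindex(index=groups.index, columns=list(PARENTS), fill_value=0)
    )
    per_lg.columns.name = None

    sex_counts = {"lg": sex_lg, "dam": 0, "sire": 0}
    if sex_lg is not None:
        on_sex = kept[kept["lg"] == sex_lg]
        sex_counts["dam"] = int((on_sex["parent"] == "dam").sum())
        sex_counts["sire"] = int((on_sex["parent"] == "sire").sum())

    return CrossoverSummary(
        overall=overall,
        per_class=per_class,
        per_tetraploid=per_tetraploid,
        per_lg=per_lg,
        sex_lg=sex_counts,
        removed=removed_totals(events, gmap),
    )


@dataclass
class PositionalDistribution:
    bin_edges: np.ndarray
    counts: pd.DataFrame  # index (parent, lg_class), columns bin left edges
    cumulative: pd.DataFrame
    external20: dict = field(default_factory=dict)


def external20_fraction(percent_pos: np.ndarray) -> float:
    p = np.asarray(percent_pos, float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        return float("nan")
    return float(((p <= EXTERNAL_PCT) | (p >= 100.0 - EXTERNAL_PCT)).mean())


def positional_distribution(events: pd.DataFrame, gmap: GeneticMap,
                            bin_width: float = 5.0,
                            include_sex_linked: bool = False
                            ) -> PositionalDistribution:
    """Histogram + cumulative curve of percent positions per parent × class."""
    kept = retained(events).copy()
    single = [lg for lg in gmap.lgs if len(gmap.lg_markers(lg)) < 2
              or gmap.lg_length(lg) <= 0]
    if single:
        import warnings
        warnings.warn(f"excluding zero-length lgs {single}")
        kept = kept[~kept["lg"].isin(set(single))]
    if not include_sex_linked and gmap.sex_lg is not None:
        kept = kept[kept["lg"] != gmap.sex_lg]
    kept = kept.join(gmap.groups["lg_class"], on="lg")

    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    rows, index = [], []
    for (parent, cls), sub in kept.groupby(["parent", "lg_class"]):
        h, _ = np.histogram(sub["percent_pos"].clip(0, 100 - 1e-9), bins=edges)
        rows.append(h)
        index.append((parent, cls))
    counts = pd.DataFrame(rows,
                          index=pd.MultiIndex.from_tuples(
                              index, names=["parent", "lg_class"]) if index
                          else pd.MultiIndex.from_arrays(
                              [[], []], names=["parent", "lg_class"]),
                          columns=edges[:-1])
    ext = {parent: external20_fraction(
        kept.loc[kept["parent"] == parent, "percent_pos"].to_numpy())
        for parent in PARENTS}
    return PositionalDistribution(
        bin_edges=edges, counts=counts, cumulative=counts.cumsum(axis=1),
        external20=ext,
    )


def infer_centromere_end(events: pd.DataFrame, gmap: GeneticMap, lg: str,
                         min_events: int = 5,
                         threshold: float = 0.8) -> dict:
    """Place the centromere of an acrocentric LG opposite the male
    crossover cluster.

    If at least ``threshold`` of the (>= min_events) retained sire events
    fall in one terminal 20%, the centromere is assigned to the opposite
    end; otherwise 'undetermined'.  Confidence is the fraction of events
    in the modal terminal 20%.
    """
    kept = retained(events)
    male = kept[(kept["lg"] == lg) & (kept["parent"] == "sire")]
    p = male["percent_pos"].to_numpy(float)
    n = p.size
    result = {"lg": lg, "n_events": int(n), "call": "undetermined",
              "confidence": float("nan")}
    if n < min_events:
        return result
    lo = float((p <= EXTERNAL_PCT).mean())
    hi = float((p >= 100.0 - EXTERNAL_PCT).mean())
    modal = max(lo, hi)
    result["confidence"] = modal
    if modal >= threshold:
        result["call"] = "end" if lo >= hi else "start"
    return result


def infer_all_centromeres(events: pd.DataFrame, gmap: GeneticMap,
                          min_events: int = 5, threshold: float = 0.8,
                          skip_tetraploid: bool = True) -> pd.DataFrame:
    """Centromere-end calls for every acrocentric LG.

    Residually tetraploid LGs are reported undetermined by default: their
    male-informative markers are censored in exactly the distal region
    the rule relies on, so the few remaining male events are proximal
    residue that points at the wrong end.
    """
    rows = []
    for lg in gmap.groups.index[gmap.groups["lg_class"] == "acrocentric"]:
        if skip_tetraploid and bool(gmap.groups.loc[lg, "tetraploid"]):
            rows.append({"lg": lg, "n_events": 0, "call": "undetermined",
                         "confidence": float("nan")})
            continue
        rows.append(infer_centromere_end(events, gmap, lg, min_events,
                                         threshold))
    return pd.DataFrame(rows)


def sensitivity(raw_events: pd.DataFrame, gmap: GeneticMap,
                windows=(50.0, 25.0, 10.0),
                chaining: str = "gap",
                odd_cluster: str = "collapse_to_one") -> pd.DataFrame:
    """Corrected female:male ratio and external-20% shares per window W."""
    rows = []
    for w in windows:
        corrected = apply_correction(
            raw_events, CorrectionParams(window=w, chaining=chaining,
                                         odd_cluster=odd_cluster))
        summ = summarize(corrected, gmap)
        dist = positional_distribution(corrected, gmap)
        rows.append({
            "window_cM": w,
            "dam": summ.overall["dam"],
            "sire": summ.overall["sire"],
            "ratio": summ.overall["ratio"],
            "ratio_1dp": summ.overall["ratio_1dp"],
            "external20_dam": dist.external20["dam"],
            "external20_sire": dist.external20["sire"],
        })
    return pd.DataFrame(rows)
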