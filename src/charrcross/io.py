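"""Readers/writers for the pipeline's tables.

Dialects (plain CSV/TSV, fixed headers):

* ``map.csv``   — marker,lg,pos_cM,seg_type,lg_class,tetraploid,sex_linked,centromere_end
* ``geno.csv``  — offspring id column, then one column per marker.  Codes may
  be observed allele pairs for the marker's segregation type (``nn``/``np``,
  ``ee``/``ef``/``eg``/``fg``, ``hh``/``hk``/``kk``) or already-phased codes
  ``ac``/``ad``/``bc``/``bd`` (dam haplotypes a/b, sire c/d).  ``-`` and the
  empty string are missing.
* ``pheno.csv`` — offspring,sex,<trait columns>.
* results       — crossovers.tsv, heterochiasmy.json, scan.tsv, qtl_table.tsv.

The four-way-cross algebra lives here: each observed code is resolved to a
(dam haplotype, sire haplotype) pair, with the hkxhk double heterozygote
``hk`` mapping to ambiguous (neither parental contribution is resolvable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEG_TYPES = ("nnxnp", "lmxll", "efxeg", "hkxhk")
LG_CLASSES = ("fused_metacentric", "acrocentric")
MISSING = ("-", "")

UNKNOWN = np.int8(-1)

# observed code -> (dam label, sire label); 0 = a/c, 1 = b/d, -1 = unknown.
# nnxnp is dam-informative in this family (the sire is homozygous), so the
# sire label is always unknown there; lmxll is accepted as an alias.
_RESOLUTION: dict[str, dict[str, tuple[int, int]]] = {
    "nnxnp": {"nn": (0, -1), "np": (1, -1)},
    "lmxll": {"ll": (0, -1), "lm": (1, -1)},
    "efxeg": {"ee": (0, 0), "eg": (0, 1), "ef": (1, 0), "fg": (1, 1)},
    "hkxhk": {"hh": (0, 0), "kk": (1, 1), "hk": (-1, -1)},
}
_PHASED = {"ac": (0, 0), "ad": (0, 1), "bc": (1, 0), "bd": (1, 1)}

BOTH_INFORMATIVE = ("efxeg", "hkxhk")


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered markers on linkage groups with per-LG annotations.

    markers: DataFrame indexed by marker id with columns lg, pos_cM,
    seg_type (file order preserved; positions non-decreasing within LG).
    groups: DataFrame indexed by lg with columns lg_class, tetraploid,
    sex_linked, centromere_end.
    """

    markers: pd.DataFrame
    groups: pd.DataFrame

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GeneticMap":
        required = ["marker", "lg", "pos_cM", "seg_type", "lg_class",
                    "tetraploid", "sex_linked", "centromere_end"]
        missing = set(required) - set(table.columns)
        if missing:
            raise ValidationError(f"map table missing columns {sorted(missing)}")
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise ValidationError(f"duplicate marker id {dup!r}")
        bad = ~table["seg_type"].isin(SEG_TYPES)
        if bad.any():
            raise ValidationError(
                f"unknown seg_type {table.loc[bad, 'seg_type'].iloc[0]!r}")
        for lg, sub in table.groupby("lg", sort=False):
            pos = sub["pos_cM"].to_numpy(float)
            if (np.diff(pos) < 0).any():
                raise ValidationError(f"positions decrease within lg {lg}")
            if (pos < 0).any():
                raise ValidationError(f"negative position in lg {lg}")
        markers = table.set_index("marker")[["lg", "pos_cM", "seg_type"]].copy()
        markers["pos_cM"] = markers["pos_cM"].astype(float)
        groups = (
            table.drop_duplicates("lg")
            .set_index("lg")[["lg_class", "tetraploid", "sex_linked",
                              "centromere_end"]]
            .copy()
        )
        groups["tetraploid"] = groups["tetraploid"].astype(bool)
        groups["sex_linked"] = groups["sex_linked"].astype(bool)
        return cls(markers=markers, groups=groups)

    @property
    def lgs(self) -> list[str]:
        return list(self.groups.index)

    @property
    def sex_lg(self) -> str | None:
        hits = self.groups.index[self.groups["sex_linked"]]
        return hits[0] if len(hits) else None

    def lg_length(self, lg: str) -> float:
        return float(self.markers.loc[self.markers["lg"] == lg, "pos_cM"].max())

    def lg_markers(self, lg: str) -> pd.DataFrame:
        return self.markers[self.markers["lg"] == lg]

    def subset(self, marker_ids) -> "GeneticMap":
        keep = self.markers.index.isin(set(marker_ids))
        markers = self.markers[keep]
        groups = self.groups.loc[markers["lg"].unique()]
        return GeneticMap(markers=markers, groups=groups)

    def to_table(self) -> pd.DataFrame:
        t = self.markers.reset_index()
        return t.join(self.groups, on="lg").loc[
            :, ["marker", "lg", "pos_cM", "seg_type", "lg_class",
                "tetraploid", "sex_linked", "centromere_end"]]


def read_map(path) -> GeneticMap:
    return GeneticMap.from_table(pd.read_csv(path, dtype={"marker": str,
                                                          "lg": str}))


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_table().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phased genotypes
# ---------------------------------------------------------------------------

@dataclass
class PhasedGenotypes:
    """Offspring × marker observed codes plus their parental resolution.

    ``dam``/``sire`` are int8 matrices aligned with ``codes``: 0 for the
    first parental haplotype (a or c), 1 for the second (b or d), -1 where
    the contribution is unknown (missing call, or ambiguous hkxhk ``hk``).
    """

    codes: pd.DataFrame
    dam: pd.DataFrame
    sire: pd.DataFrame

    @classmethod
    def from_codes(cls, codes: pd.DataFrame, gmap: GeneticMap,
                   validate: bool = True) -> "PhasedGenotypes":
        unknown_markers = [m for m in codes.columns
                           if m not in gmap.markers.index]
        if unknown_markers:
            raise ValidationError(
                f"genotype marker {unknown_markers[0]!r} not in map")
        codes = codes[[m for m in gmap.markers.index if m in codes.columns]]
        seg = gmap.markers.loc[codes.columns, "seg_type"]

        dam = np.full(codes.shape, UNKNOWN, dtype=np.int8)
        sire = np.full(codes.shape, UNKNOWN, dtype=np.int8)
        vals = codes.to_numpy(dtype=object)
        for j, (marker, st) in enumerate(zip(codes.columns, seg)):
            table = {**_RESOLUTION[st], **_PHASED}
            col = vals[:, j]
            for i, code in enumerate(col):
                code = "" if code is None or (isinstance(code, float)
                                              and np.isnan(code)) else str(code)
                if code in MISSING:
                    vals[i, j] = "-"
                    continue
                if code not in table:
                    if validate:
                        raise ValidationError(
                            f"illegal code {code!r} for {st} marker "
                            f"{marker!r} in offspring {codes.index[i]!r}")
                    vals[i, j] = "-"
                    continue
                dam[i, j], sire[i, j] = table[code]
        codes = pd.DataFrame(vals, index=codes.index, columns=codes.columns)
        return cls(
            codes=codes,
            dam=pd.DataFrame(dam, index=codes.index, columns=codes.columns),
            sire=pd.DataFrame(sire, index=codes.index, columns=codes.columns),
        )

    @property
    def offspring(self) -> list[str]:
        return list(self.codes.index)

    def missing_fraction(self) -> pd.Series:
        return (self.codes == "-").mean(axis=1)

    def subset_markers(self, marker_ids) -> "PhasedGenotypes":
        cols = [m for m in self.codes.columns if m in set(marker_ids)]
        return PhasedGenotypes(self.codes[cols], self.dam[cols],
                               self.sire[cols])

    def drop_offspring(self, ids) -> "PhasedGenotypes":
        keep = ~self.codes.index.isin(set(ids))
        return PhasedGenotypes(self.codes[keep], self.dam[keep],
                               self.sire[keep])


def read_genotypes(path, gmap: GeneticMap) -> PhasedGenotypes:
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    return PhasedGenotypes.from_codes(raw, gmap)


def write_genotypes(genotypes: PhasedGenotypes, path) -> None:
    out = genotypes.codes.copy()
    out.index.name = "offspring"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Offspring phenotypes with a mandatory sex column (F/M).

    ``transforms`` maps trait -> {"none", "log"}; unlisted traits are
    untransformed.
    """

    data: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if "sex" not in self.data.columns:
            raise ValidationError("phenotype table needs a 'sex' column")
        bad = ~self.data["sex"].isin(["F", "M"])
        if bad.any():
            raise ValidationError(
                f"sex must be F or M (offspring {self.data.index[bad][0]!r})")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c != "sex"]

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    def trait_values(self, trait: str) -> pd.Series:
        y = pd.to_numeric(self.data[trait], errors="coerce")
        if self.transforms.get(trait) == "log":
            y = np.log(y.where(y > 0))
        return y

    def drop_offspring(self, ids) -> "PhenotypeTable":
        keep = ~self.data.index.isin(set(ids))
        return PhenotypeTable(self.data[keep], dict(self.transforms))


def read_phenotypes(path, transforms: dict[str, str] | None = None
                    ) -> PhenotypeTable:
    data = pd.read_csv(path, index_col=0)
    return PhenotypeTable(data, transforms or {})


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    out = pheno.data.copy()
    out.index.name = "offspring"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# result artifacts
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["offspring", "parent", "lg", "left_marker", "left_pos",
                 "right_marker", "right_pos", "midpoint", "percent_pos",
                 "cluster", "status"]


def write_crossover_table(events: pd.DataFrame, path) -> None:
    out = events.reindex(columns=EVENT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_crossover_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"offspring": str, "lg": str})
    return df.reindex(columns=EVENT_COLUMNS)


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=1, sort_keys=True,
                                     default=_jsonify))


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"cannot serialize {type(x)}")


def write_scan(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker": str, "lg": str})
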