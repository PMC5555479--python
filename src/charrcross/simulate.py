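"""Synthetic four-way outbred cross simulator.

Generates a salmonid-style mapping family — two heterozygous parents, ~170
offspring, 42 linkage groups — with known ground truth: every meiotic
crossover, every injected genotyping error, every planted QTL.  The dam
contributes haplotype a or b at each locus, the sire c or d; offspring
genotypes are observed through the usual outbred-cross marker types
(nnxnp dam-informative, efxeg fully informative, hkxhk semi-informative
with an ambiguous double-heterozygote class).

Residual tetraploidy — homeologous chromosome arms that still pair after
the salmonid whole-genome duplication and therefore lose male-informative
markers during diploid genotype filtering — is emulated by demoting
markers in a terminal fraction of flagged linkage groups to the
dam-informative type.  One acrocentric linkage group is sex-linked:
offspring sex follows the sire haplotype at a sex locus at the centromeric
end, and male recombination on that group is confined to a distal
pseudoautosomal segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import GeneticMap, PhasedGenotypes, PhenotypeTable

FUSED = "fused_metacentric"
ACRO = "acrocentric"

OBSERVED_CODES = {
    "nnxnp": ["nn", "np"],
    "lmxll": ["ll", "lm"],
    "efxeg": ["ee", "ef", "eg", "fg"],
    "hkxhk": ["hh", "hk", "kk"],
}

DENSITIES_FEMALE = ("uniform", "center_biased")
DENSITIES_MALE = ("uniform", "telomere_biased")


@dataclass
class LGSpec:
    """One linkage group of the simulated karyotype.

    Lengths are sex-specific genetic lengths in cM; the marker map axis is
    the female axis (published salmonid maps are female-anchored because
    male markers place poorly).
    """

    lg: str
    lg_class: str  # fused_metacentric | acrocentric
    female_len: float
    male_len: float
    tetraploid: bool = False
    sex_linked: bool = False
    centromere_end: str = "start"  # start | end


@dataclass
class QTLEffect:
    marker: str
    effect: float  # additive effect per haplotype substitution
    trait: str


@dataclass
class SimConfig:
    n_offspring: int
    lg_spec: list[LGSpec]
    n_markers_per_lg: int = 91
    marker_type_mix: dict[str, float] = field(
        default_factory=lambda: {"nnxnp": 0.35, "efxeg": 0.35, "hkxhk": 0.30}
    )
    female_density: str = "center_biased"
    male_density: str = "telomere_biased"
    error_rate: float = 0.005
    missing_rate: float = 0.03
    tetraploid_depletion: float = 0.30  # terminal fraction losing male info
    par_fraction: float = 0.20  # pseudoautosomal fraction of the sex lg
    interference: str = "gamma"  # gamma (renewal, salmonid-like) | none
    interference_nu: int = 8  # gamma shape; larger = stronger interference
    qtl_effects: list[QTLEffect] = field(default_factory=list)
    sex_effect: dict[str, float] = field(default_factory=dict)
    interaction_effect: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)
    traits: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_offspring < 2:
            raise ValueError("n_offspring must be >= 2")
        for rate in (self.error_rate, self.missing_rate,
                     self.tetraploid_depletion, self.par_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if abs(sum(self.marker_type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("marker_type_mix must sum to 1")
        for t in self.marker_type_mix:
            if t not in OBSERVED_CODES:
                raise ValueError(f"unknown marker type {t!r}")
        if self.female_density not in DENSITIES_FEMALE:
            raise ValueError(f"unknown female density {self.female_density!r}")
        if self.male_density not in DENSITIES_MALE:
            raise ValueError(f"unknown male density {self.male_density!r}")
        if self.interference not in ("gamma", "none"):
            raise ValueError(f"unknown interference model {self.interference!r}")
        if self.interference_nu < 1:
            raise ValueError("interference_nu must be >= 1")
        n_sex = sum(s.sex_linked for s in self.lg_spec)
        if n_sex != 1:
            raise ValueError(f"exactly one lg must be sex_linked (got {n_sex})")
        for s in self.lg_spec:
            if s.female_len <= 0 or s.male_len <= 0:
                raise ValueError(f"{s.lg}: lengths must be > 0")
            if s.lg_class not in (FUSED, ACRO):
                raise ValueError(f"{s.lg}: unknown class {s.lg_class!r}")
            if s.centromere_end not in ("start", "end"):
                raise ValueError(f"{s.lg}: centromere_end must be start|end")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["lg_spec"] = [LGSpec(**s) for s in d["lg_spec"]]
        d["qtl_effects"] = [QTLEffect(**q) for q in d.get("qtl_effects", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Oracle record of everything the simulator did.

    crossovers: one row per true crossover (offspring, parent, lg,
    pos_cM on the map axis).  error_sites: genotype calls corrupted by the
    error model.  true_ratio: realized dam/sire crossover total ratio.
    """

    crossovers: pd.DataFrame
    error_sites: pd.DataFrame
    qtl: list[QTLEffect]
    config: SimConfig

    @property
    def true_ratio(self) -> float:
        n_dam = int((self.crossovers["parent"] == "dam").sum())
        n_sire = int((self.crossovers["parent"] == "sire").sum())
        return n_dam / n_sire if n_sire else float("nan")

    def to_json(self, path) -> None:
        payload = {
            "crossovers": self.crossovers.to_dict(orient="list"),
            "error_sites": self.error_sites.to_dict(orient="list"),
            "qtl": [asdict(q) for q in self.qtl],
            "true_ratio": self.true_ratio,
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_positions(rng: np.random.Generator, n: int, length: float,
                    density: str, centromere_end: str) -> np.ndarray:
    """Draw n crossover positions on (0, length) from a named density.

    telomere_biased puts 95% of its mass in the 20% of the axis farthest
    from the centromere end (salmonid male crossovers are close to fully
    terminal); center_biased is Beta(2, 2) scaled to the
    axis (the field reports only "biased toward the center", so a mild
    symmetric hump is used).
    """
    if n == 0:
        return np.empty(0)
    if density == "uniform":
        pos = rng.uniform(0.0, length, n)
    elif density == "center_biased":
        pos = length * rng.beta(2.0, 2.0, n)
    elif density == "telomere_biased":
        distal = rng.random(n) < 0.95
        pos = np.empty(n)
        if centromere_end == "start":
            pos[distal] = rng.uniform(0.8 * length, length, int(distal.sum()))
            pos[~distal] = rng.uniform(0.0, 0.8 * length, int((~distal).sum()))
        else:
            pos[distal] = rng.uniform(0.0, 0.2 * length, int(distal.sum()))
            pos[~distal] = rng.uniform(0.2 * length, length, int((~distal).sum()))
    else:
        raise ValueError(f"unknown density {density!r}")
    # keep positions strictly interior
    eps = 1e-9 * length
    return np.sort(np.clip(pos, eps, length - eps))


def simulate_gamete(length: float, density: str,
                    rng: np.random.Generator,
                    centromere_end: str = "start") -> np.ndarray:
    """Simulate crossover positions for one gamete on a chromosome.

    The crossover count is Poisson with mean length/100 (1 cM = 1%
    recombination, no interference); positions are i.i.d. from the named
    density, sorted ascending and strictly inside (0, length).
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    n = int(rng.poisson(length / 100.0))
    return _draw_positions(rng, n, length, density, centromere_end)


def _quantile_map(p: np.ndarray, density: str, centromere_end: str
                  ) -> np.ndarray:
    """Quantile function of a positional density on the unit axis."""
    if density in ("uniform", "par"):
        return p
    if density == "center_biased":
        from scipy.stats import beta as beta_dist
        return beta_dist.ppf(p, 2.0, 2.0)
    if density == "telomere_biased":
        # 95% of mass on the distal 20% (away from the centromere end)
        if centromere_end == "start":
            return np.where(p < 0.05, 0.8 * p / 0.05,
                            0.8 + 0.2 * (p - 0.05) / 0.95)
        return np.where(p < 0.95, 0.2 * p / 0.95,
                        0.2 + 0.8 * (p - 0.95) / 0.05)
    raise ValueError(f"unknown density {density!r}")


def simulate_gamete_interference(length: float, density: str,
                                 rng: np.random.Generator,
                                 centromere_end: str = "start",
                                 nu: int = 8) -> np.ndarray:
    """Gamete crossovers under a stationary gamma-renewal process.

    Inter-crossover distances on a uniform-intensity axis are
    Gamma(nu, 100/nu) cM (mean 100 cM, so E[count] = length/100 exactly
    under the stationary start), giving strong positive interference for
    nu >> 1 — close true double crossovers become rare, as in real
    meioses.  The first event is drawn from the equilibrium forward
    recurrence distribution (for integer nu, an equal mixture of
    Erlang(1..nu)).  Positional bias is imposed by warping the uniform
    axis through the density's quantile function, preserving both the
    count distribution and the marginal positional density.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    scale = 100.0 / nu
    pos = []
    x = float(rng.gamma(int(rng.integers(1, nu + 1)), scale))
    while x < length:
        pos.append(x)
        x += float(rng.gamma(nu, scale))
    if not pos:
        return np.empty(0)
    u = np.asarray(pos) / length
    out = length * _quantile_map(u, density, centromere_end)
    eps = 1e-9 * length
    return np.sort(np.clip(out, eps, length - eps))


def _gamete(length: float, density: str, rng: np.random.Generator,
            centromere_end: str, interference: str, nu: int) -> np.ndarray:
    if interference == "gamma":
        return simulate_gamete_interference(length, density, rng,
                                            centromere_end, nu)
    return simulate_gamete(length, density, rng, centromere_end)


def _labels_at(markers: np.ndarray, xo: np.ndarray, start: int) -> np.ndarray:
    """Haplotype label (0/1) at each marker given crossover positions."""
    return (start + np.searchsorted(xo, markers, side="left")) % 2


_CODE_TABLE = {
    # (seg_type) -> array indexed by 2*dam + sire -> observed code
    "nnxnp": None,  # handled specially (dam only)
    "efxeg": np.array(["ee", "eg", "ef", "fg"]),
    "hkxhk": np.array(["hh", "hk", "hk", "kk"]),
}


def simulate_cross(config: SimConfig):
    """Run one full cross.

    Returns (GeneticMap, PhasedGenotypes, PhenotypeTable, GroundTruth).
    Same seed gives bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_off = config.n_offspring
    offspring = [f"off_{i:03d}" for i in range(n_off)]

    types = list(config.marker_type_mix)
    type_p = np.array([config.marker_type_mix[t] for t in types])

    map_rows = []
    geno_cols: dict[str, np.ndarray] = {}
    xo_records = {"offspring": [], "parent": [], "lg": [], "pos_cM": []}
    dam_true: dict[str, np.ndarray] = {}
    sire_true: dict[str, np.ndarray] = {}
    sex_of_offspring: np.ndarray | None = None

    for spec in config.lg_spec:
        n_mark = config.n_markers_per_lg
        marker_pos = np.linspace(0.0, spec.female_len, n_mark)
        marker_ids = [f"{spec.lg}_m{j:03d}" for j in range(n_mark)]
        seg = rng.choice(types, size=n_mark, p=type_p)

        if spec.tetraploid and config.tetraploid_depletion > 0:
            # homeolog region: male-informative markers were filtered out,
            # so only dam-informative ones remain there
            frac = config.tetraploid_depletion
            if spec.centromere_end == "start":
                depleted = marker_pos >= (1 - frac) * spec.female_len
            else:
                depleted = marker_pos <= frac * spec.female_len
            seg = np.where(depleted, "nnxnp", seg)

        # --- meiosis ---------------------------------------------------
        dam_lab = np.empty((n_off, n_mark), dtype=np.int8)
        sire_lab = np.empty((n_off, n_mark), dtype=np.int8)
        scale = spec.female_len / spec.male_len
        for i in range(n_off):
            xo_d = _gamete(spec.female_len, config.female_density, rng,
                           spec.centromere_end, config.interference,
                           config.interference_nu)
            dam_lab[i] = _labels_at(marker_pos, xo_d, int(rng.integers(2)))

            if spec.sex_linked:
                # male crossovers only in the pseudoautosomal segment:
                # the count comes from the full male length, the positions
                # are squeezed into the PAR
                xo_s = _gamete(spec.male_len, "uniform", rng,
                               spec.centromere_end, config.interference,
                               config.interference_nu)
                par = config.par_fraction
                if spec.centromere_end == "start":
                    xo_s = (1 - par) * spec.male_len + par * xo_s
                else:
                    xo_s = par * xo_s
            else:
                xo_s = _gamete(spec.male_len, config.male_density, rng,
                               spec.centromere_end, config.interference,
                               config.interference_nu)
            xo_s_map = xo_s * scale
            sire_lab[i] = _labels_at(marker_pos, xo_s_map,
                                     int(rng.integers(2)))

            for parent, xo in (("dam", xo_d), ("sire", xo_s_map)):
                for p in xo:
                    xo_records["offspring"].append(offspring[i])
                    xo_records["parent"].append(parent)
                    xo_records["lg"].append(spec.lg)
                    xo_records["pos_cM"].append(float(p))

        if spec.sex_linked:
            # sex locus sits at the centromeric (non-PAR) end; offspring
            # carrying sire haplotype d are male (XY-like)
            locus = 0.0 if spec.centromere_end == "start" else spec.female_len
            j = int(np.argmin(np.abs(marker_pos - locus)))
            sex_of_offspring = sire_lab[:, j].copy()

        dam_true[spec.lg] = dam_lab
        sire_true[spec.lg] = sire_lab

        # --- observation ----------------------------------------------
        for j, (mid, st) in enumerate(zip(marker_ids, seg)):
            d, s = dam_lab[:, j], sire_lab[:, j]
            if st == "nnxnp":
                codes = np.where(d == 0, "nn", "np")
            else:
                codes = _CODE_TABLE[st][2 * d + s]
            geno_cols[mid] = codes
            map_rows.append(
                (mid, spec.lg, float(marker_pos[j]), st, spec.lg_class,
                 spec.tetraploid, spec.sex_linked, spec.centromere_end)
            )

    map_df = pd.DataFrame(
        map_rows,
        columns=["marker", "lg", "pos_cM", "seg_type", "lg_class",
                 "tetraploid", "sex_linked", "centromere_end"],
    )
    gmap = GeneticMap.from_table(map_df)

    codes = pd.DataFrame(geno_cols, index=offspring)
    codes = codes[gmap.markers.index]  # deterministic column order

    # --- genotyping errors and missingness -----------------------------
    err_mask = rng.random(codes.shape) < config.error_rate
    miss_mask = rng.random(codes.shape) < config.missing_rate
    err_rows, err_cols = np.nonzero(err_mask)
    seg_types = gmap.markers["seg_type"].to_numpy()
    vals = codes.to_numpy(dtype=object)
    for r, c in zip(err_rows, err_cols):
        legal = OBSERVED_CODES[seg_types[c]]
        others = [x for x in legal if x != vals[r, c]]
        vals[r, c] = others[int(rng.integers(len(others)))]
    vals[miss_mask] = "-"
    codes = pd.DataFrame(vals, index=codes.index, columns=codes.columns)

    error_sites = pd.DataFrame(
        {
            "offspring": [offspring[r] for r in err_rows],
            "marker": [codes.columns[c] for c in err_cols],
        }
    )

    genotypes = PhasedGenotypes.from_codes(codes, gmap)

    # --- phenotypes -----------------------------------------------------
    is_male = sex_of_offspring.astype(bool)
    sex = np.where(is_male, "M", "F")
    pheno = pd.DataFrame({"sex": sex}, index=offspring)
    marker_index = {m: k for k, m in enumerate(gmap.markers.index)}
    for trait in config.traits:
        sd = config.residual_sd.get(trait, 1.0)
        y = rng.normal(0.0, sd, n_off)
        y += config.sex_effect.get(trait, 0.0) * is_male
        for q in config.qtl_effects:
            if q.trait != trait:
                continue
            lg = gmap.markers.loc[q.marker, "lg"]
            k = marker_index[q.marker]
            k0 = marker_index[f"{lg}_m000"]
            dose = (dam_true[lg][:, k - k0] + sire_true[lg][:, k - k0])
            y += q.effect * dose
            y += config.interaction_effect.get(trait, 0.0) * dose * is_male
        pheno[trait] = y
    phenotypes = PhenotypeTable(pheno)

    truth = GroundTruth(
        crossovers=pd.DataFrame(xo_records),
        error_sites=error_sites,
        qtl=list(config.qtl_effects),
        config=config,
    )
    return gmap, genotypes, phenotypes, truth


def brook_charr_karyotype(female_male_ratio: float = 1.85,
                          n_fused: int = 8, n_acro: int = 34,
                          n_tetraploid: int = 16) -> list[LGSpec]:
    """The study karyotype: 42 LGs, 8 fused metacentric + 34 acrocentric.

    Female lengths come from the observed female crossovers per chromosome
    (fused 88 cM, acrocentric 42 cM); male lengths are female/ratio.  The
    default ratio 1.85 is the rediploidized-set estimate, i.e. the
    female:male map-length ratio once homeolog-censored regions are set
    aside.  16 chromosomes (4 fused + 12 acrocentric) are flagged
    residually tetraploid; the last acrocentric is sex-linked with a male
    length sized to the elevated crossover count seen on the Y.
    """
    spec = []
    f_len, a_len = 88.0, 42.0
    n_tet_fused = min(4, n_tetraploid)
    n_tet_acro = n_tetraploid - n_tet_fused
    for i in range(n_fused):
        spec.append(LGSpec(
            lg=f"LG{i + 1:02d}", lg_class=FUSED,
            female_len=f_len, male_len=f_len / female_male_ratio,
            tetraploid=i < n_tet_fused,
            centromere_end="start",
        ))
    for i in range(n_acro):
        sexed = i == n_acro - 1
        spec.append(LGSpec(
            lg=f"LG{n_fused + i + 1:02d}", lg_class=ACRO,
            female_len=a_len,
            male_len=a_len if sexed else a_len / female_male_ratio,
            tetraploid=(not sexed) and i < n_tet_acro,
            sex_linked=sexed,
            centromere_end="start",
        ))
    return spec


def default_config(seed: int = 0, *,
                   female_male_ratio: float = 1.85,
                   tetraploid_depletion: float = 0.30,
                   n_offspring: int = 170,
                   error_rate: float = 0.005,
                   missing_rate: float = 0.03) -> SimConfig:
    """Study-condition configuration for the full synthetic family.

    Plants one growth-like QTL (≈10% PVE) with a sex main effect, and a
    pure-noise control trait.
    """
    return SimConfig(
        n_offspring=n_offspring,
        lg_spec=brook_charr_karyotype(female_male_ratio=female_male_ratio),
        tetraploid_depletion=tetraploid_depletion,
        error_rate=error_rate,
        missing_rate=missing_rate,
        traits=["growth", "null_trait"],
        qtl_effects=[QTLEffect(marker="LG05_m045", effect=0.47,
                               trait="growth")],
        sex_effect={"growth": 0.5},
        residual_sd={"growth": 1.0, "null_trait": 1.0},
        seed=seed,
    )
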