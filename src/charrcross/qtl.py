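"""Single-locus QTL scan with permutation thresholds.

The scan statistic is marker regression: at each marker the offspring are
grouped by observable genotype class (two classes for one-parent-
informative markers, three for hkxhk including the ambiguous 'hk' het as
its own class, four for efxeg) and

    LOD = (n/2) * log10(RSS_reduced / RSS_full)

where the full model is covariates + genotype-class factor, the reduced
model covariates only, and n the offspring with complete data at that
marker.  Significance thresholds are empirical: trait values are permuted
across offspring (within sex strata when sex is a covariate) and the
genome-wide threshold is the (1 - alpha) quantile of the per-permutation
maximum LOD; chromosome-wide thresholds are per-LG quantiles of per-LG
maxima.

Also provided: the sex-covariate screen (P <= 0.20), 1.5-LOD support
intervals, the joint multi-QTL fit with drop-one percent variance
explained, the gatekept sex-by-genotype interaction test, and the binary
sex-trait scan that localizes the sex-linked linkage group.

Implementation note: per-marker orthonormal design bases are precomputed
once, so scoring a batch of (permuted) trait vectors is a single matrix
product — this is what makes 10,000-permutation thresholds and nested
null simulations cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneticMap, PhasedGenotypes

LOD_CAP = 50.0  # sentinel for a numerically perfect fit
_RANK_TOL = 1e-9


@dataclass
class ScanResult:
    trait: str
    covariates: tuple
    table: pd.DataFrame  # marker, lg, pos_cM, lod, n, uninformative
    n_perm: int = 0
    genome_threshold: float | None = None
    chrom_thresholds: pd.Series | None = None
    alpha_genome: float = 0.05
    alpha_chrom: float = 0.01

    def peak(self, lg: str | None = None) -> pd.Series:
        t = self.table if lg is None else self.table[self.table["lg"] == lg]
        return t.loc[t["lod"].idxmax()]

    def significant_peaks(self) -> pd.DataFrame:
        """Best marker per LG passing its genome- or chromosome-wide bar."""
        rows = []
        for lg, sub in self.table.groupby("lg", sort=False):
            best = sub.loc[sub["lod"].idxmax()]
            level = None
            if (self.genome_threshold is not None
                    and best["lod"] > self.genome_threshold):
                level = "genome"
            elif (self.chrom_thresholds is not None
                    and lg in self.chrom_thresholds.index
                    and best["lod"] > self.chrom_thresholds[lg]):
                level = "chromosome"
            if level:
                rows.append({**best.to_dict(), "significance": level})
        return pd.DataFrame(rows)


class MarkerRegression:
    """Precomputed per-marker designs for fast repeated LOD evaluation.

    Rows are the offspring with a non-missing trait (and sex, when sex is
    a covariate); each marker uses its own complete-case subset via a
    0/1 mask.  ``lod(Y)`` scores an (n x k) matrix of trait vectors and
    returns (M x k) LOD values.
    """

    def __init__(self, genotypes: PhasedGenotypes, gmap: GeneticMap,
                 offspring_index: pd.Index, sex: pd.Series | None = None):
        codes = genotypes.codes.loc[offspring_index]
        self.markers = list(codes.columns)
        self.map_info = gmap.markers.loc[self.markers]
        self.n = len(offspring_index)
        self.offspring = offspring_index
        self.sex_male = (None if sex is None
                         else (sex.loc[offspring_index] == "M")
                         .to_numpy(float))

        masks, qf_blocks, qr_blocks = [], [], []
        self.qf_slices, self.qr_slices = [], []
        self.uninformative = np.zeros(len(self.markers), dtype=bool)
        pf_off = pr_off = 0
        vals = codes.to_numpy(dtype=object)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            present = col != "-"
            if self.sex_male is not None:
                pass  # sex is defined for all offspring used
            mask = present.astype(float)
            sub = np.flatnonzero(present)
            classes = pd.unique(col[sub])
            # reduced design: intercept (+ sex)
            red_cols = [np.ones(len(sub))]
            if self.sex_male is not None:
                red_cols.append(self.sex_male[sub])
            full_cols = list(red_cols)
            for c in classes[1:]:
                full_cols.append((col[sub] == c).astype(float))
            if len(classes) < 2 or len(sub) < len(full_cols) + 1:
                self.uninformative[j] = True
                full_cols = red_cols
            qf = _orthonormal(np.column_stack(full_cols), sub, self.n)
            qr = _orthonormal(np.column_stack(red_cols), sub, self.n)
            masks.append(mask)
            qf_blocks.append(qf)
            qr_blocks.append(qr)
            self.qf_slices.append(slice(pf_off, pf_off + qf.shape[1]))
            self.qr_slices.append(slice(pr_off, pr_off + qr.shape[1]))
            pf_off += qf.shape[1]
            pr_off += qr.shape[1]
        self.mask = np.column_stack(masks)  # n x M
        self.qf = np.concatenate(qf_blocks, axis=1)
        self.qr = np.concatenate(qr_blocks, axis=1)
        self.n_per_marker = self.mask.sum(axis=0)

    def lod(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            return self.lod(Y[:, None])[:, 0]
        sumsq = self.mask.T @ (Y ** 2)  # M x k : ||y_sub||^2
        bf = self.qf.T @ Y
        br = self.qr.T @ Y
        M, k = len(self.markers), Y.shape[1]
        rss_f = np.empty((M, k))
        rss_r = np.empty((M, k))
        for j in range(M):
            rss_f[j] = sumsq[j] - (bf[self.qf_slices[j]] ** 2).sum(axis=0)
            rss_r[j] = sumsq[j] - (br[self.qr_slices[j]] ** 2).sum(axis=0)
        rss_f = np.maximum(rss_f, 0.0)
        rss_r = np.maximum(rss_r, 0.0)
        # centered total SS per marker subset, for the perfect-fit guard
        mean_sub = (self.mask.T @ Y) / np.maximum(
            self.n_per_marker[:, None], 1)
        tss = np.maximum(sumsq - np.maximum(
            self.n_per_marker[:, None], 1) * mean_sub ** 2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = (self.n_per_marker[:, None] / 2.0) * np.log10(rss_r / rss_f)
        lod[~np.isfinite(lod)] = LOD_CAP
        lod[rss_f < 1e-12 * np.maximum(tss, 1e-300)] = LOD_CAP
        lod[rss_r <= 0] = 0.0
        lod[self.uninformative] = 0.0
        return np.clip(lod, 0.0, LOD_CAP)


def _orthonormal(X: np.ndarray, rows: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of X's column space, scattered into n rows."""
    if X.shape[0] == 0:
        return np.zeros((n, 1))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > _RANK_TOL * max(s[0], 1.0)).sum())
    out = np.zeros((n, max(r, 1)))
    out[rows, :r] = u[:, :r]
    return out


def sex_covariate_screen(trait: pd.Series, sex: pd.Series,
                         p_threshold: float = 0.20) -> bool:
    """Should sex enter the model?  Two-group F-test at P <= 0.20."""
    y = pd.to_numeric(trait, errors="coerce")
    ok = y.notna() & sex.notna()
    y, s = y[ok], sex[ok]
    groups = [y[s == g].to_numpy() for g in ("F", "M")]
    if min(len(g) for g in groups) < 3:
        warnings.warn("one sex absent or too small; sex not used")
        return False
    if float(np.var(y)) == 0.0:
        return False
    _, p = stats.f_oneway(*groups)
    return bool(p <= p_threshold)


def marker_scan(trait: pd.Series, genotypes: PhasedGenotypes,
                gmap: GeneticMap, sex: pd.Series | None = None,
                trait_name: str = "trait") -> ScanResult:
    """LOD per marker for one trait (sex as additive covariate if given)."""
    y = pd.to_numeric(trait, errors="coerce")
    keep = y.notna()
    keep &= y.index.isin(genotypes.codes.index)
    if sex is not None:
        keep &= sex.reindex(y.index).notna()
    idx = y.index[keep]
    reg = MarkerRegression(genotypes, gmap, idx,
                           None if sex is None else sex)
    lod = reg.lod(y.loc[idx].to_numpy())
    table = pd.DataFrame({
        "marker": reg.markers,
        "lg": reg.map_info["lg"].to_numpy(),
        "pos_cM": reg.map_info["pos_cM"].to_numpy(),
        "lod": lod,
        "n": reg.n_per_marker.astype(int),
        "uninformative": reg.uninformative,
    })
    return ScanResult(trait=trait_name,
                      covariates=() if sex is None else ("sex",),
                      table=table)


def permutation_thresholds(trait: pd.Series, genotypes: PhasedGenotypes,
                           gmap: GeneticMap, sex: pd.Series | None = None,
                           n_perm: int = 1000, alpha_genome: float = 0.05,
                           alpha_chrom: float = 0.01,
                           seed: int | np.random.Generator = 0,
                           batch: int = 250,
                           reg: MarkerRegression | None = None):
    """Empirical genome- and chromosome-wide LOD thresholds.

    Permutes the trait across offspring (within sex strata when sex is a
    covariate).  Returns (genome_threshold, per-lg Series, max-LOD draws).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    y = pd.to_numeric(trait, errors="coerce")
    keep = y.notna() & y.index.isin(genotypes.codes.index)
    if sex is not None:
        keep &= sex.reindex(y.index).notna()
    idx = y.index[keep]
    if reg is None:
        reg = MarkerRegression(genotypes, gmap, idx,
                               None if sex is None else sex)
    else:
        idx = reg.offspring
    yv = y.loc[idx].to_numpy()
    n = len(yv)

    if sex is not None:
        strata = [np.flatnonzero((sex.loc[idx] == g).to_numpy())
                  for g in ("F", "M")]
    else:
        strata = [np.arange(n)]

    lgs = reg.map_info["lg"].to_numpy()
    lg_names = pd.unique(lgs)
    genome_max = np.empty(n_perm)
    lg_max = np.empty((len(lg_names), n_perm))
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        Y = np.empty((n, k))
        for c in range(k):
            perm = np.empty(n, dtype=int)
            for s in strata:
                perm[s] = rng.permutation(s)
            Y[:, c] = yv[perm]
        lod = reg.lod(Y)
        genome_max[done:done + k] = lod.max(axis=0)
        for g, lg in enumerate(lg_names):
            lg_max[g, done:done + k] = lod[lgs == lg].max(axis=0)
        done += k

    # alpha >= 1 means "everything significant": the bar drops to zero.
    # The conservative ("higher") order statistic is the permutation-test
    # convention; a linearly interpolated quantile is anti-conservative
    # at small n_perm.
    genome_thr = (0.0 if alpha_genome >= 1
                  else float(np.quantile(genome_max, 1 - alpha_genome,
                                         method="higher")))
    chrom_thr = pd.Series(
        0.0 if alpha_chrom >= 1
        else np.quantile(lg_max, 1 - alpha_chrom, axis=1, method="higher"),
        index=lg_names)
    return genome_thr, chrom_thr, genome_max


def scan_with_thresholds(trait: pd.Series, genotypes: PhasedGenotypes,
                         gmap: GeneticMap, sex: pd.Series | None = None,
                         n_perm: int = 1000, alpha_genome: float = 0.05,
                         alpha_chrom: float = 0.01, seed=0,
                         trait_name: str = "trait") -> ScanResult:
    res = marker_scan(trait, genotypes, gmap, sex, trait_name)
    g, c, _ = permutation_thresholds(trait, genotypes, gmap, sex, n_perm,
                                     alpha_genome, alpha_chrom, seed)
    res.n_perm = n_perm
    res.genome_threshold = g
    res.chrom_thresholds = c
    res.alpha_genome = alpha_genome
    res.alpha_chrom = alpha_chrom
    return res


def support_interval(result: ScanResult, lg: str,
                     drop: float = 1.5) -> tuple[float, float]:
    """1.5-LOD support interval around the LG's peak marker.

    Widest contiguous span with LOD >= peak - drop, expanded one marker
    beyond on each side where available; truncated at the LG edges.
    """
    sub = result.table[result.table["lg"] == lg].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no markers on lg {lg}")
    peak_i = int(sub["lod"].idxmax())
    bar = sub.loc[peak_i, "lod"] - drop
    lo = peak_i
    while lo > 0 and sub.loc[lo - 1, "lod"] >= bar:
        lo -= 1
    hi = peak_i
    while hi < len(sub) - 1 and sub.loc[hi + 1, "lod"] >= bar:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(sub) - 1)
    return float(sub.loc[lo, "pos_cM"]), float(sub.loc[hi, "pos_cM"])


# ---------------------------------------------------------------------------
# multi-QTL fit
# ---------------------------------------------------------------------------

@dataclass
class QTLModelFit:
    trait: str
    terms: list
    total_pve: float
    per_term_pve: dict
    class_means: dict
    effects: dict
    n: int
    dropped_terms: list = field(default_factory=list)


def _class_dummies(col: np.ndarray) -> tuple[np.ndarray, list]:
    classes = list(pd.unique(col))
    return (np.column_stack([(col == c).astype(float)
                             for c in classes[1:]])
            if len(classes) > 1 else np.empty((len(col), 0)), classes)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float((y ** 2).sum())
    beta, res, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    return float(((y - X @ beta) ** 2).sum())


def fit_multi_qtl(trait: pd.Series, genotypes: PhasedGenotypes,
                  markers: list[str], sex: pd.Series | None = None,
                  trait_name: str = "trait") -> QTLModelFit:
    """Joint linear model trait ~ QTL1 + ... + QTLn (+ sex).

    Total PVE = 100·(1 - RSS_full/TSS); per-term PVE is drop-one:
    100·(RSS_without_term - RSS_full)/TSS.  Genotype-class phenotype
    means (sex-split when sex is in the model) and the largest pairwise
    class effect are reported per marker.
    """
    y = pd.to_numeric(trait, errors="coerce")
    idx = y.index[y.notna() & y.index.isin(genotypes.codes.index)]
    codes = genotypes.codes.loc[idx, markers]
    complete = (codes != "-").all(axis=1)
    if sex is not None:
        complete &= sex.reindex(idx).notna()
    idx = idx[complete]
    yv = y.loc[idx].to_numpy()
    n = len(yv)
    tss = float(((yv - yv.mean()) ** 2).sum())

    term_blocks: dict[str, np.ndarray] = {}
    dropped = []
    if sex is not None:
        term_blocks["sex"] = (sex.loc[idx] == "M").to_numpy(float)[:, None]
    for m in markers:
        dm, classes = _class_dummies(codes.loc[idx, m].to_numpy(object))
        if dm.shape[1] == 0:
            warnings.warn(f"marker {m} has one class; dropped")
            dropped.append(m)
            continue
        term_blocks[m] = dm

    def design(exclude=None):
        cols = [np.ones((n, 1))]
        cols += [b for t, b in term_blocks.items() if t != exclude]
        return np.concatenate(cols, axis=1)

    X_full = design()
    # drop collinear terms (full-rank check, last in wins removal)
    while np.linalg.matrix_rank(X_full) < X_full.shape[1] and term_blocks:
        t = list(term_blocks)[-1]
        warnings.warn(f"term {t} collinear; dropped")
        dropped.append(t)
        del term_blocks[t]
        X_full = design()

    rss_full = _rss(X_full, yv)
    total_pve = 100.0 * (1 - rss_full / tss) if tss > 0 else 0.0
    per_term = {}
    for t in term_blocks:
        rss_wo = _rss(design(exclude=t), yv)
        per_term[t] = max(100.0 * (rss_wo - rss_full) / tss, 0.0) \
            if tss > 0 else 0.0

    class_means: dict = {}
    effects: dict = {}
    sex_series = None if sex is None else sex.loc[idx]
    for m in markers:
        if m in dropped:
            continue
        col = codes.loc[idx, m]
        groups: dict = {}
        if sex_series is not None:
            for sx in ("F", "M"):
                sel = sex_series == sx
                groups[sx] = {c: float(yv[(col == c) & sel].mean())
                              for c in pd.unique(col)
                              if ((col == c) & sel).any()}
        else:
            groups["all"] = {c: float(yv[col == c].mean())
                             for c in pd.unique(col)}
        class_means[m] = groups
        eff = {}
        for sx, means in groups.items():
            if len(means) >= 2:
                vals = list(means.values())
                eff[sx] = max(vals) - min(vals)
        effects[m] = eff

    return QTLModelFit(
        trait=trait_name, terms=list(term_blocks), total_pve=total_pve,
        per_term_pve=per_term, class_means=class_means, effects=effects,
        n=n, dropped_terms=dropped)


def interaction_test(trait: pd.Series, genotypes: PhasedGenotypes,
                     marker: str, sex: pd.Series,
                     full_alpha: float = 0.05) -> dict:
    """Gatekept sex-by-genotype interaction F-test at one marker.

    The full model (genotype + sex + genotype:sex) must itself be
    significant (vs intercept) before the interaction is tested by
    comparing full vs additive.  Empty sex × genotype cells skip the
    test with a warning.
    """
    y = pd.to_numeric(trait, errors="coerce")
    idx = y.index[y.notna() & y.index.isin(genotypes.codes.index)]
    col = genotypes.codes.loc[idx, marker]
    sx = sex.reindex(idx)
    ok = (col != "-") & sx.notna()
    idx = idx[ok]
    yv = y.loc[idx].to_numpy()
    col = col.loc[idx].to_numpy(object)
    male = (sx.loc[idx] == "M").to_numpy(float)
    n = len(yv)

    cells = pd.crosstab(pd.Series(col), pd.Series(male))
    if (cells.to_numpy() == 0).any() or cells.shape[0] < 2:
        warnings.warn("empty sex x genotype cell; interaction not tested")
        return {"tested": False, "p_full": None, "p_interaction": None}

    gdum, _ = _class_dummies(col)
    ones = np.ones((n, 1))
    X_add = np.concatenate([ones, gdum, male[:, None]], axis=1)
    X_full = np.concatenate([X_add, gdum * male[:, None]], axis=1)
    rss0 = _rss(ones, yv)
    rss_add = _rss(X_add, yv)
    rss_full = _rss(X_full, yv)

    df_full = X_full.shape[1] - 1
    df_res = n - X_full.shape[1]
    if df_res <= 0:
        return {"tested": False, "p_full": None, "p_interaction": None}
    f_full = ((rss0 - rss_full) / df_full) / (rss_full / df_res)
    p_full = float(stats.f.sf(f_full, df_full, df_res))
    if p_full > full_alpha:
        return {"tested": False, "p_full": p_full, "p_interaction": None}
    df_int = X_full.shape[1] - X_add.shape[1]
    f_int = ((rss_add - rss_full) / df_int) / (rss_full / df_res)
    p_int = float(stats.f.sf(f_int, df_int, df_res))
    return {"tested": True, "p_full": p_full, "p_interaction": p_int,
            "interaction_significant": p_int <= 0.05}


def sex_linkage_scan(sex: pd.Series, genotypes: PhasedGenotypes,
                     gmap: GeneticMap) -> ScanResult:
    """Scan offspring sex coded 0/1 as a trait; finds the sex-linked LG.

    The expected signature is elevated LOD across most of the sex LG with
    a decline toward the pseudoautosomal distal end.
    """
    if sex.nunique() < 2:
        raise ValueError("both sexes must be present")
    y = (sex == "M").astype(float)
    y[sex.isna()] = np.nan
    return marker_scan(y, genotypes, gmap, sex=None, trait_name="sex")
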