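"""LOD scan statistic, permutation thresholds, intervals, PVE, interactions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from charrcross import qtl as cqtl
from charrcross.io import GeneticMap, PhasedGenotypes
from charrcross.simulate import simulate_cross

from conftest import small_config


def random_genotypes(rng, n_off, n_markers, missing=0.1, lg="L1",
                     lgs=None):
    """Random efxeg genotype set (4 classes) on one or more LGs."""
    markers = [f"r_m{j:03d}" for j in range(n_markers)]
    lgs = lgs or [lg] * n_markers
    table = pd.DataFrame({
        "marker": markers, "lg": lgs,
        "pos_cM": [float(j) for j in range(n_markers)],
        "seg_type": "efxeg", "lg_class": "acrocentric",
        "tetraploid": False, "sex_linked": False,
        "centromere_end": "start"})
    gmap = GeneticMap.from_table(table)
    codes = pd.DataFrame(
        rng.choice(["ee", "ef", "eg", "fg"], size=(n_off, n_markers)),
        columns=markers, index=[f"o{i}" for i in range(n_off)])
    mask = rng.random((n_off, n_markers)) < missing
    codes = codes.mask(pd.DataFrame(mask, index=codes.index,
                                    columns=codes.columns), "-")
    return PhasedGenotypes.from_codes(codes, gmap), gmap


def lod_by_statsmodels(y, codes_col, sex=None):
    """Independent least-squares oracle for the marker-regression LOD."""
    ok = codes_col != "-"
    y = np.asarray(y, float)[ok]
    g = pd.get_dummies(pd.Series(codes_col[ok]), drop_first=True
                       ).to_numpy(float)
    X_red = np.ones((len(y), 1))
    if sex is not None:
        X_red = np.column_stack([X_red, np.asarray(sex, float)[ok]])
    X_full = np.column_stack([X_red, g])
    rss_red = sm.OLS(y, X_red).fit().ssr
    rss_full = sm.OLS(y, X_full).fit().ssr
    n = len(y)
    if rss_full <= 0:
        return cqtl.LOD_CAP
    return (n / 2.0) * np.log10(rss_red / rss_full)


class TestScanStatistic:
    def test_matches_statsmodels_oracle_on_random_designs(self):
        rng = np.random.default_rng(0)
        for trial in range(15):
            n = int(rng.integers(12, 30))
            geno, gmap = random_genotypes(rng, n, 6, missing=0.15)
            y = pd.Series(rng.normal(size=n), index=geno.codes.index)
            use_sex = trial % 2 == 0
            sex = pd.Series(rng.choice(["F", "M"], n),
                            index=geno.codes.index) if use_sex else None
            res = cqtl.marker_scan(y, geno, gmap, sex)
            for j, m in enumerate(geno.codes.columns):
                if res.table.loc[j, "uninformative"]:
                    continue
                expect = lod_by_statsmodels(
                    y.to_numpy(), geno.codes[m].to_numpy(object),
                    None if sex is None else (sex == "M").to_numpy())
                assert res.table.loc[j, "lod"] == pytest.approx(
                    expect, abs=1e-8)

    def test_lod_invariant_under_affine_trait_transform(self):
        rng = np.random.default_rng(1)
        geno, gmap = random_genotypes(rng, 40, 8)
        y = pd.Series(rng.normal(size=40), index=geno.codes.index)
        a = cqtl.marker_scan(y, geno, gmap).table["lod"]
        b = cqtl.marker_scan(3.5 * y - 11.0, geno, gmap).table["lod"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_perfect_fit_reports_capped_sentinel(self):
        rng = np.random.default_rng(2)
        geno, gmap = random_genotypes(rng, 30, 3, missing=0.0)
        code_level = {"ee": 0.0, "ef": 1.0, "eg": 2.0, "fg": 3.0}
        y = pd.Series([code_level[c] for c in geno.codes.iloc[:, 0]],
                      index=geno.codes.index)
        res = cqtl.marker_scan(y, geno, gmap)
        assert res.table.loc[0, "lod"] == cqtl.LOD_CAP

    def test_single_class_marker_is_uninformative_zero(self):
        rng = np.random.default_rng(3)
        geno, gmap = random_genotypes(rng, 25, 2, missing=0.0)
        codes = geno.codes.copy()
        codes.iloc[:, 1] = "ee"
        geno2 = PhasedGenotypes.from_codes(codes, gmap)
        res = cqtl.marker_scan(
            pd.Series(rng.normal(size=25), index=codes.index), geno2, gmap)
        assert bool(res.table.loc[1, "uninformative"])
        assert res.table.loc[1, "lod"] == 0.0


class TestSexScreen:
    def test_no_dimorphism_not_flagged(self):
        rng = np.random.default_rng(4)
        sex = pd.Series(["F", "M"] * 100)
        y = pd.Series(rng.normal(size=200))
        assert cqtl.sex_covariate_screen(y, sex) is False

    def test_two_sd_shift_flagged(self):
        rng = np.random.default_rng(5)
        sex = pd.Series(["F"] * 40 + ["M"] * 40)
        y = pd.Series(np.concatenate([rng.normal(0, 1, 40),
                                      rng.normal(2, 1, 40)]))
        assert cqtl.sex_covariate_screen(y, sex) is True

    def test_constant_trait_guard(self):
        sex = pd.Series(["F"] * 10 + ["M"] * 10)
        assert cqtl.sex_covariate_screen(pd.Series([1.0] * 20), sex) is False

    def test_single_sex_warns_false(self):
        with pytest.warns(UserWarning):
            got = cqtl.sex_covariate_screen(
                pd.Series(np.arange(10.0)), pd.Series(["F"] * 10))
        assert got is False


class TestPermutationThresholds:
    def test_alpha_one_gives_zero_threshold(self, small_sim):
        # at alpha = 1 every marker is "significant": the bar drops to 0
        gmap, geno, pheno, _ = small_sim
        y = pheno.trait_values("trait_a")
        g, c, _ = cqtl.permutation_thresholds(y, geno, gmap, n_perm=50,
                                              alpha_genome=1.0,
                                              alpha_chrom=1.0, seed=0)
        assert g == 0.0
        assert (c == 0.0).all()

    def test_same_seed_reproduces(self, small_sim):
        gmap, geno, pheno, _ = small_sim
        y = pheno.trait_values("trait_a")
        a = cqtl.permutation_thresholds(y, geno, gmap, n_perm=80, seed=42)
        b = cqtl.permutation_thresholds(y, geno, gmap, n_perm=80, seed=42)
        assert a[0] == b[0]
        pd.testing.assert_series_equal(a[1], b[1])

    def test_threshold_grows_with_marker_count(self, small_sim):
        """Genome-wide max-LOD null distribution is stochastically larger
        when more markers are scanned."""
        gmap, geno, pheno, _ = small_sim
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=len(geno.offspring)),
                      index=geno.codes.index)
        few = geno.subset_markers(list(geno.codes.columns[:20]))
        gmap_few = gmap.subset(few.codes.columns)
        g_few, _, _ = cqtl.permutation_thresholds(y, few, gmap_few,
                                                  n_perm=300, seed=7)
        g_all, _, _ = cqtl.permutation_thresholds(y, geno, gmap,
                                                  n_perm=300, seed=7)
        assert g_all > g_few


class TestSupportInterval:
    def _result(self, lods, lg="L1"):
        t = pd.DataFrame({
            "marker": [f"m{i}" for i in range(len(lods))],
            "lg": lg, "pos_cM": np.arange(len(lods), dtype=float) * 10,
            "lod": lods, "n": 100, "uninformative": False})
        return cqtl.ScanResult(trait="t", covariates=(), table=t)

    def test_single_spike_spans_flanking_markers(self):
        res = self._result([0.1, 0.2, 5.0, 0.2, 0.1])
        assert cqtl.support_interval(res, "L1") == (10.0, 30.0)

    def test_plateau_covered_plus_one(self):
        res = self._result([0.0, 4.2, 4.4, 4.3, 0.0, 0.0])
        assert cqtl.support_interval(res, "L1") == (0.0, 40.0)

    def test_edge_peak_truncates(self):
        res = self._result([6.0, 0.5, 0.4])
        lo, hi = cqtl.support_interval(res, "L1")
        assert lo == 0.0 and hi == 10.0


class TestMultiQTLFit:
    def test_term_explaining_everything_gives_pve_100(self):
        rng = np.random.default_rng(8)
        geno, gmap = random_genotypes(rng, 40, 2, missing=0.0)
        lvl = {"ee": 0.0, "ef": 1.0, "eg": 2.0, "fg": 3.0}
        y = pd.Series([lvl[c] for c in geno.codes.iloc[:, 0]],
                      index=geno.codes.index)
        fit = cqtl.fit_multi_qtl(y, geno, [geno.codes.columns[0]])
        assert fit.total_pve == pytest.approx(100.0, abs=1e-8)

    def test_orthogonal_terms_sum_to_total(self):
        # balanced 2x2 design: drop-one PVEs add up to the total
        idx = [f"o{i}" for i in range(40)]
        markers = ["q1", "q2"]
        table = pd.DataFrame({
            "marker": markers, "lg": "L1", "pos_cM": [0.0, 1.0],
            "seg_type": "nnxnp", "lg_class": "acrocentric",
            "tetraploid": False, "sex_linked": False,
            "centromere_end": "start"})
        gmap = GeneticMap.from_table(table)
        a = np.tile(["nn", "np"], 20)
        b = np.repeat(["nn", "np"], 20)
        geno = PhasedGenotypes.from_codes(
            pd.DataFrame({"q1": a, "q2": b}, index=idx), gmap)
        rng = np.random.default_rng(9)
        y = pd.Series((a == "np") * 1.0 + (b == "np") * 0.5
                      + rng.normal(0, 0.3, 40), index=idx)
        fit = cqtl.fit_multi_qtl(y, geno, markers)
        assert (fit.per_term_pve["q1"] + fit.per_term_pve["q2"]
                == pytest.approx(fit.total_pve, abs=1.0))

    def test_null_extra_term_contributes_nothing(self):
        rng = np.random.default_rng(10)
        geno, gmap = random_genotypes(rng, 60, 2, missing=0.0)
        lvl = {"ee": 0.0, "ef": 1.0, "eg": 2.0, "fg": 3.0}
        y = pd.Series([lvl[c] for c in geno.codes.iloc[:, 0]],
                      index=geno.codes.index) \
            + pd.Series(rng.normal(0, 0.5, 60), index=geno.codes.index)
        fit = cqtl.fit_multi_qtl(y, geno, list(geno.codes.columns))
        assert fit.per_term_pve[geno.codes.columns[1]] < 5.0

    def test_planted_pve_recovered_within_five_points(self, clean_sim):
        """Median recovered per-term PVE over 200 trait redraws stays
        within +/-5 percentage points of the planted 10%."""
        gmap, geno, _, _ = clean_sim
        marker = next(m for m in geno.codes.columns
                      if gmap.markers.loc[m, "seg_type"] == "efxeg")
        dose = (geno.dam[marker].to_numpy(float)
                + geno.sire[marker].to_numpy(float))
        effect = np.sqrt(0.1 / 0.9 / max(dose.var(), 1e-9))
        rng = np.random.default_rng(11)
        pves = []
        for _ in range(200):
            y = pd.Series(effect * dose + rng.normal(size=len(dose)),
                          index=geno.codes.index)
            fit = cqtl.fit_multi_qtl(y, geno, [marker])
            pves.append(fit.per_term_pve[marker])
        assert abs(np.median(pves) - 10.0) <= 5.0


class TestInteraction:
    def test_gatekeeping_blocks_null_locus(self):
        rng = np.random.default_rng(12)
        geno, gmap = random_genotypes(rng, 80, 1, missing=0.0)
        y = pd.Series(rng.normal(size=80), index=geno.codes.index)
        sex = pd.Series(rng.choice(["F", "M"], 80), index=geno.codes.index)
        out = cqtl.interaction_test(y, geno, geno.codes.columns[0], sex)
        assert out["tested"] is False

    def test_opposite_sign_effects_detected(self):
        """Sex-antagonistic locus (effect +/-1 SD by sex): the gatekept
        interaction test fires in >= 80% of replicates at n = 170."""
        rng = np.random.default_rng(13)
        hits = 0
        reps = 40
        for _ in range(reps):
            geno, gmap = random_genotypes(rng, 170, 1, missing=0.0)
            g = (geno.codes.iloc[:, 0].isin(["eg", "fg"])).to_numpy(float)
            male = rng.random(170) < 0.5
            y = pd.Series(np.where(male, g, -g) + rng.normal(size=170),
                          index=geno.codes.index)
            sex = pd.Series(np.where(male, "M", "F"),
                            index=geno.codes.index)
            out = cqtl.interaction_test(y, geno, geno.codes.columns[0], sex)
            if out["tested"] and out["p_interaction"] <= 0.05:
                hits += 1
        assert hits / reps >= 0.8

    def test_empty_cell_skips_with_warning(self):
        rng = np.random.default_rng(14)
        geno, gmap = random_genotypes(rng, 30, 1, missing=0.0)
        sex = pd.Series(["F"] * 30, index=geno.codes.index)
        sex.iloc[:2] = "M"
        codes = geno.codes.copy()
        codes.iloc[:2, 0] = "ee"  # males only ever 'ee'
        codes.iloc[2:, 0] = rng.choice(["ef", "eg", "fg"], 28)
        geno2 = PhasedGenotypes.from_codes(codes, gmap)
        y = pd.Series(rng.normal(size=30), index=codes.index)
        with pytest.warns(UserWarning):
            out = cqtl.interaction_test(y, geno2, codes.columns[0], sex)
        assert out["tested"] is False


class TestPeakLocalization:
    def test_planted_qtl_found_at_or_near_marker(self):
        """Strong (1 SD per substitution) QTL on a sparse map: the peak
        lands on the planted marker or its immediate neighbour in >= 90%
        of replicates, and the 1.5-LOD interval covers it."""
        hits = covered = 0
        reps = 25
        for r in range(reps):
            cfg = small_config(seed=100 + r, n_offspring=170,
                               n_markers_per_lg=13, error_rate=0.0,
                               missing_rate=0.0)
            cfg.qtl_effects[0].marker = "SM02_m006"
            cfg.qtl_effects[0].effect = 1.0
            gmap, geno, pheno, _ = simulate_cross(cfg)
            res = cqtl.marker_scan(pheno.trait_values("trait_a"), geno,
                                   gmap, trait_name="trait_a")
            peak = res.peak()
            planted_pos = gmap.markers.loc["SM02_m006", "pos_cM"]
            spacing = 42.0 / 12
            if (peak["lg"] == "SM02"
                    and abs(peak["pos_cM"] - planted_pos) <= spacing + 1e-9):
                hits += 1
            lo, hi = cqtl.support_interval(res, "SM02")
            if lo <= planted_pos <= hi:
                covered += 1
        assert hits / reps >= 0.9
        assert covered / reps >= 0.9


class TestSexLinkage:
    def test_single_sex_rejected(self):
        rng = np.random.default_rng(15)
        geno, gmap = random_genotypes(rng, 20, 2)
        with pytest.raises(ValueError):
            cqtl.sex_linkage_scan(pd.Series(["F"] * 20,
                                            index=geno.codes.index),
                                  geno, gmap)

    def test_sex_lg_dominates_with_distal_par_decline(self, study_sim):
        gmap, geno, pheno, _ = study_sim
        res = cqtl.sex_linkage_scan(pheno.sex, geno, gmap)
        sex_lg = gmap.sex_lg
        assert res.peak()["lg"] == sex_lg
        t = res.table.join(gmap.markers["seg_type"], on="marker")
        sub = t[(t["lg"] == sex_lg)
                & t["seg_type"].isin(["efxeg", "hkxhk"])]
        L = gmap.lg_length(sex_lg)
        par = sub[sub["pos_cM"] > 0.8 * L]["lod"]
        body = sub[sub["pos_cM"] <= 0.8 * L]["lod"]
        assert par.median() < body.median()
        off_lg = t[t["lg"] != sex_lg]["lod"]
        assert off_lg.max() < body.median()
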