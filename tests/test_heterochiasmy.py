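"""Sex-stratified summaries, positional distributions, centromere calls."""

import numpy as np
import pandas as pd
import pytest

from charrcross import crossovers as cxo
from charrcross import heterochiasmy as chet
from charrcross.simulate import default_config, simulate_cross

from conftest import make_events


class TestRatioArithmetic:
    def test_published_style_rounding(self):
        raw, one_dp = chet.female_male_ratio(3679, 1368)
        assert one_dp == 2.7
        assert raw == pytest.approx(2.6893, abs=1e-4)

    def test_equal_totals_give_unity(self):
        assert chet.female_male_ratio(100, 100)[1] == 1.0

    def test_zero_male_total_is_undefined(self):
        assert chet.female_male_ratio(10, 0) == (None, None)


class TestSummarize:
    def test_conservation_and_strata(self, study_sim, study_events):
        gmap, _, _, _ = study_sim
        _, corrected = study_events
        s = chet.summarize(corrected, gmap)
        kept = cxo.retained(corrected)
        sex_lg = gmap.sex_lg
        # per-lg totals (autosomes) sum to the overall totals
        auto = s.per_lg.drop(index=sex_lg)
        assert auto["dam"].sum() == s.overall["dam"]
        assert auto["sire"].sum() == s.overall["sire"]
        # class strata partition the autosomes
        for parent in ("dam", "sire"):
            assert (s.per_class["fused_metacentric"][parent]
                    + s.per_class["acrocentric"][parent]
                    == s.overall[parent])
            assert (s.per_tetraploid["tetraploid"][parent]
                    + s.per_tetraploid["rediploidized"][parent]
                    == s.overall[parent])
        # sex lg reported separately, never in autosomal totals
        on_sex = kept[kept["lg"] == sex_lg]
        assert s.sex_lg["sire"] == (on_sex["parent"] == "sire").sum()
        assert len(kept) == (s.overall["dam"] + s.overall["sire"]
                             + s.sex_lg["dam"] + s.sex_lg["sire"])

    def test_removed_events_never_counted(self, study_sim, study_events):
        gmap, _, _, _ = study_sim
        _, corrected = study_events
        s_all = chet.summarize(corrected, gmap)
        forced = corrected.copy()
        forced.loc[forced.index[:50], "status"] = cxo.REMOVED
        s_less = chet.summarize(forced, gmap)
        assert (s_less.overall["dam"] + s_less.overall["sire"]
                <= s_all.overall["dam"] + s_all.overall["sire"])

    def test_empty_events_give_null_ratio(self, study_sim):
        gmap, _, _, _ = study_sim
        s = chet.summarize(make_events([]), gmap)
        assert s.overall["dam"] == 0 and s.overall["ratio"] is None

    def test_depletion_inflates_tetraploid_stratum_ratio(self, study_sim,
                                                         study_events):
        """Residually tetraploid chromosomes lose male-informative
        markers distally, so their observed female:male ratio exceeds
        the rediploidized stratum's."""
        gmap, _, _, _ = study_sim
        _, corrected = study_events
        s = chet.summarize(corrected, gmap)
        assert (s.per_tetraploid["tetraploid"]["ratio"]
                > s.per_tetraploid["rediploidized"]["ratio"])
        assert (s.overall["ratio"]
                > s.per_tetraploid["rediploidized"]["ratio"])

    def test_sex_lg_male_crossovers_elevated_vs_acro_mean(self, study_sim,
                                                          study_events):
        gmap, _, _, _ = study_sim
        _, corrected = study_events
        s = chet.summarize(corrected, gmap)
        assert (s.sex_lg["sire"]
                > s.per_class["acrocentric"]["sire_mean_per_chr"])


class TestPositionalDistribution:
    def test_external_events_only(self, study_sim):
        gmap, _, _, _ = study_sim
        ev = pd.concat([
            make_events([2.0], lg="LG10", lg_len=42.0),
            make_events([38.0], lg="LG10", lg_len=42.0),
            make_events([40.0], lg="LG10", lg_len=42.0),
        ], ignore_index=True)
        assert chet.external20_fraction(ev["percent_pos"]) == 1.0

    def test_uniform_events_fill_bins_evenly(self):
        rng = np.random.default_rng(4)
        frac = chet.external20_fraction(rng.uniform(0, 100, 10_000))
        assert frac == pytest.approx(0.4, abs=0.02)

    def test_empty_events_all_zero(self, study_sim):
        gmap, _, _, _ = study_sim
        d = chet.positional_distribution(make_events([]), gmap)
        assert d.counts.to_numpy().sum() == 0

    def test_bin_counts_sum_to_totals_and_sire_is_distal(self, study_sim,
                                                         study_events):
        gmap, _, _, _ = study_sim
        _, corrected = study_events
        d = chet.positional_distribution(corrected, gmap)
        kept = cxo.retained(corrected)
        kept = kept[kept["lg"] != gmap.sex_lg]
        assert d.counts.to_numpy().sum() == len(kept)
        assert d.external20["sire"] > d.external20["dam"]
        # cumulative curves are monotone and end at the stratum total
        cum = d.cumulative.to_numpy()
        assert (np.diff(cum, axis=1) >= 0).all()
        np.testing.assert_array_equal(cum[:, -1],
                                      d.counts.sum(axis=1).to_numpy())


class TestCentromereInference:
    def test_distal_events_place_centromere_opposite(self, study_sim):
        gmap, _, _, _ = study_sim
        ev = make_events([36, 38, 40, 41, 39], parent="sire", lg="LG10",
                         lg_len=42.0)
        call = chet.infer_centromere_end(ev, gmap, "LG10")
        assert call["call"] == "start"
        assert call["confidence"] == 1.0

    def test_uniform_events_undetermined(self, study_sim):
        gmap, _, _, _ = study_sim
        ev = make_events(np.linspace(2, 40, 20), parent="sire", lg="LG10",
                         lg_len=42.0)
        assert chet.infer_centromere_end(ev, gmap, "LG10")["call"] \
            == "undetermined"

    def test_too_few_events_undetermined(self, study_sim):
        gmap, _, _, _ = study_sim
        ev = make_events([40, 41], parent="sire", lg="LG10", lg_len=42.0)
        assert chet.infer_centromere_end(ev, gmap, "LG10")["call"] \
            == "undetermined"

    def test_study_conditions_calls_are_correct(self, study_sim,
                                                study_events):
        """Under study conditions every determined call points at the
        simulated centromere end (position-faithful tight-window
        events; genotyping errors leave some LGs undetermined)."""
        gmap, _, _, _ = study_sim
        raw, _ = study_events
        tight = cxo.apply_correction(raw,
                                     cxo.CorrectionParams(window=10.0))
        calls = chet.infer_all_centromeres(tight, gmap)
        det = calls[calls["call"] != "undetermined"]
        truth = gmap.groups.loc[det["lg"], "centromere_end"].to_numpy()
        assert len(det) >= 5
        assert (det["call"].to_numpy() == truth).mean() >= 0.95

    def test_clean_family_calls_nearly_all_rediploidized_lgs(self):
        """Without genotyping error, male crossovers pin the centromere
        end on >= 95% of acrocentric LGs that keep male information."""
        cfg = default_config(seed=29, error_rate=0.0, missing_rate=0.0)
        gmap, geno, _, _ = simulate_cross(cfg)
        raw = cxo.detect_crossovers(geno, gmap,
                                    informative_both_only=True)
        ev = cxo.apply_correction(raw, cxo.CorrectionParams(window=10.0))
        calls = chet.infer_all_centromeres(ev, gmap)
        callable_lgs = gmap.groups[
            (gmap.groups["lg_class"] == "acrocentric")
            & ~gmap.groups["tetraploid"]]
        calls = calls[calls["lg"].isin(callable_lgs.index)]
        correct = (calls["call"].to_numpy()
                   == callable_lgs.loc[calls["lg"],
                                       "centromere_end"].to_numpy())
        assert correct.mean() >= 0.95


class TestSensitivity:
    def test_windows_report_ratio_and_external_shares(self, study_sim,
                                                      study_events):
        gmap, _, _, truth = study_sim
        raw, _ = study_events
        tab = chet.sensitivity(raw, gmap)
        assert list(tab["window_cM"]) == [50.0, 25.0, 10.0]
        assert (tab["ratio"] > 1.0).all()
        assert (tab["external20_sire"] > tab["external20_dam"]).all()

    def test_correction_moves_ratio_toward_truth_at_every_window(self):
        cfg = default_config(seed=23, female_male_ratio=2.7,
                             tetraploid_depletion=0.0)
        cfg.female_density = "uniform"
        cfg.male_density = "uniform"
        gmap, geno, _, truth = simulate_cross(cfg)
        raw = cxo.detect_crossovers(geno, gmap, informative_both_only=True)
        raw_ratio = chet.summarize(raw, gmap).overall["ratio"]
        tab = chet.sensitivity(raw, gmap)
        for r in tab["ratio"]:
            assert abs(r - truth.true_ratio) < abs(raw_ratio
                                                   - truth.true_ratio)
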