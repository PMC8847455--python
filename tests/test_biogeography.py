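"""Latitudinal profiles, habitat contingency tests, MPA congruence,
trait-removal sensitivity and the distance-decay diagnostic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from funrarity import (distance_decay, habitat_test, latitudinal_profile,
                       mpa_congruence, sensitivity_trait_removal)
from tests.conftest import random_trait_table


def make_summaries(lats, lons, ses, richness=None):
    n = len(ses)
    return pd.DataFrame(
        {"lat": lats, "lon": lons,
         "richness": richness if richness is not None else np.ones(n),
         "SES": ses, "degenerate": [False] * n},
        index=pd.Index([f"r{i}c0" for i in range(n)], name="cell_id"),
    )


class TestLatitudinalProfile:
    def test_no_qualifying_cells_is_empty_with_warning(self):
        s = make_summaries([0, 10, 20], [0, 0, 0], [0.5, 1.0, -1.0])
        with pytest.warns(UserWarning, match="empty profile"):
            prof = latitudinal_profile(s)
        assert len(prof["latitudes"]) == 0 and prof["density"] is None

    def test_density_mass_concentrates_where_cells_are(self):
        lats = [55, 57, 56, 0, 2, -40]
        ses = [3, 4, 5, 0, 1, 0.5]
        prof = latitudinal_profile(make_summaries(lats, [0] * 6, ses))
        assert sorted(prof["latitudes"]) == [55, 56, 57]
        peak = prof["grid"][np.argmax(prof["density"])]
        assert 50 <= peak <= 62

    def test_planted_high_latitude_hotspots_recovered(self):
        """Hotspots planted above 50 deg latitude dominate the profile mode."""
        from funrarity import FunctionalRarityModel, SimConfig, simulate_world

        cfg = SimConfig(n_lat_cells=70, n_lon_cells=8, n_mpas=10,
                        missingness_fraction=0.0,
                        hotspot_latitude_range=(50.0, 68.0), seed=2)
        world = simulate_world(cfg)
        res = FunctionalRarityModel(world.occurrences, world.traits).fit(
            n_iterations=200, seed=2)
        prof = res.latitudinal_profile()
        mode = prof["grid"][np.argmax(prof["density"])]
        assert mode > 40


class TestHabitatTest:
    def test_identical_proportions_give_zero(self):
        res = habitat_test(["a"] * 5 + ["b"] * 5, ["a"] * 10 + ["b"] * 10)
        assert res.g == pytest.approx(0.0, abs=1e-9)
        assert res.cramers_v == pytest.approx(0.0, abs=1e-9)

    def test_perfect_separation_closed_form(self):
        res = habitat_test(["a"] * 10, ["b"] * 10)
        assert res.g == pytest.approx(40 * np.log(2), abs=1e-9)
        assert res.cramers_v == pytest.approx(1.0, abs=1e-9)
        assert res.df == 1

    def test_perfectly_associated_two_by_k(self):
        res = habitat_test(["a"] * 4 + ["b"] * 4, ["c"] * 4 + ["d"] * 4)
        assert res.cramers_v == pytest.approx(1.0, abs=1e-9)

    def test_g_and_pearson_agree_asymptotically(self):
        rng = np.random.default_rng(0)
        p = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        a = rng.multinomial(10_000, p)
        b = rng.multinomial(10_000, np.roll(p, 1))
        habs = []
        for counts in (a, b):
            habs.append(np.repeat([f"h{i}" for i in range(5)], counts))
        res = habitat_test(habs[0], habs[1])
        chi2 = stats.chi2_contingency(res.table.to_numpy(),
                                      correction=False)[0]
        assert abs(res.g - chi2) / chi2 < 0.05

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="at least one"):
            habitat_test([], ["a"])


class TestMPACongruence:
    def hot_summaries(self):
        # 4 hotspot cells on a line at lon 0, plus 2 cold cells
        return make_summaries([0, 2, 4, 6, 8, 10], [0] * 6,
                              [3, 3, 3, 3, 0, 0])

    def test_half_of_hotspots_matched(self):
        mpas = pd.DataFrame({"id": ["m1", "m2"], "lat": [0.1, 2.2],
                             "lon": [0.0, 0.0]})
        res = mpa_congruence(self.hot_summaries(), mpas)
        assert len(res.hotspots) == 4 and len(res.matched) == 2
        assert res.percent_hotspots_matched == pytest.approx(50.0)
        assert res.percent_mpas_in_hotspots == pytest.approx(100.0)

    def test_mpa_at_exact_centroid_matches(self):
        mpas = pd.DataFrame({"id": ["m"], "lat": [0.0], "lon": [0.0]})
        res = mpa_congruence(self.hot_summaries(), mpas)
        assert "r0c0" in res.matched

    def test_strict_cutoff_discards_distant_mpa(self):
        # nearest centroid sits exactly 0.8 degrees away -> discarded
        mpas = pd.DataFrame({"id": ["m"], "lat": [0.8], "lon": [0.0]})
        res = mpa_congruence(self.hot_summaries(), mpas)
        assert len(res.matched) == 0
        boundary = pd.DataFrame({"id": ["m"], "lat": [0.75], "lon": [0.0]})
        assert len(mpa_congruence(self.hot_summaries(), boundary).matched) == 0
        inside = pd.DataFrame({"id": ["m"], "lat": [0.7499], "lon": [0.0]})
        assert len(mpa_congruence(self.hot_summaries(), inside).matched) == 1

    def test_invariant_to_ordering_and_duplication(self):
        mpas = pd.DataFrame({"id": ["m1", "m2"], "lat": [0.1, 6.2],
                             "lon": [0.0, 0.0]})
        doubled = pd.concat([mpas.iloc[::-1], mpas], ignore_index=True)
        a = mpa_congruence(self.hot_summaries(), mpas)
        b = mpa_congruence(self.hot_summaries(), doubled)
        assert set(a.matched) == set(b.matched)
        assert a.percent_hotspots_matched == b.percent_hotspots_matched

    def test_no_hotspots_percent_undefined(self):
        s = make_summaries([0, 2], [0, 0], [0.0, 0.5])
        mpas = pd.DataFrame({"id": ["m"], "lat": [0.0], "lon": [0.0]})
        with pytest.warns(UserWarning, match="undefined"):
            res = mpa_congruence(s, mpas)
        assert res.percent_hotspots_matched is None

    def test_random_mpas_match_fraction_of_covered_cells(self, rng):
        """With structureless SES, percent matched tracks MPA cell coverage."""
        n = 100
        lats = np.repeat(np.arange(10) * 2.0, 10)
        lons = np.tile(np.arange(10) * 2.0, 10)
        ses = rng.normal(0, 1, n)
        ses[rng.choice(n, 20, replace=False)] = 3.0  # random hotspots
        s = pd.DataFrame({"lat": lats, "lon": lons, "richness": 1,
                          "SES": ses, "degenerate": False},
                         index=pd.Index([f"c{i}" for i in range(n)],
                                        name="cell_id"))
        cells = rng.choice(n, 40, replace=True)
        mpas = pd.DataFrame({"id": [f"m{i}" for i in range(40)],
                             "lat": lats[cells] + rng.uniform(-0.4, 0.4, 40),
                             "lon": lons[cells] + rng.uniform(-0.4, 0.4, 40)})
        res = mpa_congruence(s, mpas)
        coverage = len(set(res.assignments.loc[res.assignments.kept, "cell_id"])) / n
        assert res.percent_hotspots_matched == pytest.approx(
            100 * coverage, abs=25)


class TestSensitivity:
    def test_empty_removal_set_correlates_perfectly(self, rng):
        table = random_trait_table(rng, 15, 4, 2)
        out = sensitivity_trait_removal(table, [[]])
        assert out.loc["(none)"].to_numpy() == pytest.approx(np.ones(4))

    def test_removing_constant_trait_changes_nothing(self, rng):
        table = random_trait_table(rng, 15, 3, 1)
        table.data["cz"] = 7.0
        table.kinds["cz"] = "continuous"
        from funrarity import TraitTable

        table = TraitTable(table.data, table.kinds)
        out = sensitivity_trait_removal(table, [["cz"]])
        assert out.loc["cz", "dis_pearson"] == pytest.approx(1.0)
        assert out.loc["cz", "uniq_spearman"] == pytest.approx(1.0)

    def test_default_world_robust_to_single_trait_removal(self, default_world):
        from funrarity import impute_traits

        table = impute_traits(default_world.traits, seed=0, n_estimators=15)
        out = sensitivity_trait_removal(table, [["temp_pref_c"], ["max_depth_m"]])
        assert (out["dis_spearman"] > 0.9).all()

    def test_removal_leaving_one_trait_is_error(self, rng):
        table = random_trait_table(rng, 10, 2, 0)
        with pytest.raises(ValueError, match="fewer than 2"):
            sensitivity_trait_removal(table, [["c0"]])


class TestDistanceDecay:
    def test_degenerate_equal_ses_gives_zero_slopes(self):
        s = make_summaries(np.arange(12) * 2.0, np.zeros(12), np.ones(12) * 1.5)
        with pytest.warns(UserWarning, match="slopes are 0"):
            out = distance_decay(s, "r0c0")
        assert out["fits"][0.5]["slope"] == 0.0
        assert (out["pairs"]["abs_ses_diff"] == 0).all()

    def test_median_fit_matches_pinball_loss_oracle(self, rng):
        s = make_summaries(np.arange(30) * 2.0, np.zeros(30),
                           rng.normal(0, 1, 30))
        out = distance_decay(s, "r0c0", taus=(0.5,))
        d = out["pairs"]["distance"].to_numpy()
        y = out["pairs"]["abs_ses_diff"].to_numpy()

        def pinball(params, tau=0.5):
            r = y - (params[0] + params[1] * d)
            return np.sum(np.where(r >= 0, tau * r, (tau - 1) * r))

        fit = out["fits"][0.5]
        loss_fit = pinball([fit["intercept"], fit["slope"]])
        oracle = optimize.minimize(pinball, x0=[np.median(y), 0.0],
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-10})
        assert loss_fit <= oracle.fun * (1 + 1e-4) + 1e-8

    def test_too_few_cells_is_error(self):
        s = make_summaries([0, 2, 4], [0, 0, 0], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 10"):
            distance_decay(s, "r0c0")

    def test_synthetic_world_slope_is_finite_diagnostic(self, default_world):
        from funrarity import FunctionalRarityModel

        res = FunctionalRarityModel(default_world.occurrences,
                                    default_world.traits).fit(
            n_iterations=150, seed=4)
        ref = res.cell_summary.index[0]
        out = res.distance_decay(ref)
        assert np.isfinite(out["fits"][0.5]["slope"])
        assert np.isfinite(out["fits"][0.9]["slope"])
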