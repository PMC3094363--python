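import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from treecarb import (
    Envelope,
    apply_envelope,
    dbh_measurement_error,
    dev_range_distance_experiment,
    form_agreement,
    regional_estimate,
    round_half_away,
    single_source_estimate,
    species_shares,
    subdivision_experiment,
    uncertainty_percent,
)
from treecarb.envelopes import UNITS_CARBON
from treecarb.regional import KG_PER_TG
from treecarb.roadmap import AddStep, Roadmap
from treecarb.synthetic import nwor_height_params

from .conftest import make_linear, make_power

GRID = np.arange(3.0, 67.0)


def carbon_env(lower, upper, species="sp", grid=None):
    grid = GRID if grid is None else np.asarray(grid, dtype=float)
    return Envelope(
        species=species,
        component="total tree",
        units=UNITS_CARBON,
        grid=grid,
        lower=np.broadcast_to(np.asarray(lower, float), grid.shape).copy(),
        upper=np.broadcast_to(np.asarray(upper, float), grid.shape).copy(),
    )


def inv(species, dbh, expansion):
    return pd.DataFrame(
        {"species": species, "dbh_cm": dbh, "expansion_factor": expansion}
    )


class TestUncertaintyPercent:
    def test_half_range_over_midpoint(self):
        assert uncertainty_percent(50.0, 150.0) == pytest.approx(50.0)

    def test_degenerate_interval_is_zero(self):
        assert uncertainty_percent(3.7, 3.7) == 0.0

    @given(
        lo=st.floats(0.1, 1e4),
        width=st.floats(0.0, 1e4),
        c=st.floats(0.01, 100.0),
    )
    def test_invariant_to_rescaling(self, lo, width, c):
        u1 = uncertainty_percent(lo, lo + width)
        u2 = uncertainty_percent(c * lo, c * (lo + width))
        assert u2 == pytest.approx(u1, rel=1e-9)

    def test_zero_midpoint_rejected(self):
        with pytest.raises(ValueError, match="midpoint"):
            uncertainty_percent(-1.0, 1.0)

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError, match="lo > hi"):
            uncertainty_percent(2.0, 1.0)

    @pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (-0.5, -1), (35.736, 36)])
    def test_presentation_rounding(self, x, expected):
        assert round_half_away(x) == expected


class TestApplyEnvelope:
    def test_unit_conversion_to_tg(self):
        env = carbon_env(2.0, 3.0)
        bounds = apply_envelope(inv(["sp"], [10.0], [1.0]), {"sp": env})
        assert bounds.loc["sp", "min_tg"] == pytest.approx(2.0e-9)
        assert bounds.loc["sp", "max_tg"] == pytest.approx(3.0e-9)

    def test_expansion_weighted_sum(self):
        lower = np.where(GRID == 10.0, 1.0, np.where(GRID == 20.0, 3.0, 0.0))
        upper = np.where(GRID == 10.0, 2.0, np.where(GRID == 20.0, 4.0, 0.0))
        env = carbon_env(lower, upper)
        bounds = apply_envelope(inv(["sp", "sp"], [10.0, 20.0], [10.0, 20.0]), {"sp": env})
        assert bounds.loc["sp", "min_tg"] * KG_PER_TG == pytest.approx(70.0)
        assert bounds.loc["sp", "max_tg"] * KG_PER_TG == pytest.approx(100.0)

    def test_empty_inventory(self):
        bounds = apply_envelope(inv([], [], []), {"sp": carbon_env(1.0, 2.0)})
        assert len(bounds) == 0

    def test_additive_over_inventory_partition(self):
        rng = np.random.default_rng(2)
        env = carbon_env(rng.uniform(1, 5, GRID.size), rng.uniform(5, 9, GRID.size))
        trees = inv(
            ["sp"] * 50,
            rng.uniform(3.0, 66.0, 50),
            rng.uniform(1.0, 30.0, 50),
        )
        whole = apply_envelope(trees, {"sp": env})
        part = apply_envelope(trees.iloc[:20], {"sp": env}) + apply_envelope(
            trees.iloc[20:], {"sp": env}
        )
        assert part.loc["sp", "min_tg"] == pytest.approx(whole.loc["sp", "min_tg"])
        assert part.loc["sp", "max_tg"] == pytest.approx(whole.loc["sp", "max_tg"])

    def test_undefined_class_lists_offenders(self):
        env = carbon_env(1.0, 2.0)
        env.defined[GRID == 20.0] = False
        env.lower[GRID == 20.0] = np.nan
        env.upper[GRID == 20.0] = np.nan
        with pytest.raises(ValueError, match="sp@20cm"):
            apply_envelope(inv(["sp"], [20.2], [1.0]), {"sp": env})

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError, match="other"):
            apply_envelope(inv(["other"], [10.0], [1.0]), {"sp": carbon_env(1.0, 2.0)})


class TestSpeciesShares:
    def test_half_width_and_midpoint_shares(self):
        bounds = {"a": (1.0, 3.0), "b": (2.0, 8.0)}  # half-widths 1, 3; mids 2, 5
        shares = species_shares(bounds)
        assert shares.loc["a", "uncertainty_share_pct"] == pytest.approx(25.0)
        assert shares.loc["b", "uncertainty_share_pct"] == pytest.approx(75.0)
        assert shares.loc["a", "midpoint_share_pct"] == pytest.approx(100 * 2 / 7)
        assert shares["uncertainty_share_pct"].sum() == pytest.approx(100.0)
        assert shares["midpoint_share_pct"].sum() == pytest.approx(100.0)

    def test_single_species_gets_everything(self):
        shares = species_shares({"only": (1.0, 2.0)})
        assert shares.loc["only", "uncertainty_share_pct"] == pytest.approx(100.0)
        assert shares.loc["only", "midpoint_share_pct"] == pytest.approx(100.0)

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            species_shares({"a": (1.0, 1.0), "b": (2.0, 2.0)})


class TestSubdivision:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 10])
    def test_ratio_is_one_over_k_for_divisible_inventory(self, k, uniform_inventory):
        trees = uniform_inventory.assign(species="sp")
        rng = np.random.default_rng(4)
        env = carbon_env(rng.uniform(1, 5, GRID.size), rng.uniform(6, 12, GRID.size))
        res = subdivision_experiment(env, trees, k)
        assert res.ratio == pytest.approx(1.0 / k, rel=1e-9)

    def test_midpoint_preserved(self, uniform_inventory):
        trees = uniform_inventory.assign(species="sp")
        env = carbon_env(2.0, 10.0)
        res = subdivision_experiment(env, trees, 5)
        assert (res.sub_min_tg + res.sub_max_tg) == pytest.approx(
            res.full_min_tg + res.full_max_tg, rel=1e-12
        )

    def test_remainder_trees_allowed(self):
        trees = inv(["sp"] * 7, [10.0] * 7, [1.0] * 7)  # 7 trees, k = 3
        env = carbon_env(2.0, 10.0)
        res = subdivision_experiment(env, trees, 3)
        assert 0 < res.ratio < 1

    def test_invalid_k_rejected(self, uniform_inventory):
        with pytest.raises(ValueError, match="k"):
            subdivision_experiment(carbon_env(1.0, 2.0), uniform_inventory.assign(species="sp"), 0)


class TestDevRangeDistance:
    def test_spanning_only_catalog_is_single_category(self):
        eqs = [make_power(f"e{i}", 0.1 * (i + 1), 2.4, dev_min_cm=5.0, dev_max_cm=80.0) for i in range(3)]
        table = dev_range_distance_experiment(eqs, target_dbhs=(20.0,))
        spanning = table[table["category"] == "spanning"].iloc[0]
        assert spanning["n"] == 3
        preds = [0.1 * (i + 1) * 20.0**2.4 for i in range(3)]
        assert spanning["min"] == pytest.approx(min(preds))
        assert spanning["max"] == pytest.approx(max(preds))
        assert (table[table["category"] != "spanning"]["n"] == 0).all()

    def test_distant_ranges_widen_with_noise_growing_away(self):
        # synthetic catalog whose coefficients scatter more for equations
        # fit far from the target diameter
        rng = np.random.default_rng(9)
        target = 60.0
        spanning = [
            make_power(f"s{i}", 0.1 * np.exp(rng.normal(0, 0.05)), 2.4,
                       dev_min_cm=10.0, dev_max_cm=100.0)
            for i in range(6)
        ]
        distant = [
            make_power(f"d{i}", 0.1 * np.exp(rng.normal(0, 0.5)), 2.4,
                       dev_min_cm=3.0, dev_max_cm=25.0)
            for i in range(6)
        ]
        table = dev_range_distance_experiment(spanning + distant, target_dbhs=(target,))
        t = table.set_index("category")
        width = lambda row: row["max"] - row["min"]
        assert width(t.loc["spanning"]) < width(t.loc["ends-at-half"])

    def test_empty_everywhere_rejected(self):
        eqs = [make_power("e", 0.1, 2.4, dev_min_cm=60.0, dev_max_cm=90.0)]
        with pytest.raises(ValueError, match="category"):
            dev_range_distance_experiment(eqs, target_dbhs=(100.0,))


class TestMeasurementError:
    def test_zero_error_gives_zero(self):
        eq = make_power("p", 0.1, 2.0)
        trees = inv(["sp"] * 3, [10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        assert dbh_measurement_error(trees, eq, rel_error=0.0) == 0.0

    def test_single_tree_closed_form(self):
        c = 0.37
        eq = make_power("p", c, 2.0)  # y = c D^2, dy/dD = 2cD
        trees = inv(["sp"], [10.0], [1.0])
        expected = abs(2 * c * 10.0) * (0.02 * 10.0 / 1.96)
        assert dbh_measurement_error(trees, eq) == pytest.approx(expected, rel=1e-12)

    def test_relative_error_shrinks_root_n(self):
        eq = make_power("p", 0.1, 2.0)
        one = inv(["sp"], [15.0], [1.0])
        many = inv(["sp"] * 100, [15.0] * 100, [1.0] * 100)
        se1 = dbh_measurement_error(one, eq)
        se100 = dbh_measurement_error(many, eq)
        assert se100 == pytest.approx(10.0 * se1, rel=1e-9)  # absolute grows as sqrt(n)

    def test_height_equation_rejected(self):
        from treecarb import AllometricEquation

        eq = AllometricEquation(
            id="h", species="sp", component="stem wood", response_kind="volume",
            form_id="combined-variable", coefficients=(0.0, 1.0),
            predictors="dbh-and-height", dev_min_cm=3.0, dev_max_cm=60.0,
        )
        with pytest.raises(ValueError, match="DBH-only"):
            dbh_measurement_error(inv(["sp"], [10.0], [1.0]), eq)


class TestSingleSource:
    def _roadmap(self):
        return Roadmap(steps=[AddStep(("stem wood", "roots coarse"), "total tree")])

    def test_two_equation_hand_computation(self):
        eqset = {
            "sp": {
                "stem wood": make_linear("s", 0.0, 2.0),
                "roots coarse": make_linear("r", 0.0, 1.0, component="roots coarse"),
            }
        }
        trees = inv(["sp", "sp"], [10.0, 20.0], [2.0, 3.0])
        total = single_source_estimate(eqset, trees, roadmap=self._roadmap())
        # per tree: 3D kg biomass * 0.5 C; 2*15 + 3*30 = 120 kg C
        assert total * KG_PER_TG == pytest.approx(0.5 * (2 * 30.0 + 3 * 60.0))

    def test_estimate_contained_in_positive_approach1_envelope(self, small_library):
        from treecarb import CarbonEnvelopeModel

        catalog, dens = small_library
        sp = "Pseudotsuga menziesii"
        cat_sp = [e for e in catalog if e.species == sp]
        model = CarbonEnvelopeModel(approach=1, correlation="positive").fit(
            cat_sp, densities=dens
        )
        rng = np.random.default_rng(6)
        trees = inv([sp] * 40, rng.uniform(4.0, 60.0, 40), rng.uniform(1.0, 20.0, 40))
        bounds = apply_envelope(trees, model.total_envelopes_)
        # pick one equation per leaf component from the catalog
        eqset = {sp: {}}
        for comp in ("stem wood", "stem bark", "branches total", "foliage", "roots coarse"):
            eqset[sp][comp] = next(
                e for e in cat_sp if e.component == comp and e.response_kind == "biomass"
            )
        rm = Roadmap(
            steps=[
                AddStep(
                    ("stem wood", "stem bark", "branches total", "foliage", "roots coarse"),
                    "total tree",
                )
            ]
        )
        total = single_source_estimate(
            eqset, trees, roadmap=rm, height_params=nwor_height_params()
        )
        assert bounds.loc[sp, "min_tg"] - 1e-12 <= total <= bounds.loc[sp, "max_tg"] + 1e-12

    def test_incomplete_coverage_rejected(self):
        eqset = {"sp": {"stem wood": make_linear("s", 0.0, 2.0)}}
        trees = inv(["sp"], [10.0], [1.0])
        with pytest.raises(KeyError, match="terminal|missing"):
            single_source_estimate(eqset, trees, roadmap=self._roadmap())


class TestFormAgreement:
    def _standard(self, eq_id, a, b):
        from treecarb import AllometricEquation

        return AllometricEquation(
            id=eq_id, species="sp", component="stem wood", response_kind="biomass",
            form_id="combined-variable", coefficients=(a, b),
            predictors="dbh-and-height", dev_min_cm=3.0, dev_max_cm=100.0,
        )

    def test_identical_equations_zero_spread(self):
        hp = nwor_height_params()["Pseudotsuga menziesii"]
        eqs = [make_power("a", 0.1, 2.4), make_power("b", 0.1, 2.4),
               self._standard("s1", 1.0, 0.001), self._standard("s2", 1.0, 0.001)]
        table = form_agreement(eqs, height_params=hp)
        local = table[table["subset"] == "local"]
        standard = table[table["subset"] == "standard"]
        assert local["spread_abs"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert standard["spread_abs"].abs().max() == pytest.approx(0.0, abs=1e-10)

    def test_intercept_difference_gives_constant_absolute_spread(self):
        hp = nwor_height_params()["Pseudotsuga menziesii"]
        eqs = [make_power("a", 0.1, 2.4), make_power("b", 0.12, 2.4),
               self._standard("s1", 1.0, 0.002), self._standard("s2", 4.0, 0.002)]
        table = form_agreement(eqs, height_params=hp)
        standard = table[(table["subset"] == "standard") & (table["axis"] == "D2H")]
        assert standard["spread_abs"].to_numpy() == pytest.approx(
            np.full(len(standard), 3.0)
        )

    def test_matches_brute_force(self):
        from treecarb import evaluate, predict_height

        hp = nwor_height_params()["Pseudotsuga menziesii"]
        eqs = [
            make_power("a", 0.10, 2.4),
            make_power("b", 0.13, 2.35),
            make_power("c", 0.08, 2.5),
            self._standard("s1", 1.0, 0.002),
            self._standard("s2", -2.0, 0.003),
        ]
        table = form_agreement(eqs, height_params=hp)
        row = table[(table["subset"] == "local") & (table["axis"] == "D")].iloc[7]
        d = row["dbh"]
        preds = [evaluate(e, d) for e in eqs if not e.needs_height]
        assert row["spread_abs"] == pytest.approx(max(preds) - min(preds))
        srow = table[(table["subset"] == "standard") & (table["axis"] == "D2H")].iloc[7]
        h = predict_height(hp, srow["dbh"])
        spreds = [evaluate(e, srow["dbh"], h) for e in eqs if e.needs_height]
        assert srow["spread_abs"] == pytest.approx(max(spreds) - min(spreds))

    def test_empty_subset_rejected(self):
        hp = nwor_height_params()["Pseudotsuga menziesii"]
        with pytest.raises(ValueError, match="standard"):
            form_agreement([make_power("a", 0.1, 2.4), make_power("b", 0.2, 2.4)],
                           height_params=hp)


class TestRegionalEstimate:
    def test_totals_are_exact_sums(self):
        envs = {
            "a": carbon_env(1.0, 2.0, species="a"),
            "b": carbon_env(3.0, 5.0, species="b"),
        }
        trees = inv(["a", "b"], [10.0, 12.0], [1.0, 1.0])
        est = regional_estimate(trees, envs)
        assert est.total_min_tg == pytest.approx(est.per_species["min_tg"].sum())
        assert est.total_max_tg == pytest.approx(est.per_species["max_tg"].sum())
        table = est.table()
        assert "total" in table.index
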