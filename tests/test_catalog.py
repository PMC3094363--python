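import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from treecarb import (
    AllometricEquation,
    CatalogError,
    DensityRecord,
    additivity_error,
    apply_inclusion_rules,
    evaluate,
    load_catalog,
    load_densities,
    log_bias_factor,
    write_catalog,
    write_densities,
)
from treecarb.catalog import dbh_derivative

from .conftest import make_linear, make_power


class TestEvaluate:
    @pytest.mark.parametrize(
        "form,coeffs,predictors,d,h,expected",
        [
            ("linear-combination", (0.0, 1.0), "dbh-only", 10.0, None, 10.0),
            ("linear-combination", (2.0, 0.0, 0.5), "dbh-only", 4.0, None, 10.0),
            ("log-log", (-2.0, 2.4), "dbh-only", 10.0, None, math.exp(-2.0 + 2.4 * math.log(10.0))),
            ("combined-variable", (7.0, 3.0), "dbh-and-height", 0.0, 12.0, 7.0),
            ("power", (0.5, 2.0), "dbh-only", 6.0, None, 18.0),
            ("power", (0.5, 2.0, 1.0), "dbh-and-height", 6.0, 2.0, 36.0),
        ],
    )
    def test_closed_forms(self, form, coeffs, predictors, d, h, expected):
        eq = AllometricEquation(
            id="e",
            species="sp",
            component="stem wood",
            response_kind="biomass",
            form_id=form,
            coefficients=coeffs,
            predictors=predictors,
            log_base_e=form == "log-log",
        )
        assert evaluate(eq, d, h) == pytest.approx(expected, rel=1e-12)

    def test_loglog_hand_value(self, loglog_eq):
        # ln y = -2.0 + 2.4 ln 10 -> about 34 kg
        assert evaluate(loglog_eq, 10.0) == pytest.approx(34.0, abs=0.05)

    def test_vectorised_matches_scalar(self, loglog_eq):
        grid = np.array([5.0, 10.0, 20.0])
        vec = evaluate(loglog_eq, grid)
        assert vec == pytest.approx([evaluate(loglog_eq, d) for d in grid])

    def test_missing_height_raises(self):
        eq = AllometricEquation(
            id="e", species="sp", component="stem wood", response_kind="volume",
            form_id="combined-variable", coefficients=(0.0, 1.0),
            predictors="dbh-and-height",
        )
        with pytest.raises(ValueError, match="height"):
            evaluate(eq, 10.0)

    def test_other_predictors_refused(self):
        eq = AllometricEquation(
            id="e", species="sp", component="branches total", response_kind="biomass",
            form_id="power", coefficients=(1.0, 2.0), predictors="other",
        )
        with pytest.raises(ValueError, match="other than DBH"):
            evaluate(eq, 10.0)

    @given(
        a=st.floats(0.001, 10.0),
        b=st.floats(0.1, 3.0),
        d1=st.floats(1.0, 200.0),
        d2=st.floats(1.0, 200.0),
    )
    def test_power_form_monotone_in_dbh(self, a, b, d1, d2):
        eq = make_power("p", a, b)
        lo, hi = sorted([d1, d2])
        assert evaluate(eq, lo) <= evaluate(eq, hi) + 1e-12

    def test_log_bias_correction_is_exact_multiplier(self, loglog_eq):
        plain = evaluate(loglog_eq, 17.0)
        corrected = evaluate(loglog_eq, 17.0, correct_log_bias=True)
        assert corrected == plain * math.exp(loglog_eq.mse_log / 2.0)


class TestLogBiasFactor:
    def test_zero_variance_gives_unity(self, loglog_eq):
        eq = AllometricEquation(
            **{**loglog_eq.__dict__, "id": "z", "mse_log": 0.0}
        )
        assert log_bias_factor(eq) == 1.0

    def test_closed_form(self, loglog_eq):
        assert log_bias_factor(loglog_eq) == pytest.approx(math.exp(0.05))
        assert log_bias_factor(loglog_eq) == pytest.approx(1.0513, abs=1e-4)

    def test_non_log_equation_rejected(self, linear_identity_eq):
        with pytest.raises(ValueError, match="not a log-scale"):
            log_bias_factor(linear_identity_eq)

    def test_missing_mse_rejected(self):
        eq = AllometricEquation(
            id="e", species="sp", component="stem wood", response_kind="biomass",
            form_id="log-log", coefficients=(-2.0, 2.4), log_base_e=True,
        )
        with pytest.raises(ValueError, match="mse_log"):
            log_bias_factor(eq)


class TestInclusionRules:
    def _catalog(self):
        ok = make_power("ok", 0.1, 2.4, stump_height_cm=15.0)
        extra = AllometricEquation(
            id="extra", species="sp", component="stem wood", response_kind="biomass",
            form_id="power", coefficients=(0.1, 2.4), predictors="other",
            dev_min_cm=3.0, dev_max_cm=60.0,
        )
        norange = make_power("norange", 0.1, 2.4, dev_min_cm=None, dev_max_cm=None)
        badstump = make_power("badstump", 0.1, 2.4, stump_height_cm=20.0)
        nottop = make_power("nottop", 0.1, 2.4, extends_to_top=False)
        waived = make_power(
            "waived", 0.1, 2.4, dev_min_cm=None, dev_max_cm=None, dev_range_waived=True
        )
        return [ok, extra, norange, badstump, nottop, waived]

    def test_partition_reasons(self):
        cat = self._catalog()
        included, excluded = apply_inclusion_rules(cat)
        assert {e.id for e in included} == {"ok", "waived"}
        assert dict((e.id, r) for e, r in excluded) == {
            "extra": "extra-predictor",
            "norange": "no-dev-range",
            "badstump": "bad-stump-height",
            "nottop": "not-to-top",
        }

    def test_partition_exhaustive_disjoint(self):
        cat = self._catalog()
        included, excluded = apply_inclusion_rules(cat)
        ids = {e.id for e in included} | {e.id for e, _ in excluded}
        assert ids == {e.id for e in cat}
        assert len(included) + len(excluded) == len(cat)

    def test_idempotent(self):
        cat = self._catalog()
        included, excluded = apply_inclusion_rules(cat)
        again_inc, again_exc = apply_inclusion_rules(included + [e for e, _ in excluded])
        assert {e.id for e in again_inc} == {e.id for e in included}
        assert dict((e.id, r) for e, r in again_exc) == dict(
            (e.id, r) for e, r in excluded
        )


class TestAdditivityError:
    def test_exactly_additive_components(self):
        parts = [
            make_linear("a", 0.0, 2.0, component="stem wood"),
            make_linear("b", 0.0, 3.0, component="branches total"),
        ]
        agg = make_linear("t", 0.0, 5.0, component="aboveground total")
        mean, mx = additivity_error(parts, agg, np.arange(5.0, 40.0))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert mx == pytest.approx(0.0, abs=1e-12)

    def test_constant_two_percent_offset(self):
        parts = [make_power("a", 0.1 * 1.02, 2.4)]
        agg = make_power("t", 0.1, 2.4, component="aboveground total")
        mean, mx = additivity_error(parts, agg, np.arange(5.0, 60.0))
        assert mean == pytest.approx(2.0, rel=1e-9)
        assert mx == pytest.approx(2.0, rel=1e-9)

    def test_matches_per_class_recomputation(self):
        rng = np.random.default_rng(3)
        parts = [
            make_power("a", 0.05 * rng.uniform(0.9, 1.1), 2.5),
            make_power("b", 0.01 * rng.uniform(0.9, 1.1), 2.3, component="stem bark"),
        ]
        agg = make_power("t", 0.061, 2.46, component="aboveground total")
        grid = np.arange(5.0, 80.0)
        mean, mx = additivity_error(parts, agg, grid)
        dev = [
            100.0
            * (sum(evaluate(p, d) for p in parts) - evaluate(agg, d))
            / evaluate(agg, d)
            for d in grid
        ]
        assert mean == pytest.approx(np.mean(dev), rel=1e-12)
        assert mx == pytest.approx(np.max(np.abs(dev)), rel=1e-12)

    def test_grid_outside_dev_ranges_rejected(self):
        parts = [make_power("a", 0.1, 2.4, dev_min_cm=10.0, dev_max_cm=30.0)]
        agg = make_power("t", 0.1, 2.4, component="aboveground total")
        with pytest.raises(ValueError, match="developmental-range"):
            additivity_error(parts, agg, np.arange(5.0, 60.0))


class TestDerivative:
    def test_matches_finite_difference(self, loglog_eq):
        for eq in (loglog_eq, make_power("p", 0.2, 2.5), make_linear("l", 1.0, 3.0)):
            d = 17.0
            eps = 1e-6
            num = (evaluate(eq, d + eps) - evaluate(eq, d - eps)) / (2 * eps)
            assert dbh_derivative(eq, d) == pytest.approx(num, rel=1e-5)


class TestValidationAndIO:
    def test_invalid_dev_range_rejected(self):
        with pytest.raises(CatalogError, match="0 < min < max"):
            make_power("bad", 0.1, 2.4, dev_min_cm=30.0, dev_max_cm=10.0)

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(CatalogError, match="non-finite"):
            make_power("bad", float("nan"), 2.4)

    def test_csv_roundtrip(self, tmp_path, loglog_eq, linear_identity_eq):
        path = tmp_path / "catalog.csv"
        eqs = [loglog_eq, linear_identity_eq]
        write_catalog(path, eqs)
        assert load_catalog(path) == eqs

    def test_json_catalog(self, tmp_path):
        path = tmp_path / "catalog.json"
        path.write_text(
            '{"equations": [{"id": "j1", "species": "sp", "component": "stem wood",'
            '"response_kind": "biomass", "form_id": "power", "coefficients": [0.1, 2.4],'
            '"predictors": "dbh-only", "dev_min_cm": 3, "dev_max_cm": 60}]}'
        )
        (eq,) = load_catalog(path)
        assert eq.id == "j1" and eq.coefficients == (0.1, 2.4)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "catalog.csv"
        path.write_text("id,species\n1,sp\n")
        with pytest.raises(CatalogError, match="header"):
            load_catalog(path)

    def test_duplicate_ids_rejected(self, tmp_path, loglog_eq):
        path = tmp_path / "catalog.csv"
        write_catalog(path, [loglog_eq, loglog_eq])
        with pytest.raises(CatalogError, match="duplicate"):
            load_catalog(path)

    def test_density_roundtrip_and_validation(self, tmp_path):
        recs = [DensityRecord("sp", "stem wood", 400.0, 500.0)]
        path = tmp_path / "dens.csv"
        write_densities(path, recs)
        assert load_densities(path) == recs
        with pytest.raises(CatalogError, match="rho_min"):
            DensityRecord("sp", "stem wood", 500.0, 400.0)
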