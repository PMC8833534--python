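"""Mean-dose regression grid: fitting, selection, prediction, adjustments."""

import numpy as np
import pandas as pd
import pytest

from protonsel.dose import (
    AdjustmentSpec,
    DmeanModel,
    DoseModelGrid,
    DoseModelGridResults,
    apply_adjustment,
    fit_dmean_model,
    select_margin,
)
from protonsel.exceptions import (
    DegenerateResponseError,
    SelectionError,
    SingularFitError,
    ValidationError,
)
from protonsel.structures import DEFAULT_MARGINS_MM, OAR_NAMES
from protonsel.synthetic import CohortSpec, TrueDoseModel, generate_cohort


def _make_model(intercept, b1, b2, residual_sd=1.0, half_width=0.5, **kw):
    ci = {
        "intercept": (intercept - half_width, intercept + half_width),
        "coef_in70": (b1 - half_width, b1 + half_width),
        "coef_in54_out70": (b2 - half_width, b2 + half_width),
    }
    defaults = dict(
        oar="parotid_left",
        modality="IMPT",
        margin_mm=5.0,
        r_squared=0.9,
        residual_sd=residual_sd,
        coef_ci95=ci,
        n_fit=151,
    )
    defaults.update(kw)
    return DmeanModel(
        intercept=intercept, coef_in70=b1, coef_in54_out70=b2, **defaults
    )


class TestFitDmeanModel:
    def test_exact_linear_data(self, rng):
        x1 = rng.uniform(0, 100, 10)
        x2 = rng.uniform(0, 60, 10)
        y = 5.0 + 0.6 * x1 + 0.2 * x2
        m = fit_dmean_model(x1, x2, y, "oral_cavity", "VMAT", 7.0)
        assert np.allclose(
            [m.intercept, m.coef_in70, m.coef_in54_out70], [5.0, 0.6, 0.2], atol=1e-9
        )
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        x1 = rng.uniform(0, 100, n)
        x2 = rng.uniform(0, 50, n)
        y = 3.0 + 0.4 * x1 + 0.3 * x2 + rng.normal(0, 2.0, n)
        m = fit_dmean_model(x1, x2, y, "pcm_medius", "VMAT", 10.0)
        X = np.column_stack([np.ones(n), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sd = np.sqrt(resid @ resid / (n - 3))
        got = np.array([m.intercept, m.coef_in70, m.coef_in54_out70])
        assert np.allclose(got, beta, rtol=1e-8)
        assert m.residual_sd == pytest.approx(sd, rel=1e-8)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert m.r_squared == pytest.approx(1 - (resid @ resid) / ss_tot, rel=1e-10)
        # t-based 95% CIs from the closed-form covariance
        cov = sd**2 * np.linalg.inv(X.T @ X)
        from scipy.stats import t as tdist

        crit = tdist.ppf(0.975, n - 3)
        for i, name in enumerate(("intercept", "coef_in70", "coef_in54_out70")):
            lo, hi = m.coef_ci95[name]
            assert lo == pytest.approx(beta[i] - crit * np.sqrt(cov[i, i]), rel=1e-6)
            assert hi == pytest.approx(beta[i] + crit * np.sqrt(cov[i, i]), rel=1e-6)

    def test_degenerate_and_singular_inputs(self, rng):
        x1 = rng.uniform(0, 100, 10)
        with pytest.raises(DegenerateResponseError, match="oral_cavity"):
            fit_dmean_model(x1, rng.uniform(0, 50, 10), np.full(10, 30.0),
                            "oral_cavity", "VMAT", 5.0)
        with pytest.raises(SingularFitError, match="margin 5"):
            fit_dmean_model(x1, 2 * x1, 1.0 + x1, "parotid_left", "IMPT", 5.0)
        with pytest.raises(ValidationError):
            fit_dmean_model([1, 2, 3], [1, 2, 4], [1, 2, 3], "oral_cavity", "VMAT", 0.0)


class TestMarginGrid:
    def test_full_grid_cardinality(self, grid_results):
        n_cells = len(OAR_NAMES) * len(DEFAULT_MARGINS_MM) * 2
        assert len(grid_results.models) + len(grid_results.failures) == n_cells
        assert not grid_results.failures

    def test_single_cell_equals_direct_fit(self, noisy_cohort):
        grid = DoseModelGrid(
            noisy_cohort.features,
            noisy_cohort.dmeans,
            margins=(5.0,),
            oars=("parotid_left",),
            modalities=("IMPT",),
        )
        res = grid.fit()
        assert set(res.models) == {("parotid_left", "IMPT", 5.0)}
        feat = noisy_cohort.features
        rows = feat[(feat["oar"] == "parotid_left") & (feat["margin_mm"] == 5.0)]
        rows = rows.sort_values("patient_id")
        dm = noisy_cohort.dmeans
        y = dm[(dm["oar"] == "parotid_left") & (dm["modality"] == "IMPT")]
        y = y.sort_values("patient_id")["dmean_gy"].to_numpy()
        direct = fit_dmean_model(
            rows["pct_in70"].to_numpy(), rows["pct_in54_out70"].to_numpy(), y,
            "parotid_left", "IMPT", 5.0,
        )
        got = res.models[("parotid_left", "IMPT", 5.0)]
        assert got.intercept == pytest.approx(direct.intercept)
        assert got.r_squared == pytest.approx(direct.r_squared)

    def test_true_margin_has_highest_r_squared(self):
        # generative truth at margin 7 with tiny noise: its cell must win
        truth = {}
        for oar in OAR_NAMES:
            truth[(oar, "VMAT")] = TrueDoseModel(7.0, 8.0, 0.5, 0.3, 0.1)
            truth[(oar, "IMPT")] = TrueDoseModel(7.0, 2.0, 0.6, 0.4, 0.1)
        cohort = generate_cohort(CohortSpec(n_patients=80, seed=21, dose_truth=truth))
        res = DoseModelGrid(cohort.features, cohort.dmeans).fit()
        for oar in OAR_NAMES:
            for modality in ("VMAT", "IMPT"):
                assert res.select(oar, modality).margin_mm == 7.0

    def test_selected_r_squared_is_maximal(self, grid_results):
        for (oar, modality), best in grid_results.selected().items():
            row = [
                m for (o, mod, _), m in grid_results.models.items()
                if o == oar and mod == modality
            ]
            assert best.r_squared == max(m.r_squared for m in row)

    def test_json_round_trip(self, grid_results, tmp_path):
        path = tmp_path / "grid.json"
        grid_results.to_json(path)
        back = DoseModelGridResults.from_json(path)
        assert set(back.models) == set(grid_results.models)
        key = next(iter(back.models))
        assert back.models[key].intercept == pytest.approx(
            grid_results.models[key].intercept
        )


class TestSelectMargin:
    def test_argmax_on_explicit_table(self):
        r2 = {0.0: 0.80, 3.0: 0.85, 5.0: 0.93, 7.0: 0.91, 10.0: 0.89, 15.0: 0.84}
        models = [_make_model(5.0, 0.5, 0.3, margin_mm=m, r_squared=v)
                  for m, v in r2.items()]
        margin, best = select_margin(models)
        assert margin == 5.0 and best.r_squared == 0.93

    def test_tie_breaks_to_smallest_margin(self):
        models = [_make_model(5.0, 0.5, 0.3, margin_mm=m, r_squared=0.93)
                  for m in (7.0, 5.0)]
        margin, _ = select_margin(models)
        assert margin == 5.0

    def test_empty_candidates_is_selection_error(self):
        with pytest.raises(SelectionError):
            select_margin([])


class TestPredict:
    def test_linear_prediction_and_clamps(self):
        m = _make_model(5.0, 0.6, 0.2)
        assert m.predict(0.0, 0.0) == 5.0
        assert m.predict(50.0, 25.0) == pytest.approx(40.0)
        low = _make_model(-2.0, 0.0, 0.0)
        assert low.predict(0.0, 0.0) == 0.0  # clamp floor
        high = _make_model(60.0, 0.6, 0.2)
        assert high.predict(100.0, 0.0) == 70.0  # clamp at prescription max

    def test_nan_features_propagate_and_range_checked(self):
        m = _make_model(5.0, 0.6, 0.2)
        assert np.isnan(m.predict(float("nan"), 0.0))
        with pytest.raises(ValidationError):
            m.predict(120.0, 0.0)


class TestAdjustments:
    def test_rescale(self):
        m = _make_model(0.0, 0.8, 0.0)
        adjusted = apply_adjustment(
            {"parotid_left": 40.0}, {"parotid_left": m},
            AdjustmentSpec("rescale", factor=0.85),
        )
        assert adjusted["parotid_left"] == pytest.approx(34.0)
        identity = apply_adjustment(
            {"parotid_left": 40.0}, {"parotid_left": m},
            AdjustmentSpec("rescale", factor=1.0),
        )
        assert identity["parotid_left"] == 40.0

    def test_sd_shift_own_and_pooled(self):
        m = _make_model(0.0, 0.8, 0.0, residual_sd=3.1)
        own = apply_adjustment(
            {"parotid_left": 40.0}, {"parotid_left": m},
            AdjustmentSpec("sd_shift", k_sd=1.0),
        )
        assert own["parotid_left"] == pytest.approx(36.9)
        pooled = apply_adjustment(
            {"parotid_left": 40.0}, {"parotid_left": m},
            AdjustmentSpec("sd_shift", k_sd=1.0, pooled_sd=2.0),
        )
        assert pooled["parotid_left"] == pytest.approx(38.0)
        floor = apply_adjustment(
            {"parotid_left": 1.0}, {"parotid_left": m},
            AdjustmentSpec("sd_shift", k_sd=2.0),
        )
        assert floor["parotid_left"] == 0.0  # clamped at 0 Gy

    def test_ci_bound_repredicts_from_bounds(self):
        m = _make_model(5.0, 0.6, 0.2, half_width=0.5)
        features = {"parotid_left": (50.0, 25.0)}
        point = m.predict(50.0, 25.0)
        lower = apply_adjustment(
            {"parotid_left": point}, {"parotid_left": m},
            AdjustmentSpec("ci_bound", bound_side="lower"), features,
        )["parotid_left"]
        upper = apply_adjustment(
            {"parotid_left": point}, {"parotid_left": m},
            AdjustmentSpec("ci_bound", bound_side="upper"), features,
        )["parotid_left"]
        # all three coefficients shifted by -+0.5: 0.5*(1 + 50 + 25) = 38
        assert lower == pytest.approx(point - 38.0)
        assert upper == pytest.approx(70.0)  # clamped (raw would be 78)
        with pytest.raises(ValidationError):
            apply_adjustment(
                {"parotid_left": point}, {"parotid_left": m},
                AdjustmentSpec("ci_bound", bound_side="lower"),
            )

    def test_target_oars_filter_and_nan_passthrough(self):
        m = _make_model(0.0, 0.8, 0.0)
        models = {"parotid_left": m, "pcm_superior": m}
        adjusted = apply_adjustment(
            {"parotid_left": 40.0, "pcm_superior": 40.0},
            models,
            AdjustmentSpec("rescale", factor=0.85, target_oars=("parotid_left",)),
        )
        assert adjusted == {"parotid_left": pytest.approx(34.0), "pcm_superior": 40.0}
        nan_through = apply_adjustment(
            {"parotid_left": float("nan")}, models,
            AdjustmentSpec("rescale", factor=0.85),
        )
        assert np.isnan(nan_through["parotid_left"])

    def test_proton_adjustments_never_increase_dose(self, grid_results, noisy_cohort):
        selected = {
            oar: m for (oar, mod), m in grid_results.selected().items() if mod == "IMPT"
        }
        feat = noisy_cohort.features
        patient = feat[feat["patient_id"] == "sim_0000"]
        features = {}
        predicted = {}
        for oar, m in selected.items():
            row = patient[(patient["oar"] == oar) & (patient["margin_mm"] == m.margin_mm)]
            pair = (float(row["pct_in70"].iloc[0]), float(row["pct_in54_out70"].iloc[0]))
            features[oar] = pair
            predicted[oar] = m.predict(*pair)
        for spec in (
            AdjustmentSpec("rescale", factor=0.85),
            AdjustmentSpec("sd_shift", k_sd=1.0),
            AdjustmentSpec("ci_bound", bound_side="lower"),
        ):
            adjusted = apply_adjustment(predicted, selected, spec, features)
            for oar in predicted:
                assert adjusted[oar] <= predicted[oar] + 1e-12

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            AdjustmentSpec("shrink")
        with pytest.raises(ValidationError):
            AdjustmentSpec("rescale")
        with pytest.raises(ValidationError):
            AdjustmentSpec("rescale", factor=-1.0)
        with pytest.raises(ValidationError):
            AdjustmentSpec("ci_bound", bound_side="middle")
        with pytest.raises(ValidationError):
            AdjustmentSpec("sd_shift")


def test_pooled_residual_sd_pools_sums_of_squares(grid_results):
    selected = [m for (_, mod), m in grid_results.selected().items() if mod == "IMPT"]
    ssr = sum(m.residual_sd**2 * (m.n_fit - 3) for m in selected)
    df = sum(m.n_fit - 3 for m in selected)
    assert grid_results.pooled_residual_sd("IMPT") == pytest.approx(np.sqrt(ssr / df))
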