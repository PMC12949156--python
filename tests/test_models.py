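"""Linear prediction models and ear-grouped repeated cross-validation."""

import numpy as np
import pandas as pd
import pytest

from synaptometry.models import (
    CVConfig,
    ModelSpec,
    build_analysis_table,
    complete_rows,
    delta_rmse_vs_reference,
    fit_model,
    repeated_grouped_cv,
    rmse,
)


def synthetic_table(n_ears=100, seed=0, sigma=1.0, b0=2.0, b1=0.3,
                    with_acute=False):
    """Two rows per ear; outcome generated from the 'm' column."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ears):
        group = "acute_noise" if (with_acute and i % 5 == 0) else "young"
        for f in (16000.0, 32000.0):
            m = rng.uniform(0, 20)
            xi = rng.uniform(20, 60)
            y = b0 + b1 * m + rng.normal(0, sigma)
            rows.append({"ear_id": f"e{i:03d}", "group": group,
                         "sex": "F" if i % 2 else "M", "frequency_hz": f,
                         "synapses": y, "m": m, "dpoae_threshold": xi})
    return pd.DataFrame(rows)


class TestRMSE:
    def test_perfect_prediction(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_case(self):
        assert rmse([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_mean_prediction_equals_population_sd(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5, 3, 1000)
        assert rmse(y, np.full_like(y, y.mean())) == pytest.approx(np.std(y))

    def test_empty_or_mismatched_errors(self):
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            rmse([1, 2], [1])


class TestBuildAnalysisTable:
    def test_join_and_row_bound(self):
        truth = pd.DataFrame({
            "ear_id": ["a", "a", "b", "b"],
            "frequency_hz": [16000.0, 32000.0] * 2,
            "synapses_per_ihc": [15.0, 12.0, 10.0, 8.0],
        })
        m = pd.DataFrame({"ear_id": ["a", "b"], "frequency_hz": [16000.0, 16000.0],
                          "abr_80": [1.5, 1.0]})
        table = build_analysis_table(truth, m)
        assert len(table) <= 4
        assert table.loc[table.ear_id.eq("a") & table.frequency_hz.eq(32000.0),
                         "abr_80"].isna().all()
        assert "synapses" in table.columns

    def test_off_grid_frequencies_dropped(self):
        truth = pd.DataFrame({
            "ear_id": ["a"] * 3,
            "frequency_hz": [8000.0, 16000.0, 32000.0],
            "synapses_per_ihc": [9.0, 15.0, 12.0],
        })
        table = build_analysis_table(truth)
        assert set(table["frequency_hz"]) == {16000.0, 32000.0}

    def test_duplicate_keys_rejected(self):
        truth = pd.DataFrame({
            "ear_id": ["a", "a"], "frequency_hz": [16000.0, 16000.0],
            "synapses_per_ihc": [1.0, 2.0],
        })
        with pytest.raises(ValueError):
            build_analysis_table(truth)


class TestFitModel:
    def test_intercept_only_predicts_mean(self):
        table = synthetic_table()
        fit = fit_model(ModelSpec(), table)
        assert fit.params["intercept"] == pytest.approx(table["synapses"].mean())
        assert fit.k == 2  # intercept + residual variance

    def test_exact_noiseless_recovery(self):
        table = synthetic_table(sigma=0.0)
        fit = fit_model(ModelSpec(evoked=("m",)), table)
        assert fit.params["intercept"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params["m"] == pytest.approx(0.3, abs=1e-10)

    def test_planted_coefficients_within_3se(self):
        rng = np.random.default_rng(3)
        n = 400
        m = rng.uniform(0, 10, n)
        xi = rng.uniform(0, 40, n)
        y = 1.5 + 0.4 * m - 0.1 * xi + rng.normal(0, 1.0, n)
        table = pd.DataFrame({
            "ear_id": [f"e{i}" for i in range(n)], "group": "young",
            "frequency_hz": 16000.0, "synapses": y, "m": m,
            "dpoae_threshold": xi, "sex": "F",
        })
        fit = fit_model(ModelSpec(evoked=("m",), dpoae="dpoae_threshold"), table)
        import statsmodels.api as sm
        X = sm.add_constant(np.column_stack([m, xi]))
        se = sm.OLS(y, X).fit().bse
        for est, true, s in zip(fit.params.values, (1.5, 0.4, -0.1), se):
            assert abs(est - true) < 3 * s

    def test_matches_lstsq_oracle(self):
        table = synthetic_table(seed=5)
        fit = fit_model(ModelSpec(evoked=("m",), dpoae="dpoae_threshold"), table)
        X = np.column_stack([
            np.ones(len(table)), table["m"], table["dpoae_threshold"]
        ])
        beta, *_ = np.linalg.lstsq(X, table["synapses"].to_numpy(), rcond=None)
        assert np.allclose(fit.params.values, beta, atol=1e-9)

    def test_rank_deficiency_names_columns(self):
        table = synthetic_table()
        table["m2"] = 2.0 * table["m"]
        with pytest.raises(ValueError, match="collinear"):
            fit_model(ModelSpec(evoked=("m", "m2")), table)

    def test_sex_indicator(self):
        table = synthetic_table(seed=6)
        fit = fit_model(ModelSpec(evoked=("m",), include_sex=True), table)
        assert "sex_f" in fit.params.index

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(dpoae="dpoae_99")


class TestGroupedCV:
    def test_no_ear_split_and_exact_partition(self):
        table = synthetic_table(n_ears=40, with_acute=True)
        cfg = CVConfig(k_folds=5, repeats=3, seed=0)
        res = repeated_grouped_cv(ModelSpec(evoked=("m",)), table, cfg)
        pool_ears = set(table.loc[table.group != "acute_noise", "ear_id"])
        per_repeat = [res.fold_ears[i : i + 5] for i in range(0, len(res.fold_ears), 5)]
        for folds in per_repeat:
            all_ears = [e for fold in folds for e in fold]
            assert len(all_ears) == len(set(all_ears))  # no ear in two folds
            assert set(all_ears) == pool_ears  # exact partition
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1
            assert not any(e in pool_ears - set(fold) for fold in folds for e in fold)

    def test_acute_rows_never_in_folds(self):
        table = synthetic_table(n_ears=40, with_acute=True)
        res = repeated_grouped_cv(ModelSpec(evoked=("m",)), table,
                                  CVConfig(k_folds=5, repeats=2, seed=1))
        acute = set(table.loc[table.group == "acute_noise", "ear_id"])
        assert all(not (fold & acute) for fold in res.fold_ears)
        assert np.isfinite(res.rmse_test).all()

    def test_intercept_only_rmse_matches_noise_sd(self):
        # y ~ N(mu, 2): intercept-only validation RMSE converges to 2
        rng = np.random.default_rng(4)
        rows = [{"ear_id": f"e{i}", "group": "young", "frequency_hz": 16000.0,
                 "synapses": rng.normal(10.0, 2.0), "sex": "F"}
                for i in range(200)]
        table = pd.DataFrame(rows)
        res = repeated_grouped_cv(ModelSpec(), table, CVConfig(seed=0))
        assert res.mean_val == pytest.approx(2.0, rel=0.05)
        # sharper: the CV estimate tracks the realized sample SD
        assert res.mean_val == pytest.approx(table["synapses"].std(), rel=0.02)

    def test_generating_predictor_beats_intercept(self):
        table = synthetic_table(n_ears=200, sigma=1.0, seed=8)
        cfg = CVConfig(seed=2)
        res_m = repeated_grouped_cv(ModelSpec(evoked=("m",)), table, cfg)
        res_0 = repeated_grouped_cv(ModelSpec(), table, cfg)
        assert res_m.mean_val == pytest.approx(1.0, rel=0.05)
        assert res_m.mean_val < res_0.mean_val

    def test_identical_seed_bit_identical(self):
        table = synthetic_table(n_ears=50, with_acute=True)
        cfg = CVConfig(k_folds=5, repeats=2, seed=9)
        r1 = repeated_grouped_cv(ModelSpec(evoked=("m",)), table, cfg)
        r2 = repeated_grouped_cv(ModelSpec(evoked=("m",)), table, cfg)
        assert np.array_equal(r1.rmse_validation, r2.rmse_validation)
        assert np.array_equal(r1.rmse_test, r2.rmse_test)
        assert r1.fold_hash == r2.fold_hash

    def test_too_few_ears_errors(self):
        table = synthetic_table(n_ears=5)
        with pytest.raises(ValueError):
            repeated_grouped_cv(ModelSpec(), table, CVConfig(k_folds=10))


class TestDeltaRMSE:
    def test_matched_adjustment_and_pairing(self):
        table = synthetic_table(n_ears=60, with_acute=True, seed=10)
        cfg = CVConfig(k_folds=5, repeats=2, seed=3)
        results = {}
        for ev in ((), ("m",)):
            for adj in (None, "dpoae_threshold"):
                spec = ModelSpec(evoked=ev, dpoae=adj)
                results[spec.name] = repeated_grouped_cv(spec, table, cfg)
        out = delta_rmse_vs_reference(results, reference_evoked=("m",))
        assert len(out) == 2  # the two intercept/dpoae-only rows
        assert set(out["adjustment"]) == {"none", "dpoae_threshold"}
        # same rows and seed -> identical partitions -> paired SEM
        assert out["paired"].all()
        # intercept-only must be worse than the generating-predictor model
        assert (out["delta_rmse"] > 0).all()

    def test_reference_compared_to_itself_is_zero(self):
        table = synthetic_table(n_ears=60, seed=11)
        cfg = CVConfig(k_folds=5, repeats=2, seed=4)
        a = repeated_grouped_cv(ModelSpec(evoked=("m",)), table, cfg)
        b = repeated_grouped_cv(ModelSpec(evoked=("m",)), table, cfg)
        results = {"self": a, "ref": b}
        out = delta_rmse_vs_reference({"other": a, "m|none": b},
                                      reference_evoked=("m",))
        # 'other' has the same spec as the reference family, so nothing to compare
        assert len(out) == 0

    def test_missing_matched_reference_errors(self):
        table = synthetic_table(n_ears=60, seed=12)
        cfg = CVConfig(k_folds=5, repeats=1, seed=5)
        res = {"intercept|dpoae_threshold": repeated_grouped_cv(
            ModelSpec(dpoae="dpoae_threshold"), table, cfg)}
        with pytest.raises(KeyError):
            delta_rmse_vs_reference(res, reference_evoked=("m",))


def test_complete_rows_drops_only_incomplete(default_cohort_config=None):
    table = synthetic_table(n_ears=10)
    table.loc[3, "m"] = np.nan
    spec = ModelSpec(evoked=("m",))
    out = complete_rows(spec, table)
    assert len(out) == len(table) - 1
    # intercept-only keeps the row (m not required)
    assert len(complete_rows(ModelSpec(), table)) == len(table)
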