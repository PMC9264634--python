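"""Joint background + TF-specific occupancy model."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jams import model, simulate


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


class TestFitJams:
    def test_planted_methylation_effects_recovered(self, sim_small, fit_small):
        dm, truth = sim_small
        fit = fit_small
        i2 = dm.columns.index("M_pos02")
        i8 = dm.columns.index("M_pos08")
        assert fit.table.loc["M_pos02", "f"] == pytest.approx(truth.beta_f[i2], abs=0.3)
        assert fit.table.loc["M_pos08", "f"] == pytest.approx(truth.beta_f[i8], abs=0.3)

    def test_null_tf_coefficients_near_zero(self):
        spec = simulate.default_spec(2000, s_p=float(np.log(20.0)))
        spec.beta_f = {b: np.zeros_like(v) for b, v in spec.beta_f.items()}
        dm, _ = simulate.simulate_design(spec, seed=5)
        fit = model.fit_jams(dm)
        f = fit.table["f"].to_numpy()
        se = fit.table["f_se"].to_numpy()
        ok = ~np.isnan(f)
        outside = np.abs(f[ok]) > 3.5 * se[ok]
        assert outside.mean() < 0.05
        assert abs(fit.t_effect) < 3.5 * fit.t_se + 0.05

    def test_doubled_pulldown_shifts_only_t_effect(self, sim_small, fit_small):
        dm, _ = sim_small
        dm2 = dm.subset_rows(np.arange(dm.k))
        dm2.pulldown = dm.pulldown * 2
        fit2 = model.fit_jams(dm2)
        assert fit2.t_effect - fit_small.t_effect == pytest.approx(np.log(2), abs=0.02)
        f1 = fit_small.table["f"].to_numpy()
        f2 = fit2.table["f"].to_numpy()
        se = np.hypot(fit_small.table["f_se"].to_numpy(), fit2.table["f_se"].to_numpy())
        ok = ~np.isnan(f1)
        # TF-specific coefficients move only within their joint uncertainty
        assert np.all(np.abs(f2[ok] - f1[ok]) <= 3 * se[ok] + 0.05)

    def test_swapping_libraries_negates_tf_effects(self, sim_small, fit_small):
        dm, _ = sim_small
        swapped = dm.subset_rows(np.arange(dm.k))
        swapped.pulldown, swapped.control = dm.control.copy(), dm.pulldown.copy()
        fit_swapped = model.fit_jams(swapped)
        assert fit_swapped.t_effect == pytest.approx(-fit_small.t_effect, abs=0.02)
        f1 = fit_small.table["f"].to_numpy()
        f2 = fit_swapped.table["f"].to_numpy()
        ok = ~(np.isnan(f1) | np.isnan(f2))
        np.testing.assert_allclose(f2[ok], -f1[ok], atol=1e-5)

    def test_too_few_peaks_rejected(self):
        spec = simulate.default_spec(20)
        dm, _ = simulate.simulate_design(spec, seed=1)
        with pytest.raises(ValueError, match="at least"):
            model.fit_jams(dm)


class TestObservedLogRatio:
    def test_equal_counts_equal_libraries_zero(self):
        r = model.observed_log_ratio(np.array([5, 10]), np.array([5, 10]))
        assert r == pytest.approx([0.0, 0.0])

    def test_global_doubling_absorbed_by_library_size(self):
        c = np.array([4, 9, 19])
        r = model.observed_log_ratio(2 * c, c)
        # ratio is constant across peaks and near zero after normalization
        assert np.ptp(r) < 0.1
        assert np.abs(r).max() < 0.15

    def test_zero_zero_peak_maps_to_minus_library_ratio(self):
        r = model.observed_log_ratio(np.array([0, 10]), np.array([0, 10]))
        assert r[0] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)),
                    min_size=2, max_size=20))
    def test_library_rescaling_invariance_of_ordering(self, pairs):
        p = np.array([a for a, _ in pairs], dtype=float)
        c = np.array([b for _, b in pairs], dtype=float)
        r1 = model.observed_log_ratio(p, c)
        r2 = model.observed_log_ratio(p * 3, c)
        np.testing.assert_allclose(np.argsort(r1, kind="stable"),
                                   np.argsort(r2, kind="stable"))


class TestCrossValidate:
    def test_noiseless_high_depth_r_above_095(self):
        spec = simulate.default_spec(
            1500, meth_effects={2: -2.0}, noiseless_counts=True,
            s_c=float(np.log(200.0)), s_p=float(np.log(200.0)) + 2.0,
        )
        dm, _ = simulate.simulate_design(spec, seed=9)
        res = model.cross_validate(dm, folds=10, seed=0)
        assert res.r > 0.95

    def test_pure_noise_r_near_zero(self):
        spec = simulate.default_spec(5000, s_p=float(np.log(20.0)))
        spec.beta_f = {b: np.zeros_like(v) for b, v in spec.beta_f.items()}
        dm, _ = simulate.simulate_design(spec, seed=11)
        res = model.cross_validate(dm, folds=10, seed=0)
        assert abs(res.r) < 0.05

    def test_same_seed_reproducible(self, sim_small):
        dm, _ = sim_small
        r1 = model.cross_validate(dm, folds=5, seed=3)
        r2 = model.cross_validate(dm, folds=5, seed=3)
        assert r1.r == r2.r
        np.testing.assert_array_equal(r1.predicted, r2.predicted)

    def test_too_few_peaks_rejected(self):
        spec = simulate.default_spec(60)
        dm, _ = simulate.simulate_design(spec, seed=1)
        with pytest.raises(ValueError):
            model.cross_validate(dm, folds=10, seed=0)


class TestPredictNewContext:
    def test_training_design_reproduces_training_predictions(self, sim_small, fit_small):
        dm, _ = sim_small
        res = model.predict_new_context(fit_small, dm)
        np.testing.assert_allclose(res.predicted, fit_small.predict_tf_signal(dm.X))

    def test_transfer_to_shifted_methylation_context(self):
        spec = simulate.default_spec(2000, meth_effects={2: -2.0, 8: 2.0})
        sim = simulate.simulate_two_cells(
            spec, simulate.DeltaSpec(meth_resample_prob=0.8), seed=21
        )
        fit = model.fit_jams(sim.dm_a)
        pred_b = fit.predict_tf_signal(sim.dm_b.X)
        true_b = sim.dm_b.X.to_numpy() @ sim.beta_f
        r = np.corrcoef(pred_b, true_b)[0, 1]
        assert r > 0.9

    def test_column_mismatch_raises(self, sim_small, fit_small):
        dm, _ = sim_small
        reduced = dm.drop_block("A")
        with pytest.raises(ValueError, match="missing model columns"):
            model.predict_new_context(fit_small, reduced)

    def test_block_disabled_model_round_trip(self):
        spec = simulate.default_spec(800)
        dm, _ = simulate.simulate_design(spec, seed=2)
        red = dm.drop_block("A")
        fit = model.fit_jams(red)
        res = model.predict_new_context(fit, red)
        assert np.isfinite(res.r)


class TestReducedFit:
    def test_reduced_loglik_not_above_full(self, sim_small, fit_small):
        dm, _ = sim_small
        reduced, test = model.reduced_fit(dm, ["M_pos02"])
        assert reduced.loglik <= fit_small.loglik + 1e-6
        assert test.df == 2  # background and TF-specific copies

    def test_active_methylation_column_strongly_significant(self, sim_small):
        dm, _ = sim_small
        _, test = model.reduced_fit(dm, ["M_pos02"])
        assert test.p < 1e-4

    def test_interaction_only_drop_df_one(self, sim_small):
        dm, _ = sim_small
        _, test = model.reduced_fit(dm, ["M_pos02"], both_copies=False)
        assert test.df == 1

    def test_empty_drop_rejected(self, sim_small):
        dm, _ = sim_small
        with pytest.raises(ValueError):
            model.reduced_fit(dm, [])


class TestResidualSort:
    def test_full_model_noiseless_residuals_small(self):
        spec = simulate.default_spec(
            1000, noiseless_counts=True,
            s_c=float(np.log(500.0)), s_p=float(np.log(500.0)) + 2.0,
        )
        dm, _ = simulate.simulate_design(spec, seed=13)
        fit = model.fit_jams(dm)
        _, resid = model.residual_sort(dm, fit)
        assert np.std(resid) < 0.1

    def test_hidden_methylation_effect_leaves_negative_correlation(self, sim_small):
        dm, _ = sim_small
        reduced, _ = model.reduced_fit(dm, ["M_pos02"])
        _, resid = model.residual_sort(
            dm.subset_rows(np.arange(dm.k)), reduced
        )
        meth = dm.X["M_pos02"].to_numpy()
        has = meth > 0
        from scipy import stats

        r, p = stats.pearsonr(resid[has], meth[has])
        assert r < 0
        assert p < 0.01

    def test_ordering_invariant_to_library_rescaling(self, sim_small, fit_small):
        dm, _ = sim_small
        order1, _ = model.residual_sort(dm, fit_small)
        rescaled = dm.subset_rows(np.arange(dm.k))
        rescaled.pulldown = dm.pulldown * 4
        order2, resid2 = model.residual_sort(rescaled, fit_small)
        _, resid1 = model.residual_sort(dm, fit_small)
        # rescaling shifts every observed ratio by the same constant, which
        # the library normalization removes up to the count pseudocount
        from scipy import stats

        rho = stats.spearmanr(resid1, resid2).statistic
        assert rho > 0.99


class TestPersistence:
    def test_save_load_round_trip(self, fit_small, tmp_path):
        path = tmp_path / "model.json"
        model.save_fit(fit_small, path, provenance={"seed": 42})
        back = model.load_fit(path)
        assert back.columns == fit_small.columns
        np.testing.assert_allclose(
            back.table["f"].to_numpy(), fit_small.table["f"].to_numpy(),
            equal_nan=True,
        )
        assert back.theta == pytest.approx(fit_small.theta)
        assert back.spec.motif_length == fit_small.spec.motif_length
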