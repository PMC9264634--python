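"""Differential-binding model and JAMS-based prediction of changes."""

import warnings

import numpy as np
import pytest

from jams import diffbind, model, nbglm, simulate
from jams.diffbind import ReplicatedCounts


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


class TestMergePeaks:
    def test_nearby_summits_merged_to_mean(self):
        merged = diffbind.merge_peaks([[("chr1", 1000)], [("chr1", 1050)]])
        assert merged == [("chr1", 1025)]

    def test_distant_summits_stay_separate(self):
        merged = diffbind.merge_peaks([[("chr1", 1000)], [("chr1", 1200)]])
        assert merged == [("chr1", 1000), ("chr1", 1200)]

    def test_single_linkage_chain(self):
        merged = diffbind.merge_peaks([[("chr1", 0), ("chr1", 90), ("chr1", 180)]])
        assert merged == [("chr1", 90)]

    def test_matches_brute_force_clustering(self):
        rng = np.random.default_rng(0)
        summits = sorted(int(s) for s in rng.integers(0, 3000, size=40))
        merged = diffbind.merge_peaks([[("chr1", s) for s in summits]])

        # brute-force transitive closure of the "within 100 bp" relation
        clusters = [[summits[0]]]
        for s in summits[1:]:
            if s - clusters[-1][-1] <= 100:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        expected = [("chr1", int(round(np.mean(c)))) for c in clusters]
        assert merged == expected


def _counts(control_a, pull_a, control_b, pull_b, reps=2):
    n = len(control_a)
    control = np.column_stack([control_a] * reps + [control_b] * reps)
    pulldown = np.column_stack([pull_a] * reps + [pull_b] * reps)
    return ReplicatedCounts(
        peak_ids=[f"p{i}" for i in range(n)],
        pulldown=pulldown,
        control=control,
        cell=["A"] * reps + ["B"] * reps,
    )


class TestFitDiff:
    def test_identical_cells_no_change(self):
        rng = np.random.default_rng(1)
        c = rng.integers(10, 60, size=30)
        p = rng.integers(10, 60, size=30)
        res = diffbind.fit_diff(_counts(c, p, c, p))
        assert np.nanmax(np.abs(res["log2_fc"])) < 1e-4
        assert not res["significant"].any()

    def test_doubled_pulldown_subset_gives_log2fc_one(self):
        # doubling at a minority of peaks is not absorbed by the
        # median-of-ratios size factors, so those peaks read log2 fc = 1
        c = np.full(20, 40)
        p_a = np.full(20, 40)
        p_b = p_a.copy()
        p_b[:5] = 80
        res = diffbind.fit_diff(_counts(c, p_a, c, p_b))
        assert res["log2_fc"].to_numpy()[:5] == pytest.approx(np.ones(5), abs=0.05)
        assert res["log2_fc"].to_numpy()[5:] == pytest.approx(np.zeros(15), abs=0.05)

    def test_all_zero_peak_excluded_from_fdr(self):
        rng = np.random.default_rng(2)
        c = rng.integers(10, 60, size=10)
        p = rng.integers(10, 60, size=10)
        counts = _counts(c, p, c, p)
        counts.pulldown[0] = 0
        counts.control[0] = 0
        res = diffbind.fit_diff(counts)
        assert np.isnan(res["log2_fc"].iloc[0])
        assert np.isnan(res["q"].iloc[0])
        assert not bool(res["significant"].iloc[0])

    def test_matches_direct_likelihood_oracle_single_peak(self):
        from test_nbglm import direct_mle

        rng = np.random.default_rng(3)
        counts = _counts(
            rng.integers(20, 40, 1), rng.integers(20, 40, 1),
            rng.integers(20, 40, 1), rng.integers(60, 90, 1),
        )
        design, names = diffbind._peak_design(counts)
        sf = diffbind.size_factors(counts)
        offset = np.log(np.concatenate([sf[:, 0], sf[:, 1]]))
        y = np.concatenate([counts.control[0], counts.pulldown[0]])
        fit = nbglm.fit(design, y, offset=offset, names=names)
        b_hat, _, _ = direct_mle(design, y, offset=offset, x0=fit.coef,
                                 theta0=fit.theta)
        np.testing.assert_allclose(fit.coef, b_hat, atol=1e-4)
        res = diffbind.fit_diff(counts)
        j_ct = names.index("c:t")
        assert res["log2_fc"].iloc[0] == pytest.approx(b_hat[j_ct] / np.log(2),
                                                       abs=1e-3)

    def test_label_swap_negates_log2fc(self):
        rng = np.random.default_rng(4)
        c = rng.integers(10, 60, size=15)
        pa = rng.integers(10, 60, size=15)
        pb = rng.integers(10, 120, size=15)
        fwd = diffbind.fit_diff(_counts(c, pa, c, pb))
        swapped_counts = ReplicatedCounts(
            peak_ids=[f"p{i}" for i in range(15)],
            pulldown=np.column_stack([pb, pb, pa, pa]),
            control=np.column_stack([c, c, c, c]),
            cell=["A", "A", "B", "B"],
        )
        rev = diffbind.fit_diff(swapped_counts)
        np.testing.assert_allclose(
            rev["log2_fc"].to_numpy(), -fwd["log2_fc"].to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(rev["p"].to_numpy(), fwd["p"].to_numpy(), atol=1e-5)

    def test_null_simulation_fdr_controlled(self):
        spec = simulate.default_spec(600, s_c=float(np.log(50.0)),
                                     s_p=float(np.log(50.0)) + 2.0)
        sim = simulate.simulate_two_cells(
            spec, simulate.DeltaSpec(meth_resample_prob=0.0), seed=6
        )
        res = diffbind.fit_diff(sim.counts)
        assert np.all(np.abs(sim.true_log2_fc) < 1e-9)
        frac = res["significant"].mean()
        assert frac <= 0.12


class TestPredictDiff:
    def test_identical_contexts_predict_zero(self, sim_small, fit_small):
        dm, _ = sim_small
        pred = diffbind.predict_diff(fit_small, dm.X, dm.X)
        assert np.all(pred == 0)

    def test_methylation_increase_with_negative_coef_predicts_loss(self, sim_small, fit_small):
        dm, _ = sim_small
        X_b = dm.X.copy()
        X_b["M_pos02"] = np.clip(X_b["M_pos02"] + 0.5, 0, 1)
        pred = diffbind.predict_diff(fit_small, dm.X, X_b)
        changed = (X_b["M_pos02"] - dm.X["M_pos02"]) > 0
        assert np.all(pred[changed.to_numpy()] < 0)

    def test_drop_accessibility_zeroes_a_contribution(self, sim_small, fit_small):
        dm, _ = sim_small
        X_b = dm.X.copy()
        for c in fit_small.blocks["A"]:
            X_b[c] = X_b[c] + 1.0
        with_a = diffbind.predict_diff(fit_small, dm.X, X_b)
        without_a = diffbind.predict_diff(fit_small, dm.X, X_b, drop_accessibility=True)
        assert np.all(np.abs(without_a) < 1e-9)
        assert np.mean(np.abs(with_a)) > 0.1

    def test_row_mismatch_raises(self, sim_small, fit_small):
        dm, _ = sim_small
        with pytest.raises(ValueError):
            diffbind.predict_diff(fit_small, dm.X, dm.X.iloc[:10])


class TestEvaluateDiff:
    def _observed(self, lfc, sem=0.1, q=0.01):
        import pandas as pd

        n = len(lfc)
        return pd.DataFrame(
            {
                "log2_fc": lfc,
                "sem": np.full(n, sem),
                "p": np.full(n, 1e-4),
                "q": np.full(n, q),
                "significant": np.full(n, q < 0.1),
            }
        )

    def test_perfect_prediction(self):
        lfc = np.linspace(-2, 2, 10)
        out = diffbind.evaluate_diff(lfc, self._observed(lfc))
        assert out["r_low_sem"] == pytest.approx(1.0)
        assert out["sign_accuracy"] == pytest.approx(1.0)

    def test_anti_prediction(self):
        lfc = np.linspace(-2, 2, 11)
        lfc = lfc[lfc != 0]
        out = diffbind.evaluate_diff(-lfc, self._observed(lfc))
        assert out["r_low_sem"] == pytest.approx(-1.0)
        assert out["sign_accuracy"] == pytest.approx(0.0)

    def test_sem_cutoff_excludes_noisy_peaks(self):
        lfc = np.linspace(-2, 2, 10)
        obs = self._observed(lfc)
        obs.loc[:4, "sem"] = 5.0
        out = diffbind.evaluate_diff(lfc, obs)
        assert out["n_low_sem"] == 5

    def test_significant_subset_beats_all_peaks_with_planted_changes(self):
        spec = simulate.default_spec(1200, meth_effects={2: -2.0, 8: 2.0},
                                     s_c=float(np.log(50.0)),
                                     s_p=float(np.log(50.0)) + 2.0)
        sim = simulate.simulate_two_cells(
            spec, simulate.DeltaSpec(meth_resample_prob=0.7), seed=8
        )
        fit = model.fit_jams(sim.dm_a)
        pred = diffbind.predict_diff(fit, sim.dm_a.X, sim.dm_b.X)
        res = diffbind.fit_diff(sim.counts)
        out = diffbind.evaluate_diff(pred, res)
        assert out["r_significant"] > out["r_low_sem"] * 0.95
        assert out["r_significant"] > 0.5
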