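"""Simulation benchmarks exercised by the validation suite.

Each function runs one self-contained experiment — generating data from
known truth, running the relevant part of the pipeline, and measuring the
outcome — and returns a small dict of named numbers.  All randomness is
controlled by the ``seed`` argument.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from . import classify, diffbind, model, nbglm, simulate
from .io_formats import PFM

__all__ = [
    "glm_oracle_deviation",
    "parameter_recovery",
    "lrt_null_calibration",
    "classification_recovery",
    "differential_pipeline",
]


def glm_oracle_deviation(seed: int, n: int = 200) -> dict:
    """IRLS engine vs direct numerical likelihood maximization.

    NB data with 3 design columns; returns the largest absolute
    per-coefficient difference between the engine and a BFGS optimizer on
    the joint (beta, log theta) likelihood.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)]
    )
    beta = np.array([2.0, 0.5, -0.8])
    theta = 5.0
    mu = np.exp(X @ beta)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    fit = nbglm.fit(X, y)

    def neg(params):
        m = np.exp(np.clip(X @ params[:3], -30, 30))
        return -nbglm.nb_loglik(y, m, float(np.exp(params[3])))

    res = optimize.minimize(
        neg, np.concatenate([fit.coef, [np.log(fit.theta)]]),
        method="BFGS", options={"maxiter": 5000, "gtol": 1e-9},
    )
    return {
        "max_coef_deviation": float(np.max(np.abs(fit.coef - res.x[:3]))),
        "n": n,
    }


def parameter_recovery(seed: int, k: int = 20_000) -> dict:
    """Joint-model coefficient recovery under the standard conditions.

    Planted TF-specific methylation effects of -2 (position 2) and +2
    (position 8), dispersion theta = 5.  Reports the fraction of true
    coefficients (background and TF-specific pooled) within +/- 3 SE of
    their estimates and the recovered planted effects.
    """
    spec = simulate.default_spec(k, meth_effects={2: -2.0, 8: 2.0})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm, truth = simulate.simulate_design(spec, seed=seed)
        fit = model.fit_jams(dm)
    est = np.concatenate([fit.table["b"].to_numpy(), fit.table["f"].to_numpy()])
    se = np.concatenate([fit.table["b_se"].to_numpy(), fit.table["f_se"].to_numpy()])
    true = np.concatenate([truth.beta_b, truth.beta_f])
    ok = ~np.isnan(est)
    within = np.abs(est[ok] - true[ok]) <= 3 * se[ok]
    return {
        "within_3se_pct": float(100.0 * within.mean()),
        "meth_minus_estimate": float(fit.table.loc["M_pos02", "f"]),
        "meth_plus_estimate": float(fit.table.loc["M_pos08", "f"]),
        "n": k,
    }


def lrt_null_calibration(
    seed: int, n_reps: int = 1000, k: int = 2000
) -> dict:
    """Fraction of null likelihood-ratio tests with p < 0.05.

    Each replicate drops a methylation column whose true coefficient is 0
    in both the background and TF-specific copies.
    """
    ps = np.empty(n_reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            dm, _ = simulate.simulate_null_design(k, seed=seed + rep)
            _, test = model.reduced_fit(dm, ["M_pos01"])
            ps[rep] = test.p
    return {
        "frac_p_below_05": float(np.mean(ps < 0.05)),
        "n": n_reps,
    }


def _no_cpg_pfm() -> PFM:
    consensus = "TAGCTAAAGGCT"  # no CG dinucleotide reachable with prevalence
    mat = np.full((12, 4), 0.05)
    for p, b in enumerate(consensus):
        mat[p, "ACGT".index(b)] = 0.85
    return PFM(mat, name="noCpG")


COHORT_EFFECTS = {
    "methyl-minus": {2: -2.0},
    "methyl-plus": {2: 2.0},
    "mixed-effect": {2: 2.0, 8: -2.0},
    "no-effect": None,
    "no-CpG": None,
}


def _classify_once(kind: str, seed: int, k: int) -> str:
    if kind == "no-CpG":
        spec = simulate.default_spec(k, pfm=_no_cpg_pfm(), cpg_prob={})
    else:
        spec = simulate.default_spec(k, meth_effects=COHORT_EFFECTS[kind])
    dm, _ = simulate.simulate_design(spec, seed=seed)
    fit = model.fit_jams(dm)
    table = classify.methyl_effect_table(fit, cpg_prevalence=dm.cpg_prevalence)
    return classify.call_class(table).category


def classification_recovery(
    seed: int, runs_per_cohort: int = 8, k: int = 4000
) -> dict:
    """Five-way methyl-preference recovery on planted cohorts.

    Each cohort (methyl-minus, methyl-plus, mixed-effect, no-effect,
    no-CpG) is simulated ``runs_per_cohort`` times with |effect| = 2 and
    classified at q < 1e-5; reports per-cohort and overall accuracy.
    """
    out = {}
    correct_total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c_idx, kind in enumerate(COHORT_EFFECTS):
            correct = sum(
                _classify_once(kind, seed + 1000 * c_idx + r, k) == kind
                for r in range(runs_per_cohort)
            )
            out[f"accuracy_{kind}_pct"] = 100.0 * correct / runs_per_cohort
            correct_total += correct
    out["accuracy_overall_pct"] = (
        100.0 * correct_total / (runs_per_cohort * len(COHORT_EFFECTS))
    )
    out["n"] = runs_per_cohort * len(COHORT_EFFECTS)
    return out


def differential_pipeline(seed: int, k: int = 1500) -> dict:
    """Two-cell differential binding: estimation and model-based prediction.

    (i) Replicated counts (2+2) at control depth 50 with methylation-driven
    changes; correlation of estimated log2 fold changes with truth over
    peaks passing the SEM < 1.28 filter.  (ii) The noiseless limit (high
    depth, counts at their expectations) for model-predicted fold changes
    vs truth.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = simulate.default_spec(
            k, meth_effects={2: -2.0, 8: 2.0},
            s_c=float(np.log(50.0)), s_p=float(np.log(50.0)) + 2.0,
        )
        sim = simulate.simulate_two_cells(
            spec, simulate.DeltaSpec(meth_resample_prob=0.7), seed=seed
        )
        res = diffbind.fit_diff(sim.counts)
        lfc = res["log2_fc"].to_numpy()
        keep = ~np.isnan(lfc) & (res["sem"].to_numpy() < diffbind.DEFAULT_SEM_CUTOFF)
        r_fit = float(stats.pearsonr(lfc[keep], sim.true_log2_fc[keep])[0])

        spec_nl = simulate.default_spec(
            max(k // 2, 600), meth_effects={2: -2.0, 8: 2.0},
            theta=1e5, noiseless_counts=True,
            s_c=float(np.log(200.0)), s_p=float(np.log(200.0)) + 2.0,
        )
        sim_nl = simulate.simulate_two_cells(
            spec_nl, simulate.DeltaSpec(meth_resample_prob=0.7), seed=seed + 1
        )
        fit_a = model.fit_jams(sim_nl.dm_a)
        pred = diffbind.predict_diff(fit_a, sim_nl.dm_a.X, sim_nl.dm_b.X)
        r_pred = float(stats.pearsonr(pred, sim_nl.true_log2_fc)[0])
    return {
        "fit_diff_truth_r": r_fit,
        "predict_diff_noiseless_r": r_pred,
        "n": k,
    }
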