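"""The joint background + TF-specific occupancy model.

Control and pulldown counts for the same k peaks are stacked into one
vector of length 2k and explained by a single negative-binomial GLM with a
shared dispersion:

    log lambda_c = X beta_b + s_c                    (control rows)
    log lambda_p = X beta_b + X beta_f + s_p         (pulldown rows)

i.e. the model ``n ~ X + t + X:t`` where t indicates pulldown.  The main
effects of X are the background coefficients beta_b (they shape both
libraries), the X:t interactions are the TF-specific coefficients beta_f
(pulldown only), s_c is the intercept and the t main effect is s_p - s_c,
absorbing the library-size ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nbglm
from .design_matrix import DesignMatrix, FeatureSpec

__all__ = [
    "JAMSFit",
    "PredictionResult",
    "fit_jams",
    "observed_log_ratio",
    "cross_validate",
    "predict_new_context",
    "reduced_fit",
    "residual_sort",
    "save_fit",
    "load_fit",
]

RATIO_PSEUDOCOUNT = 0.5


@dataclass
class JAMSFit:
    """Fitted background (beta_b) and TF-specific (beta_f) coefficients.

    ``table`` has one row per X column with columns
    (b, b_se, b_z, b_p, f, f_se, f_z, f_p); aliased entries are NaN.
    """

    columns: list[str]
    blocks: dict[str, list[str]]
    table: pd.DataFrame
    s_c: float  # background intercept (log control library scale)
    t_effect: float  # s_p - s_c
    t_se: float
    theta: float
    loglik: float
    k: int
    converged: bool
    nbfit: nbglm.NBFit  # the underlying stacked fit (for LRTs)
    spec: FeatureSpec | None = None

    @property
    def beta_b(self) -> pd.Series:
        return self.table["b"]

    @property
    def beta_f(self) -> pd.Series:
        return self.table["f"]

    def predict_tf_signal(self, X: pd.DataFrame) -> np.ndarray:
        """Per-peak TF-specific log-signal X . beta_f (aliased coefs = 0)."""
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"design is missing model columns: {missing}")
        extra = [c for c in X.columns if c not in set(self.columns)]
        if extra:
            raise ValueError(f"design has columns unknown to the model: {extra}")
        f = self.beta_f.fillna(0.0).to_numpy()
        return X[self.columns].to_numpy() @ f


@dataclass
class PredictionResult:
    predicted: np.ndarray  # TF-specific log-signal per peak
    observed: np.ndarray  # observed log pulldown-to-control ratio
    r: float
    r2: float
    p: float


def _stacked(dm: DesignMatrix):
    """(design, names, counts): the 2k-row ``n ~ X + t + X:t`` layout."""
    X = dm.X.to_numpy(dtype=float)
    k, m = X.shape
    ones = np.ones((k, 1))
    zeros = np.zeros((k, 1))
    top = np.hstack([ones, zeros, X, np.zeros_like(X)])  # control rows, t=0
    bot = np.hstack([ones, ones, X, X])  # pulldown rows, t=1
    names = (
        ["(Intercept)", "t"]
        + [f"b:{c}" for c in dm.columns]
        + [f"f:{c}" for c in dm.columns]
    )
    design = np.vstack([top, bot])
    y = np.concatenate([dm.control, dm.pulldown])
    return design, names, y


def fit_jams(dm: DesignMatrix, min_peaks: int = 50) -> JAMSFit:
    """Fit the stacked joint model to a design matrix with carried counts."""
    if dm.k < min_peaks:
        raise ValueError(f"need at least {min_peaks} peaks, got {dm.k}")
    design, names, y = _stacked(dm)
    fit = nbglm.fit(design, y, names=names)
    return _wrap(fit, dm)


def _wrap(fit: nbglm.NBFit, dm: DesignMatrix) -> JAMSFit:
    z = fit.z()
    p = fit.p()
    idx = {n: j for j, n in enumerate(fit.names)}
    rows = []
    for c in dm.columns:
        jb, jf = idx[f"b:{c}"], idx[f"f:{c}"]
        rows.append(
            dict(
                b=fit.coef[jb], b_se=fit.se[jb], b_z=z[jb], b_p=p[jb],
                f=fit.coef[jf], f_se=fit.se[jf], f_z=z[jf], f_p=p[jf],
            )
        )
    table = pd.DataFrame(rows, index=dm.columns)
    jt = idx["t"]
    return JAMSFit(
        columns=dm.columns,
        blocks={b: list(cols) for b, cols in dm.blocks.items()},
        table=table,
        s_c=float(fit.coef[idx["(Intercept)"]]),
        t_effect=float(fit.coef[jt]),
        t_se=float(fit.se[jt]),
        theta=fit.theta,
        loglik=fit.loglik,
        k=dm.k,
        converged=fit.converged,
        nbfit=fit,
        spec=dm.spec,
    )


def observed_log_ratio(
    pulldown: np.ndarray, control: np.ndarray
) -> np.ndarray:
    """Library-normalized log pulldown-to-control ratio per peak.

    log((p + 0.5) / (c + 0.5)) - log(sum(p) / sum(c)); the pseudocount keeps
    zero-count peaks finite and symmetric.
    """
    p = np.asarray(pulldown, dtype=float)
    c = np.asarray(control, dtype=float)
    lib = np.log(p.sum() / c.sum()) if p.sum() > 0 and c.sum() > 0 else 0.0
    return np.log((p + RATIO_PSEUDOCOUNT) / (c + RATIO_PSEUDOCOUNT)) - lib


def _corr(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(pred, obs)
    return float(r), float(p)


def cross_validate(
    dm: DesignMatrix, folds: int = 10, seed: int = 0
) -> PredictionResult:
    """Out-of-fold correlation between predicted TF signal and observed ratio.

    Peaks are partitioned by a seeded permutation; each fold's TF-specific
    signal is predicted from a model trained on the other folds, and the
    pooled out-of-fold predictions are correlated with the observed
    library-normalized log pulldown-to-control ratio.
    """
    if dm.k < 10 * folds:
        raise ValueError(f"need at least {10 * folds} peaks for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dm.k)
    assignment = np.empty(dm.k, dtype=int)
    assignment[perm] = np.arange(dm.k) % folds
    pred = np.empty(dm.k)
    for fold in range(folds):
        test = assignment == fold
        if test.sum() < 2 or (~test).sum() < 2:
            raise ValueError(f"fold {fold} has too few peaks")
        fit = fit_jams(dm.subset_rows(np.flatnonzero(~test)))
        pred[test] = fit.predict_tf_signal(dm.X.iloc[np.flatnonzero(test)])
    obs = observed_log_ratio(dm.pulldown, dm.control)
    r, p = _corr(pred, obs)
    return PredictionResult(predicted=pred, observed=obs, r=r, r2=r * r, p=p)


def predict_new_context(fit: JAMSFit, dm_new: DesignMatrix) -> PredictionResult:
    """Apply a trained model to a new context (e.g. another cell line)."""
    pred = fit.predict_tf_signal(dm_new.X)
    obs = observed_log_ratio(dm_new.pulldown, dm_new.control)
    r, p = _corr(pred, obs)
    return PredictionResult(predicted=pred, observed=obs, r=r, r2=r * r, p=p)


def reduced_fit(
    dm: DesignMatrix, drop: list[str], both_copies: bool = True
) -> tuple[JAMSFit, nbglm.LRTResult]:
    """Refit without the given X columns and LRT against the full fit.

    By default both the background and TF-specific copies of each dropped
    column are removed — the conservative nested test of whether the
    feature is informative at all.  With ``both_copies=False`` only the
    TF-specific (interaction) copy is dropped.
    """
    if not drop:
        raise ValueError("drop list is empty")
    unknown = [c for c in drop if c not in set(dm.columns)]
    if unknown:
        raise ValueError(f"unknown columns: {unknown}")
    full = fit_jams(dm)

    design, names, y = _stacked(dm)
    to_drop = set()
    for c in drop:
        to_drop.add(f"f:{c}")
        if both_copies:
            to_drop.add(f"b:{c}")
    keep = [j for j, n in enumerate(names) if n not in to_drop]
    red_nb = nbglm.fit(design[:, keep], y, names=[names[j] for j in keep])
    test = nbglm.lrt(full.nbfit, red_nb)

    keep_cols = [c for c in dm.columns if c not in set(drop)]
    red_dm = DesignMatrix(
        X=dm.X[keep_cols],
        blocks={
            b: [c for c in cols if c in set(keep_cols)]
            for b, cols in dm.blocks.items()
        },
        pulldown=dm.pulldown,
        control=dm.control,
        spec=dm.spec,
    )
    reduced = _wrap(red_nb, red_dm)
    return reduced, test


def residual_sort(
    dm: DesignMatrix, reduced: JAMSFit
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak residual of a reduced model and the induced peak ordering.

    residual = observed log pulldown-to-control ratio minus the reduced
    model's (mean-centered) TF-specific log-signal; peaks whose signal
    exceeds the reduced prediction sort last.  Returns (order, residuals).
    """
    pred = reduced.predict_tf_signal(dm.X[reduced.columns])
    obs = observed_log_ratio(dm.pulldown, dm.control)
    resid = (obs - obs.mean()) - (pred - pred.mean())
    return np.argsort(resid), resid


def save_fit(fit: JAMSFit, path, provenance: dict | None = None) -> None:
    doc = {
        "columns": fit.columns,
        "blocks": fit.blocks,
        "beta_b": fit.table["b"].to_dict(),
        "beta_f": fit.table["f"].to_dict(),
        "se_b": fit.table["b_se"].to_dict(),
        "se_f": fit.table["f_se"].to_dict(),
        "p_b": fit.table["b_p"].to_dict(),
        "p_f": fit.table["f_p"].to_dict(),
        "s_c": fit.s_c,
        "t_effect": fit.t_effect,
        "t_se": fit.t_se,
        "theta": fit.theta,
        "loglik": fit.loglik,
        "k": fit.k,
        "converged": fit.converged,
        "spec": None
        if fit.spec is None
        else {
            "motif_length": fit.spec.motif_length,
            "reference_bases": fit.spec.reference_bases,
            "coverage_cutoff": fit.spec.coverage_cutoff,
            "access_pseudocount": fit.spec.access_pseudocount,
            "use_blocks": list(fit.spec.use_blocks),
        },
        "provenance": provenance or {},
    }

    def _clean(x):
        if isinstance(x, float) and np.isnan(x):
            return None
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items()}
        if isinstance(x, list):
            return [_clean(v) for v in x]
        return x

    with open(path, "w") as fh:
        json.dump(_clean(doc), fh, indent=1)


def load_fit(path) -> JAMSFit:
    with open(path) as fh:
        doc = json.load(fh)
    cols = doc["columns"]

    def as_series(key):
        return pd.Series(
            [np.nan if doc[key][c] is None else doc[key][c] for c in cols],
            index=cols, dtype=float,
        )

    table = pd.DataFrame(
        {
            "b": as_series("beta_b"),
            "b_se": as_series("se_b"),
            "b_p": as_series("p_b"),
            "f": as_series("beta_f"),
            "f_se": as_series("se_f"),
            "f_p": as_series("p_f"),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        table["b_z"] = table["b"] / table["b_se"]
        table["f_z"] = table["f"] / table["f_se"]
    spec = None
    if doc.get("spec"):
        s = doc["spec"]
        spec = FeatureSpec(
            motif_length=s["motif_length"],
            reference_bases=s["reference_bases"],
            coverage_cutoff=s["coverage_cutoff"],
            access_pseudocount=s["access_pseudocount"],
            use_blocks=tuple(s["use_blocks"]),
        )
    return JAMSFit(
        columns=cols,
        blocks=doc["blocks"],
        table=table,
        s_c=doc["s_c"],
        t_effect=doc["t_effect"],
        t_se=doc["t_se"],
        theta=doc["theta"],
        loglik=doc["loglik"],
        k=doc["k"],
        converged=doc["converged"],
        nbfit=None,  # type: ignore[arg-type]
        spec=spec,
    )
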