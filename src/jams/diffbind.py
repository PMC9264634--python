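"""Differential TF binding between two cell contexts.

For each merged peak, replicated pulldown/control counts from the two cell
lines are modeled with a per-peak negative-binomial GLM of the form
``~ sample + assay + cell:assay``: the categorical sample term absorbs
library size and cell main effects, the assay term is the
pulldown-to-control log-ratio in the reference cell, and the cell:assay
interaction is the change of that log-ratio between cells — the log fold
change of differential binding.  Per-sample size factors (median of
ratios across peaks) enter as fixed offsets.  Estimates are raw MLEs with
their standard errors; no shrinkage is applied, so the SEM filter used
downstream operates on unshrunk values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nbglm
from .classify import bh_fdr
from .model import JAMSFit

__all__ = [
    "ReplicatedCounts",
    "DiffResult",
    "merge_peaks",
    "size_factors",
    "fit_diff",
    "predict_diff",
    "evaluate_diff",
]

LOG2 = float(np.log(2.0))
DEFAULT_FDR = 0.1
DEFAULT_SEM_CUTOFF = 1.28  # on the log2 scale


@dataclass
class ReplicatedCounts:
    """Counts for merged peaks across replicated samples in two cell lines.

    ``pulldown`` and ``control`` are (n_peaks, n_samples) arrays;
    ``cell`` labels each sample with its cell line (exactly two distinct
    labels, each with >= 2 replicates).
    """

    peak_ids: list[str]
    pulldown: np.ndarray
    control: np.ndarray
    cell: list[str]

    def __post_init__(self):
        self.pulldown = np.asarray(self.pulldown, dtype=np.int64)
        self.control = np.asarray(self.control, dtype=np.int64)
        if self.pulldown.shape != self.control.shape:
            raise ValueError("pulldown and control shapes differ")
        if self.pulldown.shape[1] != len(self.cell):
            raise ValueError("one cell label per sample required")
        levels = sorted(set(self.cell))
        if len(levels) != 2:
            raise ValueError("exactly two cell lines required")
        for lv in levels:
            if self.cell.count(lv) < 2:
                raise ValueError(f"cell line {lv!r} needs >= 2 replicates")
        self.cells = levels

    @property
    def n_peaks(self) -> int:
        return self.pulldown.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pulldown.shape[1]


def merge_peaks(summit_lists: list[list[tuple[str, int]]]) -> list[tuple[str, int]]:
    """Merge summits within 100 bp of each other (single linkage) per chrom.

    The merged summit is the rounded mean of member summits.  Returns
    (chrom, summit) sorted by chromosome then position.
    """
    if not summit_lists:
        raise ValueError("no summit lists given")
    per_chrom: dict[str, list[int]] = {}
    for lst in summit_lists:
        for chrom, summit in lst:
            per_chrom.setdefault(chrom, []).append(summit)
    merged = []
    for chrom in sorted(per_chrom):
        summits = sorted(per_chrom[chrom])
        cluster = [summits[0]]
        for s in summits[1:]:
            if s - cluster[-1] <= 100:
                cluster.append(s)
            else:
                merged.append((chrom, int(round(np.mean(cluster)))))
                cluster = [s]
        merged.append((chrom, int(round(np.mean(cluster)))))
    return merged


def size_factors(counts: ReplicatedCounts) -> np.ndarray:
    """Median-of-ratios size factor per (sample, assay) library.

    Returns a (n_samples, 2) array, columns = (control, pulldown).
    Libraries are normalized so factors have geometric mean 1; peaks with
    a zero count in any library are excluded from the reference.
    """
    mat = np.concatenate([counts.control, counts.pulldown], axis=1).astype(float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.all(np.isfinite(logs), axis=1)
    if finite.sum() < 1:
        factors = np.ones(mat.shape[1])
    else:
        ref = logs[finite].mean(axis=1, keepdims=True)  # log geometric mean
        factors = np.exp(np.median(logs[finite] - ref, axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    n = counts.n_samples
    return np.column_stack([factors[:n], factors[n:]])


def _peak_design(counts: ReplicatedCounts):
    """Shared per-peak design: intercept + sample dummies + t + c:t."""
    n = counts.n_samples
    cell_b = np.array([c == counts.cells[1] for c in counts.cell], dtype=float)
    rows = []
    names = ["(Intercept)"] + [f"s{j}" for j in range(1, n)] + ["t", "c:t"]
    for assay in (0, 1):  # control rows then pulldown rows
        for s in range(n):
            sample_dummies = [1.0 if s == j else 0.0 for j in range(1, n)]
            rows.append([1.0, *sample_dummies, float(assay), float(assay) * cell_b[s]])
    return np.array(rows), names


def fit_diff(counts: ReplicatedCounts, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Per-peak differential-binding estimates.

    Returns a frame indexed by peak id with columns log2_fc, sem, p, q and
    ``significant`` (q < ``fdr``).  The log2 fold change is oriented as
    cells[1] relative to cells[0].  All-zero peaks get NaN estimates and
    are excluded from the FDR correction.

    The dispersion is shared across peaks: with only a handful of
    observations per peak a free per-peak dispersion collapses toward
    Poisson and the Wald test loses calibration.  Theta is instead
    estimated once from all peaks with a residual-degrees-of-freedom
    corrected Pearson estimating equation (each per-peak model spends
    most of its observations on mean parameters, so an uncorrected
    pooled ML estimate would be badly biased toward no dispersion), then
    held fixed in every per-peak model — mirroring the
    moderated-dispersion practice of count-based differential tests.
    """
    design, names = _peak_design(counts)
    sf = size_factors(counts)
    offset = np.log(np.concatenate([sf[:, 0], sf[:, 1]]))
    j_ct = names.index("c:t")

    nonzero = [
        i
        for i in range(counts.n_peaks)
        if np.any(counts.control[i] > 0) or np.any(counts.pulldown[i] > 0)
    ]

    def per_peak_fits(theta):
        fits = {}
        for i in nonzero:
            y = np.concatenate([counts.control[i], counts.pulldown[i]])
            fits[i] = nbglm.fit(design, y, offset=offset, names=names,
                                fixed_theta=theta)
        return fits

    # shared theta via a df-corrected Pearson estimating equation:
    # sum_ij (y - mu)^2 / (mu + mu^2/theta) = total residual df,
    # iterated with per-peak refits at the current theta
    from scipy import optimize as _optimize

    y_all = np.concatenate(
        [np.concatenate([counts.control[i], counts.pulldown[i]]) for i in nonzero]
    )
    theta = nbglm._THETA_MAX
    fits = per_peak_fits(theta)
    for _ in range(4):
        mu_all = np.concatenate([fits[i].fitted for i in nonzero])
        resid_df = float(sum(fits[i].n_obs - fits[i].df_model for i in nonzero))
        sq = (y_all - mu_all) ** 2

        def excess(log_theta):
            t = np.exp(log_theta)
            return float(np.sum(sq / (mu_all + mu_all**2 / t))) - resid_df

        # excess is increasing in theta; a root exists only when the
        # Poisson-limit residuals are larger than the residual df
        if excess(np.log(nbglm._THETA_MAX)) <= 0:
            theta_new = nbglm._THETA_MAX  # not over-dispersed
        elif excess(np.log(1e-3)) >= 0:
            theta_new = 1e-3
        else:
            theta_new = float(
                np.exp(_optimize.brentq(excess, np.log(1e-3), np.log(nbglm._THETA_MAX)))
            )
        converged = abs(np.log(theta_new) - np.log(theta)) < 1e-6
        theta = theta_new
        fits = per_peak_fits(theta)
        if converged:
            break
    log2fc = np.full(counts.n_peaks, np.nan)
    sem = np.full(counts.n_peaks, np.nan)
    pvals = np.full(counts.n_peaks, np.nan)
    for i in nonzero:
        fit = fits[i]
        if np.isnan(fit.coef[j_ct]):
            continue
        log2fc[i] = fit.coef[j_ct] / LOG2
        sem[i] = fit.se[j_ct] / LOG2
        z = fit.coef[j_ct] / fit.se[j_ct]
        pvals[i] = 2.0 * stats.norm.sf(abs(z))

    q = np.full(counts.n_peaks, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        q[ok] = bh_fdr(pvals[ok])
    frame = pd.DataFrame(
        {
            "log2_fc": log2fc,
            "sem": sem,
            "p": pvals,
            "q": q,
            "significant": q < fdr,
        },
        index=pd.Index(counts.peak_ids, name="peak_id"),
    )
    return frame


def predict_diff(
    fit: JAMSFit,
    X_a: pd.DataFrame,
    X_b: pd.DataFrame,
    drop_accessibility: bool = False,
) -> np.ndarray:
    """Model-predicted log2 fold change of TF binding, cell B vs cell A.

    ``(X_b - X_a) . beta_f / log 2`` over matched peak rows.  With
    ``drop_accessibility`` the accessibility columns are zeroed out of the
    contrast, isolating methylation/sequence-driven predictions.
    """
    if X_a.shape[0] != X_b.shape[0]:
        raise ValueError("matrices must have matched peak rows")
    cols = fit.columns
    delta = X_b[cols].to_numpy(dtype=float) - X_a[cols].to_numpy(dtype=float)
    beta = fit.beta_f.fillna(0.0).to_numpy().copy()
    if drop_accessibility:
        a_cols = set(fit.blocks.get("A", []))
        beta[[c in a_cols for c in cols]] = 0.0
    return (delta @ beta) / LOG2


def evaluate_diff(
    predicted: np.ndarray,
    observed: pd.DataFrame,
    sem_cutoff: float = DEFAULT_SEM_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR,
) -> dict[str, float]:
    """Agreement between predicted and observed differential binding.

    Pearson r over (i) peaks with log2-fc SEM below ``sem_cutoff`` and
    (ii) the significant subset (q < ``fdr_cutoff``), plus sign-agreement
    accuracy on subset (ii).  Metrics on subsets with < 3 peaks are NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape[0] != len(observed):
        raise ValueError("predicted length must match observed peaks")
    lfc = observed["log2_fc"].to_numpy()
    estimable = ~np.isnan(lfc)
    low_sem = estimable & (observed["sem"].to_numpy() < sem_cutoff)
    sig = low_sem & observed["significant"].to_numpy(dtype=bool)

    out: dict[str, float] = {
        "n_low_sem": int(low_sem.sum()),
        "n_significant": int(sig.sum()),
    }
    out["r_low_sem"] = (
        float(stats.pearsonr(predicted[low_sem], lfc[low_sem])[0])
        if low_sem.sum() >= 3
        else np.nan
    )
    if sig.sum() >= 3:
        out["r_significant"] = float(stats.pearsonr(predicted[sig], lfc[sig])[0])
        agree = np.sign(predicted[sig]) == np.sign(lfc[sig])
        out["sign_accuracy"] = float(np.mean(agree))
    else:
        out["r_significant"] = np.nan
        out["sign_accuracy"] = np.nan
    return out
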