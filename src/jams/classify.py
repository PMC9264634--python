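"""Per-TF methyl-preference calls and model quality control.

A fitted occupancy model yields, for every motif position where a CpG is
prevalent enough (>= 10% of peaks by default), the TF-specific methylation
coefficient with its Wald test and a Benjamini-Hochberg q-value computed
across those positions.  TFs are then classified five ways by the
direction of significant (q < 1e-5) intra-motif methylation effects:

- methyl-minus: at least one significantly negative effect, none positive
- methyl-plus:  at least one significantly positive effect, none negative
- mixed-effect: both directions significant
- no-effect:    CpG-bearing motif, nothing significant
- no-CpG:       no motif position carries a prevalent CpG

Model QC applies four criteria: enough training peaks, out-of-fold
predictive correlation, agreement of the learned TF-specific sequence
coefficients with the known motif, and low leakage of sequence signal into
the background coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PFM
from .model import JAMSFit, PredictionResult

__all__ = [
    "MethylEffectTable",
    "TFClassification",
    "QCResult",
    "bh_fdr",
    "methyl_effect_table",
    "call_class",
    "qc_model",
    "confusion_concordance",
]

FDR_CLASSIFY = 1e-5
PREVALENCE_THRESHOLD = 0.10


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in input order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class MethylEffectTable:
    """Per-qualifying-position methylation effect estimates.

    ``frame`` columns: position, estimate, se, z, p, q, prevalence,
    signed_log10_p.
    """

    frame: pd.DataFrame

    def significant(self, fdr: float = FDR_CLASSIFY) -> pd.DataFrame:
        return self.frame[self.frame["q"] < fdr]


def methyl_effect_table(
    fit: JAMSFit,
    prevalence_threshold: float = PREVALENCE_THRESHOLD,
    cpg_prevalence: pd.Series | None = None,
) -> MethylEffectTable:
    """TF-specific methylation effects at positions with a prevalent CpG.

    ``cpg_prevalence`` (per M column, fraction of peaks carrying a CpG)
    normally comes from the design matrix used to fit the model; BH
    correction is applied across the qualifying positions only.
    """
    m_cols = fit.blocks.get("M", [])
    if not m_cols:
        raise ValueError("model has no methylation (M) block")
    rows = []
    for c in m_cols:
        prevalence = (
            float(cpg_prevalence[c])
            if cpg_prevalence is not None and c in cpg_prevalence
            else np.nan
        )
        if not np.isnan(prevalence) and prevalence < prevalence_threshold:
            continue
        est = fit.table.loc[c, "f"]
        se = fit.table.loc[c, "f_se"]
        if np.isnan(est):
            continue  # aliased (e.g. all-zero methylation column)
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            dict(
                position=int(c.rsplit("pos", 1)[1]),
                estimate=float(est),
                se=float(se),
                z=float(z),
                p=float(p),
                prevalence=prevalence,
            )
        )
    frame = pd.DataFrame(
        rows, columns=["position", "estimate", "se", "z", "p", "prevalence"]
    )
    if len(frame):
        frame["q"] = bh_fdr(frame["p"].to_numpy())
        with np.errstate(divide="ignore"):
            logp = -np.log10(np.maximum(frame["p"].to_numpy(), 1e-300))
        frame["signed_log10_p"] = np.sign(frame["estimate"].to_numpy()) * logp
    else:
        frame["q"] = pd.Series(dtype=float)
        frame["signed_log10_p"] = pd.Series(dtype=float)
    return MethylEffectTable(frame=frame.reset_index(drop=True))


@dataclass
class TFClassification:
    category: str  # methyl-minus | methyl-plus | mixed-effect | no-effect | no-CpG
    positive_positions: list[int]
    negative_positions: list[int]
    qc_pass: bool | None = None
    qc_reasons: list[str] = field(default_factory=list)


def call_class(
    table: MethylEffectTable, fdr: float = FDR_CLASSIFY
) -> TFClassification:
    """Five-way methyl-preference call from the effect table."""
    if len(table.frame) == 0:
        return TFClassification("no-CpG", [], [])
    sig = table.significant(fdr)
    pos = sorted(int(r.position) for r in sig.itertuples() if r.estimate > 0)
    neg = sorted(int(r.position) for r in sig.itertuples() if r.estimate < 0)
    if pos and neg:
        category = "mixed-effect"
    elif neg:
        category = "methyl-minus"
    elif pos:
        category = "methyl-plus"
    else:
        category = "no-effect"
    return TFClassification(category, pos, neg)


@dataclass
class QCResult:
    passed: bool
    enough_peaks: bool
    cv_correlation_ok: bool
    motif_correlation_ok: bool
    background_ratio_ok: bool
    motif_correlation: float
    background_ratio: float
    reasons: list[str]


def _sequence_coef_matrix(fit: JAMSFit) -> np.ndarray:
    """TF-specific sequence coefficients as an L x 4 matrix.

    The per-position reference base (all-zero contrast) gets coefficient 0;
    each row is then mean-centered so the comparison with the known motif
    is invariant to the contrast choice.
    """
    if fit.spec is None:
        raise ValueError("fit carries no feature spec")
    L = fit.spec.motif_length
    out = np.zeros((L, 4))
    for c in fit.blocks.get("S", []):
        stem, base = c.rsplit("_", 1)
        p = int(stem.split("pos")[1])
        coef = fit.table.loc[c, "f"]
        out[p, "ACGT".index(base)] = 0.0 if np.isnan(coef) else coef
    return out - out.mean(axis=1, keepdims=True)


def _background_sequence_ratio(fit: JAMSFit) -> float:
    """mean |beta_b,S| / mean |beta_f,S| over estimable sequence columns."""
    s_cols = fit.blocks.get("S", [])
    b = fit.table.loc[s_cols, "b"].to_numpy(dtype=float)
    f = fit.table.loc[s_cols, "f"].to_numpy(dtype=float)
    ok = ~(np.isnan(b) | np.isnan(f))
    denom = float(np.mean(np.abs(f[ok])))
    if denom == 0:
        return np.inf
    return float(np.mean(np.abs(b[ok]))) / denom


def qc_model(
    fit: JAMSFit,
    cv: PredictionResult,
    known_pfm: PFM,
    min_peaks: int = 10_000,
    min_cv_r: float = 0.2,
    min_motif_r: float = 0.3,
    max_background_ratio: float = 0.4,
    pfm_pseudo: float = 0.01,
) -> QCResult:
    """Four-criterion model QC.

    (i) at least ``min_peaks`` training peaks; (ii) cross-validated
    Pearson r > ``min_cv_r``; (iii) Pearson r > ``min_motif_r`` between the
    TF-specific sequence coefficients and the mean-centered log
    frequencies of the known motif, over all (position, base) entries;
    (iv) mean |background| / mean |TF-specific| sequence coefficient
    magnitude < ``max_background_ratio``.
    """
    if len(known_pfm) != (fit.spec.motif_length if fit.spec else -1):
        raise ValueError("known PFM length does not match the model's motif")
    coefs = _sequence_coef_matrix(fit)
    logf = np.log(known_pfm.matrix * (1 - 4 * pfm_pseudo) + pfm_pseudo)
    logf = logf - logf.mean(axis=1, keepdims=True)
    motif_r = float(stats.pearsonr(coefs.ravel(), logf.ravel())[0])
    ratio = _background_sequence_ratio(fit)

    enough = fit.k >= min_peaks
    cv_ok = cv.r > min_cv_r
    motif_ok = motif_r > min_motif_r
    ratio_ok = ratio < max_background_ratio
    reasons = []
    if not enough:
        reasons.append(f"only {fit.k} training peaks (need {min_peaks})")
    if not cv_ok:
        reasons.append(f"cross-validated r = {cv.r:.3f} (need > {min_cv_r})")
    if not motif_ok:
        reasons.append(f"motif correlation = {motif_r:.3f} (need > {min_motif_r})")
    if not ratio_ok:
        reasons.append(
            f"background/TF sequence ratio = {ratio:.3f} (need < {max_background_ratio})"
        )
    return QCResult(
        passed=enough and cv_ok and motif_ok and ratio_ok,
        enough_peaks=enough,
        cv_correlation_ok=cv_ok,
        motif_correlation_ok=motif_ok,
        background_ratio_ok=ratio_ok,
        motif_correlation=motif_r,
        background_ratio=ratio,
        reasons=reasons,
    )


def confusion_concordance(confusion: pd.DataFrame) -> dict[str, float]:
    """Concordance summaries of an in-vivo vs in-vitro call confusion matrix.

    ``confusion`` has in-vitro (reference) calls as rows and in-vivo calls
    as columns, entries are TF counts.  Following the convention that a
    mixed-effect call agrees with either single-direction call:

    - ``minus_precision``: of TFs called methyl-minus in vivo (with
      reference data), the fraction whose reference call is methyl-minus
      or mixed-effect; likewise ``plus_precision``.
    - ``minus_recall`` / ``plus_recall``: of reference methyl-minus (plus)
      TFs, the fraction called methyl-minus (plus) or mixed-effect in vivo.

    All values are percentages.
    """

    def col_total(call):
        return confusion[call].sum() if call in confusion.columns else 0

    def cell(ref, call):
        if ref in confusion.index and call in confusion.columns:
            return confusion.loc[ref, call]
        return 0

    out = {}
    for direction in ("minus", "plus"):
        call = f"methyl-{direction}"
        total = col_total(call)
        agree = cell(call, call) + cell("mixed-effect", call)
        out[f"{direction}_precision"] = 100.0 * agree / total if total else np.nan
        ref_total = confusion.loc[call].sum() if call in confusion.index else 0
        captured = cell(call, call) + cell(call, "mixed-effect")
        out[f"{direction}_recall"] = (
            100.0 * captured / ref_total if ref_total else np.nan
        )
    return out
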