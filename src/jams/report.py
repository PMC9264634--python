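"""Model reports: coefficient tables, dot-plot data and motif logos.

The logo renders the TF-specific sequence coefficients as letter heights
(per position, letters stack by coefficient magnitude after centering on
the reference base), with arrows marking the methylation effect at CpG
positions and dumbbell marks where the effect is FDR-significant.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.text import TextPath
from matplotlib.transforms import Affine2D

from .classify import FDR_CLASSIFY, MethylEffectTable, TFClassification
from .model import JAMSFit

__all__ = ["dot_plot_data", "export_model_report", "draw_logo"]

_LETTER_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def _coef_matrix(fit: JAMSFit, which: str) -> np.ndarray:
    """L x 4 (position, base) coefficients; reference base = 0, rows centered."""
    L = fit.spec.motif_length
    out = np.zeros((L, 4))
    for c in fit.blocks.get("S", []):
        stem, base = c.rsplit("_", 1)
        p = int(stem.split("pos")[1])
        coef = fit.table.loc[c, which]
        out[p, "ACGT".index(base)] = 0.0 if np.isnan(coef) else coef
    return out - out.mean(axis=1, keepdims=True)


def dot_plot_data(
    fit: JAMSFit, table: MethylEffectTable, fdr: float = FDR_CLASSIFY
) -> dict:
    """Serializable dot-plot payload: per-(position, base) coefficients and
    per-CpG-position methylation effects with signed log10 p and an
    FDR-significance flag."""
    coefs = _coef_matrix(fit, "f")
    seq = [
        {
            "position": p,
            "base": b,
            "coefficient": float(coefs[p, j]),
        }
        for p in range(coefs.shape[0])
        for j, b in enumerate("ACGT")
    ]
    meth = [
        {
            "position": int(r.position),
            "estimate": float(r.estimate),
            "se": float(r.se),
            "p": float(r.p),
            "q": float(r.q),
            "prevalence": None if np.isnan(r.prevalence) else float(r.prevalence),
            "signed_log10_p": float(r.signed_log10_p),
            "significant": bool(r.q < fdr),
        }
        for r in table.frame.itertuples()
    ]
    return {"sequence": seq, "methylation": meth, "fdr": fdr}


def draw_logo(
    fit: JAMSFit,
    table: MethylEffectTable,
    path,
    fdr: float = FDR_CLASSIFY,
) -> None:
    """Render the coefficient logo with methylation arrows to an image file."""
    coefs = _coef_matrix(fit, "f")
    L = coefs.shape[0]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * L), 3))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for p in range(L):
        pos_parts = sorted(
            [(b, coefs[p, j]) for j, b in enumerate("ACGT") if coefs[p, j] > 0],
            key=lambda x: x[1],
        )
        y = 0.0
        for b, h in pos_parts:
            _stack_letter(ax, b, p, y, h, font)
            y += h
        neg_parts = sorted(
            [(b, coefs[p, j]) for j, b in enumerate("ACGT") if coefs[p, j] < 0],
            key=lambda x: -x[1],
        )
        y = 0.0
        for b, h in neg_parts:
            _stack_letter(ax, b, p, y + h, -h, font)
            y += h
    for r in table.frame.itertuples():
        color = "#D62839" if r.estimate > 0 else "#255C99"
        ax.annotate(
            "",
            xy=(r.position + 0.5, r.estimate),
            xytext=(r.position + 0.5, 0.0),
            arrowprops=dict(arrowstyle="-|>", color=color,
                            lw=2.5 if r.q < fdr else 1.0),
        )
        if r.q < fdr:
            ax.plot(
                [r.position + 0.35, r.position + 1.35],
                [0, 0], "o-", color=color, markersize=5,
            )
    lim = max(1.0, np.abs(coefs).sum(axis=1).max())
    ax.set_xlim(0, L)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xticks(np.arange(L) + 0.5)
    ax.set_xticklabels([str(p + 1) for p in range(L)])
    ax.set_xlabel("motif position")
    ax.set_ylabel("TF-specific coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stack_letter(ax, base, x, y, height, font):
    tp = TextPath((0, 0), base, size=1.0, prop=font)
    bb = tp.get_extents()
    scale_x = 0.9 / bb.width
    scale_y = height / bb.height
    transform = (
        Affine2D()
        .translate(-bb.x0, -bb.y0)
        .scale(scale_x, scale_y)
        .translate(x + 0.05, y)
    )
    ax.add_patch(
        PathPatch(transform.transform_path(tp), fc=_LETTER_COLORS[base], ec="none")
    )


def export_model_report(
    fit: JAMSFit,
    table: MethylEffectTable,
    classification: TFClassification | None,
    out_dir,
    fdr: float = FDR_CLASSIFY,
) -> dict[str, str]:
    """Write the coefficient TSV, dot-plot JSON and logo image.

    Returns {artifact: path}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coefficients": out_dir / "coefficients.tsv",
        "dotplot": out_dir / "dotplot.json",
        "logo": out_dir / "logo.png",
    }
    coef = fit.table.copy()
    coef.index.name = "column"
    coef.to_csv(paths["coefficients"], sep="\t")

    payload = dot_plot_data(fit, table, fdr)
    if classification is not None:
        payload["classification"] = {
            "category": classification.category,
            "positive_positions": classification.positive_positions,
            "negative_positions": classification.negative_positions,
        }
    with open(paths["dotplot"], "w") as fh:
        json.dump(payload, fh, indent=1)

    draw_logo(fit, table, paths["logo"], fdr)
    return {k: str(v) for k, v in paths.items()}
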