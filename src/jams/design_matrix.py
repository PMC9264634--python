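"""Assembly of the k x m feature matrix X = [X_A X_M X_S X_RS X_RM].

Column blocks
-------------
A   eleven log-accessibility bin means (five 200-bp bins upstream of the
    motif, the motif bin, five downstream), log-transformed with a
    dataset-wide pseudocount of 1% of the smallest strictly-positive bin
    mean.
M   one column per motif position: the CpG methylation fraction of the CpG
    whose C maps to that position, 0 where the peak has no CpG there.  The
    coefficient is then the effect of full methylation at a CpG-bearing
    site.
S   contrast-coded sequence over the motif: per position, three indicator
    columns for the non-reference bases; the reference base is the PFM
    consensus, so an all-zero triple means the consensus base was observed.
    (Full one-hot plus an intercept is rank-deficient; contrast coding
    makes identifiability explicit.)
RS  flank base composition: fractions of C, G, T over the 40 flanking bp
    (A is the dropped reference).
RM  mean CpG methylation fraction over flank CpGs.

Peaks whose mean WGBS coverage over motif CpG positions is below the
coverage cutoff (default 10) are removed; peaks with no motif CpG are
exempt — the filter is only meaningful where CpGs exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PFM
from .motif_align import PeakView

__all__ = ["FeatureSpec", "DesignMatrix", "assemble", "encode_sequence",
           "methyl_columns", "accessibility_columns", "regional_columns"]

BLOCKS = ("A", "M", "S", "RS", "RM")


@dataclass
class FeatureSpec:
    """Encoding choices for the design matrix."""

    motif_length: int
    reference_bases: str  # per-position reference (PFM consensus)
    coverage_cutoff: float = 10.0
    access_pseudocount: float | None = None  # computed dataset-wide if None
    use_blocks: tuple[str, ...] = BLOCKS

    def __post_init__(self):
        if len(self.reference_bases) != self.motif_length:
            raise ValueError("reference_bases length must equal motif_length")
        unknown = set(self.use_blocks) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks {sorted(unknown)}")
        if self.access_pseudocount is not None and self.access_pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @classmethod
    def from_pfm(cls, pfm: PFM, **kwargs) -> "FeatureSpec":
        return cls(motif_length=len(pfm), reference_bases=pfm.consensus(), **kwargs)


@dataclass
class DesignMatrix:
    """Feature matrix with named, block-labelled columns and carried counts."""

    X: pd.DataFrame  # index = peak ids
    blocks: dict[str, list[str]]  # block label -> column names
    pulldown: np.ndarray
    control: np.ndarray
    spec: FeatureSpec
    dropped: dict[str, int] = field(default_factory=dict)
    cpg_prevalence: pd.Series | None = None  # per M column

    @property
    def k(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset_rows(self, idx) -> "DesignMatrix":
        return DesignMatrix(
            X=self.X.iloc[idx],
            blocks=self.blocks,
            pulldown=self.pulldown[idx],
            control=self.control[idx],
            spec=self.spec,
            dropped=dict(self.dropped),
            cpg_prevalence=self.cpg_prevalence,
        )

    def drop_block(self, block: str) -> "DesignMatrix":
        """Design with one block removed (e.g. the reduced no-methylation model)."""
        if block not in self.blocks:
            raise KeyError(f"no block {block!r}")
        keep = [c for c in self.X.columns if c not in set(self.blocks[block])]
        blocks = {b: cols for b, cols in self.blocks.items() if b != block}
        return DesignMatrix(
            X=self.X[keep],
            blocks=blocks,
            pulldown=self.pulldown,
            control=self.control,
            spec=self.spec,
            dropped=dict(self.dropped),
            cpg_prevalence=None if block == "M" else self.cpg_prevalence,
        )

    def to_tsv(self, path) -> None:
        """Serialize with a block-annotation header line."""
        labels = {c: b for b, cols in self.blocks.items() for c in cols}
        with open(path, "w") as fh:
            fh.write(
                "#blocks\t" + "\t".join(labels[c] for c in self.X.columns) + "\t-\t-\n"
            )
            out = self.X.copy()
            out["pulldown"] = self.pulldown
            out["control"] = self.control
            out.to_csv(fh, sep="\t", index_label="peak_id")


def encode_sequence(view: PeakView, spec: FeatureSpec) -> np.ndarray:
    """S-block row: 3 indicators per position for the non-reference bases."""
    L = spec.motif_length
    if "N" in view.motif_seq:
        raise ValueError(f"peak {view.peak_id}: N in motif sequence")
    row = np.zeros(3 * L)
    for p, (obs, ref) in enumerate(zip(view.motif_seq, spec.reference_bases)):
        others = [b for b in "ACGT" if b != ref]
        if obs != ref:
            row[3 * p + others.index(obs)] = 1.0
    return row


def _sequence_column_names(spec: FeatureSpec) -> list[str]:
    names = []
    for p, ref in enumerate(spec.reference_bases):
        for b in "ACGT":
            if b != ref:
                names.append(f"S_pos{p:02d}_{b}")
    return names


def methyl_columns(view: PeakView, spec: FeatureSpec) -> np.ndarray:
    """M-block row: methylation fraction per motif position, 0 without CpG.

    A CpG with zero WGBS coverage has an undefined fraction and also
    contributes 0.
    """
    frac = np.nan_to_num(view.methylation, nan=0.0)
    return np.clip(frac, 0.0, 1.0)


def accessibility_columns(view: PeakView, spec: FeatureSpec) -> np.ndarray:
    """A-block row: log(bin mean + pseudocount) for the 11 oriented bins."""
    if np.any(view.accessibility < 0):
        raise ValueError(f"peak {view.peak_id}: negative accessibility signal")
    if spec.access_pseudocount is None:
        raise ValueError("access_pseudocount not set; call assemble first")
    return np.log(view.accessibility + spec.access_pseudocount)


def regional_columns(view: PeakView) -> np.ndarray:
    """RS+RM row: flank C, G, T fractions (A = reference) and flank methylation."""
    comp = view.flank_composition
    return np.array([comp[1], comp[2], comp[3], view.flank_methylation])


def _passes_coverage(view: PeakView, cutoff: float) -> bool:
    pos = view.cpg_positions()
    if pos.size == 0:
        return True  # CpG-free peaks are exempt
    return float(np.mean(view.meth_coverage[pos])) >= cutoff


def assemble(views: list[PeakView], spec: FeatureSpec) -> DesignMatrix:
    """Build the design matrix from aligned peak views.

    Applies the motif-CpG coverage filter and computes the dataset-wide
    accessibility pseudocount (1% of the smallest strictly-positive bin
    mean over the surviving peaks) unless the spec already carries one —
    a spec from a trained model reuses its training pseudocount so
    transferred features stay on the same scale.
    """
    if not views:
        raise ValueError("no peak views provided")
    L = spec.motif_length
    for v in views:
        if v.motif_length != L:
            raise ValueError("all views must share the spec motif length")

    dropped: dict[str, int] = {}
    kept = []
    for v in views:
        if not _passes_coverage(v, spec.coverage_cutoff):
            dropped["low_motif_cpg_coverage"] = (
                dropped.get("low_motif_cpg_coverage", 0) + 1
            )
        else:
            kept.append(v)
    if not kept:
        raise ValueError("no peaks survive the coverage filter")

    if spec.access_pseudocount is None and "A" in spec.use_blocks:
        acc = np.concatenate([v.accessibility for v in kept])
        positive = acc[acc > 0]
        if positive.size == 0:
            spec.access_pseudocount = 1e-2  # fully flat signal: arbitrary scale
        else:
            spec.access_pseudocount = 0.01 * float(positive.min())

    columns: list[str] = []
    blocks: dict[str, list[str]] = {}
    parts: list[np.ndarray] = []

    def add_block(label: str, names: list[str], rows: np.ndarray) -> None:
        blocks[label] = names
        columns.extend(names)
        parts.append(rows)

    if "A" in spec.use_blocks:
        names = (
            [f"A_up{j}" for j in range(5, 0, -1)]
            + ["A_motif"]
            + [f"A_dn{j}" for j in range(1, 6)]
        )
        add_block("A", names, np.array([accessibility_columns(v, spec) for v in kept]))
    if "M" in spec.use_blocks:
        names = [f"M_pos{p:02d}" for p in range(L)]
        add_block("M", names, np.array([methyl_columns(v, spec) for v in kept]))
    if "S" in spec.use_blocks:
        add_block(
            "S",
            _sequence_column_names(spec),
            np.array([encode_sequence(v, spec) for v in kept]),
        )
    regional = np.array([regional_columns(v) for v in kept])
    if "RS" in spec.use_blocks:
        add_block("RS", ["RS_C", "RS_G", "RS_T"], regional[:, :3])
    if "RM" in spec.use_blocks:
        add_block("RM", ["RM"], regional[:, 3:])

    X = pd.DataFrame(
        np.hstack(parts), columns=columns, index=[v.peak_id for v in kept]
    )
    if X.isna().to_numpy().any():
        raise ValueError("design matrix contains missing values")

    prevalence = None
    if "M" in spec.use_blocks:
        has = np.array([v.has_cpg for v in kept], dtype=float)
        prevalence = pd.Series(has.mean(axis=0), index=blocks["M"])

    return DesignMatrix(
        X=X,
        blocks=blocks,
        pulldown=np.array([v.pulldown_count for v in kept], dtype=np.int64),
        control=np.array([v.control_count for v in kept], dtype=np.int64),
        spec=spec,
        dropped=dropped,
        cpg_prevalence=prevalence,
    )
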