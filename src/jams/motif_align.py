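"""Motif-anchored peak alignment.

Each ChIP-seq peak is aligned by locating the best log-odds match of the
TF's known motif near the peak summit, orienting the peak so position 1 of
every view is the motif's 5' end, and extracting the windows the occupancy
model consumes: the motif sequence, 20-bp flanks, per-position CpG
methylation, and eleven 200-bp accessibility bins (five upstream of the
motif start, the motif interval itself, five downstream of the motif end).

CpG methylation calls from the two strands of one CpG dinucleotide (the C
and, one base downstream, the G position) are summed before computing the
methylation fraction: CpG methylation is symmetric and merging maximizes
coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import PFM, CpGTable, GenomeSequence, PeakRecord, SignalTrack

__all__ = [
    "MotifHit",
    "PeakView",
    "pwm_from_pfm",
    "scan_best_hit",
    "build_peak_view",
    "align_peaks",
    "reverse_complement",
    "AlignmentReport",
]

logger = logging.getLogger(__name__)

FLANK_BP = 20
ACCESS_BIN_BP = 200
ACCESS_BINS_PER_SIDE = 5
SUMMIT_RANGE = 100  # hit start must lie within +/- this of the summit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """Best motif placement for one peak, relative to the summit."""

    offset: int  # hit start minus summit (genomic coordinates)
    strand: str  # '+' or '-'
    score: float


@dataclass
class PeakView:
    """One aligned peak in the motif-oriented frame."""

    peak_id: str
    chrom: str
    strand: str
    motif_start: int  # genomic, 0-based
    motif_end: int
    motif_seq: str  # oriented: position 0 is the motif 5' end
    left_flank: str  # 20 bp 5' of the motif, oriented
    right_flank: str  # 20 bp 3' of the motif, oriented
    methylation: np.ndarray  # length L; NaN where the peak has no CpG
    meth_coverage: np.ndarray  # length L; 0 where no CpG
    has_cpg: np.ndarray  # length L bool; True where the C of a CpG maps here
    accessibility: np.ndarray  # 11 oriented bin means
    flank_methylation: float  # mean fraction over flank CpGs (0 if none)
    flank_composition: np.ndarray  # fractions of A, C, G, T over 40 flank bp
    pulldown_count: int
    control_count: int

    @property
    def motif_length(self) -> int:
        return self.motif_end - self.motif_start

    def cpg_positions(self) -> np.ndarray:
        """Oriented motif positions of the C of each CpG in this peak."""
        return np.flatnonzero(self.has_cpg)


def pwm_from_pfm(pfm: PFM, pseudo_freq: float = 0.01) -> np.ndarray:
    """Log-odds scoring matrix against a uniform background.

    Each frequency is shrunk toward uniform,
    ``f' = f * (1 - 4*eps) + eps``, so every entry is finite.
    """
    if not 0 < pseudo_freq < 0.25:
        raise ValueError("pseudo_freq must be in (0, 0.25)")
    shrunk = pfm.matrix * (1.0 - 4.0 * pseudo_freq) + pseudo_freq
    return np.log(shrunk / 0.25)


def _score_all_offsets(seq: str, pwm: np.ndarray) -> np.ndarray:
    """PWM score at every start offset of ``seq`` (forward orientation).

    N contributes the minimum base score at its position.
    """
    L = pwm.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    ext = np.column_stack([pwm, pwm.min(axis=1)])  # column 4 scores N
    scores = np.zeros(n)
    for p in range(L):
        scores += ext[p, idx[p : p + n]]
    return scores


def scan_best_hit(
    genome: GenomeSequence, peak: PeakRecord, pwm: np.ndarray
) -> MotifHit:
    """Best-scoring motif placement with start within +/-100 bp of the summit.

    Both strands are scanned.  Ties break deterministically: highest score,
    then '+' strand over '-', then smallest genomic start.
    """
    L = pwm.shape[0]
    win_start = peak.summit - SUMMIT_RANGE
    win_end = peak.summit + SUMMIT_RANGE + L  # exclusive; last start = summit+100
    if win_start < 0 or win_end > genome.length(peak.chrom):
        raise ValueError(
            f"peak {peak.peak_id}: scan window [{win_start}, {win_end}) out of "
            f"bounds on {peak.chrom}"
        )
    seq = genome.fetch(peak.chrom, win_start, win_end)
    fwd = _score_all_offsets(seq, pwm)
    # score the reverse strand by scanning the reverse-complemented PWM on
    # the forward sequence: a '-' hit starting at genomic s reads
    # revcomp(seq[s:s+L]), which scores pwm reversed/complemented forward.
    rc_pwm = pwm[::-1, ::-1]
    rev = _score_all_offsets(seq, rc_pwm)
    i_fwd = int(np.argmax(fwd))  # argmax takes the first (smallest start)
    i_rev = int(np.argmax(rev))
    # '+' wins ties; the small tolerance absorbs summation-order jitter
    # between the forward and reverse-complement score accumulations
    if fwd[i_fwd] >= rev[i_rev] - 1e-9:
        return MotifHit(offset=win_start + i_fwd - peak.summit, strand="+", score=float(fwd[i_fwd]))
    return MotifHit(offset=win_start + i_rev - peak.summit, strand="-", score=float(rev[i_rev]))


def _merged_cpg_fraction(
    cpg: CpGTable, chrom: str, c_pos: int
) -> tuple[float, int]:
    """Strand-merged (fraction, coverage) for the CpG whose C is at c_pos."""
    m1, u1 = cpg.counts_at(chrom, c_pos)
    m2, u2 = cpg.counts_at(chrom, c_pos + 1)  # reverse-strand C = the G position
    meth, cov = m1 + m2, m1 + u1 + m2 + u2
    return (meth / cov if cov > 0 else float("nan")), cov


def _overlaps_mask(
    mask: dict[str, list[tuple[int, int]]] | None, chrom: str, start: int, end: int
) -> bool:
    if not mask or chrom not in mask:
        return False
    for s, e in mask[chrom]:
        if s < end and start < e:
            return True
    return False


def build_peak_view(
    genome: GenomeSequence,
    peak: PeakRecord,
    hit: MotifHit,
    cpg: CpGTable,
    access: SignalTrack,
    motif_length: int,
    mask: dict[str, list[tuple[int, int]]] | None = None,
) -> PeakView | None:
    """Extract the oriented view of one peak, or None if the peak is dropped.

    Drop reasons (logged): motif or flank window out of chromosome bounds,
    N inside the motif window, overlap with a mask interval.
    """
    L = motif_length
    g0 = peak.summit + hit.offset
    g1 = g0 + L
    chrom = peak.chrom
    span = ACCESS_BINS_PER_SIDE * ACCESS_BIN_BP
    if g0 - max(FLANK_BP, span) < 0 or g1 + max(FLANK_BP, span) > genome.length(chrom):
        logger.info("peak %s dropped: view window out of bounds", peak.peak_id)
        return None
    if _overlaps_mask(mask, chrom, g0 - FLANK_BP, g1 + FLANK_BP):
        logger.info("peak %s dropped: overlaps mask", peak.peak_id)
        return None

    fwd_motif = genome.fetch(chrom, g0, g1)
    fwd_left = genome.fetch(chrom, g0 - FLANK_BP, g0)
    fwd_right = genome.fetch(chrom, g1, g1 + FLANK_BP)
    if "N" in fwd_motif:
        logger.info("peak %s dropped: N in motif window", peak.peak_id)
        return None

    if hit.strand == "+":
        motif_seq, left, right = fwd_motif, fwd_left, fwd_right
    else:
        motif_seq = reverse_complement(fwd_motif)
        left = reverse_complement(fwd_right)
        right = reverse_complement(fwd_left)

    # Intra-motif CpG methylation: scan the oriented motif (plus one base of
    # 3' flank so a C at the last motif position still pairs with its G) for
    # CG dinucleotides; assign the strand-merged fraction to the C position.
    methylation = np.full(L, np.nan)
    coverage = np.zeros(L, dtype=np.int64)
    has_cpg = np.zeros(L, dtype=bool)
    extended = motif_seq + (right[0] if right else "")
    for p in range(L):
        if extended[p : p + 2] == "CG":
            has_cpg[p] = True
            if hit.strand == "+":
                c_gpos = g0 + p
            else:
                # oriented CpG at (p, p+1) maps to forward-strand CG whose C
                # is at g1 - 2 - p
                c_gpos = g1 - 2 - p
            frac, cov = _merged_cpg_fraction(cpg, chrom, c_gpos)
            methylation[p] = frac if cov > 0 else np.nan
            coverage[p] = cov

    # Flank methylation: mean fraction over flank CpGs with coverage.
    flank_fracs = []
    for seq_, gstart, is_rev in (
        (fwd_left, g0 - FLANK_BP, False),
        (fwd_right, g1, False),
    ):
        for p in range(len(seq_) - 1):
            if seq_[p : p + 2] == "CG":
                frac, cov = _merged_cpg_fraction(cpg, chrom, gstart + p)
                if cov > 0:
                    flank_fracs.append(frac)
    flank_meth = float(np.mean(flank_fracs)) if flank_fracs else 0.0

    flank_seq = left + right
    comp = np.array(
        [flank_seq.count(b) for b in "ACGT"], dtype=float
    )
    denom = comp.sum()
    flank_comp = comp / denom if denom > 0 else np.full(4, 0.25)

    # Accessibility: five 200-bp bins immediately upstream of the motif
    # start, the motif interval itself, five bins downstream of the motif
    # end; mirror-reordered on the '-' strand.
    bins = []
    for j in range(ACCESS_BINS_PER_SIDE, 0, -1):
        bins.append(access.mean(chrom, g0 - j * ACCESS_BIN_BP, g0 - (j - 1) * ACCESS_BIN_BP))
    bins.append(access.mean(chrom, g0, g1))
    for j in range(ACCESS_BINS_PER_SIDE):
        bins.append(access.mean(chrom, g1 + j * ACCESS_BIN_BP, g1 + (j + 1) * ACCESS_BIN_BP))
    accessibility = np.array(bins)
    if hit.strand == "-":
        accessibility = accessibility[::-1].copy()

    return PeakView(
        peak_id=peak.peak_id,
        chrom=chrom,
        strand=hit.strand,
        motif_start=g0,
        motif_end=g1,
        motif_seq=motif_seq,
        left_flank=left,
        right_flank=right,
        methylation=methylation,
        meth_coverage=coverage,
        has_cpg=has_cpg,
        accessibility=accessibility,
        flank_methylation=flank_meth,
        flank_composition=flank_comp,
        pulldown_count=peak.pulldown_count,
        control_count=peak.control_count,
    )


@dataclass
class AlignmentReport:
    """Peak-drop accounting for one alignment run."""

    n_input: int = 0
    n_aligned: int = 0
    dropped: dict = field(default_factory=dict)

    def record_drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1


def align_peaks(
    genome: GenomeSequence,
    peaks: list[PeakRecord],
    pfm: PFM,
    cpg: CpGTable,
    access: SignalTrack,
    mask: dict[str, list[tuple[int, int]]] | None = None,
    pseudo_freq: float = 0.01,
) -> tuple[list[PeakView], AlignmentReport]:
    """Scan and extract views for a full peak list, with drop accounting."""
    pwm = pwm_from_pfm(pfm, pseudo_freq)
    report = AlignmentReport(n_input=len(peaks))
    views = []
    for peak in peaks:
        try:
            hit = scan_best_hit(genome, peak, pwm)
        except ValueError:
            report.record_drop("scan_window_out_of_bounds")
            continue
        view = build_peak_view(genome, peak, hit, cpg, access, len(pfm), mask)
        if view is None:
            report.record_drop("view_dropped")
            continue
        views.append(view)
    report.n_aligned = len(views)
    return views, report
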