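"""Motif scanning and oriented peak-view extraction."""

import numpy as np
import pytest

from jams.io_formats import PFM, CpGTable, GenomeSequence, PeakRecord, SignalTrack
from jams.motif_align import (
    MotifHit,
    build_peak_view,
    pwm_from_pfm,
    reverse_complement,
    scan_best_hit,
)

import pandas as pd


def brute_force_scan(seq, pwm):
    """Independent enumeration of every placement on both strands.

    Ties break as the scanner does: '+' strand first (within 1e-9, which
    absorbs float summation-order differences), then smallest start.
    """
    L = pwm.shape[0]

    def score_at(start, strand):
        sub = seq[start : start + L]
        if strand == "-":
            sub = reverse_complement(sub)
        score = 0.0
        for p, base in enumerate(sub):
            score += pwm[p].min() if base == "N" else pwm[p, "ACGT".index(base)]
        return score

    n = len(seq) - L + 1
    plus = [score_at(s, "+") for s in range(n)]
    minus = [score_at(s, "-") for s in range(n)]
    i_plus = int(np.argmax(plus))
    i_minus = int(np.argmax(minus))
    if plus[i_plus] >= minus[i_minus] - 1e-9:
        return i_plus, "+", plus[i_plus]
    return i_minus, "-", minus[i_minus]


def embed(background, motif, offset):
    return background[:offset] + motif + background[offset + len(motif) :]


class TestPwmFromPfm:
    def test_uniform_row_scores_zero(self):
        pfm = PFM(np.full((4, 4), 0.25))
        pwm = pwm_from_pfm(pfm, 0.01)
        assert np.all(np.abs(pwm) < 1e-12)

    def test_concentrated_row_arithmetic(self):
        mat = np.full((4, 4), 0.25)
        mat[0] = [1.0, 0.0, 0.0, 0.0]
        pwm = pwm_from_pfm(PFM(mat), 0.01)
        assert pwm[0, 0] == pytest.approx(np.log(0.97 / 0.25))
        assert pwm[0, 1] == pytest.approx(np.log(0.01 / 0.25))

    def test_zero_pseudocount_rejected(self):
        mat = np.full((4, 4), 0.25)
        mat[0] = [1.0, 0.0, 0.0, 0.0]
        with pytest.raises(ValueError):
            pwm_from_pfm(PFM(mat), 0.0)
        assert np.isfinite(pwm_from_pfm(PFM(mat), 1e-6)).all()


def _genome_with(seq):
    return GenomeSequence({"chr1": seq})


class TestScanBestHit:
    def test_embedded_motif_found_on_plus(self):
        rng = np.random.default_rng(0)
        background = "".join(rng.choice(list("AT"), size=300))
        seq = embed(background, "ACGTAC", 150)
        mat = np.full((6, 4), 0.01)
        for p, b in enumerate("ACGTAC"):
            mat[p, "ACGT".index(b)] = 0.97
        pwm = pwm_from_pfm(PFM(mat))
        peak = PeakRecord("chr1", 145, 1, 1, "p1")
        hit = scan_best_hit(_genome_with(seq), peak, pwm)
        o_start, o_strand, o_score = brute_force_scan(seq[45:252], pwm)
        assert hit.strand == "+" == o_strand
        assert peak.summit + hit.offset == 150 == 45 + o_start
        assert hit.score == pytest.approx(o_score)

    def test_reverse_complement_found_on_minus(self):
        rng = np.random.default_rng(1)
        background = "".join(rng.choice(list("AT"), size=300))
        seq = embed(background, reverse_complement("ACGTAC"), 140)
        mat = np.full((6, 4), 0.01)
        for p, b in enumerate("ACGTAC"):
            mat[p, "ACGT".index(b)] = 0.97
        pwm = pwm_from_pfm(PFM(mat))
        peak = PeakRecord("chr1", 145, 1, 1, "p1")
        hit = scan_best_hit(_genome_with(seq), peak, pwm)
        o_start, o_strand, _ = brute_force_scan(seq[45:252], pwm)
        assert hit.strand == "-" == o_strand
        assert peak.summit + hit.offset == 140 == 45 + o_start

    def test_all_ties_leftmost_plus(self):
        mat = np.full((4, 4), 0.25)
        pwm = pwm_from_pfm(PFM(mat))
        seq = "A" * 400
        peak = PeakRecord("chr1", 200, 1, 1, "p1")
        hit = scan_best_hit(_genome_with(seq), peak, pwm)
        assert hit.strand == "+"
        assert hit.offset == -100  # leftmost allowed placement

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(7)
        mat = rng.dirichlet(np.ones(4) * 0.4, size=5)
        pwm = pwm_from_pfm(PFM(mat))
        for trial in range(10):
            seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            peak = PeakRecord("chr1", 150, 1, 1, f"p{trial}")
            hit = scan_best_hit(_genome_with(seq), peak, pwm)
            win = seq[50 : 255]
            o_start, o_strand, o_score = brute_force_scan(win, pwm)
            assert hit.score == pytest.approx(o_score)
            assert hit.strand == o_strand
            assert peak.summit + hit.offset == 50 + o_start

    def test_out_of_bounds_window_raises(self):
        mat = np.full((4, 4), 0.25)
        pwm = pwm_from_pfm(PFM(mat))
        with pytest.raises(ValueError, match="out of bounds"):
            scan_best_hit(_genome_with("ACGT" * 30), PeakRecord("chr1", 50, 1, 1, "p"), pwm)


def _small_context(seq, cpg_rows=(), track_rows=()):
    genome = GenomeSequence({"chr1": seq})
    frame = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "meth", "unmeth"]) if cpg_rows else pd.DataFrame(
        {"chrom": [], "pos": [], "meth": [], "unmeth": []}
    )
    cpg = CpGTable(frame)
    track = SignalTrack.from_lists(list(track_rows)) if track_rows else SignalTrack({})
    return genome, cpg, track


class TestBuildPeakView:
    L = 6

    def _setting(self, motif="ACCGTA", strand_seq=None):
        # motif has a CpG with C at oriented position 2
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AT"), size=4000))
        g0 = 2000
        insert = motif if strand_seq is None else strand_seq
        seq = seq[:g0] + insert + seq[g0 + len(insert) :]
        return seq, g0

    def test_plus_strand_cpg_merged_fraction(self):
        seq, g0 = self._setting()
        # forward C at g0+2, reverse C (the G) at g0+3: 8 meth / 2 unmeth total
        genome, cpg, track = _small_context(
            seq,
            cpg_rows=[("chr1", g0 + 2, 5, 1), ("chr1", g0 + 3, 3, 1)],
        )
        peak = PeakRecord("chr1", g0, 1, 1, "p")
        view = build_peak_view(genome, peak, MotifHit(0, "+", 1.0), cpg, track, self.L)
        assert view.motif_seq == "ACCGTA"
        assert view.has_cpg[2]
        assert view.meth_coverage[2] == 10
        assert view.methylation[2] == pytest.approx(0.8)

    def test_minus_strand_view_is_reverse_complemented(self):
        motif = "ACCGTA"
        seq, g0 = self._setting(strand_seq=reverse_complement(motif))
        genome, cpg, track = _small_context(
            seq, cpg_rows=[("chr1", g0 + 2, 9, 1), ("chr1", g0 + 3, 0, 0)]
        )
        peak = PeakRecord("chr1", g0, 1, 1, "p")
        view = build_peak_view(genome, peak, MotifHit(0, "-", 1.0), cpg, track, self.L)
        assert view.motif_seq == motif
        # forward-strand CG at g0+2 maps to oriented position L-2-2 = 2
        assert view.has_cpg[2]
        assert view.methylation[2] == pytest.approx(0.9)

    def test_mask_overlap_drops_peak(self):
        seq, g0 = self._setting()
        genome, cpg, track = _small_context(seq)
        peak = PeakRecord("chr1", g0, 1, 1, "p")
        mask = {"chr1": [(g0 - 5, g0 + 1)]}
        assert build_peak_view(genome, peak, MotifHit(0, "+", 1.0), cpg, track, self.L, mask) is None

    def test_n_in_motif_drops_peak(self):
        seq, g0 = self._setting(strand_seq="ACNGTA")
        genome, cpg, track = _small_context(seq)
        peak = PeakRecord("chr1", g0, 1, 1, "p")
        assert build_peak_view(genome, peak, MotifHit(0, "+", 1.0), cpg, track, self.L) is None

    def test_accessibility_bins_oriented_and_mirrored(self):
        seq, g0 = self._setting()
        g1 = g0 + self.L
        rows = []
        for j in range(5):
            rows.append(("chr1", g0 - (5 - j) * 200, g0 - (4 - j) * 200, float(j + 1)))
        rows.append(("chr1", g0, g1, 100.0))
        for j in range(5):
            rows.append(("chr1", g1 + j * 200, g1 + (j + 1) * 200, float(10 + j)))
        genome, cpg, track = _small_context(seq, track_rows=rows)
        peak = PeakRecord("chr1", g0, 1, 1, "p")
        plus = build_peak_view(genome, peak, MotifHit(0, "+", 1.0), cpg, track, self.L)
        assert plus.accessibility == pytest.approx(
            [1, 2, 3, 4, 5, 100, 10, 11, 12, 13, 14]
        )
        minus = build_peak_view(genome, peak, MotifHit(0, "-", 1.0), cpg, track, self.L)
        assert minus.accessibility == pytest.approx(
            [14, 13, 12, 11, 10, 100, 5, 4, 3, 2, 1]
        )
        assert len(plus.accessibility) == 11

    def test_strand_symmetry_full_view(self):
        """Reverse-complementing the genome and flipping tracks yields the
        same oriented view with the opposite strand label."""
        motif = "ACCGTA"
        seq, g0 = self._setting()
        n = len(seq)
        g1 = g0 + self.L
        cpg_rows = [("chr1", g0 + 2, 5, 1), ("chr1", g0 + 3, 3, 1)]
        track_rows = [("chr1", g0 - 200, g0, 2.0), ("chr1", g1, g1 + 200, 7.0)]
        genome, cpg, track = _small_context(seq, cpg_rows, track_rows)
        peak = PeakRecord("chr1", g0, 3, 4, "p")
        fwd = build_peak_view(genome, peak, MotifHit(0, "+", 1.0), cpg, track, self.L)

        rc_seq = reverse_complement(seq)
        rc_g0 = n - g1
        rc_cpg = [("chr1", n - 1 - (g0 + 3), 3, 1), ("chr1", n - 1 - (g0 + 2) , 5, 1)]
        rc_track = [
            ("chr1", n - (g1 + 200), n - g1, 7.0),
            ("chr1", n - g0, n - (g0 - 200), 2.0),
        ]
        genome2, cpg2, track2 = _small_context(rc_seq, rc_cpg, rc_track)
        peak2 = PeakRecord("chr1", rc_g0, 3, 4, "p")
        rev = build_peak_view(genome2, peak2, MotifHit(0, "-", 1.0), cpg2, track2, self.L)

        assert rev.strand == "-" and fwd.strand == "+"
        assert rev.motif_seq == fwd.motif_seq
        assert rev.left_flank == fwd.left_flank
        assert rev.right_flank == fwd.right_flank
        np.testing.assert_allclose(rev.accessibility, fwd.accessibility)
        np.testing.assert_array_equal(rev.meth_coverage, fwd.meth_coverage)
        np.testing.assert_allclose(
            np.nan_to_num(rev.methylation), np.nan_to_num(fwd.methylation)
        )
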