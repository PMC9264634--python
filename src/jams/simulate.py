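"""Synthetic-data generator with known ground truth.

Emulates the inputs of a TF ChIP-seq occupancy analysis — peak sequences
with an embedded motif, per-CpG bisulfite counts with binomial sampling
noise, smooth accessibility profiles, and negative-binomial pulldown and
control read counts generated from known coefficients — so that the whole
pipeline is testable without external downloads.

Two entry points:

- :func:`simulate_design` synthesizes aligned peak views in memory,
  assembles the design matrix and draws counts from the model equations;
  this is the fast path used for parameter-recovery and calibration runs.
- :func:`simulate_dataset` additionally embeds those views in a synthetic
  genome and writes the on-disk dialects (FASTA, peak count table,
  bismark coverage, bedGraph) so the reading/alignment layers can be
  exercised end to end.

Default study conditions: a 12-bp motif with CpG-capable dinucleotides at
positions 2/3 and 8/9 planted in ~60% of peaks, bimodal WGBS methylation
fractions (0.7 Beta(0.5, 8) + 0.3 Beta(8, 0.5)), per-CpG coverage
NB(mean 30, theta 5), log-normal accessibility with a bump at the motif,
count dispersion theta = 5 and a control depth of ~20 reads per peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .design_matrix import DesignMatrix, FeatureSpec, assemble
from .diffbind import ReplicatedCounts
from .io_formats import (
    PFM,
    CpGTable,
    PeakRecord,
    SignalTrack,
    write_bedgraph,
    write_cpg_coverage,
    write_peaks,
)
from .motif_align import ACCESS_BIN_BP, ACCESS_BINS_PER_SIDE, FLANK_BP, PeakView

import pandas as pd

__all__ = [
    "SimSpec",
    "SimTruth",
    "DeltaSpec",
    "TwoCellSim",
    "default_pfm",
    "default_spec",
    "simulate_views",
    "simulate_design",
    "simulate_dataset",
    "simulate_two_cells",
]

_ACCESS_PSEUDOCOUNT = 1e-3  # fixed so features transfer across contexts


def default_pfm() -> PFM:
    """A 12-bp informative motif whose consensus carries CG at 2/3 and 8/9."""
    consensus = "TACGTAAACGGT"
    mat = np.full((12, 4), 0.05)
    for p, base in enumerate(consensus):
        mat[p, "ACGT".index(base)] = 0.85
    return PFM(mat, name="simTF")


@dataclass
class SimSpec:
    """Ground-truth generating conditions for one synthetic experiment."""

    n_peaks: int
    pfm: PFM
    theta: float = 5.0  # count dispersion, shared across peaks
    s_c: float = float(np.log(20.0))  # log control depth
    s_p: float = float(np.log(20.0)) + 2.0  # log pulldown depth at the motif
    # probability of planting a CpG (forcing CG) with its C at position p
    cpg_prob: dict[int, float] = field(default_factory=lambda: {2: 0.6, 8: 0.6})
    # bimodal WGBS methylation: (weight, alpha, beta) mixture components
    meth_mix: tuple = ((0.7, 0.5, 8.0), (0.3, 8.0, 0.5))
    # shared latent methylation state within a peak (0 = independent CpGs)
    meth_peak_corr: float = 0.0
    coverage_mean: float = 30.0
    coverage_theta: float = 5.0
    access_sigma: float = 0.6
    access_peak_sd: float = 0.5
    flank_gc: float = 0.5
    beta_b: dict[str, np.ndarray] | None = None  # per block A/M/S/RS/RM
    beta_f: dict[str, np.ndarray] | None = None
    noiseless_counts: bool = False  # counts = round(lambda), for limit checks

    def __post_init__(self):
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.theta <= 0 or self.coverage_theta <= 0:
            raise ValueError("dispersions must be > 0")
        L = len(self.pfm)
        for p, prob in self.cpg_prob.items():
            if not 0 <= prob <= 1:
                raise ValueError("CpG probabilities must be in [0, 1]")
            if p + 1 >= L:
                raise ValueError(f"CpG at position {p} does not fit in the motif")
        if self.beta_b is None:
            self.beta_b = _default_beta_b(L)
        if self.beta_f is None:
            self.beta_f = _default_beta_f(L)
        for beta in (self.beta_b, self.beta_f):
            _check_beta_shapes(beta, L)

    @property
    def motif_length(self) -> int:
        return len(self.pfm)

    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec.from_pfm(
            self.pfm, coverage_cutoff=0.0, access_pseudocount=_ACCESS_PSEUDOCOUNT
        )


_ACCESS_BUMP = np.array(
    [0.0, 0.2, 0.5, 0.9, 1.4, 2.0, 1.4, 0.9, 0.5, 0.2, 0.0]
)


def _check_beta_shapes(beta: dict[str, np.ndarray], L: int) -> None:
    sizes = {"A": 11, "M": L, "S": 3 * L, "RS": 3, "RM": 1}
    for block, size in sizes.items():
        if block not in beta:
            raise ValueError(f"beta is missing block {block!r}")
        beta[block] = np.asarray(beta[block], dtype=float)
        if beta[block].shape != (size,):
            raise ValueError(f"beta[{block!r}] must have shape ({size},)")


def _default_beta_b(L: int) -> dict[str, np.ndarray]:
    return {
        "A": np.full(11, 0.05),  # weak sonication bias toward open chromatin
        "M": np.zeros(L),
        "S": np.zeros(3 * L),
        "RS": np.array([0.2, 0.2, 0.0]),
        "RM": np.array([-0.1]),
    }


def _default_beta_f(L: int) -> dict[str, np.ndarray]:
    return {
        "A": np.array([0.02, 0.04, 0.06, 0.10, 0.20, 0.50, 0.20, 0.10, 0.06, 0.04, 0.02]),
        "M": np.zeros(L),  # planted effects are set per experiment
        "S": np.full(3 * L, -1.2),  # any non-consensus base weakens binding
        "RS": np.array([0.1, 0.1, 0.0]),
        "RM": np.array([-0.3]),
    }


def beta_vector(beta: dict[str, np.ndarray], dm: DesignMatrix) -> np.ndarray:
    """True coefficient vector aligned with assembled design columns."""
    out = [np.asarray(beta[block])[: len(cols)] for block, cols in dm.blocks.items()]
    return np.concatenate(out)


@dataclass
class SimTruth:
    """Realized features and expected counts behind a simulated dataset."""

    spec: SimSpec
    views: list[PeakView]
    dm: DesignMatrix
    beta_b: np.ndarray  # aligned with dm.columns
    beta_f: np.ndarray
    lambda_c: np.ndarray
    lambda_p: np.ndarray


def _draw_methylation(
    rng: np.random.Generator, spec: SimSpec, latent_comp: int | None
) -> float:
    """One methylation fraction from the mixture.

    With peak-level correlation, each CpG copies the peak's latent mixture
    component with probability ``meth_peak_corr`` instead of drawing its
    own — nearby CpGs then share their (un)methylated state.
    """
    weights = np.array([c[0] for c in spec.meth_mix])
    weights = weights / weights.sum()
    if latent_comp is not None and rng.random() < spec.meth_peak_corr:
        idx = latent_comp
    else:
        idx = int(rng.choice(len(spec.meth_mix), p=weights))
    comp = spec.meth_mix[idx]
    return float(rng.beta(comp[1], comp[2]))


def _draw_coverage(rng: np.random.Generator, spec: SimSpec) -> int:
    theta = spec.coverage_theta
    p = theta / (theta + spec.coverage_mean)
    return int(rng.negative_binomial(theta, p))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _sample_motif(rng: np.random.Generator, spec: SimSpec) -> str:
    mat = spec.pfm.matrix
    bases = [
        "ACGT"[rng.choice(4, p=mat[p] / mat[p].sum())]
        for p in range(spec.motif_length)
    ]
    for p, prob in spec.cpg_prob.items():
        if rng.random() < prob:
            bases[p] = "C"
            bases[p + 1] = "G"
    return "".join(bases)


def _cpg_site_positions(motif: str, right0: str) -> list[int]:
    ext = motif + right0
    return [p for p in range(len(motif)) if ext[p : p + 2] == "CG"]


@dataclass
class _CpGDraw:
    fraction_drawn: float  # latent true fraction
    cov_fwd: int
    meth_fwd: int
    cov_rev: int
    meth_rev: int

    @property
    def coverage(self) -> int:
        return self.cov_fwd + self.cov_rev

    @property
    def fraction(self) -> float:
        cov = self.coverage
        return (self.meth_fwd + self.meth_rev) / cov if cov else float("nan")


def _draw_cpg(rng: np.random.Generator, spec: SimSpec, latent: float | None) -> _CpGDraw:
    f = _draw_methylation(rng, spec, latent)
    cov = _draw_coverage(rng, spec)
    cov_fwd = int(rng.binomial(cov, 0.5)) if cov else 0
    cov_rev = cov - cov_fwd
    return _CpGDraw(
        fraction_drawn=f,
        cov_fwd=cov_fwd,
        meth_fwd=int(rng.binomial(cov_fwd, f)) if cov_fwd else 0,
        cov_rev=cov_rev,
        meth_rev=int(rng.binomial(cov_rev, f)) if cov_rev else 0,
    )


def _simulate_one_view(
    spec: SimSpec, rng: np.random.Generator, peak_id: str
) -> tuple[PeakView, dict]:
    L = spec.motif_length
    motif = _sample_motif(rng, spec)
    left = _random_seq(rng, FLANK_BP, spec.flank_gc)
    right = _random_seq(rng, FLANK_BP, spec.flank_gc)
    latent = int(rng.choice(len(spec.meth_mix))) if spec.meth_peak_corr > 0 else None

    methylation = np.full(L, np.nan)
    coverage = np.zeros(L, dtype=np.int64)
    has_cpg = np.zeros(L, dtype=bool)
    draws: dict[tuple[str, int], _CpGDraw] = {}
    for p in _cpg_site_positions(motif, right[0]):
        has_cpg[p] = True
        d = _draw_cpg(rng, spec, latent)
        draws[("motif", p)] = d
        coverage[p] = d.coverage
        methylation[p] = d.fraction if d.coverage else np.nan

    flank_fracs = []
    for scope, seq in (("left", left), ("right", right)):
        for p in range(len(seq) - 1):
            if seq[p : p + 2] == "CG":
                d = _draw_cpg(rng, spec, latent)
                draws[(scope, p)] = d
                if d.coverage:
                    flank_fracs.append(d.fraction)
    flank_meth = float(np.mean(flank_fracs)) if flank_fracs else 0.0

    flank_seq = left + right
    comp = np.array([flank_seq.count(b) for b in "ACGT"], dtype=float)
    flank_comp = comp / comp.sum()

    center = rng.normal(0.0, spec.access_peak_sd)
    raw = np.exp(
        _ACCESS_BUMP + center + rng.normal(0.0, spec.access_sigma, size=11)
    )

    view = PeakView(
        peak_id=peak_id,
        chrom="chrSim",
        strand="+",
        motif_start=0,  # genomic placement assigned by the file writer
        motif_end=L,
        motif_seq=motif,
        left_flank=left,
        right_flank=right,
        methylation=methylation,
        meth_coverage=coverage,
        has_cpg=has_cpg,
        accessibility=raw,
        flank_methylation=flank_meth,
        flank_composition=flank_comp,
        pulldown_count=0,
        control_count=0,
    )
    return view, draws


def simulate_views(
    spec: SimSpec, rng: np.random.Generator
) -> tuple[list[PeakView], list[dict]]:
    """Synthesize aligned peak views (counts filled in later).

    Returns the views plus, per peak, the CpG draws keyed by oriented
    position ('motif' and 'flank' scopes) so the file writer can emit a
    consistent bisulfite coverage table.
    """
    views: list[PeakView] = []
    cpg_records: list[dict] = []
    for i in range(spec.n_peaks):
        view, draws = _simulate_one_view(spec, rng, f"peak_{i:06d}")
        views.append(view)
        cpg_records.append(draws)
    return views, cpg_records


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, theta: float, noiseless: bool
) -> np.ndarray:
    if noiseless:
        return np.round(lam).astype(np.int64)
    p = theta / (theta + lam)
    return rng.negative_binomial(theta, p).astype(np.int64)


def simulate_design(spec: SimSpec, seed: int) -> tuple[DesignMatrix, SimTruth]:
    """Fast in-memory path: views -> design matrix -> NB counts from truth."""
    rng = np.random.default_rng(seed)
    views, _ = simulate_views(spec, rng)
    dm = assemble(views, spec.feature_spec())
    bb = beta_vector(spec.beta_b, dm)
    bf = beta_vector(spec.beta_f, dm)
    X = dm.X.to_numpy(dtype=float)
    lam_c = np.exp(X @ bb + spec.s_c)
    lam_p = np.exp(X @ (bb + bf) + spec.s_p)
    control = _draw_counts(rng, lam_c, spec.theta, spec.noiseless_counts)
    pulldown = _draw_counts(rng, lam_p, spec.theta, spec.noiseless_counts)
    dm.control = control
    dm.pulldown = pulldown
    for v, c, pl in zip(views, control, pulldown):
        v.control_count = int(c)
        v.pulldown_count = int(pl)
    truth = SimTruth(
        spec=spec, views=views, dm=dm, beta_b=bb, beta_f=bf,
        lambda_c=lam_c, lambda_p=lam_p,
    )
    return dm, truth


def simulate_dataset(spec: SimSpec, out_dir, seed: int) -> tuple[dict, SimTruth]:
    """Write a complete synthetic dataset in the on-disk dialects.

    Peaks are embedded in a single synthetic chromosome with the motif
    start placed at each peak summit.  Returns ({name: path}, truth).
    The bisulfite coverage table reports the CpGs of the modeled windows
    (motif plus flanks).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    L = spec.motif_length
    span = ACCESS_BINS_PER_SIDE * ACCESS_BIN_BP
    margin = span + 200
    stride = L + 2 * margin
    if stride <= 2 * (100 + L):
        raise ValueError("motif too long for the per-peak region layout")

    views, cpg_records = simulate_views(spec, rng)

    genome_len = spec.n_peaks * stride + margin
    base = np.array(list("ACGT"))
    seq = base[rng.integers(0, 4, size=genome_len)]

    from .motif_align import _score_all_offsets, pwm_from_pfm

    pwm = pwm_from_pfm(spec.pfm)
    rc_pwm = pwm[::-1, ::-1]

    def _planted_hit_wins(g0: int, g1: int) -> bool:
        # the planted '+' placement at the summit must be the unique winner
        # of the scan under its tie rules (score, then '+', then leftmost)
        window = "".join(seq[g0 - 100 : g1 + 100])
        fwd = _score_all_offsets(window, pwm)
        rev = _score_all_offsets(window, rc_pwm)
        s = fwd[100]
        return (
            np.all(fwd[:100] < s)
            and np.all(fwd[101:] <= s)
            and np.all(rev <= s)
        )

    cov_rows = []
    bg_rows = []
    for i in range(spec.n_peaks):
        g0 = i * stride + margin  # motif start = summit
        g1 = g0 + L

        # Guarantee the planted instance is the best motif match near the
        # summit: redraw the scan-window background (and, if the sampled
        # motif instance is too weak to ever win, the peak itself) until
        # the scan would return the planted placement.
        for view_try in range(8):
            view, draws = views[i], cpg_records[i]
            seq[g0:g1] = list(view.motif_seq)
            seq[g0 - FLANK_BP : g0] = list(view.left_flank)
            seq[g1 : g1 + FLANK_BP] = list(view.right_flank)
            ok = False
            for _ in range(25):
                if _planted_hit_wins(g0, g1):
                    ok = True
                    break
                seq[g0 - 100 : g0 - FLANK_BP] = base[
                    rng.integers(0, 4, size=100 - FLANK_BP)
                ]
                seq[g1 + FLANK_BP : g1 + 100] = base[
                    rng.integers(0, 4, size=100 - FLANK_BP)
                ]
            if ok:
                break
            views[i], cpg_records[i] = _simulate_one_view(spec, rng, view.peak_id)
        else:
            raise RuntimeError(
                f"could not embed a dominant motif instance for {view.peak_id}"
            )
        view, draws = views[i], cpg_records[i]
        view.motif_start, view.motif_end = g0, g1

        for (scope, p), d in draws.items():
            if scope == "motif":
                c_pos = g0 + p
            elif scope == "left":
                c_pos = g0 - FLANK_BP + p
            else:
                c_pos = g1 + p
            cov_rows.append((c_pos, d.meth_fwd, d.cov_fwd - d.meth_fwd))
            cov_rows.append((c_pos + 1, d.meth_rev, d.cov_rev - d.meth_rev))

        # bedGraph intervals aligned exactly with the 11 oriented bins
        for j in range(ACCESS_BINS_PER_SIDE):
            start = g0 - (ACCESS_BINS_PER_SIDE - j) * ACCESS_BIN_BP
            bg_rows.append((start, start + ACCESS_BIN_BP, view.accessibility[j]))
        bg_rows.append((g0, g1, view.accessibility[ACCESS_BINS_PER_SIDE]))
        for j in range(ACCESS_BINS_PER_SIDE):
            start = g1 + j * ACCESS_BIN_BP
            bg_rows.append(
                (start, start + ACCESS_BIN_BP,
                 view.accessibility[ACCESS_BINS_PER_SIDE + 1 + j])
            )

    dm = assemble(views, spec.feature_spec())
    bb = beta_vector(spec.beta_b, dm)
    bf = beta_vector(spec.beta_f, dm)
    X = dm.X.to_numpy(dtype=float)
    lam_c = np.exp(X @ bb + spec.s_c)
    lam_p = np.exp(X @ (bb + bf) + spec.s_p)
    control = _draw_counts(rng, lam_c, spec.theta, spec.noiseless_counts)
    pulldown = _draw_counts(rng, lam_p, spec.theta, spec.noiseless_counts)
    dm.control = control
    dm.pulldown = pulldown
    peaks = []
    for v, c, pl in zip(views, control, pulldown):
        v.control_count = int(c)
        v.pulldown_count = int(pl)
        peaks.append(
            PeakRecord(
                chrom="chrSim", summit=v.motif_start, pulldown_count=int(pl),
                control_count=int(c), peak_id=v.peak_id,
            )
        )

    paths = {
        "genome": out_dir / "genome.fa",
        "peaks": out_dir / "peaks.tsv",
        "cpg": out_dir / "methylation.cov",
        "accessibility": out_dir / "accessibility.bedGraph",
        "pfm": out_dir / "motif.pfm",
    }
    genome_str = "".join(seq)
    with open(paths["genome"], "w") as fh:
        fh.write(">chrSim\n")
        for j in range(0, genome_len, 80):
            fh.write(genome_str[j : j + 80] + "\n")
    write_peaks(peaks, paths["peaks"])
    cov_frame = pd.DataFrame(
        sorted(cov_rows), columns=["pos", "meth", "unmeth"]
    ).drop_duplicates("pos")
    cov_frame.insert(0, "chrom", "chrSim")
    write_cpg_coverage(CpGTable(cov_frame), paths["cpg"])
    write_bedgraph(
        SignalTrack.from_lists([("chrSim", int(s), int(e), float(v)) for s, e, v in bg_rows]),
        paths["accessibility"],
    )
    with open(paths["pfm"], "w") as fh:
        for row in spec.pfm.matrix:
            fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")

    truth = SimTruth(
        spec=spec, views=views, dm=dm, beta_b=bb, beta_f=bf,
        lambda_c=lam_c, lambda_p=lam_p,
    )
    return {k: str(v) for k, v in paths.items()}, truth


@dataclass
class DeltaSpec:
    """Between-context shift: how cell B differs from cell A."""

    meth_resample_prob: float = 0.5  # per CpG, chance of a fresh methylation draw
    access_log_sd: float = 0.0  # lognormal perturbation of raw bin means
    shift_flanks: bool = False


@dataclass
class TwoCellSim:
    dm_a: DesignMatrix
    dm_b: DesignMatrix
    true_log2_fc: np.ndarray  # (X_b - X_a) . beta_f / log 2
    counts: ReplicatedCounts
    truth_a: SimTruth
    beta_f: np.ndarray


def simulate_two_cells(
    spec: SimSpec,
    delta: DeltaSpec,
    seed: int,
    n_replicates: int = 2,
) -> TwoCellSim:
    """Paired datasets for two contexts sharing coefficients.

    Cell B re-draws the methylation fraction of each CpG with probability
    ``delta.meth_resample_prob`` (and optionally perturbs accessibility);
    replicated NB counts are generated per cell from the model equations.
    """
    rng = np.random.default_rng(seed)
    views_a, _ = simulate_views(spec, rng)
    fspec = spec.feature_spec()
    dm_a = assemble(views_a, fspec)

    views_b = []
    for v in views_a:
        meth = v.methylation.copy()
        cov = v.meth_coverage.copy()
        for p in np.flatnonzero(v.has_cpg):
            if rng.random() < delta.meth_resample_prob:
                d = _draw_cpg(rng, spec, None)
                cov[p] = d.coverage
                meth[p] = d.fraction if d.coverage else np.nan
        acc = v.accessibility * (
            np.exp(rng.normal(0.0, delta.access_log_sd, size=11))
            if delta.access_log_sd > 0
            else 1.0
        )
        flank_meth = v.flank_methylation
        if delta.shift_flanks:
            flank_meth = float(np.clip(rng.beta(0.5, 8.0), 0, 1))
        views_b.append(replace(v, methylation=meth, meth_coverage=cov,
                               accessibility=acc, flank_methylation=flank_meth))
    dm_b = assemble(views_b, fspec)

    bb = beta_vector(spec.beta_b, dm_a)
    bf = beta_vector(spec.beta_f, dm_a)
    Xa = dm_a.X.to_numpy(dtype=float)
    Xb = dm_b.X.to_numpy(dtype=float)
    true_log2_fc = (Xb - Xa) @ bf / np.log(2.0)

    pulldown = np.zeros((spec.n_peaks, 2 * n_replicates), dtype=np.int64)
    control = np.zeros_like(pulldown)
    cells = []
    col = 0
    for cell, X, dm in (("A", Xa, dm_a), ("B", Xb, dm_b)):
        lam_c = np.exp(X @ bb + spec.s_c)
        lam_p = np.exp(X @ (bb + bf) + spec.s_p)
        for rep in range(n_replicates):
            sf = float(np.exp(rng.normal(0.0, 0.1)))
            control[:, col] = _draw_counts(rng, lam_c * sf, spec.theta,
                                           spec.noiseless_counts)
            pulldown[:, col] = _draw_counts(rng, lam_p * sf, spec.theta,
                                            spec.noiseless_counts)
            if rep == 0:
                # carried single-library counts so each cell's design can
                # be used to train/evaluate an occupancy model directly
                dm.control = control[:, col].copy()
                dm.pulldown = pulldown[:, col].copy()
            cells.append(cell)
            col += 1

    counts = ReplicatedCounts(
        peak_ids=[v.peak_id for v in views_a],
        pulldown=pulldown,
        control=control,
        cell=cells,
    )
    truth_a = SimTruth(
        spec=spec, views=views_a, dm=dm_a, beta_b=bb, beta_f=bf,
        lambda_c=np.exp(Xa @ bb + spec.s_c),
        lambda_p=np.exp(Xa @ (bb + bf) + spec.s_p),
    )
    return TwoCellSim(
        dm_a=dm_a, dm_b=dm_b, true_log2_fc=true_log2_fc, counts=counts,
        truth_a=truth_a, beta_f=bf,
    )


def simulate_null_design(
    k: int,
    seed: int,
    theta: float = 5.0,
    meth_effect: float = -1.0,
    null_column: str = "M_pos01",
) -> tuple[DesignMatrix, dict[str, float]]:
    """Small-feature design for likelihood-ratio calibration studies.

    Builds a five-column design directly (one accessibility column, two
    methylation-style columns, one regional composition column, one
    regional methylation column) with NB counts from known coefficients.
    ``null_column`` has a true coefficient of exactly 0 in both the
    background and TF-specific copies, so dropping it is a true null for
    the nested test.  Returns the design and the true coefficient map
    (background as ``b:<col>``, TF-specific as ``f:<col>``).
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=k)

    def meth_col():
        vals = np.where(
            rng.random(k) < 0.4,
            0.0,
            np.where(rng.random(k) < 0.7, rng.beta(0.5, 8.0, k), rng.beta(8.0, 0.5, k)),
        )
        return vals

    cols = {
        "A_motif": a,
        "M_pos00": meth_col(),
        "M_pos01": meth_col(),
        "RS_G": rng.normal(0.0, 0.3, size=k),
        "RM": rng.beta(2.0, 2.0, size=k),
    }
    truth = {
        "b:A_motif": 0.1, "f:A_motif": 0.5,
        "b:M_pos00": 0.0, "f:M_pos00": meth_effect,
        "b:M_pos01": 0.0, "f:M_pos01": 0.0,
        "b:RS_G": 0.2, "f:RS_G": 0.1,
        "b:RM": -0.1, "f:RM": -0.3,
    }
    truth[f"b:{null_column}"] = 0.0
    truth[f"f:{null_column}"] = 0.0
    X = pd.DataFrame(cols)
    X.index = [f"peak_{i:06d}" for i in range(k)]
    bb = np.array([truth[f"b:{c}"] for c in X.columns])
    bf = np.array([truth[f"f:{c}"] for c in X.columns])
    s_c = float(np.log(20.0))
    s_p = s_c + 1.0
    lam_c = np.exp(X.to_numpy() @ bb + s_c)
    lam_p = np.exp(X.to_numpy() @ (bb + bf) + s_p)
    dm = DesignMatrix(
        X=X,
        blocks={"A": ["A_motif"], "M": ["M_pos00", "M_pos01"],
                "RS": ["RS_G"], "RM": ["RM"]},
        pulldown=_draw_counts(rng, lam_p, theta, False),
        control=_draw_counts(rng, lam_c, theta, False),
        spec=FeatureSpec(motif_length=4, reference_bases="ACGT",
                         access_pseudocount=_ACCESS_PSEUDOCOUNT),
    )
    return dm, truth


def default_spec(
    n_peaks: int,
    meth_effects: dict[int, float] | None = None,
    **overrides,
) -> SimSpec:
    """The standard study conditions with optional planted methylation effects.

    ``meth_effects`` maps motif positions to TF-specific methylation
    coefficients (e.g. {2: -2.0, 8: 2.0}).
    """
    pfm = overrides.pop("pfm", default_pfm())
    spec = SimSpec(n_peaks=n_peaks, pfm=pfm, **overrides)
    if meth_effects:
        for p, effect in meth_effects.items():
            spec.beta_f["M"][p] = effect
    return spec
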