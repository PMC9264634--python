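"""Shared fixtures: hand-built micro-inputs plus session-scoped simulations."""

import numpy as np
import pytest

from jams import simulate
from jams.io_formats import PFM
from jams.motif_align import PeakView


@pytest.fixture(scope="session")
def sim_small():
    """k = 2,000 peaks with planted methylation effects -2 (pos 2), +2 (pos 8)."""
    spec = simulate.default_spec(2000, meth_effects={2: -2.0, 8: 2.0})
    dm, truth = simulate.simulate_design(spec, seed=42)
    return dm, truth


@pytest.fixture(scope="session")
def fit_small(sim_small):
    import warnings

    from jams import model

    dm, _ = sim_small
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit_jams(dm)


@pytest.fixture
def uniform_pfm():
    return PFM(np.full((4, 4), 0.25))


@pytest.fixture
def strong_pfm():
    mat = np.full((6, 4), 0.01)
    for p, b in enumerate("ACGTAC"):
        mat[p, "ACGT".index(b)] = 0.97
    return PFM(mat)


def make_view(
    peak_id="pk",
    motif_seq="ACGTAC",
    methylation=None,
    coverage=None,
    accessibility=None,
    left_flank="A" * 20,
    right_flank="T" * 20,
    flank_methylation=0.0,
    pulldown=10,
    control=5,
    strand="+",
):
    """A hand-specified aligned peak for design-matrix unit tests."""
    L = len(motif_seq)
    meth = np.full(L, np.nan) if methylation is None else np.asarray(methylation, float)
    cov = np.zeros(L, dtype=np.int64) if coverage is None else np.asarray(coverage)
    has = ~np.isnan(meth) | (cov > 0)
    flank = left_flank + right_flank
    comp = np.array([flank.count(b) for b in "ACGT"], float)
    return PeakView(
        peak_id=peak_id,
        chrom="chr1",
        strand=strand,
        motif_start=1000,
        motif_end=1000 + L,
        motif_seq=motif_seq,
        left_flank=left_flank,
        right_flank=right_flank,
        methylation=meth,
        meth_coverage=cov,
        has_cpg=has,
        accessibility=np.ones(11) if accessibility is None else np.asarray(accessibility, float),
        flank_methylation=flank_methylation,
        flank_composition=comp / comp.sum(),
        pulldown_count=pulldown,
        control_count=control,
    )
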