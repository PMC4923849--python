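import numpy as np
import pytest

from stresswgbs import (
    DENSE_FLOOR_QUANTILE,
    DENSE_SMOOTH_PARAMS,
    GenomeLayout,
    IntervalSet,
    MethylationTable,
    MethylomeSimConfig,
    call_dmrs,
    compute_tstat,
    simulate_methylome,
    smooth_all,
)


@pytest.fixture
def tiny_meth():
    """3 CpGs x 4 samples (2 low / 2 high), hand-written counts."""
    return MethylationTable(
        chrom=np.array(["chr1"] * 3, dtype=object),
        pos=np.array([100, 150, 300]),
        meth=np.array([[3, 5, 8, 9], [0, 2, 6, 7], [10, 9, 2, 1]]),
        total=np.array([[10, 10, 10, 10], [10, 10, 10, 10], [10, 10, 10, 10]]),
        sample_ids=["a", "b", "c", "d"],
        group_labels=["low", "low", "high", "high"],
    )


@pytest.fixture
def small_genome():
    return GenomeLayout(("chr1", "chr2"), (10_000, 5_000))


def overlaps(a_start, a_end, b_start, b_end):
    return a_start < b_end and b_start < a_end


@pytest.fixture(scope="session")
def study_simulation():
    """The 5v5 toy-genome study condition (coverage 15x, Delta=0.3, 50
    planted regions of 5-10 CpGs on 200 kb), simulated once per session,
    with its smoothed matrix and DMR calls."""
    meth, truth = simulate_methylome(MethylomeSimConfig(seed=0))
    smoothed = smooth_all(meth, DENSE_SMOOTH_PARAMS)
    track = compute_tstat(smoothed, meth, floor_quantile=DENSE_FLOOR_QUANTILE)
    dmrs = call_dmrs(track)
    return {"meth": meth, "truth": truth, "smoothed": smoothed,
            "track": track, "dmrs": dmrs}


def make_intervals(rows):
    """rows: list of (chrom, start, end[, name])."""
    name = None
    if rows and len(rows[0]) > 3:
        name = np.array([r[3] for r in rows], dtype=object)
    return IntervalSet(
        np.array([r[0] for r in rows], dtype=object),
        np.array([r[1] for r in rows], dtype=np.int64),
        np.array([r[2] for r in rows], dtype=np.int64),
        name,
    )
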