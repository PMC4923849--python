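"""DMR-annotation overlap enrichment against a shuffled-DMR null.

The observed statistic is the number of DMRs hitting an annotation track
(>= 1 bp intersection, each DMR counted once).  The null repositions each
DMR uniformly on its own chromosome, preserving its length, and records
the overlap count per shuffle; the z-score standardizes the observed
count by the null mean and standard deviation, and the empirical p uses
the add-one estimator so it is never zero.  Also here: the fraction of
DMRs containing at least one array-catalog CpG, DMR-to-gene assignment,
and hypergeometric gene-set enrichment with BH adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DMRecord, GenomeLayout, IntervalSet, ValidationError, dmrs_to_intervals

Z_UPPER_5PCT = 1.6448536269514722   # standard-normal 95th percentile
Z_UPPER_10PCT = 1.2815515655446004


@dataclass(frozen=True)
class ShuffleParams:
    n_shuffles: int = 1000
    within_chromosome: bool = True
    exclude: IntervalSet | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_shuffles < 1:
            raise ValidationError("n_shuffles must be >= 1")


@dataclass
class EnrichmentResult:
    track_name: str
    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float                   # NaN when the null is degenerate
    empirical_p: float
    n_shuffles: int
    degenerate_null: bool = False
    above_5pct_tail: bool = False    # z beyond the standard-normal 5% upper tail
    above_10pct_tail: bool = False   # display-filter flag


@dataclass
class GeneSetResult:
    set_name: str
    n_set_genes: int
    n_dmr_genes: int
    overlap: int
    p_value: float
    q_value: float = float("nan")


# ---------------------------------------------------------------- overlap ----

class _ChromIndex:
    """Sorted interval starts with a running maximum of ends, per chromosome;
    answers 'does [s, e) hit anything' in O(log n)."""

    def __init__(self, ivs: IntervalSet):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in dict.fromkeys(ivs.chrom):
            m = ivs.chrom == c
            starts = ivs.start[m]
            ends = ivs.end[m]
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            self.by_chrom[str(c)] = (starts, np.maximum.accumulate(ends))

    def hits(self, chrom: str, start: int, end: int) -> bool:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return False
        starts, maxends = entry
        k = int(np.searchsorted(starts, end, side="left"))
        return k > 0 and maxends[k - 1] > start


def overlap_count(dmrs: Sequence[DMRecord] | IntervalSet, track: IntervalSet) -> int:
    """Number of DMRs intersecting >= 1 track interval by >= 1 bp."""
    ivs = dmrs if isinstance(dmrs, IntervalSet) else dmrs_to_intervals(list(dmrs))
    index = _ChromIndex(track)
    return sum(
        index.hits(str(ivs.chrom[i]), int(ivs.start[i]), int(ivs.end[i]))
        for i in range(len(ivs))
    )


# ---------------------------------------------------------------- shuffle ----

def _draw_placement(rng: np.random.Generator, length: int, genome: GenomeLayout,
                    chrom: str | None, exclude_index: _ChromIndex | None,
                    max_tries: int = 10_000) -> tuple[str, int]:
    lengths = genome.lengths
    if chrom is not None:
        options = [(chrom, lengths[chrom])]
    else:
        options = [(c, l) for c, l in lengths.items() if l >= length]
        if not options:
            raise ValidationError("interval longer than every chromosome")
    weights = np.array([l - length + 1 for _, l in options], dtype=float)
    if np.any(weights <= 0):
        bad = options[int(np.argmin(weights))][0]
        raise ValidationError(f"interval of {length} bp does not fit on {bad}")
    weights /= weights.sum()
    for _ in range(max_tries):
        c, l = options[int(rng.choice(len(options), p=weights))]
        start = int(rng.integers(0, l - length + 1))
        if exclude_index is None or not exclude_index.hits(c, start, start + length):
            return c, start
    raise ValidationError("could not place an interval outside the exclude set")


def shuffle_dmrs(dmrs: Sequence[DMRecord] | IntervalSet, genome: GenomeLayout,
                 params: ShuffleParams = ShuffleParams(),
                 rng: np.random.Generator | None = None) -> IntervalSet:
    """One random repositioning of every DMR: identical length, uniform
    placement (same chromosome when within_chromosome), redrawn while it
    intersects the exclude set.  Placements are independent; shuffled
    intervals may overlap each other."""
    ivs = dmrs if isinstance(dmrs, IntervalSet) else dmrs_to_intervals(list(dmrs))
    if rng is None:
        rng = np.random.default_rng(params.seed)
    excl = _ChromIndex(params.exclude) if params.exclude is not None else None
    chroms, starts, ends = [], [], []
    for i in range(len(ivs)):
        length = int(ivs.end[i] - ivs.start[i])
        home = str(ivs.chrom[i]) if params.within_chromosome else None
        if home is not None and genome.lengths[home] < length:
            name = ivs.name[i] if ivs.name is not None else i
            raise ValidationError(f"DMR {name} is longer than chromosome {home}")
        c, s = _draw_placement(rng, length, genome, home, excl)
        chroms.append(c)
        starts.append(s)
        ends.append(s + length)
    return IntervalSet(np.array(chroms, dtype=object), np.array(starts),
                       np.array(ends))


def enrichment_z(dmrs: Sequence[DMRecord] | IntervalSet, track: IntervalSet,
                 genome: GenomeLayout,
                 params: ShuffleParams = ShuffleParams(),
                 track_name: str = "track") -> EnrichmentResult:
    """Observed overlap count standardized against the shuffle null.

    z = (observed - null_mean) / null_sd; empirical_p is the add-one upper
    tail (1 + #{null >= observed}) / (n_shuffles + 1).  A degenerate null
    (sd = 0, e.g. a saturating or empty track) or fewer than 30 shuffles
    flags z as NaN while the empirical p stays valid.
    """
    ivs = dmrs if isinstance(dmrs, IntervalSet) else dmrs_to_intervals(list(dmrs))
    observed = overlap_count(ivs, track)
    rng = np.random.default_rng(params.seed)
    null = np.empty(params.n_shuffles)
    for b in range(params.n_shuffles):
        null[b] = overlap_count(shuffle_dmrs(ivs, genome, params, rng=rng), track)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if params.n_shuffles > 1 else 0.0
    degenerate = (sd == 0.0) or (params.n_shuffles < 30)
    z = float("nan") if degenerate else (observed - mean) / sd
    emp_p = (1 + int((null >= observed).sum())) / (params.n_shuffles + 1)
    return EnrichmentResult(
        track_name=track_name, observed_overlap=int(observed), null_mean=mean,
        null_sd=sd, z=z, empirical_p=emp_p, n_shuffles=params.n_shuffles,
        degenerate_null=degenerate,
        above_5pct_tail=(not degenerate) and z > Z_UPPER_5PCT,
        above_10pct_tail=(not degenerate) and z > Z_UPPER_10PCT,
    )


# ----------------------------------------------------------- array overlap ----

def array_overlap(dmrs: Sequence[DMRecord] | IntervalSet,
                  array_cpgs: IntervalSet) -> tuple[int, float]:
    """(count, fraction) of DMRs containing >= 1 array-catalog CpG.

    The fraction is NaN when there are no DMRs.  Report it as a percentage
    to one decimal (e.g. 0.052 -> '5.2%')."""
    ivs = dmrs if isinstance(dmrs, IntervalSet) else dmrs_to_intervals(list(dmrs))
    n = len(ivs)
    count = overlap_count(ivs, array_cpgs)
    return count, (count / n if n else float("nan"))


# ------------------------------------------------------------------ genes ----

def assign_genes(dmrs: Sequence[DMRecord] | IntervalSet, genes: IntervalSet,
                 flank_bp: int = 0) -> dict[str, set[str]]:
    """Map each DMR to every gene whose body +/- flank_bp it overlaps."""
    if genes.name is None:
        raise ValidationError("gene track must carry names")
    ivs = dmrs if isinstance(dmrs, IntervalSet) else dmrs_to_intervals(list(dmrs))
    if ivs.name is None:
        raise ValidationError("DMR intervals must carry ids")
    flanked = IntervalSet(genes.chrom, np.maximum(genes.start - flank_bp, 0),
                          genes.end + flank_bp, genes.name)
    out: dict[str, set[str]] = {}
    for i in range(len(ivs)):
        hits = set()
        m = flanked.chrom == ivs.chrom[i]
        s, e = ivs.start[i], ivs.end[i]
        ov = m & (flanked.start < e) & (flanked.end > s)
        hits.update(str(g) for g in flanked.name[ov])
        out[str(ivs.name[i])] = hits
    return out


def geneset_enrichment(dmr_genes: set[str], sets: Mapping[str, set[str]],
                       universe: set[str]) -> list[GeneSetResult]:
    """One-sided hypergeometric enrichment of DMR-associated genes in each
    gene set, BH-adjusted across sets.

    Drawing |dmr_genes| genes from the universe, the p-value is
    P(overlap >= observed) for each set (intersected with the universe).
    """
    if not universe:
        raise ValidationError("empty gene universe")
    extra = dmr_genes - universe
    if extra:
        raise ValidationError(f"DMR genes outside the universe: {sorted(extra)[:5]}")
    M = len(universe)
    N = len(dmr_genes)
    results = []
    for name, genes in sets.items():
        inset = genes & universe
        k = len(dmr_genes & inset)
        p = float(stats.hypergeom.sf(k - 1, M, len(inset), N))
        results.append(GeneSetResult(set_name=name, n_set_genes=len(inset),
                                     n_dmr_genes=N, overlap=k,
                                     p_value=min(p, 1.0)))
    if results:
        _, q, *_ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results
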