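"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate the study design the analysis was built for: a
5-vs-5 whole-genome bisulfite comparison of high- versus low-stress
mother--child pairs with regionally coherent methylation differences,
cis genotype--methylation correlations, annotation tracks enriched near
the differential regions, and a questionnaire cohort with planted
stress -> wheeze odds ratios and a multiplicative biomarker effect.

Counts are beta-binomial (WGBS replicates are overdispersed relative to
binomial sampling); CpG positions follow a geometric-gap model; the
latent methylation baseline is a mean-reverting random walk on the logit
scale, so neighbouring CpGs are smoothly correlated as they are in real
methylomes.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import GenomeLayout, GenotypeTable, IntervalSet, MethylationTable
from .cohort import categorize_stress


class ConfigurationError(ValueError):
    """A simulation config asks for something that cannot be laid out."""


# --------------------------------------------------------------- configs ----

DEFAULT_GENOME = GenomeLayout(("chr1",), (200_000,))


@dataclass(frozen=True)
class MethylomeSimConfig:
    """Study conditions for the WGBS arm: 5 pairs per stress group,
    moderate coverage, planted regions of 5-10 CpGs with a methylation
    shift of 0.3 (comfortably above the 10% calling threshold)."""

    genome: GenomeLayout = DEFAULT_GENOME
    n_per_group: int = 5
    mean_coverage: float = 15.0
    baseline_dispersion: float = 0.05     # beta-binomial intra-class correlation
    n_true_dmrs: int = 50
    dmr_n_cpgs_range: tuple[int, int] = (5, 10)
    dmr_effect: float = 0.3               # total group shift Delta, split +/- Delta/2
    mean_cpg_gap: int = 100               # geometric gap model, mean bp between CpGs
    baseline_mean: float = 0.5            # stationary mean of the baseline walk
    baseline_logit_sd: float = 0.5        # stationary sd on the logit scale
    fixed_baseline: float | None = None   # degenerate option: constant baseline pi
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigurationError("need >= 2 samples per group")
        if not (0 <= self.dmr_effect < 1):
            raise ConfigurationError("dmr_effect must be in [0, 1)")
        if not (0 <= self.baseline_dispersion < 1):
            raise ConfigurationError("baseline_dispersion must be in [0, 1)")
        lo, hi = self.dmr_n_cpgs_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("bad dmr_n_cpgs_range")


@dataclass
class PlantedDMR:
    chrom: str
    start: int            # 0-based half-open, spanning member CpGs
    end: int
    cpg_first: int        # row indices into the MethylationTable
    cpg_last: int         # inclusive
    sign: int             # +1: high-stress group is hypermethylated
    effect: float


@dataclass
class PlantedMeQTL:
    variant_id: str
    dmr_index: int        # index into TruthSet.dmrs
    beta: float


@dataclass
class TruthSet:
    """Ground truth for everything a generator planted."""

    genome: GenomeLayout
    dmrs: list[PlantedDMR] = field(default_factory=list)
    meqtls: list[PlantedMeQTL] = field(default_factory=list)
    cohort_effects: dict[str, float] = field(default_factory=dict)
    latent_pi: np.ndarray | None = None   # (n_cpgs, n_samples) latent methylation


# ------------------------------------------------------------- methylome ----

def _truncated_poisson(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1 (every CpG retained has coverage)."""
    draws = rng.poisson(lam, size=size)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(lam, size=int(zeros.sum()))


def _betabinom_counts(rng: np.random.Generator, n: np.ndarray, pi: np.ndarray,
                      rho: float) -> np.ndarray:
    """M ~ BetaBinomial(n, pi, rho) with rho the intra-class correlation
    (rho -> 0 recovers binomial).  pi of exactly 0/1 short-circuits."""
    pi = np.clip(pi, 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(n, pi)
    s = 1.0 / rho - 1.0                    # a + b of the mixing Beta
    interior = (pi > 0) & (pi < 1)
    p = np.where(interior, pi, pi)         # copy-shaped
    if interior.any():
        a = np.clip(pi[interior] * s, 1e-9, None)
        b = np.clip((1.0 - pi[interior]) * s, 1e-9, None)
        p = p.astype(float)
        p[interior] = rng.beta(a, b)
    return rng.binomial(n, p)


def _baseline_walk(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Stationary AR(1) on the logit scale, squashed to (0,1)."""
    phi = 0.98
    step = sd * math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    mu = logit(np.clip(mean, 1e-6, 1 - 1e-6))
    x[0] = mu + rng.normal(0.0, sd)
    eps = rng.normal(0.0, step, size=n)
    for i in range(1, n):
        x[i] = mu + phi * (x[i - 1] - mu) + eps[i]
    return expit(x)


def _place_disjoint_runs(rng: np.random.Generator, n_cpgs: int, n_runs: int,
                         len_range: tuple[int, int], buffer: int = 10) -> list[tuple[int, int]]:
    """Pick n_runs disjoint CpG-index runs (first, last inclusive) separated
    by at least `buffer` CpGs; greedy with retries."""
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n_runs)
    for _ in range(200):
        taken: list[tuple[int, int]] = []
        ok = True
        for L in lengths:
            placed = False
            for _ in range(500):
                first = int(rng.integers(0, max(1, n_cpgs - L)))
                last = first + int(L) - 1
                if last >= n_cpgs:
                    continue
                if all(last + buffer < a or first - buffer > b for a, b in taken):
                    taken.append((first, last))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return sorted(taken)
    raise ConfigurationError(
        f"cannot place {n_runs} disjoint regions of {len_range} CpGs in {n_cpgs} CpGs")


def simulate_methylome(config: MethylomeSimConfig) -> tuple[MethylationTable, TruthSet]:
    """Simulate per-CpG counts for n_per_group low- and high-stress samples.

    Latent baseline pi_i follows a smooth mean-reverting walk; inside each
    planted region the high-stress group is shifted by +sign*Delta/2 and the
    low-stress group by -sign*Delta/2 (sign balanced across regions so hyper-
    and hypomethylated regions are equally frequent).  Coverage is truncated
    Poisson, methylated counts beta-binomial.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome

    chroms, poss = [], []
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        p = 1.0 / config.mean_cpg_gap
        # expected CpG count; geometric gaps starting at a random offset
        gaps = rng.geometric(p, size=max(8, int(2.5 * length * p)))
        pos = np.cumsum(gaps)
        pos = pos[pos <= length]
        chroms.append(np.full(len(pos), name, dtype=object))
        poss.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    n_cpgs = len(pos)

    if config.fixed_baseline is not None:
        baseline = np.full(n_cpgs, float(config.fixed_baseline))
    else:
        baseline = np.concatenate([
            _baseline_walk(rng, int((chrom == c).sum()), config.baseline_mean,
                           config.baseline_logit_sd)
            for c in genome.chrom_names
        ])

    n_samples = 2 * config.n_per_group
    sample_ids = ([f"low_{i+1}" for i in range(config.n_per_group)]
                  + [f"high_{i+1}" for i in range(config.n_per_group)])
    group_labels = ["low"] * config.n_per_group + ["high"] * config.n_per_group

    pi = np.repeat(baseline[:, None], n_samples, axis=1)
    truth = TruthSet(genome=genome)
    if config.n_true_dmrs > 0:
        runs = _place_disjoint_runs(rng, n_cpgs, config.n_true_dmrs,
                                    config.dmr_n_cpgs_range)
        signs = np.resize([1, -1], len(runs))
        rng.shuffle(signs)
        half = config.dmr_effect / 2.0
        is_high = np.array([g == "high" for g in group_labels])
        for (first, last), sign in zip(runs, signs):
            if len(set(chrom[first:last + 1])) != 1:
                continue  # runs never straddle chromosomes by construction
            shift = np.where(is_high, sign * half, -sign * half)
            pi[first:last + 1, :] = np.clip(pi[first:last + 1, :] + shift, 0.0, 1.0)
            truth.dmrs.append(PlantedDMR(
                chrom=str(chrom[first]), start=int(pos[first] - 1), end=int(pos[last]),
                cpg_first=first, cpg_last=last, sign=int(sign),
                effect=config.dmr_effect))

    total = _truncated_poisson(rng, config.mean_coverage, (n_cpgs, n_samples))
    meth = _betabinom_counts(rng, total, pi, config.baseline_dispersion)

    table = MethylationTable(chrom=chrom, pos=pos, meth=meth, total=total,
                             sample_ids=sample_ids, group_labels=group_labels)
    truth.latent_pi = pi
    return table, truth


# ------------------------------------------------------------- genotypes ----

MEQTL_WINDOW_BP = 5_000


def simulate_genotypes(methylome: MethylationTable, truth: TruthSet,
                       n_meqtls: int, beta_meqtl: float, maf: float, seed: int,
                       n_background: int | None = None,
                       dispersion: float = 0.05) -> tuple[GenotypeTable, TruthSet]:
    """Plant cis-meQTL SNPs next to planted regions and background SNPs.

    For each of n_meqtls randomly chosen planted regions, one SNP is placed
    within +/-5 kb and each sample's latent methylation inside the region is
    shifted by beta_meqtl per alternate allele (clipped to [0,1]); the
    methylated counts of those CpGs are redrawn in place from the shifted
    surface.  Background SNPs (default: ~2 expected per +/-5 kb test window)
    are uniform on the genome with dosage ~ Binomial(2, maf).
    """
    if n_meqtls > len(truth.dmrs):
        raise ConfigurationError("n_meqtls exceeds the number of planted regions")
    if not (0 <= maf <= 1):
        raise ConfigurationError("maf must be in [0, 1]")
    if truth.latent_pi is None:
        raise ConfigurationError("truth set lacks the latent methylation surface")
    rng = np.random.default_rng(seed)
    genome = truth.genome
    lengths = genome.lengths
    n_samples = methylome.n_samples

    if n_background is None:
        mean_dmr_len = (np.mean([d.end - d.start for d in truth.dmrs])
                        if truth.dmrs else 0.0)
        window = 2 * MEQTL_WINDOW_BP + mean_dmr_len
        n_background = max(1, round(2 * sum(genome.chrom_lengths) / window))

    records: list[tuple[str, int, str, np.ndarray]] = []

    # background SNPs, uniform over the genome
    total_len = sum(genome.chrom_lengths)
    for k in range(n_background):
        u = int(rng.integers(1, total_len + 1))
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            if u <= length:
                break
            u -= length
        dos = rng.binomial(2, maf, size=n_samples).astype(float)
        records.append((name, u, f"bg_snp_{k+1}", dos))

    chosen = rng.choice(len(truth.dmrs), size=n_meqtls, replace=False) if n_meqtls else []
    for j, di in enumerate(sorted(int(i) for i in np.atleast_1d(chosen))):
        d = truth.dmrs[di]
        lo = max(1, d.start + 1 - MEQTL_WINDOW_BP)
        hi = min(lengths[d.chrom], d.end + MEQTL_WINDOW_BP)
        if lo > hi:
            raise ConfigurationError(f"no space for a SNP within +/-5 kb of region {di}")
        p_var = int(rng.integers(lo, hi + 1))
        dos = rng.binomial(2, maf, size=n_samples).astype(float)
        for _ in range(100):                       # a constant SNP is untestable
            if len(np.unique(dos)) > 1:
                break
            dos = rng.binomial(2, maf, size=n_samples).astype(float)
        vid = f"meqtl_snp_{j+1}"
        records.append((d.chrom, p_var, vid, dos))
        truth.meqtls.append(PlantedMeQTL(variant_id=vid, dmr_index=di,
                                         beta=beta_meqtl))
        if beta_meqtl != 0.0:
            rows = slice(d.cpg_first, d.cpg_last + 1)
            shifted = np.clip(truth.latent_pi[rows, :] + beta_meqtl * dos[None, :],
                              0.0, 1.0)
            truth.latent_pi[rows, :] = shifted
            methylome.meth[rows, :] = _betabinom_counts(
                rng, methylome.total[rows, :], shifted, dispersion)

    order = {c: i for i, c in enumerate(genome.chrom_names)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    geno = GenotypeTable(
        chrom=np.array([r[0] for r in records], dtype=object),
        pos=np.array([r[1] for r in records], dtype=np.int64),
        variant_id=np.array([r[2] for r in records], dtype=object),
        dosage=np.array([r[3] for r in records], dtype=float).reshape(len(records), n_samples),
        sample_ids=list(methylome.sample_ids),
    )
    return geno, truth


# ----------------------------------------------------------- annotations ----

def simulate_annotations(genome: GenomeLayout, truth: TruthSet, n_intervals: int,
                         frac_near_dmrs: float, interval_len: int,
                         seed: int) -> IntervalSet:
    """An annotation track with a tunable fraction of intervals centered on
    planted regions (the rest uniform), emulating regulatory peak sets that
    do or do not coincide with differential methylation."""
    if not (0.0 <= frac_near_dmrs <= 1.0):
        raise ConfigurationError("frac_near_dmrs must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    rows: list[tuple[str, int, int]] = []
    n_near = int(round(frac_near_dmrs * n_intervals))
    if n_near > 0 and not truth.dmrs:
        raise ConfigurationError("frac_near_dmrs > 0 but no planted regions exist")
    # round-robin over a shuffled region order, so n_near >= #regions
    # guarantees every planted region is covered
    order = rng.permutation(len(truth.dmrs)) if truth.dmrs else []
    for k in range(n_near):
        d = truth.dmrs[int(order[k % len(order)])]
        center = (d.start + d.end) // 2
        start = max(0, min(center - interval_len // 2, lengths[d.chrom] - interval_len))
        rows.append((d.chrom, start, start + interval_len))
    total_len = sum(genome.chrom_lengths)
    for _ in range(n_intervals - n_near):
        u = int(rng.integers(0, total_len))
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            if u < length:
                break
            u -= length
        start = max(0, min(u, lengths[name] - interval_len))
        rows.append((name, start, start + interval_len))
    if not rows:
        return IntervalSet(np.array([], dtype=object), np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64))
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    rows.sort(key=lambda r: (order[r[0]], r[1]))
    return IntervalSet(np.array([r[0] for r in rows], dtype=object),
                       np.array([r[1] for r in rows]),
                       np.array([r[2] for r in rows]))


# ----------------------------------------------------------------- cohort ----

@dataclass(frozen=True)
class Confounder:
    name: str
    kind: str            # "binary" | "continuous"
    prevalence: float = 0.5     # binary: Bernoulli p; continuous: mean
    sd: float = 1.0             # continuous only
    beta: float = 0.0           # effect on the wheeze log-odds


# mirrors the adjustment set used for early-childhood wheeze
DEFAULT_CONFOUNDERS: tuple[Confounder, ...] = (
    Confounder("gender", "binary", 0.5, beta=math.log(1.2)),
    Confounder("siblings", "binary", 0.45, beta=math.log(0.8)),
    Confounder("smoking", "binary", 0.15, beta=math.log(1.6)),
    Confounder("ets", "binary", 0.05, beta=math.log(1.4)),
    Confounder("cat", "binary", 0.25, beta=math.log(1.2)),
    Confounder("atopy", "binary", 0.6, beta=math.log(1.8)),
    Confounder("education_high", "binary", 0.75, beta=math.log(0.8)),
)


@dataclass(frozen=True)
class CohortSimConfig:
    """Questionnaire-cohort conditions: 443 subjects, 20 stress items on a
    1-4 scale, planted odds ratios for persistent wheeze of 2.44 (high vs.
    low stress) and 1.39 (medium vs. low), ~9% baseline wheeze risk, and a
    biomarker with a 1.5-fold geometric-mean shift in the high-stress group."""

    n_subjects: int = 443
    stress_item_count: int = 20
    or_high: float = 2.44
    or_medium: float = 1.39
    baseline_wheeze_prob: float = 0.091
    confounders: tuple[Confounder, ...] = DEFAULT_CONFOUNDERS
    biomarker_mr: float = 1.5
    biomarker_geo_mean: float = 50.0
    biomarker_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.baseline_wheeze_prob < 1):
            raise ConfigurationError("baseline_wheeze_prob must be in (0,1)")
        if self.or_high <= 0 or self.or_medium <= 0 or self.biomarker_mr <= 0:
            raise ConfigurationError("odds ratios and mean ratio must be positive")
        if self.n_subjects < 4:
            raise ConfigurationError("need at least 4 subjects")


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate the subject-level table.

    Each subject has a latent stress propensity; the 20 questionnaire items
    are the propensity plus item noise, rounded to the 1-4 scale, and the
    total score is the mean item score.  Quartile categories are assigned by
    :func:`stresswgbs.cohort.categorize_stress`; persistent wheeze is drawn
    from a logistic model with the planted category log-odds plus confounder
    terms; the biomarker is log-normal with the planted multiplicative shift
    in the high-stress category.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    theta = rng.normal(1.9, 0.45, size=n)
    items = np.clip(np.rint(theta[:, None]
                            + rng.normal(0.0, 0.8, size=(n, config.stress_item_count))),
                    1, 4).astype(int)
    score = items.mean(axis=1)
    category, (q1, q3) = categorize_stress(score)

    table = pd.DataFrame({"subject_id": [f"S{i+1:05d}" for i in range(n)]})
    for j in range(config.stress_item_count):
        table[f"psq{j+1:02d}"] = items[:, j]
    table["stress_score"] = score
    table["stress_category"] = category

    eta = np.full(n, logit(config.baseline_wheeze_prob))
    eta += np.where(category == "medium", math.log(config.or_medium), 0.0)
    eta += np.where(category == "high", math.log(config.or_high), 0.0)
    for cf in config.confounders:
        if cf.kind == "binary":
            x = rng.binomial(1, cf.prevalence, size=n).astype(int)
        elif cf.kind == "continuous":
            x = rng.normal(cf.prevalence, cf.sd, size=n)
        else:
            raise ConfigurationError(f"unknown confounder kind {cf.kind!r}")
        table[cf.name] = x
        eta = eta + cf.beta * x
    table["persistent_wheeze"] = rng.binomial(1, expit(eta))
    table["wheeze_phenotype"] = np.where(table["persistent_wheeze"] == 1,
                                         "persistent", "never")

    ln_b = (math.log(config.biomarker_geo_mean)
            + np.where(category == "high", math.log(config.biomarker_mr), 0.0)
            + rng.normal(0.0, config.biomarker_log_sd, size=n))
    table["biomarker"] = np.exp(ln_b)

    truth = TruthSet(genome=DEFAULT_GENOME, cohort_effects={
        "or_high": config.or_high,
        "or_medium": config.or_medium,
        "biomarker_mr": config.biomarker_mr,
        "q1": float(q1),
        "q3": float(q3),
    })
    return table, truth
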