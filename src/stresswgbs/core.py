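"""Shared genomic data model.

Coordinate conventions follow the file formats the objects mirror:
CpG and SNP positions are 1-based (VCF/count-table convention), all
intervals are 0-based half-open (BED convention).  The two helpers
:func:`pos_to_interval` and :func:`interval_to_pos` own the ±1 arithmetic
so it appears nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based point position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def interval_to_pos(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    return start + 1


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass
class MethylationTable:
    """Per-CpG methylated/total read counts across samples.

    ``chrom``/``pos`` give the CpG grid (pos 1-based, strictly increasing
    within each chromosome); ``meth`` and ``total`` are CpG x sample count
    matrices; ``group_labels`` maps each sample to ``"low"`` or ``"high"``
    perceived-stress exposure.
    """

    chrom: np.ndarray           # (n_cpgs,) str
    pos: np.ndarray             # (n_cpgs,) int, 1-based
    meth: np.ndarray            # (n_cpgs, n_samples) int
    total: np.ndarray           # (n_cpgs, n_samples) int
    sample_ids: list[str]
    group_labels: list[str]     # per sample, in {"low", "high"}

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n, s = self.meth.shape
        if self.total.shape != (n, s) or self.pos.shape != (n,) or self.chrom.shape != (n,):
            raise ValidationError("inconsistent array shapes in MethylationTable")
        if len(self.sample_ids) != s or len(self.group_labels) != s:
            raise ValidationError("sample_ids/group_labels length != number of sample columns")
        bad = set(self.group_labels) - {"low", "high"}
        if bad:
            raise ValidationError(f"group labels must be 'low'/'high', got {sorted(bad)}")
        if not ({"low", "high"} <= set(self.group_labels)):
            raise ValidationError("need at least one sample per group")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValidationError("negative counts")
        viol = np.argwhere(self.meth > self.total)
        if viol.size:
            r, c = viol[0]
            raise ValidationError(
                f"meth > total at {self.chrom[r]}:{self.pos[r]} "
                f"sample {self.sample_ids[c]} ({self.meth[r, c]} > {self.total[r, c]})"
            )
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(f"positions not strictly increasing on {c}")

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def group_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == label])

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Boolean mask of rows on ``chrom``."""
        return np.asarray(self.chrom == chrom)

    def fractions(self) -> np.ndarray:
        """Raw methylation fractions M/N (NaN where N = 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)


@dataclass
class IntervalSet:
    """0-based half-open genomic intervals, optionally named."""

    chrom: np.ndarray   # (n,) str
    start: np.ndarray   # (n,) int
    end: np.ndarray     # (n,) int
    name: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.name is not None:
            self.name = np.asarray(self.name, dtype=object)
            if self.name.shape != self.start.shape:
                raise ValidationError("name column length mismatch")
        if not (self.chrom.shape == self.start.shape == self.end.shape):
            raise ValidationError("inconsistent interval arrays")
        bad = np.nonzero(self.start >= self.end)[0]
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"interval {i}: start >= end ({self.chrom[i]}:{self.start[i]}-{self.end[i]})"
            )

    def __len__(self) -> int:
        return len(self.start)

    def check_bounds(self, genome: GenomeLayout) -> None:
        lengths = genome.lengths
        for i in range(len(self)):
            c = self.chrom[i]
            if c not in lengths:
                raise ValidationError(f"interval on unknown chromosome {c!r}")
            if self.start[i] < 0 or self.end[i] > lengths[c]:
                raise ValidationError(
                    f"interval {c}:{self.start[i]}-{self.end[i]} outside chromosome bounds"
                )

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(
            self.chrom[mask], self.start[mask], self.end[mask],
            None if self.name is None else self.name[mask],
        )


@dataclass
class GenotypeTable:
    """Per-sample allele dosages (0/1/2, NaN = missing) at biallelic variants."""

    chrom: np.ndarray       # (n_variants,) str
    pos: np.ndarray         # (n_variants,) int, 1-based
    variant_id: np.ndarray  # (n_variants,) str
    dosage: np.ndarray      # (n_variants, n_samples) float with {0,1,2,NaN}
    sample_ids: list[str]

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n = len(self.pos)
        if self.dosage.shape[0] != n or self.dosage.shape[1] != len(self.sample_ids):
            raise ValidationError("dosage matrix shape mismatch")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValidationError("dosages must be in {0,1,2} or NaN")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValidationError(f"variant positions not sorted on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)


@dataclass
class DMRecord:
    """A called differentially methylated region.

    ``start``/``end`` are 0-based half-open, spanning the first to last
    member CpG inclusive.  ``direction`` is the sign of the high-stress
    minus low-stress smoothed difference; ``area_stat`` is the sum of the
    member CpG t-statistics.
    """

    chrom: str
    start: int
    end: int
    dmr_id: str
    n_cpgs: int
    mean_diff: float
    direction: str              # "hyper" | "hypo"
    area_stat: float
    class_label: str = "unclassified"   # "gDMR" | "ngDMR" | "unclassified"
    fdr: float = float("nan")
    meqtl_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"DMR {self.dmr_id}: start >= end")
        if self.n_cpgs < 1:
            raise ValidationError(f"DMR {self.dmr_id}: n_cpgs < 1")
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"DMR {self.dmr_id}: bad direction {self.direction!r}")
        if self.class_label not in ("gDMR", "ngDMR", "unclassified"):
            raise ValidationError(f"DMR {self.dmr_id}: bad class {self.class_label!r}")


def dmrs_to_intervals(dmrs: Sequence[DMRecord]) -> IntervalSet:
    if not dmrs:
        return IntervalSet(np.array([], dtype=object), np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64), np.array([], dtype=object))
    return IntervalSet(
        np.array([d.chrom for d in dmrs], dtype=object),
        np.array([d.start for d in dmrs]),
        np.array([d.end for d in dmrs]),
        np.array([d.dmr_id for d in dmrs], dtype=object),
    )
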