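"""Genetic (gDMR) versus non-genetic (ngDMR) DMR classification.

A DMR is called genetically influenced when at least one SNP within
+/-5 kb of it has allele dosages significantly correlated with the DMR's
per-sample methylation level (coverage-weighted raw fraction over the
member CpGs).  The per-SNP test is Pearson correlation at alpha = 0.05
with no multiple-testing correction by default — deliberately
conservative in the direction of over-calling gDMRs, so the retained
ngDMR set is depleted of genotype effects.  A Benjamini-Hochberg mode and
an exact permutation test (for very small sample sizes) are available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DMRecord, GenotypeTable, MethylationTable, ValidationError


@dataclass(frozen=True)
class MeQTLParams:
    window_bp: int = 5000
    alpha: float = 0.05
    test: str = "pearson"          # "pearson" | "spearman" | "pearson_exact"
    min_called_samples: int = 3
    correction: str = "none"       # "none" | "bh"

    def __post_init__(self):
        if self.window_bp < 0:
            raise ValidationError("window_bp must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.test not in ("pearson", "spearman", "pearson_exact"):
            raise ValidationError(f"unknown test {self.test!r}")


@dataclass
class MeQTLResult:
    dmr_id: str
    variant_id: str
    statistic: float
    p_value: float
    n_samples: int
    significant: bool
    testable: bool


def regional_methylation(meth: MethylationTable, dmr: DMRecord) -> np.ndarray:
    """Per-sample coverage-weighted mean methylation over the DMR's CpGs:
    sum(M)/sum(N).  Samples with zero regional coverage get NaN."""
    mask = (meth.chrom == dmr.chrom) & (meth.pos - 1 >= dmr.start) & (meth.pos - 1 < dmr.end)
    if not mask.any():
        raise ValidationError(f"DMR {dmr.dmr_id} contains no CpGs of the table")
    m = meth.meth[mask].sum(axis=0).astype(float)
    n = meth.total[mask].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, m / np.maximum(n, 1), np.nan)


def snps_near(dmr: DMRecord, geno: GenotypeTable, window_bp: int = 5000) -> list[str]:
    """Variant ids within +/-window_bp of the DMR (1-based inclusive bounds:
    a SNP exactly window_bp away is still inside)."""
    lo = dmr.start + 1 - window_bp      # first 1-based position inside
    hi = dmr.end + window_bp            # last 1-based position inside
    mask = (geno.chrom == dmr.chrom) & (geno.pos >= lo) & (geno.pos <= hi)
    return [str(v) for v in geno.variant_id[mask]]


def _exact_pearson_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for |r|: fraction of the n! dosage
    permutations with |r| at least the observed (observed included)."""
    r_obs = abs(_pearson_r(x, y))
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(_pearson_r(x[list(perm)], y))
        if r >= r_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    den = math.sqrt(float((xd * xd).sum() * (yd * yd).sum()))
    if den == 0:
        return 0.0
    return float((xd * yd).sum() / den)


def test_meqtl(regional_meth: np.ndarray, dosages: np.ndarray,
               params: MeQTLParams = MeQTLParams(),
               dmr_id: str = "", variant_id: str = "") -> MeQTLResult:
    """Correlation test between dosage and regional methylation.

    Pairs with a missing value on either side are dropped.  A constant
    dosage or methylation vector, or fewer than 3 (``min_called_samples``)
    complete pairs, makes the result untestable (never significant).
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(regional_meth, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    untestable = MeQTLResult(dmr_id, variant_id, float("nan"), float("nan"),
                             n, significant=False, testable=False)
    if n < max(3, params.min_called_samples):
        return untestable
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return untestable
    if params.test == "pearson":
        r, p = stats.pearsonr(x, y)
    elif params.test == "spearman":
        r, p = stats.spearmanr(x, y)
    else:  # pearson_exact
        if n > 8:
            raise ValidationError("exact permutation test limited to n <= 8")
        r = _pearson_r(x, y)
        p = _exact_pearson_p(x, y)
    return MeQTLResult(dmr_id, variant_id, float(r), float(p), n,
                       significant=bool(p < params.alpha), testable=True)


@dataclass
class ClassificationSummary:
    n_dmrs: int
    n_gdmr: int
    n_ngdmr: int

    @property
    def ngdmr_fraction(self) -> float:
        return self.n_ngdmr / self.n_dmrs if self.n_dmrs else float("nan")


def classify_dmrs(dmrs: list[DMRecord], meth: MethylationTable,
                  geno: GenotypeTable,
                  params: MeQTLParams = MeQTLParams(),
                  ) -> tuple[list[DMRecord], list[MeQTLResult], ClassificationSummary]:
    """Label every DMR gDMR or ngDMR.

    gDMR iff at least one significant meQTL-SNP lies in the +/-window;
    DMRs with no SNP in the window or only untestable SNPs count as ngDMR.
    Returns the annotated DMRs (labels set in place), the full per-pair
    test table, and a summary with the ngDMR fraction.
    """
    results: list[MeQTLResult] = []
    per_dmr: dict[str, list[MeQTLResult]] = {}
    vid_to_row = {str(v): i for i, v in enumerate(geno.variant_id)}
    for d in dmrs:
        reg = regional_methylation(meth, d)
        hits = []
        for vid in snps_near(d, geno, params.window_bp):
            res = test_meqtl(reg, geno.dosage[vid_to_row[vid]], params,
                             dmr_id=d.dmr_id, variant_id=vid)
            hits.append(res)
        per_dmr[d.dmr_id] = hits
        results.extend(hits)

    if params.correction == "bh":
        from statsmodels.stats.multitest import multipletests
        testable = [r for r in results if r.testable]
        if testable:
            rej, q, *_ = multipletests([r.p_value for r in testable],
                                       alpha=params.alpha, method="fdr_bh")
            for r, rj, qv in zip(testable, rej, q):
                r.p_value = float(qv)
                r.significant = bool(rj)

    n_g = 0
    for d in dmrs:
        sig = [r.variant_id for r in per_dmr[d.dmr_id] if r.significant]
        d.meqtl_ids = sig
        d.class_label = "gDMR" if sig else "ngDMR"
        n_g += bool(sig)
    summary = ClassificationSummary(n_dmrs=len(dmrs), n_gdmr=n_g,
                                    n_ngdmr=len(dmrs) - n_g)
    return dmrs, results, summary
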