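"""Readers and writers for the plain-text formats the pipeline touches.

Methylation counts travel as a single TSV (chrom, pos, then a meth/total
column pair per sample); annotations as BED3+; genotypes as minimal VCF
(GT only, biallelic); DMRs as BED6+ with extra columns; gene sets as GMT.
Every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    DMRecord,
    GenomeLayout,
    GenotypeTable,
    IntervalSet,
    MethylationTable,
    ValidationError,
)

logger = logging.getLogger("stresswgbs")

DMR_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "n_cpgs", "mean_diff", "direction", "class_label", "fdr",
]


# ---------------------------------------------------------------- genome ----

def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    return GenomeLayout(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


def write_genome_layout(genome: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{c}\t{l}\n")


# ----------------------------------------------------------- methylation ----

def read_methylation(path: str | Path, group_map: Mapping[str, str]) -> MethylationTable:
    """Read a per-CpG count TSV.

    Expected header: ``chrom  pos  <s1>_meth  <s1>_total  <s2>_meth ...``.
    Rows are returned sorted by (chromosome first-appearance order, position);
    counts are validated (0 <= meth <= total).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse methylation table {path}: {exc}") from exc
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValidationError(f"{path}: first two columns must be 'chrom', 'pos'")
    count_cols = list(df.columns[2:])
    samples = []
    for col in count_cols[::2]:
        if not col.endswith("_meth"):
            raise ValidationError(f"{path}: expected '<sample>_meth' column, got {col!r}")
        samples.append(col[: -len("_meth")])
    for s, col in zip(samples, count_cols[1::2]):
        if col != f"{s}_total":
            raise ValidationError(f"{path}: expected '{s}_total' next to '{s}_meth'")
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ValidationError(f"samples missing from group map: {missing}")

    # stable sort within each chromosome, chromosome order of first appearance
    order = {c: i for i, c in enumerate(dict.fromkeys(df["chrom"]))}
    df = df.sort_values(["chrom", "pos"], kind="stable",
                        key=lambda s: s.map(order) if s.name == "chrom" else s)
    meth = df[[f"{s}_meth" for s in samples]].to_numpy(dtype=np.int64)
    total = df[[f"{s}_total" for s in samples]].to_numpy(dtype=np.int64)
    return MethylationTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        meth=meth,
        total=total,
        sample_ids=samples,
        group_labels=[group_map[s] for s in samples],
    )


def write_methylation(table: MethylationTable, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {"chrom": table.chrom, "pos": table.pos}
    for j, s in enumerate(table.sample_ids):
        cols[f"{s}_meth"] = table.meth[:, j]
        cols[f"{s}_total"] = table.total[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_bedgraph_samples(paths: Mapping[str, str | Path],
                          group_map: Mapping[str, str]) -> MethylationTable:
    """Convenience wrapper: one 5-column file per sample
    (chrom, start, end, meth, total; BedGraph-style 0-based start = pos-1).
    All files must share an identical CpG grid.
    """
    frames = {}
    for sample, p in paths.items():
        df = pd.read_csv(p, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "meth", "total"],
                         dtype={"chrom": str})
        frames[sample] = df
    samples = list(paths)
    ref = frames[samples[0]][["chrom", "start"]]
    for s in samples[1:]:
        if not ref.equals(frames[s][["chrom", "start"]]):
            raise ValidationError(f"sample {s}: CpG grid differs from {samples[0]}")
    return MethylationTable(
        chrom=ref["chrom"].to_numpy(dtype=object),
        pos=ref["start"].to_numpy(dtype=np.int64) + 1,
        meth=np.column_stack([frames[s]["meth"].to_numpy(np.int64) for s in samples]),
        total=np.column_stack([frames[s]["total"].to_numpy(np.int64) for s in samples]),
        sample_ids=samples,
        group_labels=[group_map[s] for s in samples],
    )


# -------------------------------------------------------------- intervals ----

def read_intervals(path: str | Path) -> IntervalSet:
    """Read BED3+ into 0-based half-open intervals; column 4 (if any) is the name."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else None))
    if not rows:
        return IntervalSet(np.array([], dtype=object), np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64))
    chrom, start, end, names = zip(*rows)
    name = None if all(n is None for n in names) else np.array(
        ["" if n is None else n for n in names], dtype=object)
    return IntervalSet(np.array(chrom, dtype=object), np.array(start), np.array(end), name)


def write_intervals(ivs: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(ivs)):
            fields = [str(ivs.chrom[i]), str(ivs.start[i]), str(ivs.end[i])]
            if ivs.name is not None:
                fields.append(str(ivs.name[i]))
            fh.write("\t".join(fields) + "\n")


# -------------------------------------------------------------- genotypes ----

def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a minimal VCF; only GT is consumed.

    Encoding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> NaN.
    Multi-allelic records are skipped with a warning (the cis-meQTL analysis
    concerns simple biallelic SNPs).
    """
    chroms, poss, ids, rows = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("skipping multi-allelic record %s:%s", rec.chrom, rec.pos)
                continue
            dos = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(gt)))
            chroms.append(rec.chrom)
            poss.append(rec.pos)  # pysam reports 1-based POS
            ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
            rows.append(dos)
    return GenotypeTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        variant_id=np.array(ids, dtype=object),
        dosage=np.array(rows, dtype=float).reshape(len(rows), len(samples)),
        sample_ids=samples,
    )


def write_genotypes(geno: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for i in range(geno.n_variants):
            gts = [gt_map.get(d, "./.") if not np.isnan(d) else "./."
                   for d in geno.dosage[i]]
            fh.write(f"{geno.chrom[i]}\t{geno.pos[i]}\t{geno.variant_id[i]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ------------------------------------------------------------------- DMRs ----

def write_dmrs(dmrs: Sequence[DMRecord], path: str | Path) -> None:
    """BED6+ with n_cpgs, mean_diff, direction, class_label, fdr columns.

    The BED score slot carries the area statistic (sum of member t values).
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_COLUMNS) + "\n")
        for d in dmrs:
            fh.write("\t".join([
                d.chrom, str(d.start), str(d.end), d.dmr_id,
                repr(float(d.area_stat)), ".",
                str(d.n_cpgs), repr(float(d.mean_diff)), d.direction,
                d.class_label, repr(float(d.fdr)),
            ]) + "\n")


def read_dmrs(path: str | Path) -> list[DMRecord]:
    dmrs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) != len(DMR_COLUMNS):
                raise ValidationError(f"{path}:{lineno}: expected {len(DMR_COLUMNS)} columns")
            dmrs.append(DMRecord(
                chrom=p[0], start=int(p[1]), end=int(p[2]), dmr_id=p[3],
                area_stat=float(p[4]), n_cpgs=int(p[6]), mean_diff=float(p[7]),
                direction=p[8], class_label=p[9], fdr=float(p[10]),
            ))
    return dmrs


# -------------------------------------------------------------- gene sets ----

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ----------------------------------------------------------------- cohort ----

def read_cohort(path: str | Path) -> pd.DataFrame:
    """Cohort CSV -> DataFrame; see the column dictionary in the docs."""
    return pd.read_csv(path)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
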