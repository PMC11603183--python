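"""Readers and writers for the formats the pipeline touches.

Cytosine reports (CX-report and coverage dialects, auto-detected by column
count), expression TSVs, gene models as GFF3 (1-based inclusive) and BED
(0-based half-open), FASTA via Biopython. All coordinate conversion happens
in the two functions ``bed_to_internal`` / ``internal_to_bed``; every other
module works in 1-based inclusive coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .methylome import CYTOSINE_COLUMNS, GeneModel, classify_context

logger = logging.getLogger(__name__)


# -- coordinate chokepoint ---------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open -> internal 1-based inclusive."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Internal 1-based inclusive -> BED 0-based half-open."""
    return start1 - 1, end1


# -- cytosine reports --------------------------------------------------------

def read_cytosine_report(
    path, dialect: str = "auto", genome: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-cytosine methylation report.

    Two dialects are supported and auto-detected by column count:

    * CX-report (7 columns): chrom, pos(1-based), strand, count
      methylated, count unmethylated, context, trinucleotide;
    * coverage (6 columns): chrom, start(1-based), end, methylation
      percentage, count methylated, count unmethylated. The percentage
      is cross-checked against the counts; contexts are classified from
      ``genome`` when given (the coverage dialect does not carry them).

    Malformed lines are reported with their line numbers.
    """
    path = Path(path)
    rows = []
    bad: list[int] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("%s: empty cytosine report", path)
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)
    ncol = len(lines[0].split("\t"))
    if dialect == "auto":
        if ncol >= 7:
            dialect = "cx"
        elif ncol == 6:
            dialect = "coverage"
        else:
            raise ValueError(
                f"{path}: unknown cytosine report layout with {ncol} columns; "
                f"first line: {lines[0][:80]!r}"
            )
    for i, ln in enumerate(lines, start=1):
        f = ln.split("\t")
        try:
            if dialect == "cx":
                chrom, pos, strand, mc, uc, context = (
                    f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5]
                )
            else:
                chrom, start, _end = f[0], int(f[1]), int(f[2])
                pct, mc, uc = float(f[3]), int(f[4]), int(f[5])
                pos = start
                total = mc + uc
                if total > 0 and abs(pct - 100.0 * mc / total) > 0.51:
                    raise ValueError("percentage/count mismatch")
                strand = "+"
                context = (
                    classify_context(genome[chrom], pos, strand)
                    if genome is not None and chrom in genome
                    else "CG"
                )
            if strand not in "+-" or mc < 0 or uc < 0:
                raise ValueError("bad strand or counts")
            rows.append((chrom, pos, strand, mc, uc, context))
        except (ValueError, IndexError, KeyError):
            bad.append(i)
    if bad:
        logger.warning("%s: %d malformed lines (e.g. line %d)", path, len(bad), bad[0])
    return pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write the CX-report dialect (7th column: first base of the context)."""
    out = df.copy()
    out["tri"] = out["context"].str[:1] + out["context"].str[1:]
    out[CYTOSINE_COLUMNS + ["tri"]].to_csv(path, sep="\t", header=False, index=False)


# -- expression --------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Molecules x samples table; first column is the molecule id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated molecule ids {dup[:5]}")
    return df


def write_expression_tsv(df: pd.DataFrame, path, float_format: str = "%.4f") -> None:
    df.to_csv(path, sep="\t", index_label="molecule_id", float_format=float_format)


# -- gene models -------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Gene features from a GFF3 file (1-based inclusive, per the format)."""
    genes = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            f = ln.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"gene_{len(genes)}")
            genes.append(
                GeneModel(
                    gene_id=gid, chrom=f[0], strand=f[6],
                    start=int(f[3]), end=int(f[4]),
                )
            )
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: duplicate gene ids")
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tlunarice\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            f = ln.rstrip("\n").split("\t")
            start0, end0 = int(f[1]), int(f[2])
            if start0 >= end0:
                raise ValueError(f"{path}: empty/inverted BED interval {ln!r}")
            start, end = bed_to_internal(start0, end0)
            genes.append(
                GeneModel(
                    gene_id=f[3] if len(f) > 3 else f"gene_{len(genes)}",
                    chrom=f[0],
                    strand=f[5] if len(f) > 5 else "+",
                    start=start,
                    end=end,
                )
            )
    return genes


def write_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s0, e0 = internal_to_bed(g.start, g.end)
            fh.write(f"{g.chrom}\t{s0}\t{e0}\t{g.gene_id}\t0\t{g.strand}\n")


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# -- generic tables ----------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
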