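"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with fixed, documented column orders:

* samples TSV: ``sample, genotype, sex``
* allelic counts TSV: ``gene, sample, maternal_count, paternal_count, total_count``
* methylation calls TSV: ``sample, chrom, pos, read_id, allele, state``
  (+ optional ``read_start, read_end, strand`` for deduplication)
* ICR BED: ``chrom, start, end, name, germline_origin`` (0-based half-open)
* SNP TSV: ``chrom, pos, maternal_base, paternal_base``
* bedGraph: ``chrom, start, end, value``

FASTA goes through Biopython.
"""
from __future__ import annotations

import io as _stdio
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ICRRegion, SnpTable

SAMPLES_COLUMNS = ["sample", "genotype", "sex"]
COUNTS_COLUMNS = ["gene", "sample", "maternal_count", "paternal_count", "total_count"]
CALLS_COLUMNS = ["sample", "chrom", "pos", "read_id", "allele", "state"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in SAMPLES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"samples table {path} missing columns {missing}")
    return df[SAMPLES_COLUMNS + [c for c in df.columns if c not in SAMPLES_COLUMNS]]


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    required = ["gene", "sample", "maternal_count", "paternal_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"counts table {path} missing columns {missing}")
    return df


def read_calls(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in CALLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calls table {path} missing columns {missing}")
    return df


def read_icr_bed(path: str | Path) -> list[ICRRegion]:
    """Read ICR definitions from a 5-column BED (name and germline origin
    in columns 4-5).  BED coordinates are already 0-based half-open."""
    regions: list[ICRRegion] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(
                f"ICR BED {path}: expected 5 columns "
                "(chrom, start, end, name, germline_origin), got: " + line
            )
        chrom, start, end, name, origin = fields[:5]
        regions.append(ICRRegion(name=name, chrom=chrom, start=int(start),
                                 end=int(end), germline_origin=origin))
    return regions


def write_icr_bed(regions: list[ICRRegion], path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.germline_origin}"
        for r in regions
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_snp_tsv(path: str | Path) -> SnpTable:
    df = read_tsv(path)
    table = SnpTable()
    for row in df.itertuples(index=False):
        table.add(str(row.chrom), int(row.pos), str(row.maternal_base),
                  str(row.paternal_base))
    return table


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def format_bedgraph(rows: list[tuple[str, int, int, float]]) -> str:
    """Render (chrom, start, end, value) rows as bedGraph text, sorted."""
    buf = _stdio.StringIO()
    buf.write('track type=bedGraph name="methylation" viewLimits=0:1\n')
    for chrom, start, end, value in sorted(rows, key=lambda r: (r[0], r[1])):
        buf.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
    return buf.getvalue()
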