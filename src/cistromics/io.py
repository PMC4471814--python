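"""Readers and writers for the on-disk formats the pipeline touches.

BED and bedGraph are native 0-based half-open and pass through unchanged;
GFF gene rows (1-based, inclusive) are converted to the internal
convention on read. All tabular outputs are plain TSV.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GeneModel, GenomicInterval, Peak


class ParseError(ValueError):
    """Raised for malformed input lines; carries the file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path) -> list[Peak]:
    """Read a BED3/BED5 file into peaks, preserving input order.

    Column 4 (name) and column 5 (score -> height) are optional; a
    missing score yields height 0.
    """
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates: {fields[1:3]}")
        if start >= end or start < 0:
            raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
        name = fields[3] if len(fields) > 3 else ""
        height = 0.0
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                height = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score: {fields[4]!r}")
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        peaks.append(Peak(GenomicInterval(chrom, start, end, strand), height, name))
    return peaks


def write_bed(peaks: Iterable[Peak], path) -> None:
    """Write peaks as 5-column BED (name '.' when empty, score %g)."""
    with open(path, "w") as fh:
        for p in peaks:
            name = p.name or "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.height:g}\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    return [p.interval for p in read_bed(path)]


def write_intervals_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_GFF_GENE_TYPES = {"gene", "protein_coding_gene"}


def read_genes(path) -> list[GeneModel]:
    """Read gene models from a 5-column TSV or a GFF dialect.

    TSV columns: gene_id, chrom, start, end, strand (0-based half-open,
    with or without a header row). GFF rows of type ``gene`` use 1-based
    inclusive coordinates and are converted; the gene_id comes from an
    ``ID=`` or ``gene_id=`` attribute, else the raw attribute column.
    """
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
            # GFF: seqid source type start end score strand frame attrs
            if fields[2] not in _GFF_GENE_TYPES:
                continue
            chrom, strand = fields[0], fields[6]
            start, end = int(fields[3]) - 1, int(fields[4])
            gene_id = fields[8]
            for token in fields[8].rstrip(";").split(";"):
                key, _, val = token.strip().partition("=")
                if key in ("ID", "gene_id"):
                    gene_id = val
                    break
        elif len(fields) == 5:
            gene_id, chrom = fields[0], fields[1]
            if fields[0] == "gene_id" and fields[4] == "strand":
                continue  # header row
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates: {fields[2:4]}")
            strand = fields[4]
        else:
            raise ParseError(path, lineno, f"unrecognized gene row with {len(fields)} columns")
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"unknown strand symbol {strand!r}")
        if start >= end or start < 0:
            raise ParseError(path, lineno, f"invalid gene span [{start}, {end})")
        genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand)))
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None) -> CoverageTrack:
    """Read a bedGraph into a dense per-base coverage track.

    Chromosome lengths default to the largest end coordinate seen.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(path, lineno, f"malformed bedGraph row: {fields}")
        if value < 0:
            raise ParseError(path, lineno, f"negative coverage value {value}")
        spans.setdefault(fields[0], []).append((start, end, value))
    data = {}
    for chrom, rows in spans.items():
        n = chrom_lengths[chrom] if chrom_lengths else max(e for _, e, _ in rows)
        arr = np.zeros(n, dtype=np.float32)
        for s, e, v in rows:
            arr[s:e] = v
        data[chrom] = arr
    return CoverageTrack(data)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track run-length encoded (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = np.asarray(track.data[chrom], dtype=np.float64)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ParseError(path, 0, "sequence before first FASTA header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_kmer_table(path) -> pd.DataFrame:
    """Read a k-mer Z-score TSV with columns ``word`` and ``z``."""
    df = pd.read_csv(path, sep="\t")
    if not {"word", "z"} <= set(df.columns):
        raise ValueError(f"{path}: k-mer table needs columns 'word' and 'z'")
    return df


def read_expression(matrix_path, meta_path):
    """Read a gene x sample log2 expression matrix and its sample sheet.

    The matrix TSV has gene_id in the first column and sample ids in the
    header; the sidecar metadata TSV has columns sample_id, genotype,
    time_hr, replicate. Missing values are an error (imputation is out
    of scope).
    """
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if expr.isna().any().any():
        raise ValueError(f"{matrix_path}: expression matrix contains missing values")
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "genotype", "time_hr", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"{meta_path}: metadata needs columns {sorted(required)}")
    missing = set(expr.columns) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    return expr, meta
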