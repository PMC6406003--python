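"""Readers and writers for the plain-text formats the pipeline touches.

Supported dialects are the BED family (BED3, BED6, ENCODE narrowPeak and
broadPeak), TSV count matrices, TSV sample sheets, bedGraph output and FASTA.
Coordinates in all these formats are already 0-based half-open, so no shifting
is performed.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import GeneModel, GenomicInterval, PeakCall, Sample

DIALECT_COLUMNS = {"BED3": 3, "BED6": 6, "narrowPeak": 10, "broadPeak": 9}

_ALLOWED_NT = set("ACGTN")


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


def read_intervals(
    path, dialect: str, sample_id: Optional[str] = None
) -> List[PeakCall]:
    """Read peak calls from a BED-family file.

    narrowPeak column 10 is parsed as the summit offset (-1 means absent);
    broadPeak and plain BED yield no summit.  ``sample_id`` defaults to the
    file stem.
    """
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncol = DIALECT_COLUMNS[dialect]
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    out: List[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name, score, strand = ".", 0.0, "."
            height = 0.0
            summit_offset: Optional[int] = None
            if ncol >= 6:
                name = fields[3]
                score = float(fields[4]) if fields[4] != "." else 0.0
                strand = fields[5]
            if ncol >= 9:  # narrowPeak / broadPeak: signalValue is column 7
                height = float(fields[6])
            elif ncol == 6:
                height = score
            if ncol == 10:
                so = int(fields[9])
                summit_offset = None if so < 0 else so
            try:
                interval = GenomicInterval(chrom, start, end, name, score, strand)
                out.append(
                    PeakCall(interval, sid, summit_offset=summit_offset, height=height)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_intervals(records: Iterable[PeakCall], path, dialect: str) -> None:
    """Write peak calls sorted by (chrom, start) in the given dialect.

    Round-trips with :func:`read_intervals` for the fields the dialect carries.
    """
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    recs = sorted(records, key=lambda p: (p.interval.chrom, p.interval.start))
    with open(path, "w") as fh:
        for p in recs:
            iv = p.interval
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect != "BED3":
                cols += [iv.name, _fmt(iv.score), iv.strand]
            if dialect in ("narrowPeak", "broadPeak"):
                cols += [_fmt(p.height), "-1", "-1"]
            if dialect == "narrowPeak":
                cols.append(str(p.summit_offset if p.summit_offset is not None else -1))
            fh.write("\t".join(cols) + "\n")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_count_matrix(path) -> Tuple[List[str], List[str], np.ndarray]:
    """Read a TSV count matrix (first column gene ids, header sample ids).

    Real-valued entries are rounded half to even; negative values and
    duplicated gene ids are errors.  Returns (gene_ids, sample_ids, matrix)
    with an integer matrix of shape (genes, samples).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids: {dups}")
    if df.isna().any().any():
        raise ValueError("ragged or non-numeric rows in count matrix")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative counts in count matrix")
    # np.rint implements round-half-to-even
    mat = np.rint(values).astype(np.int64)
    return df.index.astype(str).tolist(), df.columns.astype(str).tolist(), mat


def write_count_matrix(gene_ids, sample_ids, matrix, path) -> None:
    pd.DataFrame(matrix, index=gene_ids, columns=sample_ids).to_csv(path, sep="\t")


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into a name -> uppercase DNA string mapping (ACGTN only)."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED_NT
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sample_sheet(path) -> List[Sample]:
    """Read a TSV sample sheet into Sample records; sample ids must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_system", "lif", "dox", "guide", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return [
        Sample(
            sample_id=row.sample_id,
            cell_system=row.cell_system,
            lif=row.lif,
            dox=row.dox,
            guide=row.guide,
            library_size=int(row.library_size),
        )
        for row in df.itertuples()
    ]


def write_sample_sheet(samples: Sequence[Sample], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "cell_system": s.cell_system,
                "lif": s.lif,
                "dox": s.dox,
                "guide": s.guide,
                "library_size": s.library_size,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> List[GeneModel]:
    """Read a minimal gene table TSV: gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneModel(
            gene_id=row.gene_id,
            interval=GenomicInterval(
                row.chrom, int(row.start), int(row.end), row.gene_id, 0.0, row.strand
            ),
        )
        for row in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.interval.strand,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def write_bedgraph(track: Dict[str, np.ndarray], path) -> None:
    """Write a per-bp track as bedGraph, run-length collapsing equal values."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            vals = np.asarray(track[chrom], dtype=float)
            if vals.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_g(v)}\n")


def _fmt_g(x: float) -> str:
    if math.isclose(x, round(x)):
        return str(int(round(x)))
    return f"{x:.6g}"
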