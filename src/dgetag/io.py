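"""Readers and writers for the pipeline's plain-text formats.

FASTA goes through Biopython (wrapped at 80 columns).  Tabular data is TSV:
tab-separated, header row, UTF-8, '.' decimal.  Readers validate the header
and per-row column counts and report the offending line number.  Floating
point columns are written at 12 significant digits so p-values round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import GeneRecord, InputError
from .tagproc import TagCountTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_tag_table",
    "write_tag_table",
    "read_annotations",
    "read_counts",
]

FLOAT_FORMAT = "%.12g"


def read_fasta(path) -> list:
    """Load gene records from a FASTA file."""
    records = [
        GeneRecord(gene_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(genes: Sequence[GeneRecord], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in genes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # Biopython wraps at 60..80; fine


def read_tsv(path, expected_columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a TSV with header validation and per-line column-count checks."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise InputError(f"{path}: empty file or missing header")
        header = header_line.split("\t")
        if expected_columns is not None and list(header) != list(expected_columns):
            raise InputError(
                f"{path}: line 1: expected columns {list(expected_columns)}, "
                f"got {header}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise InputError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=header)
    return frame


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tag_table(path, library_id: str, stage: str = "raw") -> TagCountTable:
    frame = read_tsv(path, expected_columns=["tag", "count"])
    frame["count"] = frame["count"].astype("int64")
    return TagCountTable(library_id=library_id, frame=frame, stage=stage)


def write_tag_table(table: TagCountTable, path) -> None:
    write_tsv(table.frame, path)


def read_annotations(path) -> pd.DataFrame:
    frame = read_tsv(path)
    if not {"gene", "term"} <= set(frame.columns):
        raise InputError(f"{path}: annotation table needs 'gene' and 'term' columns")
    return frame


def read_counts(path) -> pd.DataFrame:
    """Two-library per-gene count table (gene, x, y) indexed by gene."""
    frame = read_tsv(path, expected_columns=["gene", "x", "y"])
    frame["x"] = frame["x"].astype("int64")
    frame["y"] = frame["y"].astype("int64")
    return frame.set_index("gene")
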