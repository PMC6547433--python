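"""Aligned-read tables and their SAM / BED representations.

The in-memory form is a pandas DataFrame with columns
``chrom, start, end, name, length, strand`` (0-based half-open, ungapped
reads, so ``end - start == length``). The 6-column BED dialect stores read
length in the score slot; SAM round-trips through pysam.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "make_alignment_table",
    "read_bed",
    "write_bed",
    "read_sam",
    "write_sam",
]

COLUMNS = ["chrom", "start", "end", "name", "length", "strand"]


def make_alignment_table(chrom, start, length, strand, name=None) -> pd.DataFrame:
    start = np.asarray(start, dtype=np.int64)
    length = np.asarray(length, dtype=np.int64)
    if name is None:
        name = [f"read{i}" for i in range(len(start))]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + length,
            "name": name,
            "length": length,
            "strand": strand,
        }
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if (df["start"] < 0).any():
        raise ValueError("negative alignment start")
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=COLUMNS)
    if not (df["end"] - df["start"] == df["length"]).all():
        raise ValueError("BED length column inconsistent with interval")
    return df


def write_bed(alignments: pd.DataFrame, path) -> None:
    alignments[COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_sam(path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            length = rec.infer_read_length() or rec.query_length
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.query_name,
                    length,
                    "-" if rec.is_reverse else "+",
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "name", "length", "strand"])
    df["end"] = df["start"] + df["length"]
    return df[COLUMNS]


def write_sam(alignments: pd.DataFrame, path, chrom_sizes: dict) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in alignments.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = str(row.name)
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.cigarstring = f"{int(row.length)}M"
            a.flag = 16 if row.strand == "-" else 0
            a.mapping_quality = 255
            out.write(a)
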