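"""Genome FASTA I/O (thin Biopython wrappers)."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")
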