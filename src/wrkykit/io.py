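"""Thin FASTA I/O wrappers (Biopython-backed), full headers kept as ids."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Records as (full header, sequence) pairs, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        records.append((header, str(rec.seq)))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=header.split()[0], description=header)
        for header, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
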