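"""Thin FASTA/TSV/BED helpers shared by the pipeline stages.

All genomic coordinates handled here are 0-based half-open (BED
convention); human-readable tables produced by the pipeline convert to
1-based closed coordinates at write time and say so in a header comment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_descriptions(path: str | Path) -> list[tuple[str, str, str]]:
    """Return (id, description, sequence) triples, preserving order."""
    return [
        (rec.id, rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 60) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed6(rows: Iterable[tuple[str, int, int, str, float, str]],
               path: str | Path) -> None:
    """Write BED6 rows (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def translate(seq: str) -> str:
    """Translate a DNA string (length trimmed to a codon multiple)."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())
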