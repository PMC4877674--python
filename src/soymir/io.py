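"""Reading and writing of the sequence formats used across the pipeline.

FASTA/FASTQ parsing is delegated to Biopython; this module only adds the
small-RNA specific conventions: the collapsed-FASTA header dialect
``>id_xCOUNT`` carrying per-sequence read counts, and 4-line Phred+33 FASTQ
emission with a constant quality string.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COLLAPSED_RE = re.compile(r"^(?P<id>.*)_x(?P<count>\d+)$")

COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (U treated as T)."""
    return seq.translate(COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercased) from a 4-line Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write 4-line FASTQ with a constant per-base quality (Phred+33)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read collapsed FASTA; headers ``id_xCOUNT`` yield (id, sequence, count).

    Headers without the ``_x`` suffix are accepted with count 1.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_RE.match(rec.id)
        if m:
            out.append((m.group("id"), str(rec.seq).upper(), int(m.group("count"))))
        else:
            out.append((rec.id, str(rec.seq).upper(), 1))
    return out


def write_collapsed_fasta(path: str | Path, records: Iterable[tuple[str, str, int]]) -> None:
    with open(path, "w") as fh:
        for name, seq, count in records:
            fh.write(f">{name}_x{count}\n{seq}\n")
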