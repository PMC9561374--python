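"""Small sequence utilities and FASTQ/FASTA I/O.

Parsing goes through Biopython's fast iterators; writing uses plain 4-line
(FASTQ) and wrapped (FASTA) records so that outputs are byte-stable across
runs with the same seed.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (lowercase marks masked bases)."""
    return seq.translate(_COMPLEMENT)[::-1]


def full_conversion(seq: str) -> str:
    """Image of a sequence under complete C->T conversion."""
    return seq.replace("C", "T")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read a FASTQ file into a list of (name, sequence, quality) tuples."""
    with open(path) as handle:
        return [(name, seq.upper(), qual) for name, seq, qual in FastqGeneralIterator(handle)]


def read_paired_fastq(
    r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> list[tuple[str, str, str]]:
    """Read mate-paired FASTQ files.

    Returns a list of ``(name, read1, read2)`` with sequences uppercased.
    Records are paired positionally; a length mismatch is an error.
    """
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError(
            f"paired FASTQ record counts differ: {len(r1)} in {r1_path}, {len(r2)} in {r2_path}"
        )
    return [(n1.split()[0], s1, s2) for (n1, s1, _), (_, s2, _) in zip(r1, r2)]


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> int:
    """Write (name, sequence, quality) records as 4-line FASTQ. Returns count."""
    n = 0
    with open(path, "w") as out:
        for name, seq, qual in records:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA into (name, sequence) tuples (case preserved)."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 80) -> int:
    n = 0
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
            n += 1
    return n


def phred_to_ascii(quals: Sequence[int], cap: int = 93) -> str:
    """Encode integer Phred scores as a Phred+33 string, capped for printability."""
    return "".join(chr(min(cap, max(0, q)) + 33) for q in quals)


def ascii_to_phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def oriented_reads(pairs: Sequence[tuple[str, str, str]]) -> Iterator[tuple[str, str]]:
    """Yield individual reads oriented into the fragment-forward frame.

    In an FR paired-end library the second mate is sequenced from the opposite
    strand of the fragment; reverse-complementing it places both mates in the
    frame of the (single-stranded, conversion-imprinted) template. Yields
    ``(read_id, sequence)`` where read_id is ``name/1`` or ``name/2``.
    """
    for name, r1, r2 in pairs:
        yield f"{name}/1", r1
        yield f"{name}/2", revcomp(r2)


def oriented_pairs(pairs: Sequence[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """Like :func:`oriented_reads` but keeps mates together: (name, left, right)."""
    return [(name, r1, revcomp(r2)) for name, r1, r2 in pairs]
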