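"""Reversal of imprinted C->T mutations using the unmutated library.

A k-mer table built from the unconverted reads acts as a set of very short,
frequency-weighted local references. An unmutated k-mer maps *properly* to a
contig window when the window could have arisen from it by C->T conversion
alone (mismatches only as k-mer C against contig T). Every properly mapped
k-mer votes its own base at each position it covers, weighted by its table
count; a contig T whose weighted pileup is confidently C (or T) is restored
(or confirmed), while split or thin pileups are left masked for resolution
during consensus.

Because proper mapping forces the k-mer and window to share a full-conversion
image, every vote at a contig T position is either C or T; at non-T positions
all votes equal the contig base, so the pileup stores the total mapped weight
per position and the C-vote weight at T positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import full_conversion, revcomp

__all__ = [
    "KmerTable",
    "UnmaskPileup",
    "UnmaskedContig",
    "build_kmer_table",
    "map_kmers_to_contig",
    "unmask_contig",
    "estimate_conversion_rate",
]


@dataclass
class KmerTable:
    """Occurrence counts of unmutated-library k-mers (both orientations)."""

    k: int
    counts: dict[str, int]
    _images: dict[str, list[tuple[str, tuple[int, ...], int]]] | None = field(
        default=None, repr=False
    )

    def image_index(self, min_count: int = 2):
        """Full-conversion image -> [(kmer, C-positions, count)] for k-mers
        meeting ``min_count``. Cached."""
        if self._images is None or self._min_count_used != min_count:
            images: dict[str, list[tuple[str, tuple[int, ...], int]]] = {}
            for km, c in self.counts.items():
                if c < min_count:
                    continue
                cpos = tuple(i for i, b in enumerate(km) if b == "C")
                images.setdefault(full_conversion(km), []).append((km, cpos, c))
            for lst in images.values():
                lst.sort()
            self._images = images
            self._min_count_used = min_count
        return self._images

    _min_count_used: int = field(default=-1, repr=False)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class UnmaskPileup:
    """Weighted votes from properly mapped unmutated k-mers over one contig.

    ``total[i]`` is the summed weight of mapped k-mers covering position i;
    ``c_votes[i]`` the weight voting C. At a contig T position the T-vote
    weight is ``total[i] - c_votes[i]``; at other positions all votes match
    the contig base.
    """

    contig_sequence: str
    total: np.ndarray
    c_votes: np.ndarray

    def t_votes_at(self, pos: int) -> float:
        return float(self.total[pos] - self.c_votes[pos])


@dataclass
class UnmaskedContig:
    """A contig with conversions reversed where the pileup is confident.

    ``masked_positions`` maps still-ambiguous positions to their ambiguity
    channel: ``'Y'`` (observed T, true base C or T). After reverse
    complementing into the opposite strand frame the channel becomes ``'R'``
    (observed A, true base A or G).
    """

    contig_id: str
    sequence: str
    masked_positions: dict[int, str]
    source_contig_id: str

    def display_sequence(self) -> str:
        """Sequence with masked positions lowercased ('t' / 'a')."""
        chars = list(self.sequence)
        for pos in self.masked_positions:
            chars[pos] = chars[pos].lower()
        return "".join(chars)

    def reverse_complement(self) -> "UnmaskedContig":
        n = len(self.sequence)
        flipped = {
            n - 1 - pos: ("R" if ch == "Y" else "Y")
            for pos, ch in self.masked_positions.items()
        }
        return UnmaskedContig(
            contig_id=self.contig_id,
            sequence=revcomp(self.sequence),
            masked_positions=flipped,
            source_contig_id=self.source_contig_id,
        )

    def __len__(self) -> int:
        return len(self.sequence)


def build_kmer_table(reads: Sequence[str], k: int) -> KmerTable:
    """Count k-mers of the unmutated library in both orientations.

    Unmutated molecules are double-stranded, so each read contributes its own
    k-mers and those of its reverse complement.
    """
    if not reads:
        raise ValueError("unmutated library is empty; cannot build k-mer table")
    if k > max(len(r) for r in reads):
        raise ValueError(f"k={k} exceeds the longest unmutated read")
    counts: dict[str, int] = {}
    for read in reads:
        for seq in (read, revcomp(read)):
            n = len(seq)
            for i in range(n - k + 1):
                km = seq[i : i + k]
                counts[km] = counts.get(km, 0) + 1
    return KmerTable(k=k, counts=counts)


def map_kmers_to_contig(
    contig_sequence: str,
    table: KmerTable,
    min_table_count: int = 2,
) -> UnmaskPileup:
    """Vote pileup of properly mapped unmutated k-mers over one contig.

    For every contig offset, table k-mers whose full-conversion image equals
    the window's are retrieved and verified (every window C must be a k-mer
    C); each then votes its bases over the covered span, weighted by its
    table count.
    """
    k = table.k
    seq = contig_sequence.upper()
    n = len(seq)
    total_diff = np.zeros(n + 1, dtype=np.float64)
    c_votes = np.zeros(n, dtype=np.float64)
    if n < k:
        return UnmaskPileup(seq, np.zeros(n), c_votes)
    images = table.image_index(min_table_count)
    conv_seq = full_conversion(seq)
    get = images.get
    contig_c = [i for i, b in enumerate(seq) if b == "C"]
    lo = hi = 0  # sliding pointers into contig_c for the current window
    for i in range(n - k + 1):
        while lo < len(contig_c) and contig_c[lo] < i:
            lo += 1
        while hi < len(contig_c) and contig_c[hi] < i + k:
            hi += 1
        cands = get(conv_seq[i : i + k])
        if cands is None:
            continue
        window_c = contig_c[lo:hi]
        for km, kc_pos, weight in cands:
            # proper mapping: window C positions must be C in the k-mer too
            ok = True
            for j in window_c:
                if km[j - i] != "C":
                    ok = False
                    break
            if not ok:
                continue
            total_diff[i] += weight
            total_diff[i + k] -= weight
            for p in kc_pos:  # k-mer C positions: votes C wherever contig has T
                j = i + p
                if seq[j] == "T":
                    c_votes[j] += weight
    total = np.cumsum(total_diff[:-1])
    return UnmaskPileup(seq, total, c_votes)


def unmask_contig(
    contig_sequence: str,
    pileup: UnmaskPileup,
    contig_id: str = "",
    confidence: float = 0.99,
    min_votes: float = 10.0,
) -> UnmaskedContig:
    """Restore confidently converted positions; mask ambiguous ones.

    A contig T becomes C when the weighted C fraction of its pileup reaches
    ``confidence``; it stays T (unmasked) when the T fraction does. Split
    pileups, and pileups with fewer than ``min_votes`` total weight, are kept
    as T and recorded in ``masked_positions`` — absence of unmutated evidence
    cannot distinguish a true T from a converted C. Non-T positions are never
    altered.
    """
    seq = contig_sequence.upper()
    chars = list(seq)
    masked: dict[int, str] = {}
    for pos, base in enumerate(seq):
        if base != "T":
            continue
        tot = float(pileup.total[pos])
        if tot < min_votes:
            masked[pos] = "Y"
            continue
        c_frac = float(pileup.c_votes[pos]) / tot
        if c_frac >= confidence:
            chars[pos] = "C"
        elif (1.0 - c_frac) >= confidence:
            pass  # confirmed T
        else:
            masked[pos] = "Y"
    return UnmaskedContig(
        contig_id=contig_id or "contig",
        sequence="".join(chars),
        masked_positions=masked,
        source_contig_id=contig_id or "contig",
    )


def estimate_conversion_rate(
    mutated_sequence: str, unmasked: UnmaskedContig
) -> tuple[int, int, float]:
    """Per-template conversion fraction from the truth-free pattern call.

    Converted positions are contig Ts restored to C by unmasking; the
    denominator adds the cytosines that were never converted (C in both
    sequences). Masked positions are excluded (their state is unknown).
    Returns ``(converted, total_cytosines, fraction)``.
    """
    src = mutated_sequence.upper()
    converted = 0
    unconverted = 0
    for pos, (a, b) in enumerate(zip(src, unmasked.sequence)):
        if pos in unmasked.masked_positions:
            continue
        if a == "T" and b == "C":
            converted += 1
        elif a == "C" and b == "C":
            unconverted += 1
    total = converted + unconverted
    frac = converted / total if total else float("nan")
    return converted, total, frac
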