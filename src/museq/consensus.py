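"""Per-haplotype consensus calling with per-base Phred quality.

Contigs assigned to one haplotype are co-aligned to the longest of them with
an iterative loop that corrects indel errors in the working reference
(columns where a gap is the majority call edit the reference, which is then
realigned, for up to five rounds). Each final column is summarised and the
most likely base called under the same per-observation error channel used
for phasing:

    P(obs | true base b) = 1 - eps        if obs == b (unmasked, incl. gap)
                         = eps / 3        otherwise
    masked-T observation: p if b == C, 1 - eps if b == T, eps / 3 otherwise
    (mirrored for masked-A with G on the opposite-strand channel)

with a uniform prior over {A, C, G, T, gap}. The posterior error probability
of the call is log-transformed into a Phred score, capped at 93 for FASTQ
encoding. Because different templates of the same molecule carry independent
conversion patterns, aggregation resolves the positions unmasking had to
leave open: a true C shows a mix of unmasked C (unconverted templates) and
masked T, while a true T shows masked T in every template.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .phasing import MASK_EQUALITIES
from .seqio import full_conversion, phred_to_ascii, write_fastq
from .unmask import UnmaskedContig

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusParams",
    "ConsensusColumn",
    "HaplotypeAssembly",
    "ErrorReport",
    "iterative_consensus_align",
    "call_consensus",
    "write_assemblies_fastq",
    "error_report",
]

_SYMBOLS = ("A", "C", "G", "T", "-")


@dataclass(frozen=True)
class ConsensusParams:
    epsilon: float = 0.005
    conversion_rate: float = 0.5
    max_rounds: int = 5
    quality_cap: int = 93


@dataclass
class ConsensusColumn:
    position: int
    base_counts: dict[str, int]  # over A, C, G, T, '-'
    masked_t: int = 0  # masked observations on the C/T channel
    masked_a: int = 0  # masked observations on the G/A channel
    low_confidence: bool = False

    @property
    def covering(self) -> int:
        return sum(self.base_counts.values()) + self.masked_t + self.masked_a


@dataclass
class HaplotypeAssembly:
    label: str
    sequence: str
    qualities: list[int]
    coverage: list[int]  # covering templates per emitted base

    def median_quality(self) -> float:
        return float(np.median(self.qualities)) if self.qualities else 0.0

    def trimmed(self, min_coverage: int = 3) -> "HaplotypeAssembly":
        """Sub-assembly between the first and last base reaching
        ``min_coverage`` covering templates (ends of the region are seen by
        few fragments and carry correspondingly low confidence)."""
        idx = [i for i, c in enumerate(self.coverage) if c >= min_coverage]
        if not idx:
            return HaplotypeAssembly(self.label, "", [], [])
        lo, hi = idx[0], idx[-1] + 1
        return HaplotypeAssembly(
            self.label,
            self.sequence[lo:hi],
            self.qualities[lo:hi],
            self.coverage[lo:hi],
        )


@dataclass
class ErrorReport:
    per_contig: pd.DataFrame
    snv_rate: float
    indel_rate: float
    microsatellite_fraction: float  # indels at mono-/di-nucleotide repeats
    post_conversion_repeat_fraction: float
    n_excluded: int = 0


def _align_obs(contig: UnmaskedContig, ref: str) -> tuple[dict[int, str], dict[int, str]]:
    """Observations of one contig over reference coordinates.

    Returns (per-position symbol, insertions-after-position). Symbols are
    A/C/G/T, 'y'/'r' for masked channels, '-' for deletions.
    """
    disp = contig.display_sequence()
    res = edlib.align(disp, ref, mode="HW", task="path",
                      additionalEqualities=MASK_EQUALITIES)
    start = res["locations"][0][0]
    obs: dict[int, str] = {}
    inserts: dict[int, str] = {}
    qi, ti = 0, start
    pending: list[str] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                if pending:
                    inserts[ti - 1] = "".join(pending)
                    pending = []
                mask = contig.masked_positions.get(qi)
                if mask == "Y":
                    obs[ti] = "y"
                elif mask == "R":
                    obs[ti] = "r"
                else:
                    obs[ti] = contig.sequence[qi]
                qi += 1
                ti += 1
        elif ch == "I":
            for _ in range(n):
                pending.append(contig.sequence[qi])
                qi += 1
        elif ch == "D":
            for _ in range(n):
                if pending:
                    inserts[ti - 1] = "".join(pending)
                    pending = []
                obs[ti] = "-"
                ti += 1
    return obs, inserts


def iterative_consensus_align(
    contigs: Sequence[UnmaskedContig], params: ConsensusParams = ConsensusParams()
) -> list[ConsensusColumn]:
    """Co-align one haplotype's contigs, correcting reference indel errors.

    Round 1 aligns every contig to the longest; any column where a gap (or a
    shared insertion) is the strict majority call edits the working
    reference, which is realigned, until no such column remains or the round
    cap is hit (then affected columns are flagged low-confidence).
    """
    if not contigs:
        raise ValueError("consensus requires at least one contig")
    ordered = sorted(contigs, key=lambda c: (-len(c), c.contig_id))
    ref = ordered[0].display_sequence()
    oscillating = False
    for round_no in range(params.max_rounds):
        all_obs = [_align_obs(c, ref) for c in ordered]
        edits: list[tuple[int, str, str]] = []  # (pos, 'del'|'ins', seq)
        n_ref = len(ref)
        for pos in range(n_ref):
            cover = sum(1 for obs, _ in all_obs if pos in obs)
            if cover == 0:
                continue
            gaps = sum(1 for obs, _ in all_obs if obs.get(pos) == "-")
            if gaps * 2 > cover:
                edits.append((pos, "del", ""))
                continue
            ins_here = [ins[pos] for _, ins in all_obs if pos in ins]
            if ins_here and 2 * len(ins_here) > cover:
                top = sorted(ins_here, key=lambda s: (-ins_here.count(s), s))[0]
                edits.append((pos, "ins", top))
        if not edits:
            break
        for pos, kind, seq in sorted(edits, reverse=True):
            if kind == "del":
                ref = ref[:pos] + ref[pos + 1 :]
            else:
                ref = ref[: pos + 1] + seq + ref[pos + 1 :]
    else:
        oscillating = True
        logger.warning(
            "indel correction did not settle within %d rounds", params.max_rounds
        )
        all_obs = [_align_obs(c, ref) for c in ordered]

    columns = []
    for pos in range(len(ref)):
        counts = {s: 0 for s in _SYMBOLS}
        masked_t = masked_a = 0
        for obs, _ in all_obs:
            sym = obs.get(pos)
            if sym is None:
                continue
            if sym == "y":
                masked_t += 1
            elif sym == "r":
                masked_a += 1
            else:
                counts[sym] += 1
        columns.append(
            ConsensusColumn(
                position=pos,
                base_counts=counts,
                masked_t=masked_t,
                masked_a=masked_a,
                low_confidence=oscillating,
            )
        )
    return columns


def call_consensus(
    columns: Sequence[ConsensusColumn],
    params: ConsensusParams = ConsensusParams(),
    label: str = "H1",
) -> HaplotypeAssembly:
    """Posterior base call and Phred quality per column.

    Gap calls are dropped from the emitted sequence; zero-coverage columns
    are emitted as N with Q0.
    """
    eps = params.epsilon
    p = params.conversion_rate
    log1me = math.log1p(-eps)
    loge3 = math.log(eps / 3.0)
    logp = math.log(p)
    seq: list[str] = []
    quals: list[int] = []
    cover: list[int] = []
    for col in columns:
        n_cov = col.covering
        if n_cov == 0:
            seq.append("N")
            quals.append(0)
            cover.append(0)
            continue
        logpost = np.zeros(len(_SYMBOLS))
        for bi, b in enumerate(_SYMBOLS):
            ll = 0.0
            for sym, count in col.base_counts.items():
                if count == 0:
                    continue
                ll += count * (log1me if sym == b else loge3)
            if col.masked_t:
                if b == "C":
                    ll += col.masked_t * logp
                elif b == "T":
                    ll += col.masked_t * log1me
                else:
                    ll += col.masked_t * loge3
            if col.masked_a:
                if b == "G":
                    ll += col.masked_a * logp
                elif b == "A":
                    ll += col.masked_a * log1me
                else:
                    ll += col.masked_a * loge3
            logpost[bi] = ll
        logpost -= logpost.max()
        post = np.exp(logpost)
        post /= post.sum()
        bi = int(np.argmax(post))  # ties: first in A,C,G,T,- order
        err = float(1.0 - post[bi])
        q = params.quality_cap if err <= 0 else min(
            params.quality_cap, int(round(-10.0 * math.log10(max(err, 1e-300))))
        )
        if col.low_confidence:
            q = min(q, 2)
        if _SYMBOLS[bi] == "-":
            continue  # deletion in the consensus: emit nothing
        seq.append(_SYMBOLS[bi])
        quals.append(q)
        cover.append(n_cov)
    return HaplotypeAssembly(label=label, sequence="".join(seq),
                             qualities=quals, coverage=cover)


def write_assemblies_fastq(
    assemblies: Sequence[HaplotypeAssembly], path, cap: int = 93
) -> int:
    """Write final haplotype assemblies as Phred+33 FASTQ."""
    records = []
    for a in assemblies:
        name = f"{a.label} length={len(a.sequence)} medianQ={a.median_quality():.0f}"
        records.append((name, a.sequence, phred_to_ascii(a.qualities, cap=cap)))
    return write_fastq(records, path)


# ---------------------------------------------------------------------------
# residual error audit

def _is_mononucleotide_run(seq: str, pos: int, min_run: int = 3) -> bool:
    for s in range(max(0, pos - min_run + 1), min(pos + 1, len(seq) - min_run + 1)):
        window = seq[s : s + min_run]
        if len(set(window)) == 1:
            return True
    return False


def _is_dinucleotide_repeat(seq: str, pos: int, min_units: int = 2) -> bool:
    span = 2 * min_units
    for s in range(max(0, pos - span + 1), min(pos + 1, len(seq) - span + 1)):
        window = seq[s : s + span]
        unit = window[:2]
        if unit[0] != unit[1] and window == unit * min_units:
            return True
    return False


def error_report(
    assigned: dict[str, Sequence[UnmaskedContig]],
    assemblies: dict[str, HaplotypeAssembly],
    n_excluded: int = 0,
) -> ErrorReport:
    """Residual per-template error rates against the final assemblies.

    Aligns each assigned contig to its haplotype consensus; counts SNV
    mismatches and indel events per aligned base (masked positions align as
    matches and are not counted); classifies each indel's sequence context:
    mononucleotide runs (>=3), dinucleotide repeats (>=2 units), and
    mononucleotide runs on the fully converted consensus.
    """
    rows = []
    n_ms = n_post = n_indel_total = 0
    for label in sorted(assigned):
        if label not in assemblies:
            continue
        cons = assemblies[label].sequence
        conv_cons = full_conversion(cons)
        for contig in assigned[label]:
            disp = contig.display_sequence()
            res = edlib.align(disp, cons, mode="HW", task="path",
                              additionalEqualities=MASK_EQUALITIES)
            start = res["locations"][0][0]
            snv = 0
            indel_events = 0
            aligned = 0
            ti = start
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                    continue
                n = int(num)
                num = ""
                if ch == "=":
                    aligned += n
                    ti += n
                elif ch == "X":
                    snv += n
                    aligned += n
                    ti += n
                elif ch in "ID":
                    indel_events += 1
                    n_indel_total += 1
                    pos = min(ti, len(cons) - 1)
                    if _is_mononucleotide_run(cons, pos) or _is_dinucleotide_repeat(cons, pos):
                        n_ms += 1
                    if _is_mononucleotide_run(conv_cons, pos):
                        n_post += 1
                    if ch == "D":
                        ti += n
                    aligned += n
            rows.append(
                {
                    "contig_id": contig.contig_id,
                    "haplotype": label,
                    "aligned_bases": aligned,
                    "snv_mismatches": snv,
                    "indel_events": indel_events,
                    "snv_rate": snv / aligned if aligned else 0.0,
                    "indel_rate": indel_events / aligned if aligned else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    total_bases = int(df["aligned_bases"].sum()) if len(df) else 0
    snv_rate = float(df["snv_mismatches"].sum()) / total_bases if total_bases else 0.0
    indel_rate = float(df["indel_events"].sum()) / total_bases if total_bases else 0.0
    ms_frac = n_ms / n_indel_total if n_indel_total else 0.0
    post_frac = n_post / n_indel_total if n_indel_total else 0.0
    return ErrorReport(
        per_contig=df,
        snv_rate=snv_rate,
        indel_rate=indel_rate,
        microsatellite_fraction=ms_frac,
        post_conversion_repeat_fraction=post_frac,
        n_excluded=n_excluded,
    )
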