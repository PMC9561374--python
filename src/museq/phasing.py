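"""Maximum-likelihood partitioning of unmasked contigs into haplotypes.

Long unmasked contigs (>1.5 kb by default) are co-aligned to the longest one,
bi-allelic sites are extracted into a contigs x sites observation matrix, and
the best set of M haplotypes is found by maximising

    sum over contigs of  max over haplotypes h of  log L(contig | h)

where each non-missing site contributes log(1-eps) on a match, log(eps) on a
mismatch, and a still-masked T observation contributes log(p) when the
haplotype carries C there (the T could be that C, converted) and log(1-eps)
when it carries T. Small problems are solved by exhaustive enumeration over
allele configurations (up to haplotype relabeling); larger ones by simulated
annealing with single-allele flip moves, geometric cooling and restarts.
Contigs are assigned to a haplotype only when they are far more likely
(1000:1 by default) to derive from it than from any other.

Pairwise alignment is delegated to edlib with additional equality pairs so
that a masked 't' matches either C or T (and a masked 'a' matches A or G);
the reported score recomputes the alignment under match +1, mismatch -1,
gap open -3, gap extend -1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .unmask import UnmaskedContig

logger = logging.getLogger(__name__)

__all__ = [
    "PhasingParams",
    "AnnealSchedule",
    "CoAlignment",
    "ContigAlignment",
    "BiallelicMatrix",
    "Haplotype",
    "PartitionResult",
    "coalign",
    "build_biallelic_matrix",
    "contig_loglik",
    "fit_haplotypes",
    "assign_contigs",
    "detect_recombinants",
]

MASK_EQUALITIES = [("t", "T"), ("t", "C"), ("a", "A"), ("a", "G")]

# observation codes in the matrix
OBS_A0, OBS_A1, OBS_MASKED, OBS_MISSING = 0, 1, 2, 3


@dataclass(frozen=True)
class AnnealSchedule:
    initial_temperature: float = 2.0
    cooling: float = 0.995
    steps: int = 5000
    restarts: int = 8
    seed: int = 0


@dataclass(frozen=True)
class PhasingParams:
    min_contig_length: int = 1500
    ploidy: int = 2
    epsilon: float = 0.005  # per-site observation error probability
    conversion_rate: float = 0.5  # masked-T channel probability
    assignment_ratio: float = 1000.0
    exhaustive_limit: int = 100_000  # max enumerated configurations
    min_identity: float = 0.90
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)

    def validate(self) -> None:
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.assignment_ratio <= 1.0:
            raise ValueError("assignment_ratio must exceed 1")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass
class ContigAlignment:
    contig_id: str
    target_start: int
    # per contig base: reference-contig column, -1 for inserted bases
    ref_columns: np.ndarray
    gapped_query: str
    gapped_target: str
    identity: float
    score: int


@dataclass
class CoAlignment:
    reference_contig_id: str
    reference_sequence: str  # masked-display frame of the reference contig
    alignments: dict[str, ContigAlignment]
    excluded: list[str]


@dataclass
class Column:
    position: int  # reference-contig coordinate
    kind: str  # 'snv' | 'del' | 'ins'
    alleles: tuple[str, str]
    conv_allele: int  # allele index that masked evidence may hide, -1 if none


@dataclass
class BiallelicMatrix:
    contig_ids: list[str]
    columns: list[Column]
    data: np.ndarray  # (contigs x columns) int8 of OBS_* codes

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class Haplotype:
    label: str
    alleles: tuple[int, ...]  # 0/1 per matrix column


@dataclass
class PartitionResult:
    haplotypes: list[Haplotype]
    logliks: np.ndarray  # (contigs x M)
    assignments: dict[str, list[str]]  # haplotype label -> contig ids
    unassigned: list[str]
    total_loglik: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# co-alignment

def _align_score(gq: str, gt: str) -> int:
    """Score a gapped alignment: match +1, mismatch -1, gap open -3, extend -1.

    Masked characters count as matches against their compatible bases.
    """
    eq = {frozenset(p) for p in MASK_EQUALITIES}
    score = 0
    in_gap = False
    for a, b in zip(gq, gt):
        if a == "-" or b == "-":
            score += -3 if not in_gap else -1
            in_gap = True
            continue
        in_gap = False
        if a == b or frozenset((a, b)) in eq:
            score += 1
        else:
            score -= 1
    return score


def _edlib_align(query: str, target: str) -> dict:
    return edlib.align(
        query, target, mode="HW", task="path", additionalEqualities=MASK_EQUALITIES
    )


def coalign(
    contigs: Sequence[UnmaskedContig], params: PhasingParams
) -> CoAlignment:
    """Co-align long unmasked contigs to the longest one.

    Contigs below ``min_contig_length`` are dropped; alignments below the
    identity floor are excluded with a warning. Masked positions match either
    of their compatible bases during alignment.
    """
    params.validate()
    retained = [c for c in contigs if len(c) >= params.min_contig_length]
    if not retained:
        raise ValueError(
            f"no contig reaches min_contig_length={params.min_contig_length}; "
            "lower the threshold"
        )
    retained.sort(key=lambda c: (-len(c), c.contig_id))
    ref = retained[0]
    ref_disp = ref.display_sequence()
    alignments: dict[str, ContigAlignment] = {}
    excluded: list[str] = []
    for c in retained:
        disp = c.display_sequence()
        res = _edlib_align(disp, ref_disp)
        start = res["locations"][0][0]
        gq, gt, ref_cols = _expand_cigar(res["cigar"], disp, ref_disp, start)
        ident = 1.0 - res["editDistance"] / max(1, len(gq))
        if ident < params.min_identity:
            logger.warning(
                "contig %s aligns at %.1f%% identity (< %.0f%%); excluded",
                c.contig_id, 100 * ident, 100 * params.min_identity,
            )
            excluded.append(c.contig_id)
            continue
        alignments[c.contig_id] = ContigAlignment(
            contig_id=c.contig_id,
            target_start=start,
            ref_columns=ref_cols,
            gapped_query=gq,
            gapped_target=gt,
            identity=ident,
            score=_align_score(gq, gt),
        )
    return CoAlignment(ref.contig_id, ref_disp, alignments, excluded)


def _expand_cigar(
    cigar: str, query: str, target: str, target_start: int
) -> tuple[str, str, np.ndarray]:
    """Expand an edlib extended cigar into gapped strings and a per-query-base
    reference column map (-1 for inserted bases)."""
    gq: list[str] = []
    gt: list[str] = []
    ref_cols = np.full(len(query), -1, dtype=np.int64)
    qi, ti = 0, target_start
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                gq.append(query[qi])
                gt.append(target[ti])
                ref_cols[qi] = ti
                qi += 1
                ti += 1
        elif ch == "I":  # insertion relative to the reference contig
            for _ in range(n):
                gq.append(query[qi])
                gt.append("-")
                qi += 1
        elif ch == "D":  # deletion: reference base absent from the query
            for _ in range(n):
                gq.append("-")
                gt.append(target[ti])
                ti += 1
        else:
            raise ValueError(f"unexpected cigar op {ch!r}")
    return "".join(gq), "".join(gt), ref_cols


# ---------------------------------------------------------------------------
# bi-allelic matrix

def build_biallelic_matrix(
    coalignment: CoAlignment,
    contigs: Sequence[UnmaskedContig],
    min_allele_support: int = 2,
) -> BiallelicMatrix:
    """Extract bi-allelic sites from the co-alignment.

    Substitution columns are reference positions where exactly two distinct
    unmasked bases each appear in >= ``min_allele_support`` contigs. Indel
    polymorphisms become presence/absence columns (runs of reference
    positions with identical deletion patterns merge into one column;
    insertions are keyed by the position they follow). Entries are allele
    codes, masked (where the masked channel spans the two alleles), or
    missing.
    """
    by_id = {c.contig_id: c for c in contigs}
    ref_len = len(coalignment.reference_sequence)
    ids = sorted(coalignment.alignments)
    # per contig: observation over reference positions
    # symbols: A/C/G/T (unmasked), 'y'/'r' masked channels, '-' deletion, '' missing
    obs: dict[str, np.ndarray] = {}
    ins_events: dict[str, dict[int, str]] = {}
    for cid in ids:
        aln = coalignment.alignments[cid]
        contig = by_id[cid]
        row = np.full(ref_len, "", dtype=object)
        inserts: dict[int, str] = {}
        qi, ti = 0, aln.target_start
        pending_ins: list[str] = []
        for a, b in zip(aln.gapped_query, aln.gapped_target):
            if b == "-":
                pending_ins.append(a.upper())
                qi += 1
                continue
            if pending_ins:
                inserts[ti - 1] = "".join(pending_ins)
                pending_ins = []
            if a == "-":
                row[ti] = "-"
            else:
                ch = contig.masked_positions.get(qi)
                if ch == "Y":
                    row[ti] = "y"
                elif ch == "R":
                    row[ti] = "r"
                else:
                    row[ti] = a.upper()
                qi += 1
            ti += 1
        obs[cid] = row
        ins_events[cid] = inserts

    columns: list[Column] = []
    entries: list[np.ndarray] = []

    # substitution columns
    for pos in range(ref_len):
        tally: dict[str, int] = {}
        for cid in ids:
            sym = obs[cid][pos]
            if sym in ("A", "C", "G", "T"):
                tally[sym] = tally.get(sym, 0) + 1
        supported = sorted(b for b, n in tally.items() if n >= min_allele_support)
        if len(supported) != 2:
            continue
        a0, a1 = supported
        conv_allele = -1
        if {a0, a1} == {"C", "T"}:
            conv_allele = supported.index("C")
        elif {a0, a1} == {"A", "G"}:
            conv_allele = supported.index("G")
        col = np.full(len(ids), OBS_MISSING, dtype=np.int8)
        for r, cid in enumerate(ids):
            sym = obs[cid][pos]
            if sym == a0:
                col[r] = OBS_A0
            elif sym == a1:
                col[r] = OBS_A1
            elif sym == "y" and {a0, a1} == {"C", "T"}:
                col[r] = OBS_MASKED
            elif sym == "r" and {a0, a1} == {"A", "G"}:
                col[r] = OBS_MASKED
        columns.append(Column(pos, "snv", (a0, a1), conv_allele))
        entries.append(col)

    # deletion columns: merge adjacent positions with the same pattern
    del_state = np.zeros((len(ids), ref_len), dtype=np.int8)  # 1 del, 2 base, 0 n/a
    for r, cid in enumerate(ids):
        row = obs[cid]
        for pos in range(ref_len):
            if row[pos] == "-":
                del_state[r, pos] = 1
            elif row[pos] != "":
                del_state[r, pos] = 2
    prev_pattern = None
    for pos in range(ref_len):
        n_del = int((del_state[:, pos] == 1).sum())
        n_base = int((del_state[:, pos] == 2).sum())
        if n_del >= min_allele_support and n_base >= min_allele_support:
            pattern = tuple(del_state[:, pos])
            if pattern == prev_pattern:
                continue  # same event as the previous reference position
            prev_pattern = pattern
            col = np.full(len(ids), OBS_MISSING, dtype=np.int8)
            for r in range(len(ids)):
                if del_state[r, pos] == 1:
                    col[r] = OBS_A0
                elif del_state[r, pos] == 2:
                    col[r] = OBS_A1
            columns.append(Column(pos, "del", ("-", "+"), -1))
            entries.append(col)
        else:
            prev_pattern = None

    # insertion columns (presence/absence after a reference position)
    ins_positions = sorted({p for cid in ids for p in ins_events[cid]})
    for pos in ins_positions:
        have = [cid for cid in ids if pos in ins_events[cid]]
        lack = [
            cid for cid in ids
            if pos not in ins_events[cid] and obs[cid][pos] != ""
        ]
        if len(have) < min_allele_support or len(lack) < min_allele_support:
            continue
        col = np.full(len(ids), OBS_MISSING, dtype=np.int8)
        for r, cid in enumerate(ids):
            if cid in have:
                col[r] = OBS_A1
            elif cid in lack:
                col[r] = OBS_A0
        columns.append(Column(pos, "ins", ("-", "+"), -1))
        entries.append(col)

    if columns:
        order = sorted(range(len(columns)), key=lambda i: (columns[i].position, columns[i].kind))
        columns = [columns[i] for i in order]
        data = np.stack([entries[i] for i in order], axis=1)
    else:
        data = np.zeros((len(ids), 0), dtype=np.int8)
    return BiallelicMatrix(contig_ids=ids, columns=columns, data=data)


# ---------------------------------------------------------------------------
# likelihood model

def contig_loglik(
    row: np.ndarray,
    hap: Sequence[int],
    params: PhasingParams,
    columns: Sequence[Column] | None = None,
    conv_alleles: np.ndarray | None = None,
) -> float:
    """Log-likelihood that one contig row derives from haplotype ``hap``.

    Per non-missing column: matching allele -> log(1-eps); mismatching ->
    log(eps); masked observation -> log(p) if the haplotype carries the
    convertible allele (C, or G on the mirrored strand), else log(1-eps).
    Missing columns contribute 0.
    """
    if conv_alleles is None:
        if columns is None:
            raise ValueError("provide either columns or conv_alleles")
        conv_alleles = np.array([c.conv_allele for c in columns], dtype=np.int8)
    hap_arr = np.asarray(hap, dtype=np.int8)
    eps = params.epsilon
    log1me = math.log1p(-eps)
    loge = math.log(eps)
    logp = math.log(params.conversion_rate)
    total = 0.0
    for j, o in enumerate(row):
        if o == OBS_MISSING:
            continue
        if o == OBS_MASKED:
            total += logp if hap_arr[j] == conv_alleles[j] else log1me
        elif o == hap_arr[j]:
            total += log1me
        else:
            total += loge
    return total


def _row_logliks_for_hap(
    data: np.ndarray, hap: np.ndarray, conv: np.ndarray, params: PhasingParams
) -> np.ndarray:
    """Vectorised contig_loglik for all rows against one haplotype."""
    eps = params.epsilon
    log1me = math.log1p(-eps)
    loge = math.log(eps)
    logp = math.log(params.conversion_rate)
    out = np.zeros(data.shape[0])
    for j in range(data.shape[1]):
        col = data[:, j]
        contrib = np.zeros(data.shape[0])
        match = col == hap[j]
        mismatch = (col == (1 - hap[j])) & (col <= 1)
        masked = col == OBS_MASKED
        contrib[match & (col <= 1)] = log1me
        contrib[mismatch] = loge
        if hap[j] == conv[j]:
            contrib[masked] = logp
        else:
            contrib[masked] = log1me
        out += contrib
    return out


# ---------------------------------------------------------------------------
# haplotype fitting

def _objective(loglik_matrix: np.ndarray) -> float:
    return float(loglik_matrix.max(axis=1).sum())


def _n_combinations(n_codes: int, m: int) -> float:
    return math.comb(n_codes + m - 1, m)


def fit_haplotypes(
    matrix: BiallelicMatrix, params: PhasingParams
) -> PartitionResult:
    """Find the M haplotypes maximising the partition likelihood.

    Exhaustive enumeration over unordered M-sets of allele configurations
    when their number is within ``exhaustive_limit``; otherwise simulated
    annealing (single-allele flips, geometric cooling, restarts, best kept).
    Deterministic under the schedule seed.
    """
    params.validate()
    M = params.ploidy
    R, n = matrix.shape
    if n == 0:
        haps = [Haplotype(label=f"H{i + 1}", alleles=()) for i in range(M)]
        logliks = np.zeros((R, M))
        assignments = {h.label: [] for h in haps}
        assignments["H1"] = list(matrix.contig_ids)
        return PartitionResult(
            haplotypes=haps,
            logliks=logliks,
            assignments=assignments,
            unassigned=[],
            total_loglik=0.0,
            flags=["monomorphic"],
        )
    conv = np.array([c.conv_allele for c in matrix.columns], dtype=np.int8)
    data = matrix.data

    flags: list[str] = []
    if n <= 20 and _n_combinations(2**n, M) <= params.exhaustive_limit:
        codes = np.array(
            [[(c >> j) & 1 for j in range(n)] for c in range(2**n)], dtype=np.int8
        )
        RL = np.stack(
            [_row_logliks_for_hap(data, codes[c], conv, params) for c in range(2**n)],
            axis=1,
        )  # rows x codes
        best_obj = -np.inf
        best_combo: tuple[int, ...] = ()
        for combo in itertools.combinations_with_replacement(range(2**n), M):
            obj = float(RL[:, list(combo)].max(axis=1).sum())
            if obj > best_obj + 1e-12:
                best_obj = obj
                best_combo = combo
        hap_arrays = [codes[c].copy() for c in best_combo]
    else:
        hap_arrays, best_obj, spread = _anneal(data, conv, params)
        if spread > 1e-6:
            flags.append("anneal_nonconvergent")

    # canonical order for label stability
    hap_arrays.sort(key=lambda a: tuple(a))
    haps = [
        Haplotype(label=f"H{i + 1}", alleles=tuple(int(x) for x in a))
        for i, a in enumerate(hap_arrays)
    ]
    logliks = np.stack(
        [_row_logliks_for_hap(data, np.asarray(h.alleles, dtype=np.int8), conv, params)
         for h in haps],
        axis=1,
    )
    result = PartitionResult(
        haplotypes=haps,
        logliks=logliks,
        assignments={},
        unassigned=[],
        total_loglik=best_obj,
        flags=flags,
    )
    return assign_contigs(matrix, result, params)


def _anneal(
    data: np.ndarray, conv: np.ndarray, params: PhasingParams
) -> tuple[list[np.ndarray], float, float]:
    M = params.ploidy
    R, n = data.shape
    sched = params.anneal
    best_overall = None
    best_obj = -np.inf
    restart_objs = []
    for restart in range(sched.restarts):
        rng = np.random.default_rng((sched.seed, restart))
        haps = rng.integers(0, 2, size=(M, n)).astype(np.int8)
        RL = np.stack(
            [_row_logliks_for_hap(data, haps[h], conv, params) for h in range(M)],
            axis=1,
        )
        cur_obj = _objective(RL)
        local_best = cur_obj
        local_best_haps = haps.copy()
        temp = sched.initial_temperature
        for step in range(sched.steps):
            h = int(rng.integers(0, M))
            j = int(rng.integers(0, n))
            haps[h, j] ^= 1
            new_col = _row_logliks_for_hap(data, haps[h], conv, params)
            old_col = RL[:, h].copy()
            RL[:, h] = new_col
            new_obj = _objective(RL)
            delta = new_obj - cur_obj
            if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-9)):
                cur_obj = new_obj
                if cur_obj > local_best:
                    local_best = cur_obj
                    local_best_haps = haps.copy()
            else:
                haps[h, j] ^= 1
                RL[:, h] = old_col
            temp *= sched.cooling
        restart_objs.append(local_best)
        if local_best > best_obj:
            best_obj = local_best
            best_overall = local_best_haps
    spread = float(max(restart_objs) - min(restart_objs)) if restart_objs else 0.0
    if spread > 1e-6:
        logger.warning(
            "annealing restarts disagree (objective spread %.3g); "
            "result may not be the global optimum", spread,
        )
    return [best_overall[h].copy() for h in range(M)], best_obj, spread


def assign_contigs(
    matrix: BiallelicMatrix, result: PartitionResult, params: PhasingParams
) -> PartitionResult:
    """Finalise assignment sets under the likelihood-ratio threshold.

    A contig joins haplotype h only when its likelihood under h beats the
    best alternative by at least ``assignment_ratio``; otherwise it stays
    unassigned.
    """
    if "monomorphic" in result.flags:
        return result
    log_ratio = math.log(params.assignment_ratio)
    assignments: dict[str, list[str]] = {h.label: [] for h in result.haplotypes}
    unassigned: list[str] = []
    for r, cid in enumerate(matrix.contig_ids):
        lls = result.logliks[r]
        order = np.argsort(lls)[::-1]
        best, second = order[0], order[1] if len(lls) > 1 else order[0]
        if len(lls) == 1 or lls[best] - lls[second] >= log_ratio:
            assignments[result.haplotypes[best].label].append(cid)
        else:
            unassigned.append(cid)
    result.assignments = assignments
    result.unassigned = unassigned
    return result


def detect_recombinants(
    matrix: BiallelicMatrix, result: PartitionResult, params: PhasingParams
) -> list[dict]:
    """Flag contigs whose alleles switch haplotype along their length.

    Compares the best single-haplotype explanation with the best two-
    haplotype single-switch explanation (columns ordered by reference
    position); a contig is flagged when the switch model wins by the
    assignment ratio, and the switch interval (between matrix columns) is
    reported.
    """
    if matrix.shape[1] == 0 or params.ploidy < 2:
        return []
    conv = np.array([c.conv_allele for c in matrix.columns], dtype=np.int8)
    log_ratio = math.log(params.assignment_ratio)
    eps = params.epsilon
    log1me = math.log1p(-eps)
    loge = math.log(eps)
    logp = math.log(params.conversion_rate)
    R, n = matrix.shape
    M = len(result.haplotypes)

    # per-column contribution of each row under each haplotype
    contrib = np.zeros((R, M, n))
    for h, hap in enumerate(result.haplotypes):
        a = np.asarray(hap.alleles, dtype=np.int8)
        for j in range(n):
            col = matrix.data[:, j]
            cc = np.zeros(R)
            cc[(col <= 1) & (col == a[j])] = log1me
            cc[(col <= 1) & (col != a[j])] = loge
            cc[col == OBS_MASKED] = logp if a[j] == conv[j] else log1me
            contrib[:, h, j] = cc

    flagged = []
    for r, cid in enumerate(matrix.contig_ids):
        per_hap = contrib[r].sum(axis=1)
        best_single = float(per_hap.max())
        prefix = np.concatenate(
            [np.zeros((M, 1)), np.cumsum(contrib[r], axis=1)], axis=1
        )  # prefix[h, s] = sum of columns < s under h
        total = prefix[:, -1]
        best_switch = -np.inf
        best_cfg = None
        for h1 in range(M):
            for h2 in range(M):
                if h1 == h2:
                    continue
                for s in range(1, n):
                    ll = prefix[h1, s] + (total[h2] - prefix[h2, s])
                    if ll > best_switch:
                        best_switch = float(ll)
                        best_cfg = (h1, h2, s)
        if best_cfg is not None and best_switch - best_single >= log_ratio:
            h1, h2, s = best_cfg
            flagged.append(
                {
                    "contig_id": cid,
                    "from": result.haplotypes[h1].label,
                    "to": result.haplotypes[h2].label,
                    "switch_after_column": s - 1,
                    "switch_interval": (
                        matrix.columns[s - 1].position,
                        matrix.columns[s].position,
                    ),
                    "log_likelihood_gain": best_switch - best_single,
                }
            )
    return flagged
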