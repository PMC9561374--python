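"""Assembly of individual mutation-imprinted template molecules.

Because every template carries a dense, essentially unique pattern of C->T
conversions, long k-mers (k=111 by default) almost never collide between
templates, and the de Bruijn graph of the mutated library decomposes into one
clean path per template wherever coverage permits. The stages are:

1. ``build_graph`` — k-mer graph of the mutated reads, mate 2 reoriented into
   the fragment-forward frame, no strand folding (conversion breaks strand
   symmetry; each template is assembled in its read orientation).
2. ``initial_contigs`` — maximal unambiguous paths of the graph.
3. ``extend_contigs`` — paired-end joining: mates anchored on a contig by an
   exact k-mer place their partners over the contig end; single-base
   extensions are accepted while the fraction of overlapping placed mates
   agreeing with the consensus base is at least the disruption parameter D,
   and contigs sharing a unique exact overlap of >= k bases are merged.
4. ``estimate_template_count`` — distinct mutation patterns per unmutated
   k-mer, thresholded at a minimum read support, summarised by a high
   quantile.
5. ``validate_templates`` / ``detect_chimeras`` — read re-mapping coverage
   audit and provenance-based chimera screening.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .seqio import BASES, full_conversion
from .simdata import parse_provenance

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyParams",
    "DeBruijnGraph",
    "Contig",
    "TemplateCountEstimate",
    "ChimeraReport",
    "build_graph",
    "initial_contigs",
    "extend_contigs",
    "estimate_template_count",
    "validate_templates",
    "detect_chimeras",
    "chimera_rate",
]


@dataclass(frozen=True)
class AssemblyParams:
    """Tunable parameters of the template-assembly stage.

    ``D`` is the disruption parameter: the minimum fraction of placed,
    overlapping mates that must agree with the consensus base for a
    single-base extension to be accepted. 0.95 tolerates ~5% discordant
    evidence (strict); 0.55 requires only a majority (permissive).
    """

    k: int = 111
    D: float = 0.95
    min_kmer_count: int = 2
    min_pattern_support: int = 20
    min_template_median_coverage: float = 100.0
    seed_size: int = 25  # exact seed used to place mates during extension
    max_rounds: int = 30
    table_subsample: int = 1  # template counting: keep 1/n of unmutated k-mers

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.5 < self.D <= 1.0:
            raise ValueError("disruption parameter D must lie in (0.5, 1]")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


@dataclass
class DeBruijnGraph:
    """k-mer graph with (k-1)-overlap edges supported by read adjacency."""

    k: int
    nodes: dict[str, int]  # k-mer -> occurrence count (>= min_kmer_count)
    edges: dict[str, int]  # (k+1)-mer -> adjacency support count
    _succ: dict[str, list[tuple[str, int]]] | None = field(default=None, repr=False)
    _pred: dict[str, list[tuple[str, int]]] | None = field(default=None, repr=False)

    def _adjacency(self) -> tuple[dict, dict]:
        if self._succ is None:
            succ: dict[str, list[tuple[str, int]]] = {}
            pred: dict[str, list[tuple[str, int]]] = {}
            for e, c in self.edges.items():
                u, v = e[:-1], e[1:]
                succ.setdefault(u, []).append((v, c))
                pred.setdefault(v, []).append((u, c))
            for d in (succ, pred):
                for lst in d.values():
                    lst.sort()
            self._succ, self._pred = succ, pred
        return self._succ, self._pred

    def successors(self, kmer: str) -> list[tuple[str, int]]:
        return self._adjacency()[0].get(kmer, [])

    def predecessors(self, kmer: str) -> list[tuple[str, int]]:
        return self._adjacency()[1].get(kmer, [])

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Contig:
    contig_id: str
    sequence: str
    stage: str  # 'initial' | 'extended'
    supporting_read_ids: set[str] = field(default_factory=set)
    per_position_coverage: np.ndarray | None = None
    library_label_counts: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TemplateCountEstimate:
    per_kmer_distinct_pattern_counts: np.ndarray
    estimate: int
    k: int
    min_pattern_support: int


@dataclass
class ChimeraReport:
    contig_id: str
    label_composition: dict[str, int]
    breakpoint_interval: tuple[int, int] | None
    verdict: str  # 'clean' | 'chimeric' | 'not evaluable'


# ---------------------------------------------------------------------------
# graph construction and unambiguous paths

def build_graph(reads: Sequence[str], params: AssemblyParams) -> DeBruijnGraph:
    """Count k-mers and (k+1)-mer adjacencies over oriented reads.

    Reads must already be in fragment-forward frame (see
    :func:`museq.seqio.oriented_reads`); no reverse-complement folding is
    performed because converted templates are single-stranded. Nodes with
    fewer than ``min_kmer_count`` occurrences are dropped, as are edges
    lacking a surviving endpoint.
    """
    params.validate()
    k = params.k
    if reads:
        maxlen = max(len(r) for r in reads)
        if k > maxlen:
            raise ValueError(f"k={k} exceeds the longest read length {maxlen}")
    node_counts: Counter[str] = Counter()
    edge_counts: Counter[str] = Counter()
    for seq in reads:
        n = len(seq)
        if n < k:
            continue
        node_counts.update(seq[i : i + k] for i in range(n - k + 1))
        if n > k:
            edge_counts.update(seq[i : i + k + 1] for i in range(n - k))
    nodes = {km: c for km, c in node_counts.items() if c >= params.min_kmer_count}
    edges = {
        e: c
        for e, c in edge_counts.items()
        if e[:-1] in nodes and e[1:] in nodes
    }
    logger.info("graph: %d nodes, %d edges (k=%d)", len(nodes), len(edges), k)
    return DeBruijnGraph(k=k, nodes=nodes, edges=edges)


def initial_contigs(graph: DeBruijnGraph) -> list[Contig]:
    """Emit maximal simple paths: every interior node has exactly one
    supported successor and one supported predecessor.

    Output is deterministic: longest first, ties broken lexicographically.
    Pure cycles are broken at their lexicographically smallest node and the
    resulting contig flagged ``cycle``.
    """
    succ, pred = graph._adjacency()
    visited: set[str] = set()
    paths: list[tuple[str, list[str]]] = []  # (flag, node path)

    def walk(start: str) -> list[str]:
        path = [start]
        cur = start
        while True:
            s = succ.get(cur, [])
            if len(s) != 1:
                break
            nxt = s[0][0]
            if len(pred.get(nxt, [])) != 1 or nxt in visited or nxt == start:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        return path

    for v in sorted(graph.nodes):
        if v in visited:
            continue
        p = pred.get(v, [])
        is_start = len(p) != 1 or len(succ.get(p[0][0], [])) != 1
        if not is_start:
            continue
        visited.add(v)
        paths.append(("", walk(v)))
    # remaining nodes belong to perfect cycles
    for v in sorted(graph.nodes):
        if v in visited:
            continue
        visited.add(v)
        paths.append(("cycle", walk(v)))

    seqs = []
    for flag, path in paths:
        seq = path[0] + "".join(node[-1] for node in path[1:])
        seqs.append((flag, seq))
    seqs.sort(key=lambda fs: (-len(fs[1]), fs[1]))
    contigs = []
    for idx, (flag, seq) in enumerate(seqs):
        c = Contig(contig_id=f"i{idx:05d}", sequence=seq, stage="initial")
        if flag:
            c.flags.append(flag)
        contigs.append(c)
    return contigs


# ---------------------------------------------------------------------------
# paired-end extension

_AMBIG = ("*", -1)


def _contig_kmer_index(seqs: dict[str, str], k: int) -> dict[str, tuple[str, int]]:
    index: dict[str, tuple[str, int]] = {}
    for cid in sorted(seqs):
        seq = seqs[cid]
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            prev = index.get(km)
            if prev is None:
                index[km] = (cid, i)
            elif prev is not _AMBIG and prev[0] != cid:
                index[km] = _AMBIG
    return index


def _anchor(
    seq: str, index: dict, k: int, seqs: dict[str, str] | None = None
) -> tuple[str, int] | None:
    """Position of the read start on a contig via an exact k-mer anchor.

    When contig sequences are supplied the placement is verified: the
    read/contig overlap must agree at >= 90% of its bases, which rejects
    chance k-mer collisions between near-identical templates.
    """
    get = index.get
    for i in range(len(seq) - k + 1):
        hit = get(seq[i : i + k])
        if hit is None or hit is _AMBIG:
            continue
        cid, start = hit[0], hit[1] - i
        if seqs is None:
            return cid, start
        contig = seqs[cid]
        lo = max(0, start)
        hi = min(len(contig), start + len(seq))
        a = contig[lo:hi]
        b = seq[lo - start : hi - start]
        mismatches = sum(1 for x, y in zip(a, b) if x != y)
        if mismatches <= 0.1 * (hi - lo):
            return cid, start
    return None


def _grow_right(
    seq: str,
    mates: list[str],
    D: float,
    seed_size: int,
    max_overhang: int,
) -> str:
    """Consensus extension of the right end from overhanging mate sequences.

    Each mate is placed by an exact seed against the contig suffix and must
    agree with >=90% of its overlap; the extension then advances one base at
    a time while the leading base carries at least fraction D of the votes.
    """
    n = len(seq)
    s = seed_size
    region_start = max(0, n - max_overhang - 250)
    suffix = seq[region_start:]
    seeds: dict[str, int] = {}
    for i in range(len(suffix) - s + 1):
        seeds.setdefault(suffix[i : i + s], region_start + i)
    votes: list[dict[str, int]] = []
    for mseq in mates:
        off = None
        for j in range(0, len(mseq) - s + 1, s):
            pos = seeds.get(mseq[j : j + s])
            if pos is not None:
                off = pos - j
                break
        if off is None or off < 0:
            continue
        overlap = n - off
        if overlap <= 0 or overlap >= len(mseq):
            continue
        a = seq[off:n]
        b = mseq[:overlap]
        mismatches = sum(1 for x, y in zip(a, b) if x != y)
        if mismatches > max(1, int(0.1 * overlap)):
            continue
        for t, base in enumerate(mseq[overlap:]):
            if t == len(votes):
                votes.append({})
            v = votes[t]
            v[base] = v.get(base, 0) + 1
    ext = []
    for v in votes:
        if not v:
            break
        total = sum(v.values())
        base, count = min(v.items(), key=lambda kv: (-kv[1], kv[0]))
        if count / total >= D:
            ext.append(base)
        else:
            break  # disruption: evidence too discordant to extend
    return "".join(ext)


def _estimate_fragment_stats(frags: list[int]) -> tuple[float, float]:
    if not frags:
        return 400.0, 60.0
    arr = np.asarray(frags, dtype=float)
    med = float(np.median(arr))
    sd = float(1.4826 * np.median(np.abs(arr - med))) or 60.0
    return med, sd


def extend_contigs(
    contigs: Sequence[Contig],
    pairs: Sequence[tuple[str, str, str]],
    params: AssemblyParams,
) -> list[Contig]:
    """Join and extend initial contigs with paired-end information.

    ``pairs`` are fragment-forward oriented mate pairs ``(name, left, right)``
    (see :func:`museq.seqio.oriented_pairs`). Iterates anchoring, end
    extension under the disruption parameter D, and unique exact-overlap
    merging until convergence. Conflicting merges (one contig end claimed by
    two partners) are skipped and logged.
    """
    params.validate()
    k = params.k
    seqs = {c.contig_id: c.sequence for c in contigs}
    support: dict[str, set[str]] = {cid: set() for cid in seqs}
    flags: dict[str, list[str]] = {c.contig_id: list(c.flags) for c in contigs}
    if not seqs:
        return []

    frag_lengths: list[int] = []
    for round_no in range(params.max_rounds):
        # re-anchor from scratch: support reflects the current contig set, so
        # each read pair backs at most one contig
        support = {cid: set() for cid in seqs}
        index = _contig_kmer_index(seqs, k)
        pend_right: dict[str, list[tuple[int, str]]] = {cid: [] for cid in seqs}
        pend_left: dict[str, list[tuple[int, str]]] = {cid: [] for cid in seqs}
        join_votes: Counter[tuple[str, str]] = Counter()
        frag_lengths = []
        for name, left, right in pairs:
            a_l = _anchor(left, index, k, seqs)
            a_r = _anchor(right, index, k, seqs)
            if a_l and a_r and a_l[0] == a_r[0]:
                support[a_l[0]].add(name)
                frag_lengths.append(a_r[1] + len(right) - a_l[1])
            elif a_l and a_r:
                # mates split across two contigs: each mate is extension
                # evidence for the other contig's end, until they merge
                support[a_l[0]].add(name)
                join_votes[(a_l[0], a_r[0])] += 1
                pend_right[a_l[0]].append((a_l[1], right))
                pend_left[a_r[0]].append((a_r[1], left))
            elif a_l:
                support[a_l[0]].add(name)
                pend_right[a_l[0]].append((a_l[1], right))
            elif a_r:
                support[a_r[0]].add(name)
                pend_left[a_r[0]].append((a_r[1], left))
        frag_med, frag_sd = _estimate_fragment_stats(frag_lengths)
        max_frag = int(frag_med + 4 * frag_sd)

        changed = False
        for cid in sorted(seqs):
            seq = seqs[cid]
            n = len(seq)
            right_mates = [m for (start, m) in pend_right[cid] if start + max_frag > n]
            if right_mates:
                ext = _grow_right(seq, right_mates, params.D, params.seed_size, max_frag)
                if ext:
                    seq = seq + ext
                    changed = True
            left_mates = [
                m for (start, m) in pend_left[cid] if start < max_frag
            ]
            if left_mates:
                rext = _grow_right(
                    seq[::-1], [m[::-1] for m in left_mates], params.D,
                    params.seed_size, max_frag,
                )
                if rext:
                    seq = rext[::-1] + seq
                    changed = True
            seqs[cid] = seq

        # unique exact-overlap merging (>= k bases)
        right_partners: dict[str, list[tuple[str, int]]] = {}
        left_partners: dict[str, list[str]] = {}
        for a in sorted(seqs):
            for b in sorted(seqs):
                if a == b:
                    continue
                off = seqs[a].find(seqs[b][:k])
                if off < 0:
                    continue
                overlap = len(seqs[a]) - off
                m = min(overlap, len(seqs[b]))
                if seqs[a][off : off + m] != seqs[b][:m]:
                    continue
                right_partners.setdefault(a, []).append((b, off))
                left_partners.setdefault(b, []).append(a)
        consumed: set[str] = set()
        for a in sorted(right_partners):
            if a in consumed:
                continue
            partners = [
                (b, off) for b, off in right_partners[a] if b not in consumed
            ]
            # drop fully contained partners first (no end conflict involved)
            merged_any = True
            while merged_any:
                merged_any = False
                for b, off in list(partners):
                    if len(seqs[a]) - off >= len(seqs[b]):
                        support[a] |= support.pop(b)
                        flags[a] = sorted(set(flags[a]) | set(flags.pop(b)))
                        consumed.add(b)
                        del seqs[b]
                        partners = [(x, o) for x, o in partners if x != b]
                        changed = True
                        merged_any = True
            if len(partners) > 1:
                logger.warning(
                    "contig %s right end claimed by %d partners; merges skipped",
                    a, len(partners),
                )
                flags[a] = sorted(set(flags[a]) | {"merge_conflict"})
                continue
            if len(partners) == 1:
                b, off = partners[0]
                if len(left_partners.get(b, [])) > 1:
                    logger.warning(
                        "contig %s left end claimed by multiple partners; merge skipped", b
                    )
                    flags[b] = sorted(set(flags[b]) | {"merge_conflict"})
                    continue
                seqs[a] = seqs[a][:off] + seqs[b]
                support[a] |= support.pop(b)
                flags[a] = sorted(set(flags[a]) | set(flags.pop(b)))
                consumed.add(b)
                del seqs[b]
                changed = True
        if not changed:
            break

    ordered = sorted(seqs, key=lambda cid: (-len(seqs[cid]), seqs[cid]))
    out = []
    for idx, cid in enumerate(ordered):
        out.append(
            Contig(
                contig_id=f"e{idx:05d}",
                sequence=seqs[cid],
                stage="extended",
                supporting_read_ids=support[cid],
                flags=flags[cid],
            )
        )
    return out


# ---------------------------------------------------------------------------
# template counting

def estimate_template_count(
    reads: Sequence[str],
    table,
    params: AssemblyParams,
    min_table_count: int = 2,
) -> TemplateCountEstimate:
    """Estimate the number of starting template molecules.

    For each unmutated k-mer (grouped by its full-conversion image), mutated
    read windows compatible under C->T substitution are collected and grouped
    by their realised C/T pattern; patterns supported by at least
    ``min_pattern_support`` reads each mark one distinct template. The
    estimate is the 90th percentile of per-k-mer distinct-pattern counts,
    which is robust to low-complexity and variant-overlapping k-mers.
    """
    from .unmask import KmerTable  # local import to avoid a cycle

    if not isinstance(table, KmerTable):
        raise TypeError("table must be a KmerTable built from the unmutated library")
    k = table.k
    buckets: dict[str, dict[str, int]] = {}
    sub = max(1, params.table_subsample)
    for km, c in table.counts.items():
        if c < min_table_count:
            continue
        img = full_conversion(km)
        if sub > 1 and zlib.crc32(img.encode()) % sub:
            continue
        buckets.setdefault(img, {})
    if not buckets:
        raise ValueError(
            "no unmutated k-mers available for template counting "
            f"(k={k}, min_table_count={min_table_count})"
        )
    for read in reads:
        n = len(read)
        if n < k:
            continue
        conv_read = full_conversion(read)
        get = buckets.get
        for i in range(n - k + 1):
            b = get(conv_read[i : i + k])
            if b is None:
                continue
            w = read[i : i + k]
            b[w] = b.get(w, 0) + 1
    per_kmer = []
    for img in buckets:
        counts = buckets[img]
        total = sum(counts.values())
        if total < params.min_pattern_support:
            continue  # k-mer lacks mutated coverage; uninformative
        per_kmer.append(
            sum(1 for c in counts.values() if c >= params.min_pattern_support)
        )
    arr = np.asarray(per_kmer, dtype=int)
    if arr.size == 0 or arr.max() == 0:
        warnings.warn(
            "no mutation pattern reached the support threshold "
            f"({params.min_pattern_support}); template count estimate is 0"
        )
        estimate = 0
    else:
        estimate = int(round(float(np.percentile(arr, 90))))
    return TemplateCountEstimate(
        per_kmer_distinct_pattern_counts=arr,
        estimate=estimate,
        k=k,
        min_pattern_support=params.min_pattern_support,
    )


# ---------------------------------------------------------------------------
# validation and chimera audit

def validate_templates(
    contigs: Sequence[Contig],
    reads: Sequence[tuple[str, str]],
    params: AssemblyParams,
) -> pd.DataFrame:
    """Re-map reads to contigs by exact k-mer anchoring and audit coverage.

    Fills each contig's ``per_position_coverage`` and returns a table with
    median coverage, the coverage filter verdict, and a full-length flag
    (length >= 95% of the modal length of the ten longest contigs).
    """
    k = params.k
    seqs = {c.contig_id: c.sequence for c in contigs}
    index = _contig_kmer_index(seqs, k)
    diffs = {cid: np.zeros(len(seq) + 1, dtype=np.int32) for cid, seq in seqs.items()}
    nreads: Counter[str] = Counter()
    for rid, seq in reads:
        hit = _anchor(seq, index, k, seqs)
        if hit is None:
            continue
        cid, start = hit
        L = len(seqs[cid])
        lo = max(0, start)
        hi = min(L, start + len(seq))
        if hi > lo:
            diffs[cid][lo] += 1
            diffs[cid][hi] -= 1
            nreads[cid] += 1
    rows = []
    lengths = sorted((len(c.sequence) for c in contigs), reverse=True)
    top = lengths[: min(10, len(lengths))]
    modal = float(np.median(top)) if top else 0.0
    for c in contigs:
        cov = np.cumsum(diffs[c.contig_id][:-1])
        c.per_position_coverage = cov
        med = float(np.median(cov)) if len(cov) else 0.0
        rows.append(
            {
                "contig_id": c.contig_id,
                "length": len(c.sequence),
                "n_reads": int(nreads[c.contig_id]),
                "median_coverage": med,
                "passes_coverage": med >= params.min_template_median_coverage,
                "full_length": modal > 0 and len(c.sequence) >= 0.95 * modal,
            }
        )
    return pd.DataFrame(rows)


def detect_chimeras(
    contigs: Sequence[Contig],
    pairs: Sequence[tuple[str, str, str]],
    params: AssemblyParams,
    label_fn: Callable[[str], str | None] | None = None,
    min_length: int = 1500,
    min_share: float = 0.10,
) -> list[ChimeraReport]:
    """Screen contigs for reads drawn from more than one source library.

    Labels come from read provenance (simulated read names) or a caller
    supplied ``label_fn``. A contig is chimeric when two labels each supply
    more than ``min_share`` of its anchored reads over disjoint spans of the
    contig; the gap between the spans is reported as the breakpoint interval.
    """
    if label_fn is None:
        def label_fn(name: str) -> str | None:
            prov = parse_provenance(name)
            return prov["library"] if prov else None

    k = params.k
    seqs = {c.contig_id: c.sequence for c in contigs}
    index = _contig_kmer_index(seqs, k)
    placements: dict[str, list[tuple[str, int]]] = {cid: [] for cid in seqs}
    for name, left, right in pairs:
        label = label_fn(name)
        if label is None:
            continue
        for seq in (left, right):
            hit = _anchor(seq, index, k, seqs)
            if hit is not None:
                placements[hit[0]].append((label, hit[1]))

    reports = []
    for c in contigs:
        if len(c.sequence) < min_length:
            continue
        placed = placements[c.contig_id]
        if not placed:
            reports.append(ChimeraReport(c.contig_id, {}, None, "not evaluable"))
            continue
        composition = Counter(label for label, _ in placed)
        c.library_label_counts = dict(composition)
        total = sum(composition.values())
        qualifying = {
            label for label, count in composition.items()
            if count / total > min_share
        }
        # windowed composition: spans are runs of windows a label dominates,
        # which is robust to junction-spanning reads anchoring on either side
        window = max(200, len(c.sequence) // 20)
        n_windows = max(1, -(-len(c.sequence) // window))
        win_counts: list[Counter] = [Counter() for _ in range(n_windows)]
        for label, pos in placed:
            w = min(n_windows - 1, max(0, pos) // window)
            win_counts[w][label] += 1
        spans: dict[str, tuple[int, int]] = {}
        for label in qualifying:
            wins = [
                w for w, counts in enumerate(win_counts)
                if counts and counts.most_common(1)[0][0] == label
            ]
            if wins:
                spans[label] = (wins[0], wins[-1])
        verdict = "clean"
        breakpoint_interval = None
        labels = sorted(spans, key=lambda l: spans[l])
        for i in range(len(labels) - 1):
            a, b = labels[i], labels[i + 1]
            if spans[a][1] < spans[b][0]:  # disjoint window spans
                verdict = "chimeric"
                breakpoint_interval = (
                    (spans[a][1] + 1) * window - window,
                    (spans[b][0] + 1) * window,
                )
                break
        reports.append(
            ChimeraReport(c.contig_id, dict(composition), breakpoint_interval, verdict)
        )
    return reports


def chimera_rate(reports: Sequence[ChimeraReport]) -> float:
    evaluable = [r for r in reports if r.verdict != "not evaluable"]
    if not evaluable:
        return 0.0
    return sum(r.verdict == "chimeric" for r in evaluable) / len(evaluable)
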