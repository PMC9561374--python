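"""Tests of graph construction, contig extension and assembly audits."""

import numpy as np
import pytest

from conftest import tiling_reads
from museq.assembly import (
    AssemblyParams,
    Contig,
    build_graph,
    chimera_rate,
    detect_chimeras,
    estimate_template_count,
    extend_contigs,
    initial_contigs,
    validate_templates,
)
from museq.seqio import oriented_pairs, oriented_reads
from museq.simdata import SimulationConfig, mutate_template, simulate_experiment
from museq.unmask import build_kmer_table


def _params(**kw):
    defaults = dict(k=31, D=0.95, min_kmer_count=1)
    defaults.update(kw)
    return AssemblyParams(**defaults)


class TestBuildGraph:
    def test_single_read_gives_unbranched_path(self, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        g = build_graph([read], _params())
        assert len(g.nodes) == len(read) - 31 + 1
        branch = [n for n in g.nodes if len(g.successors(n)) > 1 or len(g.predecessors(n)) > 1]
        assert branch == []

    def test_distinct_mutation_patterns_separate_components(self, rng):
        # two imprints of the same 400 bp sequence: with ~8 C per 31-window at
        # p=0.5, patterns differ within every window, so the graph has two
        # components -- checked against networkx as an independent oracle
        networkx = pytest.importorskip("networkx")
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        k = 31
        for _ in range(100):  # draw until the patterns differ in every window
            t1, _ = mutate_template(base, 0.5, rng)
            t2, _ = mutate_template(base, 0.5, rng)
            if all(t1[i : i + k] != t2[i : i + k] for i in range(len(t1) - k + 1)):
                break
        else:
            pytest.fail("could not realise window-disjoint imprints")
        reads = tiling_reads(t1, 80, 10) + tiling_reads(t2, 80, 10)
        g = build_graph(reads, _params())
        nxg = networkx.Graph()
        nxg.add_nodes_from(g.nodes)
        nxg.add_edges_from((e[:-1], e[1:]) for e in g.edges)
        assert networkx.number_connected_components(nxg) == 2

    def test_empty_input_gives_empty_graph(self):
        g = build_graph([], _params())
        assert len(g.nodes) == 0 and len(g.edges) == 0

    def test_k_longer_than_reads_rejected(self):
        with pytest.raises(ValueError, match="k=31"):
            build_graph(["ACGTACGT"], _params())

    def test_min_kmer_count_drops_singletons(self, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        g = build_graph([read], _params(min_kmer_count=2))
        assert len(g.nodes) == 0
        g2 = build_graph([read, read], _params(min_kmer_count=2))
        assert len(g2.nodes) == 60 - 31 + 1


class TestInitialContigs:
    def test_single_read_reproduced_exactly(self, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
        contigs = initial_contigs(build_graph([read], _params()))
        assert [c.sequence for c in contigs] == [read]
        assert contigs[0].stage == "initial"

    def test_branch_point_splits_into_three_contigs(self, rng):
        # two sequences sharing a prefix and diverging after it meet at one
        # branch node: shared contig + two private contigs
        shared = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        a = shared + "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        b = shared + "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        reads = tiling_reads(a, 45, 5) + tiling_reads(b, 45, 5)
        contigs = initial_contigs(build_graph(reads, _params()))
        assert len(contigs) == 3
        in_both = [c for c in contigs if c.sequence in a and c.sequence in b]
        assert len(in_both) == 1  # the common prefix up to the branch k-mer
        assert shared in in_both[0].sequence or in_both[0].sequence in shared

    def test_contig_kmers_all_in_graph_once(self, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        g = build_graph([read], _params())
        for c in initial_contigs(g):
            kmers = [c.sequence[i : i + 31] for i in range(len(c.sequence) - 30)]
            assert len(set(kmers)) == len(kmers)
            assert all(km in g.nodes for km in kmers)


class TestExtendContigs:
    def test_no_junction_pairs_leave_contigs_unchanged(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        contigs = initial_contigs(build_graph(tiling_reads(seq, 100, 10), _params()))
        pairs = [("p0", seq[:100], seq[100:200])]  # both mates interior
        out = extend_contigs(contigs, pairs, _params())
        assert [c.sequence for c in out] == [c.sequence for c in contigs]
        assert out[0].stage == "extended"

    def test_error_free_templates_recovered_exactly(self, clean_diploid):
        # the oracle is the simulation truth: with error-free reads and
        # adequate coverage every template assembles to (an infix of) itself
        # at >= 95% length, for any D
        params = AssemblyParams(k=41, D=0.95)
        pairs = [p.as_record() for p in clean_diploid.mutated["top"]]
        reads = [s for _, s in oriented_reads(pairs)]
        ext = extend_contigs(
            initial_contigs(build_graph(reads, params)),
            oriented_pairs(pairs),
            params,
        )
        truth = [t.final_sequence for t in clean_diploid.templates]
        recovered = sum(
            1
            for c in ext
            if any(len(c.sequence) >= 0.95 * len(t) and c.sequence in t for t in truth)
        )
        assert recovered == len(truth)

    def test_permissive_extension_recovers_no_fewer_than_strict(self, small_diploid):
        pairs = [p.as_record() for p in small_diploid.mutated["top"]]
        reads = [s for _, s in oriented_reads(pairs)]
        truth = [t.final_sequence for t in small_diploid.templates]

        def recovery(D):
            params = AssemblyParams(k=41, D=D)
            ext = extend_contigs(
                initial_contigs(build_graph(reads, params)),
                oriented_pairs(pairs), params,
            )
            return sum(
                1 for c in ext
                if any(len(c.sequence) >= 0.95 * len(t) and c.sequence in t for t in truth)
            )

        assert recovery(0.55) >= recovery(0.95)

    def test_supporting_reads_unique_to_one_contig(self, clean_diploid):
        params = AssemblyParams(k=41, D=0.95)
        pairs = [p.as_record() for p in clean_diploid.mutated["top"]]
        reads = [s for _, s in oriented_reads(pairs)]
        ext = extend_contigs(
            initial_contigs(build_graph(reads, params)), oriented_pairs(pairs), params
        )
        seen: set[str] = set()
        for c in ext:
            assert not (c.supporting_read_ids & seen)
            seen |= c.supporting_read_ids


class TestTemplateCount:
    def test_single_template_estimates_one(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        mutated, _ = mutate_template(base, 0.5, rng)
        reads = tiling_reads(mutated, 100, 3) * 8  # deep coverage of one imprint
        table = build_kmer_table(tiling_reads(base, 100, 5) * 2, 41)
        params = AssemblyParams(k=41, min_pattern_support=20)
        est = estimate_template_count(reads, table, params)
        assert est.estimate == 1

    def test_threshold_above_read_count_estimates_zero(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        mutated, _ = mutate_template(base, 0.5, rng)
        table = build_kmer_table(tiling_reads(base, 100, 5) * 2, 41)
        params = AssemblyParams(k=41, min_pattern_support=10_000)
        with pytest.warns(UserWarning, match="estimate is 0"):
            est = estimate_template_count(tiling_reads(mutated, 100, 3), table, params)
        assert est.estimate == 0

    def test_multi_template_estimate_close_to_truth(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        reads = []
        n_templates = 8
        for _ in range(n_templates):
            m, _ = mutate_template(base, 0.5, rng)
            reads.extend(tiling_reads(m, 120, 4))
        table = build_kmer_table(tiling_reads(base, 120, 5) * 2, 41)
        est = estimate_template_count(
            reads, table, AssemblyParams(k=41, min_pattern_support=20)
        )
        assert abs(est.estimate - n_templates) <= 1


class TestValidation:
    def test_unmapped_contig_has_zero_median_coverage(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        other = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        contigs = [Contig("c0", seq, "extended"), Contig("c1", other, "extended")]
        reads = [(f"r{i}", seq[i : i + 60]) for i in range(0, 140, 5)]
        report = validate_templates(contigs, reads, _params(k=31))
        by_id = report.set_index("contig_id")
        assert by_id.loc["c1", "median_coverage"] == 0
        assert not by_id.loc["c1", "passes_coverage"]
        assert by_id.loc["c0", "median_coverage"] > 0

    def test_high_coverage_simulation_passes_filter(self, small_diploid):
        params = AssemblyParams(k=41, D=0.55)
        pairs = [p.as_record() for p in small_diploid.mutated["top"]]
        reads = [s for _, s in oriented_reads(pairs)]
        ext = extend_contigs(
            initial_contigs(build_graph(reads, params)), oriented_pairs(pairs), params
        )
        read_recs = list(oriented_reads(pairs))
        report = validate_templates(ext, read_recs, AssemblyParams(k=41, min_template_median_coverage=50))
        full = report[report["full_length"]]
        assert (full["median_coverage"] >= 50).all()
        # hockey-stick: full-length contigs all near the modal length, the
        # rest drop off sharply
        assert full["length"].min() >= 0.95 * report["length"].max()


class TestChimeraDetection:
    def test_single_label_contigs_are_clean(self, clean_diploid):
        params = AssemblyParams(k=41, D=0.95)
        pairs = [p.as_record() for p in clean_diploid.mutated["top"]]
        reads = [s for _, s in oriented_reads(pairs)]
        ext = extend_contigs(
            initial_contigs(build_graph(reads, params)), oriented_pairs(pairs), params
        )
        def label_fn(name):
            return name.split(":")[1]  # template id as pseudo-library label

        reports = detect_chimeras(
            ext, oriented_pairs(pairs), params, label_fn=label_fn, min_length=1000
        )
        # every full-length template contig draws reads from one template only
        assert all(r.verdict in ("clean", "not evaluable") for r in reports)
        assert chimera_rate(reports) == 0.0

    def test_concatenated_halves_flagged_with_breakpoint(self, clean_diploid):
        t1, t2 = clean_diploid.templates[0], clean_diploid.templates[-1]
        junction = len(t1.final_sequence) // 2
        chimera = t1.final_sequence[:junction] + t2.final_sequence[junction:]
        contig = Contig("chimera0", chimera, "extended")
        pairs = [
            p.as_record()
            for p in clean_diploid.mutated["top"]
            if p.name.split(":")[1] in (t1.template_id, t2.template_id)
        ]
        params = AssemblyParams(k=41)
        reports = detect_chimeras(
            [contig], oriented_pairs(pairs), params,
            label_fn=lambda name: name.split(":")[1], min_length=1000,
        )
        assert len(reports) == 1
        assert reports[0].verdict == "chimeric"
        lo, hi = reports[0].breakpoint_interval
        assert lo <= junction <= hi + 200
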