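"""Tests of co-alignment, the bi-allelic matrix and likelihood phasing."""

import itertools
import math

import numpy as np
import pytest

from museq.phasing import (
    OBS_A0,
    OBS_A1,
    OBS_MASKED,
    OBS_MISSING,
    AnnealSchedule,
    BiallelicMatrix,
    Column,
    PhasingParams,
    build_biallelic_matrix,
    coalign,
    contig_loglik,
    detect_recombinants,
    fit_haplotypes,
)
from museq.unmask import UnmaskedContig


def _contig(cid, seq, masked=None):
    return UnmaskedContig(
        contig_id=cid, sequence=seq, masked_positions=masked or {},
        source_contig_id=cid,
    )


def _matrix(rows, columns=None):
    """Build a BiallelicMatrix from a list of observation-code rows."""
    data = np.asarray(rows, dtype=np.int8)
    n = data.shape[1]
    if columns is None:
        columns = [Column(10 * (j + 1), "snv", ("A", "G"), -1) for j in range(n)]
    return BiallelicMatrix(
        contig_ids=[f"c{i}" for i in range(data.shape[0])],
        columns=columns,
        data=data,
    )


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestCoalign:
    def test_single_contig_aligns_to_itself(self, rng):
        c = _contig("c0", _random_seq(rng, 2000))
        params = PhasingParams(min_contig_length=1500)
        co = coalign([c], params)
        assert co.reference_contig_id == "c0"
        assert co.alignments["c0"].identity == 1.0

    def test_identical_contigs_align_gapless(self, rng):
        seq = _random_seq(rng, 2000)
        co = coalign([_contig("c0", seq), _contig("c1", seq)],
                     PhasingParams(min_contig_length=1500))
        aln = co.alignments["c1"]
        assert "-" not in aln.gapped_query and "-" not in aln.gapped_target
        assert aln.score == len(seq)  # all matches at +1

    def test_deletion_gap_placed_at_true_coordinate(self, rng):
        seq = _random_seq(rng, 2000)
        deleted = seq[:800] + seq[804:]  # 4 bp deletion at position 800
        co = coalign([_contig("ref", seq), _contig("del", deleted)],
                     PhasingParams(min_contig_length=1500))
        aln = co.alignments["del"]
        gap_cols = [i for i, b in enumerate(aln.gapped_query) if b == "-"]
        assert len(gap_cols) == 4
        # gap may shift within a repeat, but stays near the true coordinate
        assert abs(gap_cols[0] - 800) < 20

    def test_length_filter_failure_is_explicit(self, rng):
        with pytest.raises(ValueError, match="min_contig_length"):
            coalign([_contig("c0", _random_seq(rng, 100))], PhasingParams())

    def test_masked_t_scores_as_match_against_c(self, rng):
        seq = _random_seq(rng, 1600)
        pos = [i for i, b in enumerate(seq) if b == "C"][:30]
        masked_seq = "".join(
            "T" if i in pos else b for i, b in enumerate(seq)
        )
        c1 = _contig("m", masked_seq, {i: "Y" for i in pos})
        co = coalign([_contig("ref", seq), c1], PhasingParams())
        assert co.alignments["m"].identity == 1.0


class TestBiallelicMatrix:
    def test_identical_contigs_give_zero_columns(self, rng):
        seq = _random_seq(rng, 1600)
        contigs = [_contig(f"c{i}", seq) for i in range(4)]
        matrix = build_biallelic_matrix(coalign(contigs, PhasingParams()), contigs)
        assert matrix.shape == (4, 0)

    def test_true_snvs_recovered_without_spurious_columns(self, rng):
        base = _random_seq(rng, 2000)
        sites = [300, 700, 1100, 1500, 1900]
        hap_b = list(base)
        for s in sites:
            hap_b[s] = {"A": "G", "C": "A", "G": "T", "T": "C"}[hap_b[s]]
        hap_b = "".join(hap_b)
        contigs = [_contig(f"a{i}", base) for i in range(5)]
        contigs += [_contig(f"b{i}", hap_b) for i in range(5)]
        matrix = build_biallelic_matrix(coalign(contigs, PhasingParams()), contigs)
        assert [c.position for c in matrix.columns] == sites
        # rows split cleanly by haplotype
        for j in range(5):
            col = matrix.data[:, j]
            assert len(set(col[:5])) == 1 and len(set(col[5:])) == 1
            assert col[0] != col[5]

    def test_ct_site_admits_masked_entries(self, rng):
        base = _random_seq(rng, 1600)
        site = 800
        hap_c = base[:site] + "C" + base[site + 1 :]
        hap_t = base[:site] + "T" + base[site + 1 :]
        contigs = [_contig(f"c{i}", hap_c) for i in range(2)]
        contigs += [_contig(f"t{i}", hap_t) for i in range(2)]
        contigs += [_contig("m0", hap_t, {site: "Y"}), _contig("m1", hap_t, {site: "Y"})]
        matrix = build_biallelic_matrix(coalign(contigs, PhasingParams()), contigs)
        cols = [c for c in matrix.columns if c.position == site]
        assert len(cols) == 1 and set(cols[0].alleles) == {"C", "T"}
        j = matrix.columns.index(cols[0])
        ids = matrix.contig_ids
        for r, cid in enumerate(ids):
            if cid.startswith("m"):
                assert matrix.data[r, j] == OBS_MASKED

    def test_deletion_polymorphism_becomes_presence_column(self, rng):
        seq = _random_seq(rng, 2000)
        deleted = seq[:800] + seq[806:]
        contigs = [_contig(f"r{i}", seq) for i in range(3)]
        contigs += [_contig(f"d{i}", deleted) for i in range(3)]
        matrix = build_biallelic_matrix(coalign(contigs, PhasingParams()), contigs)
        del_cols = [c for c in matrix.columns if c.kind == "del"]
        assert len(del_cols) == 1  # one event, not six per-base columns


class TestContigLoglik:
    def test_perfect_match_closed_form(self):
        params = PhasingParams()
        row = np.array([OBS_A0] * 6, dtype=np.int8)
        ll = contig_loglik(row, [0] * 6, params,
                           conv_alleles=np.full(6, -1, dtype=np.int8))
        assert ll == pytest.approx(6 * math.log(0.995))

    def test_single_mismatch_closed_form(self):
        params = PhasingParams()
        row = np.array([OBS_A0] * 4 + [OBS_A1], dtype=np.int8)
        ll = contig_loglik(row, [0] * 5, params,
                           conv_alleles=np.full(5, -1, dtype=np.int8))
        assert ll == pytest.approx(4 * math.log(0.995) + math.log(0.005))

    def test_masked_channel_hand_computed_fixture(self):
        # 3 columns: matched allele, masked over a C-allele, masked over T
        params = PhasingParams()
        columns = [
            Column(10, "snv", ("A", "G"), -1),
            Column(20, "snv", ("C", "T"), 0),
            Column(30, "snv", ("C", "T"), 0),
        ]
        row = np.array([OBS_A0, OBS_MASKED, OBS_MASKED], dtype=np.int8)
        hap = [0, 0, 1]  # carries C at col 2 (conv allele), T at col 3
        ll = contig_loglik(row, hap, params, columns=columns)
        expected = math.log(0.995) + math.log(0.5) + math.log(0.995)
        assert ll == pytest.approx(expected)

    def test_missing_columns_contribute_nothing(self):
        params = PhasingParams()
        row = np.array([OBS_MISSING] * 3, dtype=np.int8)
        ll = contig_loglik(row, [1, 0, 1], params,
                           conv_alleles=np.full(3, -1, dtype=np.int8))
        assert ll == 0.0


class TestFitHaplotypes:
    def test_single_column_forced_optimum(self):
        rows = [[OBS_A0]] * 6 + [[OBS_A1]] * 4
        matrix = _matrix(rows)
        params = PhasingParams(ploidy=2, min_contig_length=1)
        result = fit_haplotypes(matrix, params)
        alleles = sorted(h.alleles for h in result.haplotypes)
        assert alleles == [(0,), (1,)]
        assert result.total_loglik == pytest.approx(10 * math.log(0.995))

    def test_diploid_recovery_with_noise(self, rng):
        n, per = 6, 12
        hap_a = tuple(int(x) for x in rng.integers(0, 2, n))
        hap_b = tuple(1 - x for x in hap_a)
        rows = []
        for hap in (hap_a, hap_b):
            for _ in range(per):
                row = list(hap)
                if rng.random() < 0.2:  # occasional observation error
                    j = int(rng.integers(0, n))
                    row[j] = 1 - row[j]
                rows.append(row)
        result = fit_haplotypes(_matrix(rows), PhasingParams(ploidy=2))
        fitted = sorted(h.alleles for h in result.haplotypes)
        assert fitted == sorted([hap_a, hap_b])

    def test_annealing_matches_exhaustive_oracle(self, rng):
        # brute-force enumeration is the oracle; annealing must reach the
        # same objective on every small random fixture
        params_ex = PhasingParams(ploidy=2)
        for fixture in range(20):
            data = rng.integers(0, 2, size=(8, 4)).astype(np.int8)
            # sprinkle missing and masked entries
            mask = rng.random(data.shape)
            data[mask < 0.08] = OBS_MISSING
            matrix = _matrix(data.tolist())
            exact = fit_haplotypes(matrix, params_ex)
            for seed in range(2):
                params_sa = PhasingParams(
                    ploidy=2, exhaustive_limit=1,
                    anneal=AnnealSchedule(steps=1500, restarts=4, seed=seed),
                )
                annealed = fit_haplotypes(matrix, params_sa)
                assert annealed.total_loglik == pytest.approx(
                    exact.total_loglik, abs=1e-9
                ), f"fixture {fixture}, seed {seed}"

    def test_objective_invariant_under_label_permutation(self, rng):
        data = rng.integers(0, 2, size=(10, 5)).astype(np.int8)
        matrix = _matrix(data.tolist())
        result = fit_haplotypes(matrix, PhasingParams(ploidy=2))
        perm = _matrix(data.tolist())
        result2 = fit_haplotypes(perm, PhasingParams(ploidy=2))
        assert result.total_loglik == pytest.approx(result2.total_loglik)
        assert sorted(h.alleles for h in result.haplotypes) == sorted(
            h.alleles for h in result2.haplotypes
        )

    def test_zero_columns_returns_monomorphic_partition(self):
        matrix = BiallelicMatrix(contig_ids=["a", "b"], columns=[],
                                 data=np.zeros((2, 0), dtype=np.int8))
        result = fit_haplotypes(matrix, PhasingParams(ploidy=2))
        assert "monomorphic" in result.flags
        assert result.assignments["H1"] == ["a", "b"]


class TestAssignment:
    def test_five_discriminating_columns_assigns(self):
        rows = [[OBS_A0] * 5] * 3 + [[OBS_A1] * 5] * 3
        result = fit_haplotypes(_matrix(rows), PhasingParams(ploidy=2))
        assert result.unassigned == []
        sizes = sorted(len(v) for v in result.assignments.values())
        assert sizes == [3, 3]

    def test_single_column_ratio_below_threshold_unassigned(self):
        # one discriminating site: ratio (1-eps)/eps = 199 < 1000
        rows = [[OBS_A0]] * 3 + [[OBS_A1]] * 3
        result = fit_haplotypes(
            _matrix(rows), PhasingParams(ploidy=2, assignment_ratio=1000.0)
        )
        assert len(result.unassigned) == 6
        result2 = fit_haplotypes(
            _matrix(rows), PhasingParams(ploidy=2, assignment_ratio=100.0)
        )
        assert result2.unassigned == []

    def test_contig_covering_no_discriminating_column_unassigned(self):
        rows = [[OBS_A0, OBS_A0]] * 3 + [[OBS_A1, OBS_A1]] * 3
        rows += [[OBS_MISSING, OBS_MISSING]]
        result = fit_haplotypes(_matrix(rows), PhasingParams(ploidy=2))
        assert result.unassigned == ["c6"]

    def test_raising_ratio_never_assigns_more(self, rng):
        data = rng.integers(0, 2, size=(14, 4)).astype(np.int8)
        matrix = _matrix(data.tolist())
        n_assigned = []
        for ratio in (10.0, 1000.0, 100000.0):
            result = fit_haplotypes(
                matrix, PhasingParams(ploidy=2, assignment_ratio=ratio)
            )
            n_assigned.append(sum(len(v) for v in result.assignments.values()))
        assert n_assigned == sorted(n_assigned, reverse=True)


class TestRecombinants:
    def test_consistent_contig_not_flagged(self):
        rows = [[OBS_A0] * 6] * 4 + [[OBS_A1] * 6] * 4
        matrix = _matrix(rows)
        result = fit_haplotypes(matrix, PhasingParams(ploidy=2))
        assert detect_recombinants(matrix, result, PhasingParams(ploidy=2)) == []

    def test_half_switch_contig_flagged_at_junction(self):
        rows = [[OBS_A0] * 6] * 4 + [[OBS_A1] * 6] * 4
        rows.append([OBS_A0] * 3 + [OBS_A1] * 3)  # switches after column 3
        matrix = _matrix(rows)
        params = PhasingParams(ploidy=2)
        result = fit_haplotypes(matrix, params)
        flagged = detect_recombinants(matrix, result, params)
        assert len(flagged) == 1
        assert flagged[0]["contig_id"] == "c8"
        assert flagged[0]["switch_after_column"] == 2  # between columns 3 and 4
        assert flagged[0]["switch_interval"] == (30, 40)
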