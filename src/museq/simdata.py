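"""Synthetic mutation-imprinted sequencing experiments with full ground truth.

This module emulates the statistical output of the bench protocols that
imprint each template molecule with a random C->T conversion pattern:

* a random (or user-supplied) target region and ``ploidy`` haplotypes that
  differ at roughly 1 SNV per kb (plus occasional short indels);
* per-template independent C->T conversion of each cytosine at rate ``p``
  (~0.5 in the protocols), applied in the strand orientation of the template;
* early-round polymerase replication errors at per-base substitution and
  single-base indel rates, applied once per template so that all reads of a
  template share them;
* 150 bp paired-end reads from ~400 bp fragments at a chosen per-template
  fold coverage, for the mutated library, plus an unmutated library drawn
  from the unconverted (double-stranded) region.

Every read name carries provenance (library, template, haplotype, strand,
fragment coordinates) so that downstream evaluation can audit chimerism and
recovery; the analysis pipeline itself never relies on read names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import BASES, revcomp, write_fastq

__all__ = [
    "SimulationConfig",
    "HaplotypeTruth",
    "TemplateMolecule",
    "ReadPair",
    "SimulatedExperiment",
    "simulate_haplotypes",
    "mutate_template",
    "apply_replication_errors",
    "make_templates",
    "fragment_library",
    "simulate_unmutated_library",
    "downsample",
    "expected_pair_count",
    "simulate_experiment",
    "parse_provenance",
]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment.

    Defaults are the study conditions: a 5 kb diploid region, ~1 SNV/kb
    between haplotypes, conversion rate 0.5, replication substitution rate
    7.4e-4 and single-base indel rate 7.7e-5 per base per template, 150 bp
    paired-end reads with 400 bp mean inserts.
    """

    region_length: int = 5000
    ploidy: int = 2
    snv_density: float = 1.0  # SNVs per kb between haplotype pairs
    indel_density: float = 0.2  # indels per kb between haplotype pairs
    templates_per_haplotype_per_strand: int = 25
    conversion_rate: float = 0.5
    pcr_snv_rate: float = 7.4e-4
    pcr_indel_rate: float = 7.7e-5
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 60.0  # not stated by the protocols; see docs/methods.md
    per_template_coverage: float = 256.0
    unmutated_coverage: float = 100.0
    strands: tuple[str, ...] = ("top",)
    library_labels: tuple[str, ...] | None = None
    reference: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must lie in [0, 1]")
        if self.region_length < 2 * self.read_length:
            raise ValueError(
                f"region_length {self.region_length} shorter than two read lengths "
                f"({2 * self.read_length})"
            )
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        for name in ("snv_density", "indel_density", "pcr_snv_rate", "pcr_indel_rate",
                     "per_template_coverage", "unmutated_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not set(self.strands) <= {"top", "bottom"}:
            raise ValueError("strands must be a subset of {'top', 'bottom'}")

    def labels(self) -> tuple[str, ...]:
        if self.library_labels is not None:
            return self.library_labels
        return tuple(f"mut_{s}" for s in self.strands)


@dataclass
class HaplotypeTruth:
    """The simulated region, its haplotypes and the variant truth table."""

    reference_sequence: str
    haplotype_labels: list[str]
    haplotypes: list[str]
    # (reference_position, kind, ref_allele, alt_allele, haplotype_label)
    variants: list[tuple[int, str, str, str, str]]

    def pairwise_snv_count(self, a: int, b: int) -> int:
        la, lb = self.haplotype_labels[a], self.haplotype_labels[b]
        return sum(1 for _, kind, _, _, h in self.variants
                   if kind == "snv" and h in (la, lb))


@dataclass
class TemplateMolecule:
    """One simulated single molecule with its imprinted mutation pattern."""

    template_id: str
    haplotype_label: str
    strand: str  # 'top' | 'bottom'
    conversion_pattern: tuple[int, ...]  # converted C positions, template coords
    replication_errors: list[tuple[int, str, str, str]]  # (pos, kind, ref, alt)
    final_sequence: str
    pre_error_sequence: str = ""

    def map_to_final(self, pos: int) -> int | None:
        """Map a pre-replication-error coordinate into ``final_sequence``.

        Returns None when the position was deleted by a replication error.
        """
        shift = 0
        for epos, kind, _, _ in self.replication_errors:
            if kind == "ins" and epos <= pos:
                shift += 1
            elif kind == "del":
                if epos == pos:
                    return None
                if epos < pos:
                    shift -= 1
        return pos + shift


@dataclass
class ReadPair:
    name: str
    read1: str
    read2: str
    quality: str

    def as_record(self) -> tuple[str, str, str]:
        return self.name, self.read1, self.read2


def _random_reference(length: int, rng: np.random.Generator) -> str:
    return _BASE_ARR[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_haplotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> HaplotypeTruth:
    """Draw ``ploidy`` haplotypes over a reference region.

    Variant sites are placed uniformly and each is private to one haplotype,
    so that any two haplotypes differ at Binomial(L, density/1000) sites in
    expectation. SNV alternate alleles are uniform over the three
    non-reference bases; indels are 1-10 bp insertions or deletions.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.region_length
    M = config.ploidy
    ref = config.reference.upper() if config.reference else _random_reference(L, rng)
    if config.reference and len(ref) != L:
        raise ValueError("supplied reference length does not match region_length")
    labels = [chr(ord("A") + i) for i in range(M)]

    variants: list[tuple[int, str, str, str, str]] = []
    if M >= 2:
        # per-site probability chosen so every pair differs at density*L/1000
        # sites in expectation (each variant is private; a pair differs at a
        # site with probability 2/M).
        site_p = min(1.0, config.snv_density / 1000.0 * M / 2.0)
        n_snv = rng.binomial(L, site_p)
        indel_p = min(1.0, config.indel_density / 1000.0 * M / 2.0)
        n_indel = rng.binomial(L, indel_p)
        if n_snv + n_indel > L // 20:
            raise ValueError(
                f"region of {L} bases too short for {n_snv + n_indel} variants"
            )
        # keep variant sites >= 12 bp apart so indels never overlap
        positions = []
        tries = 0
        while len(positions) < n_snv + n_indel and tries < 10000:
            cand = int(rng.integers(50, L - 50))
            if all(abs(cand - p) > 12 for p in positions):
                positions.append(cand)
            tries += 1
        if len(positions) < n_snv + n_indel:
            raise ValueError("could not place requested variants in region")
        positions.sort()
        order = rng.permutation(len(positions))
        snv_pos = sorted(positions[i] for i in order[:n_snv])
        indel_pos = sorted(positions[i] for i in order[n_snv:])
        for pos in snv_pos:
            ref_base = ref[pos]
            alts = [b for b in BASES if b != ref_base]
            alt = alts[rng.integers(0, 3)]
            hap = labels[rng.integers(0, M)]
            variants.append((pos, "snv", ref_base, alt, hap))
        for pos in indel_pos:
            size = int(rng.integers(1, 11))
            hap = labels[rng.integers(0, M)]
            if rng.random() < 0.5:  # deletion of `size` bases at pos
                variants.append((pos, "del", ref[pos : pos + size], "", hap))
            else:  # insertion after pos
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size=size))
                variants.append((pos, "ins", "", ins, hap))
        variants.sort()

    haplotypes = []
    for label in labels:
        seq = ref
        for pos, kind, ref_allele, alt, hap in sorted(variants, reverse=True):
            if hap != label:
                continue
            if kind == "snv":
                seq = seq[:pos] + alt + seq[pos + 1 :]
            elif kind == "del":
                seq = seq[:pos] + seq[pos + len(ref_allele) :]
            else:
                seq = seq[: pos + 1] + alt + seq[pos + 1 :]
        haplotypes.append(seq)
    return HaplotypeTruth(ref, labels, haplotypes, variants)


def mutate_template(
    sequence: str, p: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Convert each C of ``sequence`` to T independently with probability p.

    Returns the mutated sequence and the sorted tuple of converted positions.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("conversion probability must lie in [0, 1]")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    cpos = np.flatnonzero(arr == ord("C"))
    if cpos.size == 0:
        return sequence, ()
    hit = cpos[rng.random(cpos.size) < p]
    arr[hit] = ord("T")
    return arr.tobytes().decode(), tuple(int(i) for i in hit)


def apply_replication_errors(
    sequence: str,
    pcr_snv_rate: float,
    pcr_indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, str, str, str]]]:
    """Apply per-base Bernoulli substitution and single-base indel errors.

    Substitutions pick a uniform alternate base; indels are single-base
    insertions or deletions with equal probability. The error list (position
    in the input sequence, kind, ref, alt) is returned for truth tracking.
    """
    if not (0 <= pcr_snv_rate <= 1 and 0 <= pcr_indel_rate <= 1):
        raise ValueError("error rates must lie in [0, 1]")
    L = len(sequence)
    if L == 0:
        return sequence, []
    errors: list[tuple[int, str, str, str]] = []
    sub_pos = np.flatnonzero(rng.random(L) < pcr_snv_rate)
    indel_pos = np.flatnonzero(rng.random(L) < pcr_indel_rate)
    chars = list(sequence)
    for pos in sub_pos:
        ref_base = sequence[pos]
        alts = [b for b in BASES if b != ref_base]
        alt = alts[rng.integers(0, len(alts))]
        chars[pos] = alt
        errors.append((int(pos), "sub", ref_base, alt))
    # apply indels right-to-left so earlier positions stay valid
    for pos in sorted((int(i) for i in indel_pos), reverse=True):
        if rng.random() < 0.5:
            errors.append((pos, "del", sequence[pos], ""))
            del chars[pos]
        else:
            ins = BASES[rng.integers(0, 4)]
            errors.append((pos, "ins", "", ins))
            chars.insert(pos, ins)
    errors.sort()
    return "".join(chars), errors


def make_templates(
    truth: HaplotypeTruth, config: SimulationConfig, rng: np.random.Generator
) -> list[TemplateMolecule]:
    """Generate mutated template molecules for every haplotype and strand."""
    templates = []
    for strand in config.strands:
        for label, hap_seq in zip(truth.haplotype_labels, truth.haplotypes):
            oriented = hap_seq if strand == "top" else revcomp(hap_seq)
            for i in range(config.templates_per_haplotype_per_strand):
                mutated, pattern = mutate_template(oriented, config.conversion_rate, rng)
                final, errors = apply_replication_errors(
                    mutated, config.pcr_snv_rate, config.pcr_indel_rate, rng
                )
                templates.append(
                    TemplateMolecule(
                        template_id=f"t{label}{strand[0]}{i:04d}",
                        haplotype_label=label,
                        strand=strand,
                        conversion_pattern=pattern,
                        replication_errors=errors,
                        final_sequence=final,
                        pre_error_sequence=mutated,
                    )
                )
    return templates


def expected_pair_count(coverage: float, template_length: int, read_length: int) -> int:
    """Read pairs needed for ``coverage``-fold redundancy of one template."""
    return math.ceil(coverage * template_length / (2 * read_length))


def fragment_library(
    templates: Sequence[TemplateMolecule],
    config: SimulationConfig,
    rng: np.random.Generator,
    library_label: str = "mut",
    coverage: float | None = None,
) -> list[ReadPair]:
    """Draw paired-end fragments from each template.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated to
    [read_length, template length]; start positions are uniform. Read 2 is the
    reverse complement of the fragment's 3' end. Provenance is encoded in the
    read name as colon-separated fields.
    """
    rl = config.read_length
    cov = config.per_template_coverage if coverage is None else coverage
    pairs: list[ReadPair] = []
    qual = "I" * rl
    for tpl in templates:
        L = len(tpl.final_sequence)
        if L < rl:
            raise ValueError(
                f"template {tpl.template_id} ({L} bp) shorter than read length {rl}"
            )
        n = expected_pair_count(cov, L, rl)
        if n == 0:
            continue
        flens = rng.normal(config.insert_mean, config.insert_sd, size=n)
        flens = np.clip(np.rint(flens).astype(int), rl, L)
        starts = (rng.random(n) * (L - flens + 1)).astype(int)
        for i in range(n):
            s = int(starts[i])
            e = s + int(flens[i])
            frag = tpl.final_sequence
            r1 = frag[s : s + rl]
            r2 = revcomp(frag[e - rl : e])
            name = (
                f"{library_label}:{tpl.template_id}:{tpl.haplotype_label}:"
                f"{tpl.strand}:{s}:{e}:{i}"
            )
            pairs.append(ReadPair(name, r1, r2, qual))
    return pairs


def simulate_unmutated_library(
    truth: HaplotypeTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    library_label: str = "unmut",
) -> list[ReadPair]:
    """Paired-end reads from the unconverted (double-stranded) region.

    Fragments are drawn from each haplotype and flipped to the opposite strand
    with probability 1/2, as for a conventional double-stranded library.
    """
    rl = config.read_length
    qual = "I" * rl
    pairs: list[ReadPair] = []
    for label, hap_seq in zip(truth.haplotype_labels, truth.haplotypes):
        L = len(hap_seq)
        n = expected_pair_count(config.unmutated_coverage, L, rl)
        flens = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n)).astype(int),
            rl,
            L,
        )
        starts = (rng.random(n) * (L - flens + 1)).astype(int)
        flips = rng.random(n) < 0.5
        for i in range(n):
            s, e = int(starts[i]), int(starts[i] + flens[i])
            frag = hap_seq[s:e]
            if flips[i]:
                frag = revcomp(frag)
            name = f"{library_label}:{label}:{'rev' if flips[i] else 'fwd'}:{s}:{e}:{i}"
            pairs.append(ReadPair(name, frag[:rl], revcomp(frag[-rl:]), qual))
    return pairs


def downsample(
    pairs: Sequence[ReadPair],
    rng: np.random.Generator,
    fraction: float | None = None,
    target_pairs: int | None = None,
) -> list[ReadPair]:
    """Subsample read pairs, preserving pairing.

    Exactly one of ``fraction`` (independent Bernoulli keep) or
    ``target_pairs`` (uniform subsample to an exact count) must be given. A
    target exceeding the available count returns all pairs with a warning.
    """
    if (fraction is None) == (target_pairs is None):
        raise ValueError("specify exactly one of fraction or target_pairs")
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if fraction == 1.0:
            return list(pairs)
        keep = rng.random(len(pairs)) < fraction
        return [p for p, k in zip(pairs, keep) if k]
    if target_pairs >= len(pairs):
        if target_pairs > len(pairs):
            import warnings

            warnings.warn(
                f"requested {target_pairs} pairs but only {len(pairs)} available; "
                "returning all reads"
            )
        return list(pairs)
    idx = rng.choice(len(pairs), size=target_pairs, replace=False)
    idx.sort()
    return [pairs[i] for i in idx]


def parse_provenance(read_name: str) -> dict | None:
    """Decode the provenance fields of a simulated read name, if present."""
    fields = read_name.split("/")[0].split(":")
    if len(fields) != 7:
        return None
    lib, tid, hap, strand, s, e, i = fields
    try:
        return {
            "library": lib,
            "template_id": tid,
            "haplotype": hap,
            "strand": strand,
            "fragment_start": int(s),
            "fragment_end": int(e),
            "index": int(i),
        }
    except ValueError:
        return None


@dataclass
class SimulatedExperiment:
    """A complete simulated experiment with its ground truth."""

    config: SimulationConfig
    truth: HaplotypeTruth
    templates: list[TemplateMolecule]
    mutated: dict[str, list[ReadPair]]  # strand -> pairs
    unmutated: list[ReadPair]

    def templates_for_strand(self, strand: str) -> list[TemplateMolecule]:
        return [t for t in self.templates if t.strand == strand]

    def write(self, outdir: str | Path) -> dict:
        """Write paired FASTQ per library, truth tables as TSV. Returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict = {"mutated": {}, "unmutated": None}
        for strand, pairs in self.mutated.items():
            r1 = outdir / f"mut_{strand}_R1.fastq"
            r2 = outdir / f"mut_{strand}_R2.fastq"
            write_fastq(((p.name, p.read1, p.quality) for p in pairs), r1)
            write_fastq(((p.name, p.read2, p.quality) for p in pairs), r2)
            paths["mutated"][strand] = (str(r1), str(r2))
        r1 = outdir / "unmut_R1.fastq"
        r2 = outdir / "unmut_R2.fastq"
        write_fastq(((p.name, p.read1, p.quality) for p in self.unmutated), r1)
        write_fastq(((p.name, p.read2, p.quality) for p in self.unmutated), r2)
        paths["unmutated"] = (str(r1), str(r2))

        with open(outdir / "variants.tsv", "w") as out:
            out.write("position\tkind\tref\talt\thaplotype\n")
            for pos, kind, ref_a, alt, hap in self.truth.variants:
                out.write(f"{pos}\t{kind}\t{ref_a}\t{alt}\t{hap}\n")
        with open(outdir / "templates.tsv", "w") as out:
            out.write("template_id\thaplotype\tstrand\tlength\tn_converted\tn_errors\n")
            for t in self.templates:
                out.write(
                    f"{t.template_id}\t{t.haplotype_label}\t{t.strand}\t"
                    f"{len(t.final_sequence)}\t{len(t.conversion_pattern)}\t"
                    f"{len(t.replication_errors)}\n"
                )
        with open(outdir / "haplotypes_truth.fasta", "w") as out:
            for label, seq in zip(self.truth.haplotype_labels, self.truth.haplotypes):
                out.write(f">{label}\n{seq}\n")
        paths["truth"] = str(outdir / "variants.tsv")
        return paths


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the full generator: haplotypes, templates, mutated + unmutated reads.

    A single seeded generator drives every draw, so identical configs produce
    byte-identical libraries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = simulate_haplotypes(config, rng)
    templates = make_templates(truth, config, rng)
    labels = config.labels()
    mutated: dict[str, list[ReadPair]] = {}
    for strand, label in zip(config.strands, labels):
        strand_templates = [t for t in templates if t.strand == strand]
        mutated[strand] = fragment_library(strand_templates, config, rng, library_label=label)
    unmutated = simulate_unmutated_library(truth, config, rng)
    return SimulatedExperiment(config, truth, templates, mutated, unmutated)
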