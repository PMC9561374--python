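"""End-to-end orchestration: assemble -> unmask -> phase -> consensus.

``analyze`` is the in-memory core used by tests and scripts; ``run_pipeline``
wraps it with file I/O, structured logging and a run manifest, and is what
the ``museq run`` command calls. Coordinates are 0-based half-open
internally; human-readable reports state their convention in the header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .assembly import (
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
from .consensus import (
    ConsensusParams,
    HaplotypeAssembly,
    call_consensus,
    error_report,
    iterative_consensus_align,
    write_assemblies_fastq,
)
from .phasing import PhasingParams, build_biallelic_matrix, coalign, detect_recombinants, fit_haplotypes
from .seqio import oriented_pairs, oriented_reads, read_paired_fastq, write_fasta
from .simdata import SimulationConfig, simulate_experiment
from .unmask import UnmaskedContig, build_kmer_table, map_kmers_to_contig, unmask_contig

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "assemble_library",
    "unmask_library",
    "analyze",
    "run_pipeline",
    "evaluate_run",
]


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # strand -> (R1 path, R2 path); ignored when simulate is set
    mutated: dict[str, tuple[str, str]] = field(default_factory=dict)
    unmutated: tuple[str, str] | None = None
    simulate: SimulationConfig | None = None
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    phasing: PhasingParams = field(default_factory=PhasingParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    unmask_k: int | None = None  # defaults to the assembly k
    unmask_confidence: float = 0.99
    unmask_min_votes: float = 10.0
    min_table_count: int = 2
    log_level: str = "INFO"

    def validate(self) -> None:
        self.assembly.validate()
        self.phasing.validate()
        if self.simulate is None:
            if not self.mutated:
                raise ValueError("no mutated libraries configured")
            for strand, (r1, r2) in self.mutated.items():
                for p in (r1, r2):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"mutated {strand} library: {p}")
            if self.unmutated is not None:
                for p in self.unmutated:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"unmutated library: {p}")


@dataclass
class AnalysisResult:
    contigs: dict[str, list[Contig]]  # strand -> extended contigs
    validation: dict[str, "object"]  # strand -> DataFrame
    template_estimates: dict[str, int]
    chimera_reports: dict[str, list]
    unmasked: list[UnmaskedContig]  # all strands, oriented to top frame
    partition: "object | None"
    recombinants: list[dict]
    assemblies: list[HaplotypeAssembly]
    errors: "object | None"
    warnings: list[str] = field(default_factory=list)


def assemble_library(
    pairs: Sequence[tuple[str, str, str]], params: AssemblyParams
):
    """Stage 1 for one library: graph, initial contigs, paired-end extension.

    ``pairs`` are raw (name, read1, read2) records; mate 2 is reoriented here.
    Returns (extended contigs, validation table).
    """
    opairs = oriented_pairs(pairs)
    reads = [seq for _, seq in oriented_reads(pairs)]
    graph = build_graph(reads, params)
    initial = initial_contigs(graph)
    logger.info("stage 1: %d initial contigs (longest %d)",
                len(initial), len(initial[0]) if initial else 0)
    extended = extend_contigs(initial, opairs, params)
    read_records = []
    for name, left, right in opairs:
        read_records.append((f"{name}/1", left))
        read_records.append((f"{name}/2", right))
    report = validate_templates(extended, read_records, params)
    return extended, report


def unmask_library(
    contigs: Sequence[Contig],
    table,
    confidence: float = 0.99,
    min_votes: float = 10.0,
    min_table_count: int = 2,
) -> list[UnmaskedContig]:
    """Stage 2 for one library's extended contigs."""
    out = []
    for c in contigs:
        pileup = map_kmers_to_contig(c.sequence, table, min_table_count)
        out.append(
            unmask_contig(c.sequence, pileup, contig_id=c.contig_id,
                          confidence=confidence, min_votes=min_votes)
        )
    return out


def analyze(
    mutated: dict[str, Sequence[tuple[str, str, str]]],
    unmutated_reads: Sequence[str] | None,
    assembly_params: AssemblyParams = AssemblyParams(),
    phasing_params: PhasingParams = PhasingParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
    unmask_k: int | None = None,
    unmask_confidence: float = 0.99,
    unmask_min_votes: float = 10.0,
    min_table_count: int = 2,
    estimate_templates: bool = True,
) -> AnalysisResult:
    """Run the full analysis in memory.

    ``mutated`` maps strand ('top'/'bottom') to raw read-pair records;
    bottom-strand contigs are reverse-complemented into top-strand frame
    after unmasking so phasing and consensus pool both strands, with their
    masked channels mirrored (C/T on top is G/A on bottom).
    """
    warnings_log: list[str] = []
    contigs: dict[str, list[Contig]] = {}
    validation: dict[str, object] = {}
    estimates: dict[str, int] = {}
    chimeras: dict[str, list] = {}

    table = None
    if unmutated_reads:
        table = build_kmer_table(
            list(unmutated_reads), unmask_k or assembly_params.k
        )

    for strand in sorted(mutated):
        pairs = list(mutated[strand])
        extended, report = assemble_library(pairs, assembly_params)
        contigs[strand] = extended
        validation[strand] = report
        opairs = oriented_pairs(pairs)
        if table is not None and estimate_templates:
            try:
                est = estimate_template_count(
                    [s for _, s in oriented_reads(pairs)], table, assembly_params,
                    min_table_count=min_table_count,
                )
                estimates[strand] = est.estimate
            except ValueError as exc:
                warnings_log.append(f"template count ({strand}): {exc}")
        chimeras[strand] = detect_chimeras(extended, opairs, assembly_params)

    if table is None:
        raise RuntimeError(
            "stage 2 (unmasking) requires the unmutated library; none was "
            "provided — supply unmutated FASTQ files for the same region"
        )

    unmasked: list[UnmaskedContig] = []
    for strand in sorted(contigs):
        for u in unmask_library(
            contigs[strand], table, unmask_confidence, unmask_min_votes,
            min_table_count,
        ):
            u.contig_id = f"{strand}_{u.contig_id}"
            u.source_contig_id = u.contig_id
            if strand == "bottom":
                u = u.reverse_complement()
            unmasked.append(u)

    partition = None
    recombinants: list[dict] = []
    assemblies: list[HaplotypeAssembly] = []
    errors = None
    phase_input = [u for u in unmasked if len(u) >= phasing_params.min_contig_length]
    if phase_input:
        co = coalign(phase_input, phasing_params)
        matrix = build_biallelic_matrix(co, phase_input)
        partition = fit_haplotypes(matrix, phasing_params)
        recombinants = detect_recombinants(matrix, partition, phasing_params)
        by_id = {u.contig_id: u for u in phase_input}
        assigned = {
            label: [by_id[cid] for cid in cids]
            for label, cids in partition.assignments.items()
        }
        for label in sorted(assigned):
            members = assigned[label]
            if not members:
                continue
            columns = iterative_consensus_align(members, consensus_params)
            assemblies.append(call_consensus(columns, consensus_params, label=label))
        errors = error_report(
            {k: v for k, v in assigned.items() if v},
            {a.label: a for a in assemblies},
            n_excluded=len(partition.unassigned),
        )
    else:
        warnings_log.append("no contig passed the phasing length filter")

    return AnalysisResult(
        contigs=contigs,
        validation=validation,
        template_estimates=estimates,
        chimera_reports=chimeras,
        unmasked=unmasked,
        partition=partition,
        recombinants=recombinants,
        assemblies=assemblies,
        errors=errors,
        warnings=warnings_log,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages with on-disk outputs and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("run: outdir=%s seed=%d k=%d D=%.2f ploidy=%d",
                outdir, config.seed, config.assembly.k, config.assembly.D,
                config.phasing.ploidy)

    experiment = None
    if config.simulate is not None:
        sim_config = config.simulate
        experiment = simulate_experiment(sim_config)
        experiment.write(outdir / "sim")
        mutated = {
            strand: [p.as_record() for p in pairs]
            for strand, pairs in experiment.mutated.items()
        }
        unmut = [p.read1 for p in experiment.unmutated]
        unmut += [p.read2 for p in experiment.unmutated]
    else:
        mutated = {
            strand: read_paired_fastq(r1, r2)
            for strand, (r1, r2) in config.mutated.items()
        }
        unmut = None
        if config.unmutated is not None:
            recs = read_paired_fastq(*config.unmutated)
            unmut = [r[1] for r in recs] + [r[2] for r in recs]

    result = analyze(
        mutated,
        unmut,
        assembly_params=config.assembly,
        phasing_params=config.phasing,
        consensus_params=config.consensus,
        unmask_k=config.unmask_k,
        unmask_confidence=config.unmask_confidence,
        unmask_min_votes=config.unmask_min_votes,
        min_table_count=config.min_table_count,
    )

    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "k": config.assembly.k,
            "D": config.assembly.D,
            "ploidy": config.phasing.ploidy,
            "assignment_ratio": config.phasing.assignment_ratio,
        },
        "stages": {},
        "warnings": result.warnings,
    }
    for strand, contigs in result.contigs.items():
        fa = outdir / f"contigs_{strand}.fasta"
        report = result.validation[strand]
        med = dict(zip(report["contig_id"], report["median_coverage"]))
        write_fasta(
            (
                (
                    f"{c.contig_id} stage={c.stage} length={len(c.sequence)} "
                    f"median_coverage={med.get(c.contig_id, 0):.0f}",
                    c.sequence,
                )
                for c in contigs
            ),
            fa,
        )
        report.to_csv(outdir / f"validation_{strand}.tsv", sep="\t", index=False)
        manifest["stages"].setdefault("assemble", {})[strand] = {
            "n_extended_contigs": len(contigs),
            "n_full_length": int(report["full_length"].sum()),
            "template_estimate": result.template_estimates.get(strand),
            "chimera_rate": chimera_rate(result.chimera_reports[strand]),
            "contigs_fasta": str(fa),
        }

    un_fa = outdir / "unmasked_contigs.fasta"
    write_fasta(
        ((f"{u.contig_id} masked={len(u.masked_positions)}", u.display_sequence())
         for u in result.unmasked),
        un_fa,
    )
    with open(outdir / "masked_positions.tsv", "w") as out:
        out.write("# 0-based positions\ncontig_id\tposition\tchannel\n")
        for u in result.unmasked:
            for pos in sorted(u.masked_positions):
                out.write(f"{u.contig_id}\t{pos}\t{u.masked_positions[pos]}\n")
    manifest["stages"]["unmask"] = {
        "n_contigs": len(result.unmasked),
        "total_masked_positions": sum(len(u.masked_positions) for u in result.unmasked),
        "fasta": str(un_fa),
    }

    if result.partition is not None:
        with open(outdir / "assignments.tsv", "w") as out:
            out.write("contig_id\thaplotype\n")
            for label, cids in sorted(result.partition.assignments.items()):
                for cid in cids:
                    out.write(f"{cid}\t{label}\n")
            for cid in result.partition.unassigned:
                out.write(f"{cid}\tunassigned\n")
        with open(outdir / "haplotype_alleles.tsv", "w") as out:
            out.write("haplotype\talleles\n")
            for h in result.partition.haplotypes:
                out.write(f"{h.label}\t{''.join(map(str, h.alleles))}\n")
        manifest["stages"]["phase"] = {
            "n_assigned": {
                label: len(cids)
                for label, cids in result.partition.assignments.items()
            },
            "n_unassigned": len(result.partition.unassigned),
            "n_recombinant": len(result.recombinants),
            "total_loglik": result.partition.total_loglik,
        }

    fq = outdir / "haplotypes.fastq"
    write_assemblies_fastq(result.assemblies, fq)
    manifest["stages"]["consensus"] = {
        "fastq": str(fq),
        "haplotypes": {
            a.label: {
                "length": len(a.sequence),
                "median_Q": a.median_quality(),
            }
            for a in result.assemblies
        },
    }
    if result.errors is not None:
        result.errors.per_contig.to_csv(outdir / "error_report.tsv", sep="\t", index=False)
        manifest["stages"]["consensus"]["snv_error_rate"] = result.errors.snv_rate
        manifest["stages"]["consensus"]["indel_error_rate"] = result.errors.indel_rate

    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2)
    if experiment is not None:
        manifest["_experiment"] = experiment  # in-memory only, for evaluation
    manifest["_result"] = result
    return manifest


def evaluate_run(manifest: dict, experiment=None) -> dict:
    """Compare a (simulated) run against its ground truth.

    Reports full-length template recovery, chimera and recombinant counts,
    and consensus-vs-truth exactness. Skipped with a notice when no truth is
    available.
    """
    experiment = experiment or manifest.get("_experiment")
    result: AnalysisResult | None = manifest.get("_result")
    if experiment is None or result is None:
        return {"evaluated": False, "notice": "no simulation truth available"}

    truth_templates = {t.template_id: t.final_sequence for t in experiment.templates}
    n_templates = len(truth_templates)
    recovered = 0
    for strand, contigs in result.contigs.items():
        strand_truth = [
            t.final_sequence
            for t in experiment.templates
            if t.strand == strand
        ]
        for c in contigs:
            if any(
                len(c.sequence) >= 0.95 * len(t) and c.sequence in t
                for t in strand_truth
            ):
                recovered += 1
    n_chimeric = sum(
        sum(r.verdict == "chimeric" for r in reports)
        for reports in result.chimera_reports.values()
    )
    exact = 0
    mismatch_total = 0
    for a in result.assemblies:
        best = min(
            (_hamming_extended(a.sequence, h) for h in experiment.truth.haplotypes),
        )
        mismatch_total += best
        if best == 0:
            exact += 1
    return {
        "evaluated": True,
        "n_templates": n_templates,
        "n_recovered_full_length": recovered,
        "recovery_fraction": recovered / n_templates if n_templates else 0.0,
        "n_chimeric": n_chimeric,
        "n_recombinant": len(result.recombinants),
        "n_haplotypes_assembled": len(result.assemblies),
        "n_haplotypes_exact": exact,
        "consensus_mismatches": mismatch_total,
        "median_Q": float(np.median([q for a in result.assemblies for q in a.qualities]))
        if result.assemblies else 0.0,
    }


def _hamming_extended(a: str, b: str) -> int:
    """Edit distance between a consensus and a true haplotype."""
    import edlib

    return edlib.align(a, b, mode="NW")["editDistance"]
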