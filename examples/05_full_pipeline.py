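"""The whole pipeline on one simulated diploid experiment, checked vs truth.

simulate -> assemble (k=111, D=0.55) -> unmask -> phase -> consensus, then
compare the two haplotype assemblies with the simulated haplotypes.
"""

import edlib

from museq.assembly import AssemblyParams
from museq.phasing import PhasingParams
from museq.pipeline import analyze
from museq.simdata import SimulationConfig, simulate_experiment

config = SimulationConfig(
    region_length=2500, ploidy=2, snv_density=2.0,
    templates_per_haplotype_per_strand=10,
    per_template_coverage=128, unmutated_coverage=80, seed=19,
)
experiment = simulate_experiment(config)

result = analyze(
    {"top": [p.as_record() for p in experiment.mutated["top"]]},
    [p.read1 for p in experiment.unmutated] + [p.read2 for p in experiment.unmutated],
    assembly_params=AssemblyParams(k=111, D=0.55),
    phasing_params=PhasingParams(min_contig_length=1500),
)

print(f"extended contigs: {len(result.contigs['top'])}")
print(f"template-count estimate: {result.template_estimates['top']} "
      f"(simulated: {len(experiment.templates)})")
print(f"assignments: { {k: len(v) for k, v in result.partition.assignments.items()} }")
for assembly in result.assemblies:
    trimmed = assembly.trimmed(min_coverage=3)  # region ends see few fragments
    dist = min(
        edlib.align(trimmed.sequence, h, mode="HW")["editDistance"]
        for h in experiment.truth.haplotypes
    )
    print(
        f"{assembly.label}: {len(assembly.sequence)} bp, median Q "
        f"{assembly.median_quality():.0f}, edit distance to closest true "
        f"haplotype over the covered span: {dist}"
    )
if result.errors is not None:
    print(f"residual per-template SNV rate: {result.errors.snv_rate:.2e} "
          f"(injected {config.pcr_snv_rate:.1e})")
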