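"""Simulate a mutation-imprinted sequencing experiment with ground truth.

Builds a small diploid 2 kb region, imprints 8 template molecules per
haplotype with random C->T conversion patterns, and draws paired-end reads
for both the mutated and the unmutated library.
"""

from museq.simdata import SimulationConfig, simulate_experiment

config = SimulationConfig(
    region_length=2000,
    ploidy=2,
    snv_density=2.0,                       # SNVs per kb between haplotypes
    templates_per_haplotype_per_strand=8,
    conversion_rate=0.5,                   # per-cytosine C->T probability
    per_template_coverage=64,
    unmutated_coverage=50,
    seed=7,
)
experiment = simulate_experiment(config)

print(f"haplotypes: {experiment.truth.haplotype_labels}")
print(f"variants between them: {len(experiment.truth.variants)}")
for pos, kind, ref, alt, hap in experiment.truth.variants:
    print(f"  {kind} at {pos} ({ref or '-'} -> {alt or '-'}) on haplotype {hap}")
print(f"templates: {len(experiment.templates)}")
tpl = experiment.templates[0]
n_c = tpl.pre_error_sequence.count("C") + len(tpl.conversion_pattern)
print(
    f"first template: {len(tpl.conversion_pattern)} of {n_c} cytosines "
    f"converted ({len(tpl.conversion_pattern) / n_c:.0%})"
)
print(f"mutated read pairs: {len(experiment.mutated['top'])}")
print(f"unmutated read pairs: {len(experiment.unmutated)}")
# each template carries a unique imprint, so its reads can be told apart
patterns = {t.conversion_pattern for t in experiment.templates}
print(f"distinct imprints: {len(patterns)} (= number of templates)")
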