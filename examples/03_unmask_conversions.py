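"""Reverse the imprinted C->T mutations using the unmutated library.

k-mers from unconverted reads act as weighted micro-references: wherever
their pileup confidently reports C under the C->T compatibility rule, the
contig T is restored. Positions with split pileups (heterozygous C/T sites,
imperfect repeats) stay masked for the consensus stage.
"""

from museq.simdata import SimulationConfig, simulate_experiment
from museq.unmask import (
    build_kmer_table,
    estimate_conversion_rate,
    map_kmers_to_contig,
    unmask_contig,
)

config = SimulationConfig(
    region_length=2000, ploidy=2, templates_per_haplotype_per_strand=5,
    per_template_coverage=0, unmutated_coverage=80, seed=13,
)
experiment = simulate_experiment(config)
table = build_kmer_table(
    [p.read1 for p in experiment.unmutated] + [p.read2 for p in experiment.unmutated],
    k=111,
)
print(f"unmutated k-mer table: {len(table.counts)} distinct 111-mers")

tpl = experiment.templates[0]
pileup = map_kmers_to_contig(tpl.final_sequence, table)
unmasked = unmask_contig(tpl.final_sequence, pileup, tpl.template_id)

restored = sum(
    1 for pos in tpl.conversion_pattern
    if (m := tpl.map_to_final(pos)) is not None and unmasked.sequence[m] == "C"
)
print(
    f"template {tpl.template_id}: {restored}/{len(tpl.conversion_pattern)} "
    f"converted positions restored, {len(unmasked.masked_positions)} left masked"
)
converted, total, frac = estimate_conversion_rate(tpl.final_sequence, unmasked)
print(
    f"truth-free conversion estimate: {converted}/{total} cytosines = {frac:.1%} "
    f"(simulated rate {config.conversion_rate:.0%})"
)
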