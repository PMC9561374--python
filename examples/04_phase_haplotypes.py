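"""Partition unmasked contigs into haplotypes by maximum likelihood.

Contigs are co-aligned to the longest one, bi-allelic sites become a
contigs x sites matrix, and the best pair of haplotypes is found by
enumerating allele configurations (simulated annealing takes over on large
matrices). Contigs are assigned only at 1000:1 likelihood odds.
"""

from museq.phasing import PhasingParams, build_biallelic_matrix, coalign, fit_haplotypes
from museq.unmask import UnmaskedContig


def contig(cid, seq):
    return UnmaskedContig(cid, seq, {}, cid)


# a toy region: two haplotypes differing at three SNVs
import numpy as np

rng = np.random.default_rng(3)
base = "".join("ACGT"[i] for i in rng.integers(0, 4, 1800))
sites = (400, 900, 1400)
hap_b = list(base)
for s in sites:
    hap_b[s] = {"A": "G", "C": "A", "G": "T", "T": "C"}[hap_b[s]]
hap_b = "".join(hap_b)

contigs = [contig(f"a{i}", base) for i in range(6)]
contigs += [contig(f"b{i}", hap_b) for i in range(6)]

params = PhasingParams(ploidy=2, min_contig_length=1500)
matrix = build_biallelic_matrix(coalign(contigs, params), contigs)
print(f"bi-allelic sites found: {[c.position for c in matrix.columns]} (true: {list(sites)})")

result = fit_haplotypes(matrix, params)
for h in result.haplotypes:
    members = result.assignments[h.label]
    print(f"{h.label}: alleles {h.alleles}, {len(members)} contigs -> {members}")
print(f"unassigned (below 1000:1 odds): {result.unassigned}")
print(f"partition log-likelihood: {result.total_loglik:.2f}")
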