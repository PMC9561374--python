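# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the procedure was genuinely open.

## The experimental design being modelled

A targeted region (5–10 kb) is amplified and each template molecule is
imprinted with a random pattern of C→T conversions before further
amplification: either by partial bisulfite conversion tuned to convert
40–60% of cytosines, or by amplifying with a dCTP / 5-methyl-dCTP mixture so
that subsequent complete enzymatic deamination converts only the unprotected
(unmethylated) cytosines. Either way the statistical output is the same: per
template, each cytosine is converted independently with probability
*p* ≈ 0.5. One strand is then selectively amplified and sequenced as 150 bp
paired-end reads from ~400 bp fragments; an unconverted aliquot of the same
amplicon yields an "unmutated" library. The package consumes the two read
libraries and nothing else — no reference genome.

## Synthetic data generator (`museq.simdata`)

The generator's defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `region_length` | 5000 bp | amplicon size (bisulfite-regime) |
| `ploidy` | 2 | haplotypes in the mixture |
| `snv_density` | 1.0 /kb | pairwise haplotype SNV density |
| `indel_density` | 0.2 /kb | pairwise 1–10 bp indel density |
| `conversion_rate` | 0.5 | per-cytosine C→T probability |
| `pcr_snv_rate` | 7.4×10⁻⁴ /base | per-template substitution errors |
| `pcr_indel_rate` | 7.7×10⁻⁵ /base | per-template 1 bp indel errors |
| `read_length`, `insert_mean` | 150 bp, 400 bp | read geometry |
| `insert_sd` | 60 bp | fragment-size spread (see below) |
| `per_template_coverage` | 256× | mutated-library redundancy |
| `unmutated_coverage` | 100× | unconverted-library depth |

Haplotypes are drawn over a random uniform-composition reference (GC ≈ 50%,
which reproduces the ~2/3 vs ~1/3 split of T- vs C-majority unmask pileups);
variant sites are uniform, each private to one haplotype, with the per-site
rate scaled by `M/2` so that every *pair* of haplotypes differs at
`density × L / 1000` sites in expectation for any ploidy M. A bottom-strand
template is the reverse complement of its haplotype, converted in that
orientation, so imprints are always C→T in library orientation (they appear
as G→A in top-strand frame).

Replication errors are applied **once per template**, modelling early-round
polymerase errors that propagate to all of a molecule's reads — this is the
error class the disruption parameter exists to tolerate, and it is what the
reported per-template error rates measure. Indel errors are placed
uniformly: the strong microsatellite enrichment of real polymerase slippage
is an emergent property of real enzymes and is deliberately not forced into
the simulation, so context-fraction statistics from simulated data are not
comparable to bench data. Later-round (read-private) errors and base-quality
miscalls are not modelled; passing tests therefore demonstrate correctness
of the algorithms under the stated error model, not robustness to raw-read
noise, which in real data is suppressed by the `min_kmer_count` filter and
the extension consensus. Fragment sizes are Normal(400, 60) truncated to
[read length, template length]; the fragment-size spread is not stated by
the protocols and 60 bp is this package's calibration choice. Sonication
end-bias is not modelled, so template *ends* are covered only by fragments
starting exactly at the boundary — recovery metrics consequently define
"full length" as ≥ 95% of the template.

Every read name encodes provenance (library, template, haplotype, strand,
fragment coordinates). The pipeline never reads it; only evaluation and
chimera auditing do, and both degrade gracefully to "not evaluable" on
anonymous names.

## Template assembly (`museq.assembly`)

With ~28 cytosines per 111-mer window at p = 0.5, two templates share a
k-mer only when their imprints coincide across the window (probability
≈ 2⁻²⁸ per window pair), so the graph of the mutated library is essentially
a disjoint union of per-template paths. Reads enter the graph in
fragment-forward orientation — mate 2 is reverse-complemented under the
standard FR layout — and k-mers are **not** canonicalised by strand, because
conversion destroys strand symmetry; each template assembles in its read
orientation. Nodes need `min_kmer_count = 2` occurrences (suppressing
singleton artefacts), edges are (k+1)-mer adjacencies observed in reads, and
initial contigs are maximal unambiguous paths, emitted longest-first with
lexicographic tie-breaks. Pure cycles are broken at their lexicographically
smallest node and flagged.

Paired-end extension interprets the disruption parameter D as: *a
single-base extension of a contig end is accepted while the fraction of
placed, overlapping mates agreeing with the consensus base is ≥ D*. Mates
are recruited through their partners (anchored on the contig by an exact
k-mer whose full read placement agrees at ≥ 90%), placed against the contig
end by an exact 25-mer seed, and vote per overhang position. When an
extended end reaches an exact overlap of ≥ k bases with another contig the
two merge; an end claimed by several partners merges with none (conflict
logged). The loop runs to convergence. D = 0.95 tolerates ~5% discordant
evidence; D = 0.55 only requires a majority, and recovers no fewer
full-length templates.

Template counting groups mutated read windows by the full-conversion image
of unmutated k-mers: windows compatible with a k-mer under C→T substitution
are binned by their realised sequence, bins supported by ≥ 20 reads count as
distinct molecules, and the estimate is the **90th percentile** of
per-k-mer distinct-pattern counts — robust to k-mers straddling variants
(which see only one haplotype's templates) and to thinly covered windows.
The exact summary statistic was an open choice; the percentile was fixed
before use and validated on simulations (± 10% at ≥ 128× coverage). For
large libraries the k-mer set can be deterministically subsampled
(`table_subsample`, CRC32-based) without changing the percentile materially.

Validation re-maps reads by verified exact-k-mer anchoring; "full length" is
≥ 95% of the modal length of the ten longest contigs (implemented as their
median, which for near-identical full-length contigs is the mode). Chimera
auditing tiles each contig into windows, finds which provenance label
dominates each window, and calls a contig chimeric when two labels that each
supply > 10% of its reads dominate disjoint window spans; the gap between
the spans is the breakpoint interval. Windowed spans, rather than raw
anchor-position extrema, are needed because junction-spanning reads anchor
legitimately on either side of a junction.

## Unmasking (`museq.unmask`)

The k-mer table is built from both orientations of the unmutated reads
(unconverted molecules are double-stranded) and entries below a minimum
count (default 2) are ignored, suppressing error k-mers. A table k-mer maps
*properly* at a contig offset when the window could have arisen from it by
C→T conversion alone; operationally, candidates are retrieved by equality of
full-conversion images and verified by requiring every window C to be C in
the k-mer. Each properly mapped k-mer votes its own bases over the covered
span, weighted by its count. Because image equality forces every vote at a
contig T position to be C or T, the pileup stores total weight and C-weight.

A contig T is restored to C (or confirmed as T) when the corresponding
weighted fraction reaches the confidence threshold (0.99) over at least 10
weighted votes; anything else — split pileups at heterozygous C/T sites or
imperfect repeats, and empty or thin pileups — stays T and is recorded as
masked, because absence of unconverted evidence cannot distinguish a true T
from a converted C. The 99% threshold is applied to weighted vote fractions;
whether the original procedure counted reads or distinct k-mers is unknown,
and the weighted interpretation was chosen because it uses the library's
full evidence. Unmasking is idempotent. The unmask k defaults to the
assembly k (111) and is independently configurable; smaller values trade
specificity for coverage.

Masked positions carry a channel: `Y` (observed T, truly C or T) in the
frame of the converted strand, mirrored to `R` (observed A, truly A or G)
when a bottom-strand contig is reverse-complemented into top-strand frame.
This mirror rule is how both strands share one phasing matrix and one
consensus: the bookkeeping travels with the contig, and the likelihood
channels below treat `R` exactly as `Y` with G in place of C.

## Phasing (`museq.phasing`)

Co-alignment uses edlib (banded bit-vector edit distance) with additional
equality pairs so a masked `t` matches C or T (and masked `a` matches A or
G); alignments under 90% identity are excluded with a warning. The
conventional score (match +1, mismatch −1, gap open −3, extend −1) is
recomputed from the alignment for reporting. On the ≥ 90%-identity inputs
this stage sees, unit-cost and scored optima coincide, and edlib is orders
of magnitude faster than a dense dynamic program at 5–10 kb.

Bi-allelic columns are reference positions where exactly two unmasked bases
each appear in ≥ 2 contigs; masked entries are admitted where the masked
channel spans the two alleles (C/T columns for `Y`, G/A for `R`). Indel
polymorphisms become presence/absence columns — runs of reference positions
with identical deletion patterns merge into one column per event, and
insertions are keyed by the position they follow; this encoding was an open
choice, fixed here because it lets indels phase through the same likelihood
as SNVs.

The per-contig likelihood under haplotype *H* multiplies, over non-missing
columns: (1−ε) on an allele match, ε on a mismatch, and for a masked entry
*p* if H carries the convertible allele, (1−ε) if it carries the other. The
default ε = 0.005 covers residual per-template error plus alignment noise;
*p* is the conversion rate, shared with the generator's semantics. The
partition objective takes, per contig, the **maximum** likelihood over the M
haplotypes, and maximises the sum. When the number of unordered
configurations `C(2ⁿ+M−1, M)` is within `exhaustive_limit` (10⁵) the
optimum is found by enumeration (with haplotype-relabeling symmetry
removed); otherwise simulated annealing runs single-allele flips under
geometric cooling (T₀ = 2.0, ×0.995 per step, 5000 steps, 8 restarts, best
kept, fully seeded). The schedule was validated against the exhaustive
oracle on small random matrices; disagreement between restarts beyond
tolerance attaches a non-convergence warning. A zero-column matrix returns M
consensus copies flagged `monomorphic` with every contig in set one.

Assignment requires likelihood odds of ≥ `assignment_ratio` (default 1000)
over the best alternative haplotype; contigs covering no discriminating
column stay unassigned. Recombinant screening compares each contig's best
single-haplotype explanation with its best single-switch two-haplotype
explanation over the ordered columns and flags the contig when the switch
model wins by the same odds, reporting the switch interval.

## Consensus (`museq.consensus`)

Contigs of one haplotype are aligned to the longest; any column where a gap
(or a shared insertion) is the strict majority (> 50% of covering contigs)
edits the working reference, which is realigned — up to five rounds, after
which surviving disagreement flags the affected columns low-confidence
(capped at Q2). Per final column the posterior over {A, C, G, T, gap} under
a uniform prior uses: (1−ε) for a matching unmasked observation, ε/3
otherwise (the gap is a fifth symbol on the same channel), and for masked
observations *p* toward C (or G), (1−ε) toward T (or A). The call is the
argmax; its error probability is log-transformed to a Phred score capped at
93 (the FASTQ printable range); zero-coverage columns emit N at Q0 and gap
calls emit nothing.

Masked columns resolve here by aggregation across imprints: a true C shows a
mix of unmasked C (unconverted templates) and masked T, overwhelming the
all-T alternative, while a true T shows masked T in every template and wins
because 1−ε > p. Both-strand data pools naturally because bottom-strand
contigs arrive mirrored; whether strand merging happens inside this stage or
as a post-hoc step was open, and the in-stage pooling was chosen because it
feeds both channels into one posterior. Ends of the region are covered by
few fragments; `HaplotypeAssembly.trimmed(min_coverage)` yields the
well-supported span for comparisons that should not count single-coverage
end artefacts.

The residual-error report aligns each assigned contig to its consensus,
counts substitution and indel-event rates per aligned base (masked positions
align as matches), and classifies indel contexts: mononucleotide runs ≥ 3,
dinucleotide repeats ≥ 2 full units (common convention; none was
prescribed), and mononucleotide runs on the fully converted consensus.

## Problem sizes and numerical conventions

The test suite and acceptance script run desk-scale versions of the study
conditions — 5 kb regions, 45–50 templates, 256× per-template coverage,
k = 111 — chosen so the full suite completes in minutes on one CPU while
preserving the regime that matters (k-mer uniqueness, coverage per template,
error rates). Coordinates are 0-based half-open internally; human-readable
reports say so in their headers. All randomness flows from
`numpy.random.default_rng` seeds carried in the configuration objects, and
ties everywhere (contig ordering, consensus argmax, annealing restarts)
break deterministically, so identical configurations are byte-reproducible.

## Known limitations

* Read-private (late-round PCR and sequencing) errors are not simulated;
  the disruption-parameter ordering (permissive ≥ strict recovery) is
  therefore demonstrated but not stressed.
* The extension heuristic places mates by exact 25-mer seeds; extreme
  low-complexity regions could defeat seed placement and are only partially
  exercised by uniform-composition references.
* Indel-context fractions from simulation are not comparable to bench data
  (uniform placement by design).
* Template ends are recovered only when a fragment starts exactly at the
  boundary; "full length" deliberately means ≥ 95% of the template.
* The annealing schedule is validated on small matrices; very large
  matrices (hundreds of columns) may need more steps or restarts.
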