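# Methods

This note records the scientific model implemented by `hgtsim`, the
defaults and conventions chosen where the problem left room, and what the
synthetic fixtures can and cannot establish about real data.

## Codon mutation model

Mutations are introduced codon-by-codon. Using whole codons as the unit
of change guarantees frame preservation and makes the synonymous /
non-synonymous composition of the introduced divergence an explicit dial
rather than an emergent property. Four event categories are defined:
C1 (one base, silent), C2 (one base, non-silent), C3 (two bases, silent
or not) and C4 (three bases). Two- and three-base silent changes are rare
(≈1% of their buckets), which is why C3 and C4 are not split by synonymy.

**Excluded codons.** Start and stop codons are removed from the mutation
space as both sources and targets. The start set is the bacterial-style
{ATG, GTG, TTG}; together with the stops {TAA, TAG, TGA} this gives 58
mutable codons. Exhaustive enumeration of ordered pairs then yields
124 C1, 356 C2, 22 + 1,392 two-base and 12 + 1,400 three-base mutations.
The single-start convention {ATG} does not reproduce these totals; the
three-start convention does, which is why it is the default (the set is
configurable on `CodonTable`). Translation always uses the standard code —
the start set affects only exclusion. One consequence worth noting: an
*internal* GTG or TTG codon (Val/Leu) is protected from mutation even
though it is not functionally a start; this is the price of a purely
sequence-level exclusion rule.

**Two-base synonymy split.** Independent enumeration fixes the two-base
total at 1,414 but classifies 22 ordered pairs as silent rather than 20.
The discrepancy does not affect the simulator (C3 ignores synonymy); the
census reports both buckets as enumerated rather than forcing a
convention that cannot be derived from first principles.

## Budget and apportionment

For a gene of length L (nt) at level I (percent), the base budget is
N = round(L·I/100), rounded half away from zero (the choice only matters
when L·I/100 lands exactly on .5; it is documented and tested). The
budget is split into event counts c1..c4 under the cost identity
N = c1 + c2 + 2·c3 + 3·c4 by deterministic largest-remainder
apportionment on event counts weighted by the user ratio — no RNG is
involved, so (N, ratio) fully determines the plan.

A residual can remain when the active categories' costs cannot tile N
(e.g. ratio 0:0:0:1 with N not divisible by 3 — a situation that arises
for most gene lengths at most levels). The residual is closed
deterministically: first by a C3→C4 swap within the active set when both
are active, otherwise by borrowing a single cheap event (one C3 for two
leftover bases, one C2 for one). The borrowed event slightly perturbs
the requested composition — at most one event per gene — which is the
smallest intervention that keeps the nucleotide budget exact for
arbitrary gene lengths. A budget smaller than the cheapest active
category's cost (e.g. N = 1 with ratio 0:0:0:1) is genuinely
unrepresentable and raises an error.

**Sampling.** Distinct internal codons are selected uniformly without
replacement; the first and last codon are never touched, and internal
codons that are themselves in the excluded set are skipped. Categories
are placed in order C1, C2, C3, C4 because C1 is the only one whose
neighborhood can be empty (e.g. TGG/Trp has no synonymous one-base
neighbor): codons rejected for C1 stay available for later categories,
and the run aborts with a feasibility error naming the category if the
eligible pool is exhausted. Each event's target codon is drawn uniformly
from the category-compatible neighborhood. Because no codon is mutated
twice, the Hamming distance between input and output equals N exactly and
nucleotide identity is exactly 100 − 100·N/L.

**Protein comparison.** Donor and mutated copies are equal-length and
gap-free by construction, so amino-acid identity is computed positionally
on the two translations; FASTA export of both proteins is provided for
users who prefer an external protein aligner. Identity of empty
sequences is defined as 100%.

## Transfer model

Cassettes are `flank + gene + flank` (the flank emulating, e.g.,
transposon insertion context) and insertion is purely additive — no
recipient bases are deleted or replaced. Breakpoints are recorded
1-based, "insert after this base", 0 meaning before the first base, in
ORIGINAL coordinates; insertions are spliced right-to-left so the
recorded positions remain valid, which is what makes report-driven
excision restore the original genome byte-exactly.

Uniform mode samples distinct positions over the concatenated replicon
space, so longer replicons receive proportionally more insertions.
Intergenic mode takes the complement of the (merged) annotated feature
intervals and cuts selected regions at their integer midpoint; a cut is
therefore never strictly inside a feature. Cassettes are inserted on the
forward strand as supplied. Breakpoints are sampled without replacement —
two cassettes never share a cut point.

## Read simulation

Fragments of exactly `insert_size` bases are drawn (insert size = total
fragment length, so 2×100 bp reads at 250 bp insert leave a 50 bp inner
gap, and 2×250 bp reads at 250 bp insert are fully overlapping mates).
An optional normal jitter on the fragment length (sd parameter, default
0) is available; fragments never wrap sequence ends, and circular
replicons are treated as linear. The member sequenced for each pair is
chosen with probability ∝ abundance weight × genome length, which makes
equal weights produce even *depth* rather than even read counts; within a
member, sequences are chosen ∝ number of valid fragment starts and the
start position uniformly. Reads are error-free exact substrings in FR
orientation, written as R1/R2 FASTQ with maximal quality characters plus
a per-pair provenance table (genome, sequence, fragment start, strand).
The simulator streams; memory does not grow with the pair count.

For a community of total length G, the expected depth of n pairs of
2×r bp reads is 2·n·r/G. The 20-genome benchmark community used in the
coverage check totals 75.83 Mbp, for which 10 M pairs of 2×100 bp give
26.4×.

## Recovery criterion

A planted transfer is recovered when some contig carries the gene at
≥99% identity over ≥99% of the gene length AND at least one contig
region flanking the gene match is strictly longer than 1 kb (1,001 bp
qualifies, 1,000 bp does not) and matches the recipient genome. Hits are
consumed in the standard 12-column tabular format, so any aligner with
that output can feed the evaluator; coverage is measured on the query.
Candidate hits are ranked by bit score (ties: longer alignment, then
contig id) and scanned best-first until one passes the flank test — a
gene echoed near a neighboring cassette on another contig therefore does
not mask a genuine recovery.

"Matches the recipient genome" has no canonical operationalization; two
rules are provided. Default: exact substring search (either strand) of
the flank, or of a trimmed core covering ≥95% of it, against the
recipient — appropriate for error-free synthetic contigs and needing no
external binary. Alternative: a flanks-vs-recipient hit table, where a
flank matches if a hit with ≥99% identity covers ≥95% of it. Both
thresholds are configurable; neither is claimed to be the original
benchmark's exact rule.

## Synthetic fixtures

The fixture generator emulates the *shape* of a ten-donor → ten-recipient
transfer experiment at a reduced default scale chosen for fast test runs
(20 donor genes of 100–400 codons, 3 recipients of 150–250 kb, GC 0.5,
40 annotated features per recipient). Donor genes are valid CDSs (start +
non-excluded internal codons + stop), so any generated gene is mutable up
to the 30% maximum level exercised in the tests. Recipient genomes are
i.i.d. base sequences: they have no gene content, repeats, codon-usage
bias or phylogenetic structure. Consequently, passing tests establish
the *bookkeeping* contracts (exact budgets, round-trips, criterion
boundaries, depth scaling) — they do not establish that any particular
assembler will recover transfers from real communities, where repeats and
coverage fluctuations dominate. `perfect_contigs` plays a flawless
assembler (cassette ± a chosen amount of true context) so the recovery
criterion can be tested at known flank lengths.

## Numerical and procedural choices

- All randomness flows through `numpy.random.Generator`; the CLI derives
  one stream per pipeline stage from the master seed with stable labels,
  so re-running or adding a stage never perturbs another stage's draws.
  Identical (inputs, parameters, seed) yield identical outputs; each CLI
  run writes a manifest with SHA-256 checksums to make this checkable.
- Test and demonstration problem sizes (e.g. 200 genes for the budget
  sweep, 10⁵ pairs for the depth check, 60–80 kb fixture recipients) were
  chosen as the smallest scales at which the stochastic contracts are
  statistically sharp.
- Degenerate inputs: a zero mutation level is the identity map; zero
  placements return the genome unchanged; an empty hit list marks a gene
  unrecovered rather than erroring.

## Known limitations

- No insertions/deletions, no codon-usage-aware targeting, no
  evolutionary models (K80/GTR, dN/dS): divergence is a controlled count
  of codon rewrites, not a time-reversible process.
- A codon is mutated at most once, which caps the usable mutation level
  (roughly 3 bases per internal codon minus excluded ones); levels beyond
  ~30% on short genes can exhaust the eligible pool and error.
- Insertion is additive only — no replacement or recombination-style
  transfer, no insertion-site motifs.
- The read simulator is deliberately error-free; benchmarking against
  realistic sequencing noise requires an external read simulator.
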