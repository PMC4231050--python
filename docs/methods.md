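# Methods

## The problem

Microsatellites (simple sequence repeats, SSRs) are tandem arrays of 2–6 bp
motifs whose length variability makes them cheap, co-dominant PCR markers
for plant breeding and population genetics. A *gene-centered* SSR atlas
links each repeat to its genomic context — inside an exon, straddling a
splice junction, inside an intron, or intergenic — so that breeders can pick
markers that segregate with candidate genes. `ssratlas` implements the full
desk pipeline: repeat mining, motif canonicalization, context
classification, linkage-group assignment, stringent primer design,
candidate-gene nomination from protein-alignment tables, and catalog/summary
emission.

## Repeat model

A reported SSR is a **perfect maximal run**: an interval `[s, e)` of a
scaffold such that `seq[k] == seq[k+p]` for all `k` in `[s, e-p)`, where `p`
is the **primitive** (smallest) period of the run, and extending the
interval by one base on either side breaks the equality or leaves the
sequence. Thresholds (all configurable via `ScanParams`):

| parameter | default | meaning |
|---|---|---|
| `min_period` / `max_period` | 2 / 6 | motif length range, bases |
| `min_size` | 12 | run length, bases (inclusive: a 12-base run qualifies) |
| `min_exponent` | 2.0 | repeat units = size/period; fractional allowed |
| `exclude_primitive_period_1` | true | drop homopolymer runs |

Rulings worth stating explicitly:

* **Size 12 is inclusive.** The size distribution of reported SSR catalogs
  starts at 12, so the threshold is `size >= 12`, not `> 12`.
* **Fractional exponents.** A run need not end on a whole motif
  (`GATCGATCGATCG` is period 4, size 13, exponent 3.25).
* **Primitive-period reporting.** A run satisfying the period-4 equality
  whose primitive period is 2 is reported once, as a period-2 repeat.
  Overlapping runs of *different* primitive periods are all reported; only
  same-period runs merge (into the unique maximal run).
* **Homopolymers** satisfy every period's equality; they are excluded by
  default because mononucleotide arrays are not 2–6 bp markers. The flag
  `exclude_primitive_period_1=False` retains them, reported at period 1.
* **Non-ACGT characters break runs.** Perfect repeats require exact base
  identity, so scanning segments the sequence at N and at any IUPAC
  ambiguity code. Soft-masking (lowercase) is recorded on FASTA read but
  deliberately ignored by the scanner; only primer design consults masking,
  and it computes its own.
* No statistical-significance filtering is applied beyond the thresholds:
  with `min_size=12` such a filter would be marginal, and omitting it keeps
  the scanner exactly equivalent to its brute-force oracle.

`find_repeats` computes, per period `p`, the boolean vector
`seq[k] == seq[k+p]` (vectorised) and converts its maximal true-blocks into
runs; `oracle_find_repeats` re-derives the same contract by growing a run
from every left-maximal position in pure Python. The two implementations
share nothing but the `primitive_period` helper and must agree exactly —
this equivalence is a standing property test.

## Motif classes

Two motifs name the same repeat if one is a circular permutation of the
other or of its reverse complement (reading frame and strand are
arbitrary). Classes are named by the lexicographically smallest member
(A < C < G < T) and labelled by the full member list — rotations of the
representative first, then their reverse complements in the same order,
which yields the conventional labels `AG/GA/CT/TC` and
`ACG/CGA/GAC/CGT/TCG/GTC`. There are 4 dinucleotide and 10 trinucleotide
classes; exhaustive enumeration fixes 33, 102 and 350 classes for k = 4, 5,
6, frozen as regression values.

"Primitive" here means *not an integer power of a shorter motif*: `ATAT`
is rejected (it is a period-2 repeat in disguise), but `AATA` — whose
smallest period 3 does not divide its length — is a genuine period-4 motif
and occurs as a member of a class whose representative is aperiodic.
Non-primitive motifs are rejected with an error rather than silently
reduced; reduction is the scanner's responsibility, and rejecting prevents
double counting.

## Genomic context

Categories are assigned with priority **exon > exon_intron > intron >
intergenic**, evaluated over every transcript of every gene whose span
fully contains the SSR:

* *exon*: entirely within one exon segment of some transcript;
* *exon_intron*: within some transcript's extent, overlapping both exonic
  sequence and an intron (introns are derived as gaps between consecutive
  exons, never read from GFF `intron` features);
* *intron*: entirely within one such gap;
* *intergenic*: everything else.

Design choices where the convention was genuinely open:

* `mode="exon"` (default) classifies against exon features; `mode="cds"`
  uses CDS segments instead, under which UTR-located SSRs fall out of the
  exon category. Both readings are legitimate when UTR annotation is
  absent; the switch preserves them.
* An SSR overlapping a gene but not fully contained in its span is
  **intergenic with `boundary_flag`** — such straddlers are rare and the
  flag preserves auditability.
* Isoform disagreements resolve by the category priority (an SSR exonic in
  any isoform is exonic).
* All containing genes are attached; the first by coordinate is the atlas'
  primary gene column.

Scaffolds absent from the scaffold→linkage-group map are labelled `Un`
(unplaced). Conflicting duplicate map rows are an error at load time.

Internally every interval is 0-based half-open; all printed output is
1-based inclusive. The conversion happens exactly once, in `io_formats`.

## Length classes and summaries

Class I arrays are ≥ 20 bases; class II are 12–19. Cross-tabulations
(`summarize`) print counts with margin totals and per-column percentage
companions at one decimal; percentages use **half-up** rounding, not
banker's rounding, because that is what reproduces conventional printed
tables (e.g. 139,087/160,318 → 86.8). Marker-screen rates
(`screen_summary`) round to the nearest integer (19/73 → 26). SSRs-per-gene
means divide total markers by genes with ≥ 1 marker and round to one
decimal.

## Primer design

Templates are the SSR ± 250 bp of flank (clipped at scaffold ends, with the
clipping flagged). Low complexity is masked with a DUST-style score: in
each sliding 64-base window, `sum_t c_t(c_t-1)/2 / (w-3)` over ACGT 3-mer
counts, masking every position of windows scoring > 2.0. A 64-base
homopolymer scores 31; a window of all-distinct triplets scores 0; raising
the threshold can only shrink the masked area.

Candidate gates (each independently falsifiable, each with a reason code):
length 18–25 (optimum 20); Tm 57–63 °C (optimum 60); GC 20–60 %; no N; at
most half of the bases masked; neither of the two 3'-terminal bases masked
(the conservative reading of a lowercase-masking 3'-end rule); no
qualifying SSR run inside the primer (the mispriming-library rule reduces
to screening candidates with the repeat scanner, since the library *is* the
SSR set); and no self-complementary hairpin stem of more than 6 pairs with
a loop ≥ 3 bases (4 points per stem pair against a ceiling of 24).

Melting temperature is a nearest-neighbor calculation with the unified
ΔH/ΔS stack table, terminal A·T/G·C initiation terms, a symmetry correction
for self-complementary primers, and the entropy salt correction
`0.368·(N−1)·ln[Na+]`, at 50 mM monovalent salt and 25 nM of each strand.
It is deterministic and agrees with an independent published-table
implementation (Biopython's `Tm_NN`, used in tests as a cross-check oracle,
never in the production path) to well within 0.01 °C. Because the stack sum
is additive along the template, the pair search evaluates substring Tm in
O(1) via prefix sums; Tm is identical for a primer and its reverse
complement, so reverse candidates reuse the same prefix arrays.

Pairing: forward candidates live entirely upstream of the SSR, reverse
candidates entirely downstream; products must span 250–350 bp (optimum
300) and pair Tm difference ≤ 3 °C (a standard-practice ceiling, exposed in
`PrimerParams`). The winner minimises
`|len−20| + |Tm−60|` (both primers) `+ |product−300|/10`, with ties broken
by leftmost forward primer, then shortest product, then a fixed total
order — the search is exhaustive, deterministic and order-independent, and
every gate is re-verified on the returned pair. "No pair" is a value
(`DesignFailure` with aggregated per-gate failure counts), not an error.

This module approximates a Primer3-style configuration with transparent,
testable rules; it does not attempt full secondary-structure
thermodynamics (hairpins are scored by stem length only), multiplexing, or
cross-pair dimer checks.

## Ortholog markers

Hit tables are extended tabular alignments (qseqid, sseqid, evalue, ppos,
length, qlen, slen). Filters are all inclusive: E ≤ 1e-30, similarity
(percent positives — a config switch allows identity instead) ≥ 50 %, and
alignment length ≥ 75 % of both the query and the subject length, with no
gap-compression correction. Filtering is monotone in every threshold, and
best-hit-per-subject deduplication (lowest E-value, ties to highest
similarity) is idempotent. Nominated genes join to the genic atlas with
counts of markers that actually have designed primers.

## Synthetic validation genome

The generator emulates exactly what the pipeline must measure, nothing
more: i.i.d. background at 35 % GC (a typical plant nuclear genome) that
is **certified repeat-free** by rejection-resampling until the brute-force
oracle reports zero hits; declared SSR plants spliced in verbatim, with
junction bases resampled until the scan reports exactly the planted
intervals; hand-laid gene models; and a partial LG map (one scaffold
deliberately unplaced). The standard fixture is ~100 kb over 3 scaffolds
with 20 plants covering periods 2–6, fractional exponents, and all four
context categories.

Because backgrounds are repeat-free by construction, scanner recall and
precision are exactly 100 % on any fixture — passing this says the scanner
finds precisely what was planted, not that real genomes are this clean.
Real assemblies add compositional structure (isochores, transposon decay
products, near-perfect repeats) that this generator deliberately omits;
the oracle-equivalence property test, which salts random sequences with
tandem and near-tandem arrays across mixed GC, is the evidence that the
scanner's *definition* is implemented correctly on arbitrary input.

## Problem sizes

The test suite and the acceptance script use the 20-plant ~100 kb fixture,
300–1,000 random oracle-equivalence sequences of 100–10,000 bases, and a
60–200 template primer suite; these sizes give exact, reproducible answers
in seconds while exercising every code path at genome-realistic local
scale. All randomness flows from explicit seeds; the repository contains
no unseeded entropy.

## Known limitations

* Approximate/imperfect repeats, periods > 6, and compound SSR annotation
  are out of scope.
* The hairpin model counts stem pairs; it is not a thermodynamic folder.
* UTRs are not a category of their own; `mode="cds"` merely reclassifies
  them out of `exon`.
* Everything is single-threaded; outputs never depend on execution order.
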