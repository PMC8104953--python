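# Methods

This note documents the models, conventions and design choices behind
phagecompare, in the order the pipeline applies them.

## Coordinates and call identity

All gene calls use 1-based, both-ends-inclusive coordinates (the GFF
convention) and are normalized on input so `left ≤ right` regardless of
strand; orientation lives solely in the strand field. Native caller
dialects that print start/stop in transcription order (start > stop on the
minus strand) are normalized by the 5-column tabular reader. Wrap-around
calls spanning a contig end (circular genomes) are rejected: every
downstream operation (sequence extraction, interval complement for the
synthetic generator, report ordering) assumes linear intervals, and
accepting wrapped calls would make call identity ambiguous.

A call's *identity* for all set algebra is the exact tuple
`(contig, left, right, strand)`. Duplicate identities within one caller's
set are collapsed (first occurrence wins, the duplicate is logged), giving
call sets true set semantics.

## Compare Gene Calls

Agreement between callers is **exact** coordinate identity. Two calls that
share contig, strand and stop codon position (the `right` end on `+`, the
`left` end on `-`) but differ in start are *not* counted as agreeing;
instead every row in such a stop-sharing cluster is flagged `alt_start`.
Rationale: start-codon disagreement is the dominant mode of caller
disagreement in phage annotation, and any fuzzy-agreement rule would need
an arbitrary tolerance; the exact rule is auditable and the flag preserves
the biological signal. The consensus therefore deliberately excludes
alternate-start variants — they appear side by side in the report for the
user to adjudicate.

Merged sets: superset = all distinct identities; consensus = identities
supported by ≥ 2 callers; common = identities supported by all callers.
With one caller the consensus is empty (support 2 is unreachable) and the
common set equals that caller's set (vacuously "all callers"). Merged sets
get freshly generated sequential gene ids — a merged call has no unique
source caller, so caller ids are not propagated (provenance stays in the
report).

## Pairwise alignment

The built-in aligner is optimal local (Smith–Waterman) alignment with
affine gaps, computed by Biopython's `PairwiseAligner`. Gap costs follow
the BLAST convention — a gap of length L costs `open + L·extend` — and are
translated internally to Biopython's first/subsequent-position convention.

Default scoring, chosen to mirror blastn/blastp defaults:

| level   | substitution        | gap open | gap extend |
|---------|---------------------|----------|------------|
| gene    | match +2 / mismatch −3 | −5    | −2         |
| protein | BLOSUM62            | −11      | −1         |

Derived hit statistics: percent identity = identities / aligned columns
(gap columns included) × 100; query coverage = aligned query span / query
length × 100. Coverage is computed on the **query only**, because the
profile comparison orders and judges hits with respect to the query genome.
Identity and coverage are rounded to 2 decimals and scores to 1 decimal at
hit creation, so hit tables written in the 12-column BLAST tabular layout
re-parse to exactly equal values. The internal aligner reports raw
alignment scores and no e-values (Karlin–Altschul calibration is out of
scope); e-values exist only on hits read from real BLAST tabular files,
where they participate in best-hit ordering.

Degenerate inputs: empty sequences and sequence pairs with no
positive-scoring local alignment yield no hit. Among co-optimal alignments
Biopython's first enumerated traceback supplies the identity/coverage
figures — deterministic, though a different co-optimal path could report
slightly different identity; the score is always the optimum.

Both cutoffs (default identity 60%, coverage 75%) are inclusive (≥) and
exposed independently, since a single "matching cutoff" number is
ambiguous between the two semantics.

## Reciprocal-best-hit profiling

Best hits are selected by a fixed total ordering: higher score, then lower
e-value (hits without e-values rank after any with one), then longer
alignment, then lexicographically smallest subject id. The chain is total,
so classification is reproducible; the tail tie-break matters in practice
exactly when a genome carries identical duplicate genes.

Statuses partition each query genome's genes: *mutual* (reciprocal best),
*singular* (best hit whose reciprocal points elsewhere), *loner* (no hit
above cutoffs). N genomes produce N(N−1) directed reports; self-comparison
is never emitted as a genome-to-genome report and serves only paralog
detection. A paralog pair is any non-self gene pair with a surviving
filtered self-hit in either direction — deliberately recall-favouring,
because paralogs act only as an expansion set for homology groups and a
stricter (reciprocal) definition would silently shrink groups.

## Homology groups

Groups are oriented to the reference genome (first configured). Only
**mutual** hits admit members: mutuality is the only orientation-symmetric
correspondence available, and admitting singular hits would make group
content depend on comparison direction. Paralog expansion is one level
deep — the reference gene's paralogs and *their* mutual partners — never a
transitive closure, which could chain unrelated families through a
promiscuous domain. Paralogy inside non-reference genomes does not expand
groups (groups are defined strictly with respect to the reference).
Gene-level and protein-level groups are built independently from their own
alignments; on clean data they coincide, and divergence between them is
itself a useful signal (e.g. synonymous saturation).

Annotation carry-through is a pure join: per-genome 2-column tables
(gene id, text) validated against the selected call set, copied onto every
group member, `unannotated` for members without entries.

## Workflow driver

Configuration is a flat `key = value` file (comments `#`), with repeated
`genome =` lines opening per-genome blocks — trivially diffable, which the
checkpoint fingerprinting exploits. Defaults: workers 1, identity 60,
coverage 75, levels gene+protein, selected set `superset` (retains all
candidate genes, the recall-favouring default for comparison work).

Every stage reads its inputs from the on-disk artifacts of earlier stages
(selected-call GFFs, gene/protein FASTAs, raw hit tables). Restarting at a
checkpoint is therefore literally "skip earlier stages", which is what
makes interrupted-then-resumed runs byte-identical to uninterrupted ones.
`state.json` records, per stage, the configuration subset that stage
depends on; resuming refuses with a field-level diff when upstream
configuration changed (changing, say, cutoffs is allowed at the `cgp`
checkpoint but refused at `genomics`, whose inputs those cutoffs shaped).
Worker count, verbosity and flow control are excluded from fingerprints
and from the per-genome JSON run records, since they must not affect
scientific outputs. Parallelism is applied over genomes (gene calling,
annotation) and over genome pairs (profile comparison); results are merged
in configured order, so output trees are identical for any worker count.
A failing stage quarantines its partial output directories as
`<name>.failed` rather than leaving them in place.

## Synthetic data generator

The generator emulates the one regime the comparison stack is designed
for: small families of closely related phage genomes.

* **Ancestor**: one linear contig, non-overlapping genes (`ATG` + sense
  codons + stop, random strand), lengths uniform in 150–450 bp (multiples
  of 3; typical small phage gene sizes), intergenic gaps uniform in
  30–90 bp.
* **Divergence**: per-base point substitutions, uniform over the three
  alternative bases, applied to internal gene positions (start/stop codons
  protected, internal codons that would become stops are resampled to sense
  codons) and to intergenic spacers at the same rate. Default 5% — high
  enough to make identity cutoffs meaningful, well inside the
  reciprocal-best-hit recovery regime.
* **Duplications/deletions**: whole-gene events; a duplicate is an exact
  copy of the already-diverged gene appended at the contig end and recorded
  as a planted paralog pair; deletions drop the gene from calls and
  ortholog map.
* **Caller noise**: each true call independently missed
  (default 0.1); surviving calls start-shifted inward by 1–5 whole codons
  (default rate 0.2), preserving frame and stop so the emitted call is a
  genuine alternate-start variant; Poisson-many spurious calls (default
  mean 1/genome) placed only in intergenic space so truth evaluation stays
  unambiguous.

What it does **not** emulate: overlapping genes (common in real phages),
non-coding features (tRNAs, terminators), indels within genes, rearrangement,
transition/transversion bias, GC skew, or sequencing error. Consequently,
passing the planted-truth tests demonstrates correctness of the comparison
algebra and workflow under the stated model — not robustness of
reciprocal-best-hit orthology to genome rearrangement or to deep
divergence, which are properties of the method itself, not of this
implementation. One realistic emergent behaviour worth knowing about:
because intergenic spacers also descend from the common ancestor, spurious
calls planted in homologous spacers of different genomes can legitimately
match each other and form (correctly computed) homology groups of
annotation-free pseudo-genes.

One caveat on noise detection: a planted start shift surfaces as an
`alt_start` flag only if some other caller emits a differing-start call for
the same stop. If every other caller misses the gene or shifts it by the
identical codon count, the shifted call stands alone and cannot be flagged.
Under the default rates this affects roughly 1–2% of shifts in expectation,
so measured detection rates can fall just short of 100% on some seeds.

Everything is deterministic per seed (NumPy PCG64 streams; child seeds
drawn from a parent generator).

## Validation strategy and problem sizes

The test suite checks each layer against an *independent* oracle that
shares no code with the implementation: the aligner against a pure-Python
memoized recursion over the same scoring model (~6,500 sequence pairs,
lengths ≤ 8 over a 2-letter alphabet, where exhaustive recursion is exact
and fast); the merge algebra against literal k-of-n counting (200 random
fixtures, ≤ 4 callers × ≤ 20 calls); reciprocal-best-hit classification
against a brute-force sort-and-check oracle (200 random hit tables,
≤ 10 genes/genome). Planted-truth recovery uses 3 genomes × 20 genes at 5%
divergence with one reference duplication; workflow determinism checks use
3 genomes × 6 genes so that full pipeline runs stay in seconds. Property
tests (hypothesis, derandomized) cover round-trips, ordering invariances
and cutoff monotonicity. `scripts/acceptance.py` re-runs all of these from
scratch under a user-supplied seed and reports the measured rates.

## Known limitations

* The internal aligner is exact Smith–Waterman without heuristic seeding:
  fine for phage-sized gene sets (hundreds of genes), not for large-scale
  searches — supply precomputed BLAST `-outfmt 6` tables for those.
* Orthology is 1:1 reciprocal-best-hit with one-level paralog expansion;
  many-to-many families (beyond planted-style duplications) need proper
  graph clustering, which is out of scope.
* Checkpoint fingerprints cover configuration, not input file contents:
  editing a genome FASTA in place between runs without changing its path
  will not be detected.
* Translation uses the bacterial/plant-plastid genetic code (table 11)
  with literal start codons; alternative initiation (GTG/TTG) translates
  as the literal amino acid rather than methionine.
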