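# phagecompare

Comparative annotation support for sets of closely related bacteriophage
genomes: merge and reconcile gene calls from multiple gene callers, profile
genes between genomes by reciprocal best hits, and consolidate the pairwise
profiles into annotated homology groups across all genomes.

The package is aimed at phage researchers who have several newly sequenced,
related phage genomes and per-genome gene predictions (from any combination
of ab initio callers, GenBank records, web services, or hand curation) and
want a reproducible, scriptable answer to three questions:

1. **Where do my gene callers agree?** For each genome the *Compare Gene
   Calls* step tabulates every distinct call `(contig, start, stop, strand)`
   across callers and derives three merged call sets:
   the **superset** (nonredundant union), the **consensus** (calls made by
   ≥ 2 callers), and the **common core** (calls made by *all* callers), with
   `common ⊆ consensus ⊆ superset`. Calls that share a stop codon but
   disagree on the start — the classic alternate-initiation signature — are
   cross-flagged `alt_start` rather than merged.
2. **Which genes correspond between two genomes?** For each ordered genome
   pair (A, B), every A-gene is classified against B from filtered pairwise
   local alignments (Smith–Waterman, affine gaps, blastn/blastp-like
   scoring; or hits supplied as standard BLAST `-outfmt 6` tables):
   **mutual** if gene *a* and its best hit *b* are each other's best hit
   (the standard reciprocal-best-hit proxy for orthology), **singular** if
   the best hit is one-directional, **loner** if nothing survives the
   identity/coverage cutoffs. Within-genome self-comparison yields
   **paralog** pairs.
3. **Which genes correspond across *all* genomes?** With respect to the
   reference genome (the first one configured), each reference gene *r*
   seeds a homology group containing its mutual partners in every other
   genome, its reference-genome paralogs, and each paralog's mutual
   partners. User-supplied functional annotations are carried through onto
   every group member.

A workflow driver runs the four stages (gene calling → annotation → profile
comparison → genomics) from a single flat configuration file, with optional
stop points, restart checkpoints whose consistency is fingerprint-checked,
and deterministic parallelism: result trees are byte-identical for any
worker count and for interrupted-then-resumed runs.

A synthetic-data module generates families of related phage genomes
(common ancestor, per-base divergence, planted duplications/deletions) with
known ortholog/paralog maps, plus simulated noisy gene callers (missed
calls, codon-wise start shifts, intergenic spurious calls), so the entire
pipeline can be exercised and validated without any external data.

## Worked example

```bash
phagecompare fixtures demo --genomes 3 --genes 8 --seed 7
phagecompare run demo/run.config
```

The first command plants three related genomes (5% diverged from a common
ancestor, one gene duplicated in the reference) and simulates three noisy
callers per genome; the second runs the full pipeline:

```
fixture bundle written to demo (config: demo/run.config)
INFO phagecompare.driver: running stage genecalling
INFO phagecompare.driver: running stage annotation
INFO phagecompare.driver: running stage cgp
INFO phagecompare.driver: running stage genomics
completed stages: genecalling, annotation, cgp, genomics; outputs in demo/results
```

`demo/results/genome_1/CGC_results.txt` shows the caller comparison; note
the flagged alternate-start pair in the first gene (callerC shifted the
start by one codon, stop 65 on the minus strand is shared):

```
contig    left  right  strand  callerA  callerB  callerC  n_support  flags
contig_1  65    502    -       absent   absent   present  1          alt_start
contig_1  65    508    -       present  present  absent   2          alt_start
contig_1  553   975    -       present  present  absent   2          -
contig_1  1019  1426   +       present  absent   present  2          -
```

`demo/results/GENOMICS_RESULTS/homology_groups_gene.txt` holds one row per
reference gene. Group 4 shows paralog expansion at work — the duplicated
reference gene `genome_1_0004d` joins its twin's group, and both groups list
the same correspondents:

```
group_id      reference_gene  ...  genome_2       genome_3       paralogs
hg_gene_0001  genome_1_0001        genome_2_0001  genome_3_0001  -
hg_gene_0003  genome_1_0003        genome_2_0003  -              -
hg_gene_0004  genome_1_0004        genome_2_0004  genome_3_0004  genome_1_0004d
```

Gene `genome_1_0003` has no genome_3 correspondent because the selected
caller missed that gene there — exactly the kind of asymmetry the report is
designed to surface. Annotations (here, the demo's per-gene tables) appear
in the final column; members without an entry are marked `unannotated`.

## Library use

Every pipeline stage is an ordinary function:

```python
from phagecompare import (
    make_related_genomes, extract_gene_sequences,
    merge_call_sets, all_binary_comparisons, build_homology_groups,
    NUCLEOTIDE_SCHEME,
)

truth = make_related_genomes(n_genomes=3, n_genes=20, divergence=0.05, seed=1)
seqs = {
    g.genome_id: extract_gene_sequences(g, truth.true_calls[g.genome_id])
    for g in truth.genomes
}
reports = all_binary_comparisons(
    truth.genome_ids, truth.true_calls, seqs,
    NUCLEOTIDE_SCHEME, min_identity=60, min_coverage=75,
)
```

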