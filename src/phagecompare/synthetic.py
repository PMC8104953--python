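"""Synthetic phage genomes with known gene truth, for testing the pipeline.

The generator plants a single-contig ancestor of non-overlapping
protein-coding genes (ATG + sense codons + stop, either strand), then derives
related genomes by per-base point substitution inside genes and spacers,
whole-gene duplication, and whole-gene deletion — recording the true
coordinates, the ortholog map back to ancestral genes, and the planted
paralog pairs.  Noisy gene-caller outputs are simulated on top of the truth:
calls are missed, starts are shifted inward by whole codons (preserving
frame and stop, i.e. producing the alternate-start signature), and spurious
calls are planted in intergenic space only, so truth evaluation stays
unambiguous.

Everything is deterministic for a given seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genecalls import GeneCall, GeneCallSet, GenomeRecord, write_fasta, write_gff_calls

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOPS
]

TRUTH_CALLER = "truth"


@dataclass
class CallerNoiseModel:
    """Error model of a simulated gene caller."""

    miss_rate: float = 0.0
    start_shift_rate: float = 0.0
    start_shift_codons: tuple[int, int] = (1, 5)
    false_call_rate: float = 0.0  # expected spurious calls per genome

    def __post_init__(self):
        for name in ("miss_rate", "start_shift_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} {p} not a probability")
        if self.false_call_rate < 0:
            raise ValueError("false_call_rate must be >= 0")


@dataclass
class CallerNoiseRecord:
    """What one simulated caller actually did, keyed to the truth."""

    caller_id: str
    missed: list[str] = field(default_factory=list)
    #: gene_id -> (true call key, emitted shifted key)
    shifted: dict[str, tuple[tuple, tuple]] = field(default_factory=dict)
    false_keys: list[tuple] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Planted genomes with their complete ground truth."""

    genomes: list[GenomeRecord]
    true_calls: dict[str, GeneCallSet]
    #: (genome_id, gene_id) -> ancestral gene id
    ortholog_map: dict[tuple[str, str], str]
    #: genome_id -> list of (gene_a, gene_b) planted duplicate pairs
    paralog_map: dict[str, list[tuple[str, str]]]
    seed: int

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(SENSE_CODONS, size=n_codons))
    stop = STOPS[rng.integers(0, len(STOPS))]
    return "ATG" + body + stop


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _assemble(
    genome_id: str,
    caller_id: str,
    parts: list[tuple[str, str, str, str]],  # (spacer, oriented gene nt, strand, id)
    contig_id: str = "contig_1",
    tail: str = "",
) -> tuple[GenomeRecord, GeneCallSet]:
    """Lay genes on one contig, spacer before each, returning genome + truth."""
    chunks: list[str] = []
    pos = 0
    calls: list[GeneCall] = []
    for spacer, gene_nt, strand, gene_id in parts:
        chunks.append(spacer)
        pos += len(spacer)
        left = pos + 1
        placed = gene_nt if strand == "+" else _revcomp(gene_nt)
        chunks.append(placed)
        pos += len(gene_nt)
        calls.append(
            GeneCall(genome_id, contig_id, left, pos, strand, caller_id, gene_id)
        )
    chunks.append(tail)
    genome = GenomeRecord(genome_id, {contig_id: "".join(chunks)})
    return genome, GeneCallSet.from_calls(genome_id, caller_id, calls)


def generate_ancestor(
    n_genes: int,
    gene_length_range: tuple[int, int] = (150, 450),
    intergenic_range: tuple[int, int] = (30, 90),
    seed: int = 0,
) -> tuple[GenomeRecord, GeneCallSet]:
    """A single-contig ancestor genome of non-overlapping planted genes.

    Gene lengths (multiples of 3, ATG and stop included) and intergenic gaps
    are drawn uniformly from the given ranges; strands are random.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo < 9 or hi < lo:
        raise ValueError(f"infeasible gene length range {gene_length_range}")
    ig_lo, ig_hi = intergenic_range
    if ig_lo < 1 or ig_hi < ig_lo:
        raise ValueError(f"infeasible intergenic range {intergenic_range}")
    rng = np.random.default_rng(seed)
    parts = []
    for i in range(1, n_genes + 1):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1)) - 2
        spacer = _random_seq(rng, int(rng.integers(ig_lo, ig_hi + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append((spacer, _random_gene(rng, n_codons), strand, f"anc_{i:04d}"))
    tail = _random_seq(rng, int(rng.integers(ig_lo, ig_hi + 1)))
    return _assemble("ancestor", TRUTH_CALLER, parts, tail=tail)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Uniform point substitutions: each base flips to one of the other three."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        base = arr[i].decode()
        others = [b for b in BASES if b != base]
        arr[i] = others[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def _mutate_gene(rng: np.random.Generator, gene: str, rate: float) -> str:
    """Mutate a gene's internal codons, preserving start/stop and avoiding
    the creation of internal stop codons (resampled to a sense codon)."""
    if len(gene) < 9 or rate <= 0:
        return gene
    inner = _mutate(rng, gene[3:-3], rate)
    codons = [inner[i : i + 3] for i in range(0, len(inner), 3)]
    for i, codon in enumerate(codons):
        if codon in STOPS:
            codons[i] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
    return gene[:3] + "".join(codons) + gene[-3:]


def evolve_genome(
    ancestor: GenomeRecord,
    ancestor_calls: GeneCallSet,
    genome_id: str,
    divergence: float = 0.05,
    duplications: int = 0,
    deletions: int = 0,
    seed: int = 0,
) -> tuple[GenomeRecord, GeneCallSet, dict[str, str], list[tuple[str, str]]]:
    """Derive one related genome from the ancestor.

    Returns (genome, true calls, ortholog map new-id -> ancestral id,
    planted paralog pairs).  Substitutions hit internal gene positions and
    intergenic spacers at the same per-base rate; duplicated genes are exact
    copies of the already-diverged gene appended at the contig end (id
    suffix ``d``); deleted genes disappear from calls and ortholog map.
    """
    if not (0.0 <= divergence <= 0.5):
        raise ValueError(f"divergence {divergence} out of [0, 0.5]")
    calls = list(ancestor_calls)
    if duplications + deletions > len(calls):
        raise ValueError("more duplications+deletions than genes")
    rng = np.random.default_rng(seed)
    contig = next(iter(ancestor.sequences.values()))

    doomed = set(
        rng.choice(len(calls), size=deletions, replace=False).tolist()
    ) if deletions else set()
    survivors = [i for i in range(len(calls)) if i not in doomed]
    dup_idx = (
        sorted(rng.choice(survivors, size=duplications, replace=False).tolist())
        if duplications
        else []
    )

    parts = []
    ortholog_map: dict[str, str] = {}
    new_ids: dict[int, str] = {}
    mutated: dict[int, str] = {}
    prev_end = 0
    for i, call in enumerate(calls):
        spacer = contig[prev_end : call.left - 1]
        prev_end = call.right
        if i in doomed:
            continue  # gene lost; its spacer merges into the next gap
        gene_nt = contig[call.left - 1 : call.right]
        if call.strand == "-":
            gene_nt = _revcomp(gene_nt)
        gene_nt = _mutate_gene(rng, gene_nt, divergence)
        new_id = f"{genome_id}_{i + 1:04d}"
        new_ids[i], mutated[i] = new_id, gene_nt
        ortholog_map[new_id] = call.gene_id
        parts.append((_mutate(rng, spacer, divergence), gene_nt, call.strand, new_id))

    paralog_pairs: list[tuple[str, str]] = []
    for i in dup_idx:
        dup_id = f"{new_ids[i]}d"
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append((_random_seq(rng, 50), mutated[i], strand, dup_id))
        ortholog_map[dup_id] = calls[i].gene_id
        paralog_pairs.append((new_ids[i], dup_id))

    tail = _mutate(rng, contig[prev_end:], divergence)
    genome, true_calls = _assemble(genome_id, TRUTH_CALLER, parts, tail=tail)
    return genome, true_calls, ortholog_map, paralog_pairs


def make_related_genomes(
    n_genomes: int = 3,
    n_genes: int = 20,
    divergence: float = 0.05,
    duplications_in_reference: int = 1,
    deletions: int = 0,
    seed: int = 0,
) -> SyntheticTruth:
    """A family of related genomes descended from one common ancestor.

    Each genome diverges independently from the ancestor at the given
    per-base substitution rate; the reference genome (the first) additionally
    carries the planted gene duplications.
    """
    rng = np.random.default_rng(seed)
    anc_genome, anc_calls = generate_ancestor(
        n_genes, seed=int(rng.integers(2**31))
    )
    genomes, true_calls = [], {}
    ortholog_map: dict[tuple[str, str], str] = {}
    paralog_map: dict[str, list[tuple[str, str]]] = {}
    for k in range(1, n_genomes + 1):
        gid = f"genome_{k}"
        genome, calls, omap, pairs = evolve_genome(
            anc_genome,
            anc_calls,
            gid,
            divergence=divergence,
            duplications=duplications_in_reference if k == 1 else 0,
            deletions=deletions if k > 1 else 0,
            seed=int(rng.integers(2**31)),
        )
        genomes.append(genome)
        true_calls[gid] = calls
        for gene_id, anc_id in omap.items():
            ortholog_map[(gid, gene_id)] = anc_id
        paralog_map[gid] = pairs
    return SyntheticTruth(genomes, true_calls, ortholog_map, paralog_map, seed)


def simulate_caller(
    true_calls: GeneCallSet,
    genome: GenomeRecord,
    noise: CallerNoiseModel,
    caller_id: str,
    seed: int = 0,
) -> tuple[GeneCallSet, CallerNoiseRecord]:
    """Simulate one noisy gene caller on top of the planted truth.

    Each true call is independently missed with ``miss_rate``; surviving
    calls have their start shifted inward by a random whole-codon count with
    ``start_shift_rate`` (never past the stop, so the emitted call shares
    contig, strand and stop with the truth); Poisson(``false_call_rate``)
    spurious calls are planted in intergenic space.
    """
    rng = np.random.default_rng(seed)
    record = CallerNoiseRecord(caller_id)
    out: list[GeneCall] = []
    for call in true_calls:
        if rng.random() < noise.miss_rate:
            record.missed.append(call.gene_id)
            continue
        left, right = call.left, call.right
        if rng.random() < noise.start_shift_rate:
            lo, hi = noise.start_shift_codons
            shift = 3 * int(rng.integers(lo, hi + 1))
            if call.strand == "+" and left + shift <= right - 5:
                left += shift
            elif call.strand == "-" and right - shift >= left + 5:
                right -= shift
            if (left, right) != (call.left, call.right):
                record.shifted[call.gene_id] = (
                    call.key, (call.contig_id, left, right, call.strand)
                )
        out.append(
            GeneCall(call.genome_id, call.contig_id, left, right, call.strand,
                     caller_id, call.gene_id)
        )

    n_false = int(rng.poisson(noise.false_call_rate))
    occupied: dict[str, list[tuple[int, int]]] = {}
    for call in true_calls:
        occupied.setdefault(call.contig_id, []).append((call.left, call.right))
    placed = 0
    for contig_id, contig_seq in genome.sequences.items():
        if placed >= n_false:
            break
        gaps = _intergenic_gaps(occupied.get(contig_id, []), len(contig_seq))
        for _ in range(n_false - placed):
            roomy = [g for g in gaps if g[1] - g[0] + 1 >= 60]
            if not roomy:
                break
            gap = roomy[int(rng.integers(0, len(roomy)))]
            gap_len = gap[1] - gap[0] + 1
            length = 3 * int(rng.integers(20, gap_len // 3 + 1))
            left = gap[0] + int(rng.integers(0, gap_len - length + 1))
            right = left + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            placed += 1
            gene_id = f"{caller_id}.fp{placed}"
            out.append(
                GeneCall(true_calls.genome_id, contig_id, left, right, strand,
                         caller_id, gene_id)
            )
            record.false_keys.append((contig_id, left, right, strand))
            # split the gap so later false calls cannot overlap this one
            gaps.remove(gap)
            if left - gap[0] >= 1:
                gaps.append((gap[0], left - 1))
            if gap[1] - right >= 1:
                gaps.append((right + 1, gap[1]))
            gaps.sort()
    return GeneCallSet.from_calls(true_calls.genome_id, caller_id, out), record


def _intergenic_gaps(
    occupied: list[tuple[int, int]], contig_len: int
) -> list[tuple[int, int]]:
    gaps = []
    pos = 1
    for left, right in sorted(occupied):
        if left > pos:
            gaps.append((pos, left - 1))
        pos = max(pos, right + 1)
    if pos <= contig_len:
        gaps.append((pos, contig_len))
    return gaps


def write_fixture_bundle(truth: SyntheticTruth, outdir) -> None:
    """Write FASTA + truth GFF3 per genome and a JSON truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in truth.genomes:
        write_fasta(genome.sequences, outdir / f"{genome.genome_id}.fasta")
        write_gff_calls(
            truth.true_calls[genome.genome_id],
            outdir / f"{genome.genome_id}.truth.gff",
        )
    payload = {
        "seed": truth.seed,
        "genomes": truth.genome_ids,
        "true_calls": {
            gid: [
                {"gene_id": c.gene_id, "contig": c.contig_id, "left": c.left,
                 "right": c.right, "strand": c.strand}
                for c in calls
            ]
            for gid, calls in truth.true_calls.items()
        },
        "ortholog_map": {
            f"{gid}:{gene}": anc for (gid, gene), anc in sorted(truth.ortholog_map.items())
        },
        "paralog_map": {
            gid: [list(p) for p in pairs] for gid, pairs in truth.paralog_map.items()
        },
    }
    with (outdir / "truth.json").open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
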