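"""Gene-call I/O: GFF3 and tabular call sets, sequence extraction, translation.

All coordinates are 1-based and inclusive on both ends (the GFF convention).
Reverse-strand calls are normalized so that ``left <= right`` always holds;
the strand column alone records orientation. This single convention removes
the silent dialect differences among gene callers, whose native outputs
variously print start/stop in transcription order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoordinateError, ParseError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Genetic code used for all CDS translation (bacterial/plant plastid code,
#: the standard for phage and bacterial protein-coding genes).
TRANSLATION_TABLE = 11

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


@dataclass(frozen=True)
class GeneCall:
    """One predicted protein-coding gene.

    ``left``/``right`` are 1-based inclusive positions on the forward strand
    of ``contig_id``; a ``-`` strand gene is transcribed right-to-left but
    still stored with ``left <= right``.
    """

    genome_id: str
    contig_id: str
    left: int
    right: int
    strand: str
    caller_id: str
    gene_id: str
    score: float | None = None

    def __post_init__(self):
        if self.left < 1 or self.left > self.right:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.left}..{self.right}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Identity of the call for set algebra: (contig, left, right, strand)."""
        return (self.contig_id, self.left, self.right, self.strand)

    @property
    def length(self) -> int:
        return self.right - self.left + 1


@dataclass
class GeneCallSet:
    """All calls made by one caller on one genome, sorted and deduplicated."""

    genome_id: str
    caller_id: str
    calls: list[GeneCall] = field(default_factory=list)

    @classmethod
    def from_calls(
        cls, genome_id: str, caller_id: str, calls: Iterable[GeneCall]
    ) -> "GeneCallSet":
        """Normalize: sort by position, collapse duplicate (contig,left,right,strand).

        The first call for a duplicated key wins; later duplicates are logged
        and dropped, giving the set semantics the comparison algebra requires.
        """
        ordered = sorted(calls, key=lambda c: (c.contig_id, c.left, c.right, c.strand))
        seen: dict[tuple, GeneCall] = {}
        ids: set[str] = set()
        for call in ordered:
            if call.key in seen:
                logger.info(
                    "duplicate call %s at %s in %s/%s dropped (kept %s)",
                    call.gene_id, call.key, genome_id, caller_id,
                    seen[call.key].gene_id,
                )
                continue
            if call.gene_id in ids:
                raise ValueError(
                    f"gene_id {call.gene_id!r} not unique within {genome_id}/{caller_id}"
                )
            seen[call.key] = call
            ids.add(call.gene_id)
        return cls(genome_id, caller_id, list(seen.values()))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def keys(self) -> set[tuple[str, int, int, str]]:
        return {c.key for c in self.calls}

    def by_id(self) -> dict[str, GeneCall]:
        return {c.gene_id: c for c in self.calls}


@dataclass
class GenomeRecord:
    """A genome as a mapping of contig id to nucleotide string."""

    genome_id: str
    sequences: dict[str, str]

    def __post_init__(self):
        for cid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"contig {cid} of {self.genome_id} is empty")


def read_gff_calls(path, genome_id: str, caller_id: str) -> GeneCallSet:
    """Read gene/CDS features from a GFF3 file into a normalized GeneCallSet.

    Only ``gene`` and ``CDS`` feature lines contribute calls; comments,
    directives and other feature types are ignored.  Feature lines without an
    ``ID`` attribute get a sequential auto-generated id.
    """
    path = Path(path)
    calls: list[GeneCall] = []
    auto = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, found {len(fields)}",
                    path, lineno,
                )
            contig, _source, ftype, start_s, end_s, score_s, strand, _phase, attrs = fields
            if ftype.lower() not in ("gene", "cds"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"malformed coordinates {start_s!r}..{end_s!r}", path, lineno
                ) from None
            if start > end:
                raise ParseError(
                    f"start {start} > end {end} (GFF3 requires start <= end)",
                    path, lineno,
                )
            if strand not in STRANDS:
                raise ParseError(f"unknown strand symbol {strand!r}", path, lineno)
            m = _GFF_ID_RE.search(attrs)
            if m:
                gene_id = m.group(1).strip()
            else:
                auto += 1
                gene_id = f"{caller_id}_{auto:05d}"
            score = None if score_s in (".", "") else float(score_s)
            calls.append(
                GeneCall(genome_id, contig, start, end, strand, caller_id, gene_id, score)
            )
    return GeneCallSet.from_calls(genome_id, caller_id, calls)


def read_tabular_calls(path, genome_id: str, caller_id: str) -> GeneCallSet:
    """Read the 5-column custom-call dialect: contig, left, right, strand, id.

    A line whose right coordinate is smaller than its left is taken to be a
    reverse-strand call printed in transcription order; it is normalized by
    swapping the coordinates and forcing strand ``-``.  An optional header
    line (non-integer coordinate columns) is skipped.
    """
    path = Path(path)
    calls: list[GeneCall] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"expected 5 tab-separated columns, found {len(fields)}",
                    path, lineno,
                )
            contig, left_s, right_s, strand, gene_id = (f.strip() for f in fields)
            try:
                left, right = int(left_s), int(right_s)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ParseError(
                    f"malformed coordinates {left_s!r}/{right_s!r}", path, lineno
                ) from None
            if right < left:
                left, right = right, left
                strand = "-"
            if strand not in STRANDS:
                raise ParseError(f"unknown strand symbol {strand!r}", path, lineno)
            calls.append(
                GeneCall(genome_id, contig, left, right, strand, caller_id, gene_id)
            )
    return GeneCallSet.from_calls(genome_id, caller_id, calls)


def write_gff_calls(calls: GeneCallSet, path) -> None:
    """Write a GeneCallSet as GFF3, one CDS feature per call.

    The output round-trips through :func:`read_gff_calls` to an identical
    normalized set (given the same genome and caller labels).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls:
            score = "." if call.score is None else f"{call.score:g}"
            fh.write(
                f"{call.contig_id}\tphagecompare\tCDS\t{call.left}\t{call.right}\t"
                f"{score}\t{call.strand}\t0\tID={call.gene_id}\n"
            )


def read_genome_fasta(path, genome_id: str) -> GenomeRecord:
    """Read a (multi-)FASTA nucleotide file into a GenomeRecord."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ParseError(f"duplicate contig id {rec.id!r}", path)
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ParseError("no sequences found", path)
    return GenomeRecord(genome_id, sequences)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write an id->sequence mapping as FASTA, 70 columns, insertion order."""
    path = Path(path)
    with path.open("w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def extract_gene_sequences(
    genome: GenomeRecord, calls: GeneCallSet
) -> dict[str, str]:
    """Extract each call's nucleotide sequence, reverse-complemented for '-' genes."""
    out: dict[str, str] = {}
    for call in calls:
        contig = genome.sequences.get(call.contig_id)
        if contig is None:
            raise CoordinateError(
                f"gene {call.gene_id}: contig {call.contig_id!r} not in genome "
                f"{genome.genome_id}"
            )
        if call.right > len(contig):
            raise CoordinateError(
                f"gene {call.gene_id}: right end {call.right} exceeds contig "
                f"{call.contig_id} length {len(contig)}"
            )
        nt = contig[call.left - 1 : call.right]
        if call.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        out[call.gene_id] = nt
    return out


def translate_gene(nt: str, gene_id: str = "?") -> str:
    """Translate a CDS nucleotide string with the bacterial/phage genetic code.

    A single trailing stop is stripped; internal stops are retained as ``*``
    and logged (they usually indicate a bad call, not a bad genome); a
    dangling final 1-2 bases are dropped with a warning.
    """
    if len(nt) < 3:
        raise ValueError(f"gene {gene_id}: sequence shorter than one codon")
    usable = len(nt) - len(nt) % 3
    if usable != len(nt):
        logger.warning(
            "gene %s: length %d not a multiple of 3; dropping %d trailing base(s)",
            gene_id, len(nt), len(nt) - usable,
        )
    aa = str(Seq(nt[:usable]).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning("gene %s: internal stop codon(s) in translation", gene_id)
    return aa


def relabel(calls: GeneCallSet, caller_id: str, id_prefix: str) -> GeneCallSet:
    """Return a copy of a call set under a new caller label with sequential ids."""
    new = [
        replace(c, caller_id=caller_id, gene_id=f"{id_prefix}_{i:04d}")
        for i, c in enumerate(calls, start=1)
    ]
    return GeneCallSet(calls.genome_id, caller_id, new)
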