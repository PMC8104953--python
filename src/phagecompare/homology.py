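"""Genomics subsystem: consolidate binary comparisons into homology groups.

Groups are built with respect to the *reference* genome — the first genome
configured.  Each reference gene seeds exactly one group holding:

* its mutual best-hit partners in every other genome;
* its within-reference paralogs;
* each paralog's mutual partners in every other genome.

Only mutual (reciprocal) best hits admit members: mutuality is the only
symmetric correspondence notion available, so admitting singular hits would
make group content depend on comparison orientation.  Paralog expansion is
one level deep — paralogs of the reference gene and their partners — never a
transitive closure, which could chain unrelated families.  Paralogy inside
non-reference genomes does not expand groups.

Functional annotations supplied per genome are carried through onto every
group member; members without an entry are marked ``unannotated``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cgp import BinaryComparisonReport, ParalogPair
from .errors import ConsistencyError, ParseError
from .genecalls import GeneCallSet

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


@dataclass
class AnnotationTable:
    """User-supplied functional annotations for one genome's genes."""

    genome_id: str
    entries: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class HomologyGroup:
    """A reference gene with its cross-genome correspondents and paralogs."""

    reference_gene: str
    reference_genome: str
    contig_id: str
    left: int
    right: int
    strand: str
    level: str  # "gene" | "protein"
    correspondents: dict[str, list[str]] = field(default_factory=dict)
    paralogs: list[str] = field(default_factory=list)
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def members(self) -> list[tuple[str, str]]:
        """All (genome_id, gene_id) members, reference first."""
        out = [(self.reference_genome, self.reference_gene)]
        out += [(self.reference_genome, p) for p in self.paralogs]
        for gid in sorted(self.correspondents):
            out += [(gid, g) for g in self.correspondents[gid]]
        return out


def read_annotation_table(
    path, genome_id: str, valid_ids: set[str] | None = None
) -> AnnotationTable:
    """Read a 2-column (gene_id, annotation) tab-delimited table.

    Repeated gene ids accumulate multiple annotation strings.  Entries naming
    a gene outside ``valid_ids`` (when given) are skipped with a warning.
    """
    path = Path(path)
    table = AnnotationTable(genome_id)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"expected 2 columns, found {len(fields)}", path, lineno
                )
            gene_id, text = fields[0].strip(), fields[1].strip()
            if valid_ids is not None and gene_id not in valid_ids:
                logger.warning(
                    "annotation for unknown gene %r (%s:%d) skipped",
                    gene_id, path, lineno,
                )
                continue
            table.entries.setdefault(gene_id, []).append(text)
    return table


def build_homology_groups(
    reference: str,
    genome_ids: list[str],
    reference_calls: GeneCallSet,
    reports: list[BinaryComparisonReport],
    reference_paralogs: list[ParalogPair],
    level: str = "gene",
) -> list[HomologyGroup]:
    """One group per reference gene, ordered by reference genome position."""
    if genome_ids[0] != reference:
        raise ValueError("reference must be the first configured genome")
    others = [g for g in genome_ids if g != reference]
    ref_reports = {
        r.subject_genome: r
        for r in reports
        if r.query_genome == reference and r.level == level
    }
    missing = [g for g in others if g not in ref_reports]
    if missing:
        raise ConsistencyError(
            "missing binary report(s) for pair(s): "
            + ", ".join(f"{reference} vs {g}" for g in missing)
        )

    # mutual partners of each reference gene, per subject genome
    mutual: dict[str, dict[str, str]] = {}
    for gid, rep in ref_reports.items():
        for rec in rep.records:
            if rec.status == "mutual":
                mutual.setdefault(rec.query_gene, {})[gid] = rec.partner_gene

    paralogs_of: dict[str, list[str]] = {}
    for pair in reference_paralogs:
        paralogs_of.setdefault(pair.gene_a, []).append(pair.gene_b)
        paralogs_of.setdefault(pair.gene_b, []).append(pair.gene_a)

    groups = []
    for call in reference_calls:  # position order
        my_paralogs = sorted(paralogs_of.get(call.gene_id, []))
        correspondents: dict[str, list[str]] = {}
        for gid in others:
            members: set[str] = set()
            own = mutual.get(call.gene_id, {}).get(gid)
            if own is not None:
                members.add(own)
            for p in my_paralogs:
                via = mutual.get(p, {}).get(gid)
                if via is not None:
                    members.add(via)
            if members:
                correspondents[gid] = sorted(members)
        groups.append(
            HomologyGroup(
                reference_gene=call.gene_id,
                reference_genome=reference,
                contig_id=call.contig_id,
                left=call.left,
                right=call.right,
                strand=call.strand,
                level=level,
                correspondents=correspondents,
                paralogs=my_paralogs,
            )
        )
    return groups


def attach_annotations(
    groups: list[HomologyGroup], tables: list[AnnotationTable]
) -> list[HomologyGroup]:
    """Copy per-gene annotations onto every group member (in place, returned).

    Members with no table entry are annotated ``unannotated``, so every
    member always carries at least one annotation string.
    """
    by_genome = {t.genome_id: t.entries for t in tables}
    for group in groups:
        group.annotations = {}
        for genome_id, gene_id in group.members():
            texts = by_genome.get(genome_id, {}).get(gene_id)
            group.annotations[gene_id] = list(texts) if texts else [UNANNOTATED]
    return groups


def write_genomics_results(
    groups: list[HomologyGroup], genome_ids: list[str], path
) -> None:
    """Write one level's homology groups as tab-delimited text (deterministic).

    Columns: group id, reference gene and coordinates, one member-list column
    per non-reference genome (configured order), paralogs, annotations.
    """
    path = Path(path)
    others = genome_ids[1:]
    with path.open("w") as fh:
        cols = ["group_id", "reference_gene", "contig", "left", "right",
                "strand", *others, "paralogs", "annotations"]
        fh.write("\t".join(cols) + "\n")
        for i, g in enumerate(groups, start=1):
            member_cols = [
                ",".join(g.correspondents.get(gid, [])) or "-" for gid in others
            ]
            paralogs = ",".join(g.paralogs) or "-"
            annotations = (
                ";".join(
                    f"{gene}:{'|'.join(texts)}"
                    for gene, texts in sorted(g.annotations.items())
                )
                or "-"
            )
            fh.write(
                "\t".join(
                    [f"hg_{g.level}_{i:04d}", g.reference_gene, g.contig_id,
                     str(g.left), str(g.right), g.strand, *member_cols,
                     paralogs, annotations]
                )
                + "\n"
            )
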