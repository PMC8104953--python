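"""Compare Gene Profiles: reciprocal-best-hit classification between genomes.

For every ordered genome pair (A, B) each A-gene is classified against B:

* **mutual** — its best B-hit points back at it (reciprocal best hit, the
  standard operational proxy for orthology);
* **singular** — it has a best hit in B, but the reciprocal best points
  elsewhere;
* **loner** — no hit above the cutoffs survives.

Best hits are chosen by a fixed total ordering (score, then e-value when
present, then alignment length, then subject id) so results are reproducible.
Within-genome self-comparison serves only paralog detection and is never
emitted as a genome-to-genome report; a paralog is any non-self gene pair
with a surviving filtered hit in either direction — a deliberately
recall-favouring definition, since paralogs act as an expansion set for
homology groups downstream.
"""

from __future__ import annotations

import itertools
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .align import Hit, ScoringScheme, all_vs_all, filter_hits, hit_sort_key
from .errors import ConsistencyError
from .genecalls import GeneCall, GeneCallSet

logger = logging.getLogger(__name__)

STATUSES = ("mutual", "singular", "loner")


@dataclass
class BestHitRecord:
    """Classification of one query gene against one subject genome."""

    query_gene: str
    query_genome: str
    subject_genome: str
    status: str
    partner_gene: str | None
    hit: Hit | None
    # query gene coordinates, carried for position-ordered reporting
    contig_id: str = ""
    left: int = 0
    right: int = 0
    strand: str = "+"


@dataclass
class BinaryComparisonReport:
    """All best-hit records for one ordered genome pair, query-position ordered."""

    query_genome: str
    subject_genome: str
    records: list[BestHitRecord]
    min_identity: float
    min_coverage: float
    level: str  # "gene" | "protein"


@dataclass(frozen=True)
class ParalogPair:
    """An unordered within-genome homolog pair (stored with gene_a < gene_b)."""

    genome_id: str
    gene_a: str
    gene_b: str
    hit: Hit


def best_hit(hits: list[Hit]) -> tuple[str, Hit] | None:
    """Best subject for one query under the fixed tie-break chain, or None."""
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    top = min(hits, key=hit_sort_key)
    return top.subject_id, top


def _by_query(hits: list[Hit]) -> dict[str, list[Hit]]:
    out: dict[str, list[Hit]] = {}
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


def _check_known(hits: list[Hit], queries: set[str], subjects: set[str]) -> None:
    for h in hits:
        if h.query_id not in queries:
            raise ConsistencyError(f"hit query {h.query_id!r} not in call set")
        if h.subject_id not in subjects:
            raise ConsistencyError(f"hit subject {h.subject_id!r} not in call set")


def _classify(
    calls: GeneCallSet,
    other_genome: str,
    hits_fwd: dict[str, list[Hit]],
    hits_rev: dict[str, list[Hit]],
) -> list[BestHitRecord]:
    records = []
    for call in calls:  # call sets are position-sorted
        best = best_hit(hits_fwd.get(call.gene_id, []))
        if best is None:
            status, partner, hit = "loner", None, None
        else:
            partner, hit = best
            reciprocal = best_hit(hits_rev.get(partner, []))
            status = (
                "mutual"
                if reciprocal is not None and reciprocal[0] == call.gene_id
                else "singular"
            )
        records.append(
            BestHitRecord(
                query_gene=call.gene_id,
                query_genome=calls.genome_id,
                subject_genome=other_genome,
                status=status,
                partner_gene=partner,
                hit=hit,
                contig_id=call.contig_id,
                left=call.left,
                right=call.right,
                strand=call.strand,
            )
        )
    return records


def compare_binary(
    calls_a: GeneCallSet,
    calls_b: GeneCallSet,
    hits_ab: list[Hit],
    hits_ba: list[Hit],
    min_identity: float,
    min_coverage: float,
    level: str = "gene",
) -> tuple[BinaryComparisonReport, BinaryComparisonReport]:
    """Classify both directions of one genome pair from pre-filtered hits."""
    a_ids, b_ids = set(calls_a.by_id()), set(calls_b.by_id())
    _check_known(hits_ab, a_ids, b_ids)
    _check_known(hits_ba, b_ids, a_ids)
    fwd, rev = _by_query(hits_ab), _by_query(hits_ba)
    rep_ab = BinaryComparisonReport(
        calls_a.genome_id, calls_b.genome_id,
        _classify(calls_a, calls_b.genome_id, fwd, rev),
        min_identity, min_coverage, level,
    )
    rep_ba = BinaryComparisonReport(
        calls_b.genome_id, calls_a.genome_id,
        _classify(calls_b, calls_a.genome_id, rev, fwd),
        min_identity, min_coverage, level,
    )
    return rep_ab, rep_ba


def _pair_hits(args) -> tuple[str, str, list[Hit], list[Hit]]:
    gid_a, gid_b, seqs_a, seqs_b, scheme = args
    return (
        gid_a,
        gid_b,
        all_vs_all(seqs_a, seqs_b, scheme),
        all_vs_all(seqs_b, seqs_a, scheme),
    )


def compute_pair_hits(
    genome_ids: list[str],
    sequences: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme,
    workers: int = 1,
) -> dict[tuple[str, str], list[Hit]]:
    """Raw (unfiltered) hit tables for every ordered genome pair.

    The unordered pairs are aligned independently — in parallel when
    ``workers > 1`` — and merged back in configured genome order, so the
    result is identical for any worker count.
    """
    pairs = list(itertools.combinations(genome_ids, 2))
    jobs = [
        (a, b, dict(sequences[a]), dict(sequences[b]), scheme) for a, b in pairs
    ]
    if workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_pair_hits, jobs))
    else:
        results = [_pair_hits(j) for j in jobs]
    tables: dict[tuple[str, str], list[Hit]] = {}
    for gid_a, gid_b, hits_ab, hits_ba in results:
        tables[(gid_a, gid_b)] = hits_ab
        tables[(gid_b, gid_a)] = hits_ba
    return tables


def all_binary_comparisons(
    genome_ids: list[str],
    call_sets: Mapping[str, GeneCallSet],
    sequences: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme,
    min_identity: float,
    min_coverage: float,
    level: str = "gene",
    workers: int = 1,
) -> list[BinaryComparisonReport]:
    """Directed reports for every genome pair: N genomes give N(N-1) reports.

    With fewer than two genomes the stage is skipped with a logged notice.
    Reports are ordered by configured genome order (query, then subject).
    """
    if len(genome_ids) < 2:
        logger.info(
            "fewer than two genomes supplied; skipping genome comparisons"
        )
        return []
    tables = compute_pair_hits(genome_ids, sequences, scheme, workers=workers)
    reports: list[BinaryComparisonReport] = []
    for a, b in itertools.combinations(genome_ids, 2):
        rep_ab, rep_ba = compare_binary(
            call_sets[a],
            call_sets[b],
            filter_hits(tables[(a, b)], min_identity, min_coverage),
            filter_hits(tables[(b, a)], min_identity, min_coverage),
            min_identity,
            min_coverage,
            level,
        )
        reports.append(rep_ab)
        reports.append(rep_ba)
    order = {g: i for i, g in enumerate(genome_ids)}
    reports.sort(key=lambda r: (order[r.query_genome], order[r.subject_genome]))
    return reports


def find_paralogs(
    calls: GeneCallSet, self_hits: list[Hit]
) -> list[ParalogPair]:
    """Within-genome homolog pairs from filtered self-hits.

    Trivial self-hits (a, a) are discarded; (a, b)/(b, a) collapse to one
    unordered pair, keeping the better-scoring direction's hit.
    """
    ids = set(calls.by_id())
    _check_known(self_hits, ids, ids)
    best: dict[tuple[str, str], Hit] = {}
    for h in self_hits:
        if h.query_id == h.subject_id:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        if key not in best or hit_sort_key(h) < hit_sort_key(best[key]):
            best[key] = h
    return [
        ParalogPair(calls.genome_id, a, b, best[(a, b)])
        for a, b in sorted(best)
    ]


def write_binary_report(report: BinaryComparisonReport, path) -> None:
    """Serialize one directed report as tab-delimited text (deterministic)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# query={report.query_genome} subject={report.subject_genome} "
            f"level={report.level} min_identity={report.min_identity:g} "
            f"min_coverage={report.min_coverage:g}\n"
        )
        cols = ["query_gene", "contig", "left", "right", "strand", "status",
                "partner_gene", "pct_identity", "coverage", "score"]
        fh.write("\t".join(cols) + "\n")
        for rec in report.records:
            if rec.hit is None:
                ident = cov = score = "NA"
                partner = "-"
            else:
                ident = f"{rec.hit.pct_identity:.2f}"
                cov = "NA" if rec.hit.q_coverage is None else f"{rec.hit.q_coverage:.2f}"
                score = f"{rec.hit.score:.1f}"
                partner = rec.partner_gene
            fh.write(
                "\t".join(
                    [rec.query_gene, rec.contig_id, str(rec.left),
                     str(rec.right), rec.strand, rec.status, partner,
                     ident, cov, score]
                )
                + "\n"
            )


def write_paralogs(pairs: list[ParalogPair], path) -> None:
    """Serialize paralog pairs as tab-delimited text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tpct_identity\tcoverage\tscore\n")
        for p in pairs:
            cov = "NA" if p.hit.q_coverage is None else f"{p.hit.q_coverage:.2f}"
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.hit.pct_identity:.2f}\t"
                f"{cov}\t{p.hit.score:.1f}\n"
            )
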