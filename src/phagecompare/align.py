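"""Pairwise hits: a local aligner, BLAST-tabular I/O, and cutoff filtering.

The built-in aligner performs Smith-Waterman optimal local alignment with
affine gap penalties (a gap of length L costs ``gap_open + L * gap_extend``,
the BLAST convention), via Biopython's ``PairwiseAligner``.  Default scoring
mirrors blastn (match +2 / mismatch -3 / open -5 / extend -2) and blastp
(BLOSUM62, open -11 / extend -1).  The internal aligner reports raw alignment
scores only; e-values appear solely on hits read from BLAST tabular files.

Percent identity is matches over aligned columns (gap columns included);
coverage is the aligned span over the *query* length, since downstream
profiling orders and judges hits with respect to the query genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters for one sequence level."""

    mode: str  # "nucleotide" | "protein"
    match: float | None = None
    mismatch: float | None = None
    matrix_name: str | None = None
    gap_open: float = -5.0  # charged once per gap
    gap_extend: float = -2.0  # charged per gapped position

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mode == "nucleotide" and self.match is not None:
            if self.match <= self.mismatch:
                raise ValueError("match score must exceed mismatch score")

    def substitution(self, a: str, b: str) -> float:
        if self.matrix_name is not None:
            return float(_load_matrix(self.matrix_name)[a, b])
        return self.match if a == b else self.mismatch


NUCLEOTIDE_SCHEME = ScoringScheme(
    mode="nucleotide", match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0
)
PROTEIN_SCHEME = ScoringScheme(
    mode="protein", matrix_name="BLOSUM62", gap_open=-11.0, gap_extend=-1.0
)

_MATRICES: dict[str, object] = {}


def _load_matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


@dataclass
class Hit:
    """One pairwise local-alignment match between two genes/proteins."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    score: float
    evalue: float | None = None
    q_coverage: float | None = None
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 0  # 1-based inclusive on the query
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} out of [0,100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.q_coverage is not None and not (0.0 < self.q_coverage <= 100.0):
            raise ValueError(f"q_coverage {self.q_coverage} out of (0,100]")


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scheme.matrix_name is not None:
        aligner.substitution_matrix = _load_matrix(scheme.matrix_name)
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    # PairwiseAligner charges open_gap_score on the first gapped position and
    # extend_gap_score on each subsequent one; translate from the BLAST
    # convention (open charged once, extend on every position).
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: Align.PairwiseAligner | None = None,
) -> Hit | None:
    """Optimal local alignment of query ``a`` against subject ``b``.

    Returns ``None`` when no alignment scores above zero (including when
    either sequence is empty).  Among co-optimal alignments Biopython's
    first enumerated traceback is reported, which is deterministic.
    """
    if not a or not b:
        return None
    if aligner is None:
        aligner = _make_aligner(scheme)
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    blocks_q, blocks_s = aln.aligned
    q_start, q_end = int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]) + 1, int(blocks_s[-1][1])
    gap_opens = (len(blocks_q) - 1) + (len(blocks_s) - 1)
    return Hit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=round(100.0 * counts.identities / columns, 2),
        aln_length=columns,
        score=round(float(score), 1),
        evalue=None,
        q_coverage=round(100.0 * (q_end - q_start + 1) / len(a), 2),
        mismatches=counts.mismatches,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


def all_vs_all(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    scheme: ScoringScheme,
) -> list[Hit]:
    """Best local alignment for every (query, subject) pair with positive score.

    Output is sorted by query id, then descending score, then subject id, so
    the hit table is deterministic and best hits come first per query.
    """
    aligner = _make_aligner(scheme)
    hits: list[Hit] = []
    for qid in sorted(queries):
        for sid in sorted(subjects):
            hit = local_align(
                queries[qid], subjects[sid], scheme, qid, sid, aligner=aligner
            )
            if hit is not None:
                hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, -h.score, h.subject_id))
    return hits


def filter_hits(
    hits: list[Hit], min_identity: float, min_coverage: float
) -> list[Hit]:
    """Keep hits with identity and query coverage at or above the cutoffs.

    The coverage test is skipped (with a warning) for hits whose coverage is
    unknown, e.g. BLAST tabular input without query lengths.
    """
    for name, cutoff in (("identity", min_identity), ("coverage", min_coverage)):
        if not (0.0 <= cutoff <= 100.0):
            raise ConfigError(f"{name} cutoff {cutoff} out of [0, 100]")
    out = []
    warned = False
    for h in hits:
        if h.pct_identity < min_identity:
            continue
        if h.q_coverage is None:
            if not warned and min_coverage > 0:
                logger.warning(
                    "hits lack query coverage; coverage filtering disabled"
                )
                warned = True
        elif h.q_coverage < min_coverage:
            continue
        out.append(h)
    return out


def read_blast_tabular(
    path, query_lengths: Mapping[str, int] | None = None
) -> list[Hit]:
    """Read a 12-column BLAST tabular (outfmt 6) hit file.

    Column order: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Query coverage is computed as
    (qend - qstart + 1) / query length when ``query_lengths`` is supplied,
    otherwise left unset.  An evalue of ``NA`` (written by this package's own
    hit tables) maps to ``None``.
    """
    path = Path(path)
    hits: list[Hit] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 columns, found {len(fields)}", path, lineno
                )
            try:
                (qid, sid, pident, length, mism, gapo,
                 qstart, qend, sstart, send, evalue_s, score) = fields
                pident = float(pident)
                length = int(length)
                mism, gapo = int(mism), int(gapo)
                qstart, qend = int(qstart), int(qend)
                sstart, send = int(sstart), int(send)
                evalue = None if evalue_s == "NA" else float(evalue_s)
                score = float(score)
            except ValueError:
                raise ParseError("non-numeric field", path, lineno) from None
            coverage = None
            if query_lengths is not None and qid in query_lengths:
                coverage = round(
                    100.0 * (qend - qstart + 1) / query_lengths[qid], 2
                )
            hits.append(
                Hit(qid, sid, pident, length, score, evalue, coverage,
                    mism, gapo, qstart, qend, sstart, send)
            )
    return hits


def write_blast_tabular(hits: list[Hit], path) -> None:
    """Write hits in the 12-column BLAST tabular layout.

    The raw alignment score goes in the bitscore column; hits without an
    e-value print ``NA`` there, so internally generated tables remain
    inspectable with standard tooling yet re-parse losslessly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            evalue = "NA" if h.evalue is None else repr(h.evalue)
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                        str(h.q_start), str(h.q_end), str(h.s_start),
                        str(h.s_end), evalue, f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


def hit_sort_key(hit: Hit) -> tuple:
    """Total ordering for best-hit selection: score, e-value, length, subject id."""
    return (
        -hit.score,
        hit.evalue if hit.evalue is not None else math.inf,
        -hit.aln_length,
        hit.subject_id,
    )
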