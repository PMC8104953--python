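"""Compare Gene Calls: side-by-side comparison of call sets from several callers.

Agreement between callers is exact identity of (contig, strand, left, right).
Two calls that share contig, strand and stop but disagree on the start — the
classic alternate-initiation signature — are *not* merged; both rows are
cross-flagged ``alt_start`` so the disagreement stays visible in the report
without corrupting the consensus sets.

From the comparison rows three merged call sets are derived:

* **superset** — the nonredundant union of every caller's calls;
* **consensus** — calls supported by at least two callers;
* **common** — calls made by every caller.

For two or more callers these nest: common ⊆ consensus ⊆ superset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genecalls import GeneCall, GeneCallSet

CallKey = tuple[str, int, int, str]  # (contig, left, right, strand)


@dataclass
class ComparisonRow:
    """One distinct call key with its per-caller support vector."""

    key: CallKey
    support: dict[str, bool]
    flags: set[str] = field(default_factory=set)

    @property
    def n_support(self) -> int:
        return sum(self.support.values())


def compare_calls(sets: list[GeneCallSet]) -> list[ComparisonRow]:
    """Tabulate all distinct call keys across callers, one row per key.

    Rows are sorted by (contig, left, right, strand).  Every row whose
    (contig, strand, right) is shared by another row with a different left
    coordinate is flagged ``alt_start``.
    """
    if not sets:
        raise ValueError("at least one call set required")
    genome_ids = {s.genome_id for s in sets}
    if len(genome_ids) != 1:
        raise ValueError(f"call sets span multiple genomes: {sorted(genome_ids)}")
    caller_ids = [s.caller_id for s in sets]
    if len(set(caller_ids)) != len(caller_ids):
        raise ValueError("caller ids must be distinct")

    keys: set[CallKey] = set()
    for s in sets:
        keys |= s.keys()
    rows = []
    for key in sorted(keys):
        support = {s.caller_id: key in s.keys() for s in sets}
        rows.append(ComparisonRow(key=key, support=support))

    # alternate starts: same contig/strand/stop, different start
    by_stop: dict[tuple[str, str, int], list[ComparisonRow]] = {}
    for row in rows:
        contig, left, right, strand = row.key
        stop = right if strand == "+" else left
        by_stop.setdefault((contig, strand, stop), []).append(row)
    for group in by_stop.values():
        if len({r.key for r in group}) > 1:
            for r in group:
                r.flags.add("alt_start")
    return rows


def _rows_to_set(
    rows: list[ComparisonRow], genome_id: str, caller_id: str
) -> GeneCallSet:
    calls = [
        GeneCall(genome_id, contig, left, right, strand, caller_id,
                 f"{caller_id}_{i:04d}")
        for i, (contig, left, right, strand) in enumerate(
            (r.key for r in rows), start=1
        )
    ]
    return GeneCallSet(genome_id, caller_id, calls)


def compute_superset(rows: list[ComparisonRow], genome_id: str) -> GeneCallSet:
    """Nonredundant union of all callers' calls, ids assigned in sort order."""
    return _rows_to_set(rows, genome_id, "superset")


def compute_consensus(rows: list[ComparisonRow], genome_id: str) -> GeneCallSet:
    """Calls in agreement among two or more callers."""
    return _rows_to_set([r for r in rows if r.n_support >= 2], genome_id, "consensus")


def compute_common(
    rows: list[ComparisonRow], n_callers: int, genome_id: str
) -> GeneCallSet:
    """Calls made by every caller."""
    return _rows_to_set(
        [r for r in rows if r.n_support == n_callers], genome_id, "common"
    )


@dataclass
class MergedCallSets:
    superset: GeneCallSet
    consensus: GeneCallSet
    common: GeneCallSet


def merge_call_sets(sets: list[GeneCallSet]) -> tuple[list[ComparisonRow], MergedCallSets]:
    """Convenience wrapper: comparison rows plus all three merged sets."""
    rows = compare_calls(sets)
    gid = sets[0].genome_id
    return rows, MergedCallSets(
        superset=compute_superset(rows, gid),
        consensus=compute_consensus(rows, gid),
        common=compute_common(rows, len(sets), gid),
    )


def write_cgc_report(
    rows: list[ComparisonRow], caller_order: list[str], path
) -> None:
    """Write the side-by-side comparison as tab-delimited text.

    One line per distinct call key; caller columns appear in configured order
    and hold ``present``/``absent``.  Output is byte-deterministic.
    """
    path = Path(path)
    with path.open("w") as fh:
        cols = ["contig", "left", "right", "strand", *caller_order,
                "n_support", "flags"]
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            contig, left, right, strand = row.key
            marks = [
                "present" if row.support.get(c, False) else "absent"
                for c in caller_order
            ]
            flags = ",".join(sorted(row.flags)) if row.flags else "-"
            fh.write(
                "\t".join(
                    [contig, str(left), str(right), strand, *marks,
                     str(row.n_support), flags]
                )
                + "\n"
            )
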