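"""Workflow orchestration: configuration, stages, stop points, checkpoints.

The pipeline runs four stages in fixed order:

1. **genecalling** — per genome: read every caller's calls, run the
   side-by-side comparison, write the CGC report and the merged
   superset/consensus/common sets, forward one selected set, and extract its
   gene and protein sequences.
2. **annotation** — per genome: attach user-supplied functional annotations
   to the selected calls, write the sequence-annotation GFF and a JSON run
   record.
3. **cgp** — all binary genome-to-genome comparisons (gene and/or protein
   level) plus within-genome self-comparisons for paralog detection.
4. **genomics** — consolidate the binary comparisons into homology groups
   with respect to the reference genome (the first one configured).

Every stage reads its inputs from the on-disk artifacts of earlier stages,
so restarting from a checkpoint is exactly "skip the earlier stages": an
interrupted-then-resumed run produces a byte-identical result tree.  A
fingerprint of the configuration fields relevant to each stage is stored in
``state.json``; resuming refuses to mix stale outputs with a changed
upstream configuration and reports which fields differ.

Per-genome work (genecalling/annotation) and per-pair work (cgp) may be
parallelized; outputs are merged in configured order, so result trees are
identical for any worker count.
"""

from __future__ import annotations

import json
import logging
import shutil
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import align, cgc, cgp, homology
from .errors import ConfigError, ParseError, PhageCompareError, StageError
from .genecalls import (
    GeneCallSet,
    extract_gene_sequences,
    read_genome_fasta,
    read_gff_calls,
    read_tabular_calls,
    translate_gene,
    write_fasta,
    write_gff_calls,
)

logger = logging.getLogger(__name__)

STAGES = ("genecalling", "annotation", "cgp", "genomics")
STOP_POINTS = ("genecalling", "annotation")
CHECKPOINTS = ("annotation", "cgp", "genomics")
MERGED_SETS = ("superset", "consensus", "common")
LEVELS = ("gene", "protein")
VERBOSITIES = ("quiet", "normal", "verbose")
CALL_FORMATS = ("gff", "tab")

GLOBAL_KEYS = {
    "output_dir", "select_calls", "identity_cutoff", "coverage_cutoff",
    "levels", "workers", "stop_after", "checkpoint", "verbosity", "seed",
}
GENOME_KEYS = {"genome", "genome_fasta", "calls", "annotation"}


@dataclass
class GenomeSpec:
    genome_id: str
    fasta: str = ""
    call_sources: list[tuple[str, str, str]] = field(default_factory=list)
    annotation: str | None = None


@dataclass
class RunConfig:
    genomes: list[GenomeSpec]
    output_dir: str
    select_calls: str = "superset"
    min_identity: float = 60.0
    min_coverage: float = 75.0
    levels: list[str] = field(default_factory=lambda: ["gene", "protein"])
    workers: int = 1
    stop_after: str | None = None
    checkpoint: str | None = None
    verbosity: str = "normal"
    seed: int | None = None

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    @property
    def reference(self) -> str:
        return self.genomes[0].genome_id

    def stage_fingerprints(self) -> dict[str, dict]:
        """Configuration subset relevant to each stage.

        Worker count, verbosity and flow control are deliberately excluded:
        they must not change scientific outputs.
        """
        return {
            "genecalling": {
                "genomes": [
                    [g.genome_id, g.fasta, [list(s) for s in g.call_sources]]
                    for g in self.genomes
                ],
                "select_calls": self.select_calls,
            },
            "annotation": {
                "annotations": [[g.genome_id, g.annotation] for g in self.genomes],
            },
            "cgp": {
                "identity": self.min_identity,
                "coverage": self.min_coverage,
                "levels": list(self.levels),
            },
            "genomics": {},
        }


def parse_config(path) -> RunConfig:
    """Parse the flat ``key = value`` run-configuration file.

    A ``genome =`` line opens a new genome block; ``genome_fasta``, ``calls``
    (repeatable, ``caller:format:path``) and ``annotation`` attach to the
    open block.  Relative paths are resolved against the config file's
    directory.  Defaults: workers 1, identity 60, coverage 75, levels
    gene+protein, selected set "superset".
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    base = path.parent
    genomes: list[GenomeSpec] = []
    raw: dict[str, str] = {}

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            if "=" not in text:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in text.split("=", 1))
            if key == "genome":
                if any(g.genome_id == value for g in genomes):
                    raise ConfigError(f"line {lineno}: duplicate genome id {value!r}")
                genomes.append(GenomeSpec(genome_id=value))
            elif key in GENOME_KEYS:
                if not genomes:
                    raise ConfigError(
                        f"line {lineno}: {key!r} outside a genome block"
                    )
                spec = genomes[-1]
                if key == "genome_fasta":
                    spec.fasta = resolve(value)
                elif key == "annotation":
                    spec.annotation = resolve(value)
                else:  # calls
                    parts = value.split(":", 2)
                    if len(parts) != 3:
                        raise ConfigError(
                            f"line {lineno}: calls must be caller:format:path"
                        )
                    caller, fmt, cpath = (p.strip() for p in parts)
                    if fmt not in CALL_FORMATS:
                        raise ConfigError(
                            f"line {lineno}: unknown call format {fmt!r}"
                        )
                    spec.call_sources.append((caller, fmt, resolve(cpath)))
            elif key in GLOBAL_KEYS:
                raw[key] = value
            else:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")

    if not genomes:
        raise ConfigError("no genomes configured")
    for spec in genomes:
        if not spec.fasta:
            raise ConfigError(f"genome {spec.genome_id}: missing genome_fasta")
        if not spec.call_sources:
            raise ConfigError(f"genome {spec.genome_id}: no call sources")
        for p in [spec.fasta, *(s[2] for s in spec.call_sources)] + (
            [spec.annotation] if spec.annotation else []
        ):
            if not Path(p).exists():
                raise ConfigError(f"genome {spec.genome_id}: file not found: {p}")
        callers = [s[0] for s in spec.call_sources]
        if len(set(callers)) != len(callers):
            raise ConfigError(
                f"genome {spec.genome_id}: duplicate caller ids {callers}"
            )

    if "output_dir" not in raw:
        raise ConfigError("missing required key 'output_dir'")
    config = RunConfig(genomes=genomes, output_dir=resolve(raw["output_dir"]))

    config.select_calls = raw.get("select_calls", "superset")
    if config.select_calls not in MERGED_SETS:
        for spec in genomes:
            if config.select_calls not in [s[0] for s in spec.call_sources]:
                raise ConfigError(
                    f"select_calls {config.select_calls!r} is neither a merged "
                    f"set nor a caller of genome {spec.genome_id}"
                )
    for key, attr in (("identity_cutoff", "min_identity"),
                      ("coverage_cutoff", "min_coverage")):
        if key in raw:
            try:
                value = float(raw[key])
            except ValueError:
                raise ConfigError(f"{key} must be numeric, got {raw[key]!r}") from None
            if not (0.0 <= value <= 100.0):
                raise ConfigError(f"{key} {value} out of [0, 100]")
            setattr(config, attr, value)
    if "levels" in raw:
        levels = [s.strip() for s in raw["levels"].split(",") if s.strip()]
        if not levels or any(l not in LEVELS for l in levels):
            raise ConfigError(f"levels must be a subset of {LEVELS}, got {raw['levels']!r}")
        config.levels = levels
    if "workers" in raw:
        try:
            config.workers = int(raw["workers"])
        except ValueError:
            raise ConfigError(f"workers must be an integer, got {raw['workers']!r}") from None
        if config.workers < 1:
            raise ConfigError(f"workers must be >= 1, got {config.workers}")
    if "stop_after" in raw and raw["stop_after"]:
        if raw["stop_after"] not in STOP_POINTS:
            raise ConfigError(f"stop_after must be one of {STOP_POINTS}")
        config.stop_after = raw["stop_after"]
    if "checkpoint" in raw and raw["checkpoint"]:
        if raw["checkpoint"] not in CHECKPOINTS:
            raise ConfigError(f"checkpoint must be one of {CHECKPOINTS}")
        config.checkpoint = raw["checkpoint"]
    if "verbosity" in raw:
        if raw["verbosity"] not in VERBOSITIES:
            raise ConfigError(f"verbosity must be one of {VERBOSITIES}")
        config.verbosity = raw["verbosity"]
    if "seed" in raw and raw["seed"]:
        try:
            config.seed = int(raw["seed"])
        except ValueError:
            raise ConfigError(f"seed must be an integer, got {raw['seed']!r}") from None
    return config


@dataclass
class RunState:
    """Persisted record of which stages completed, with config fingerprints."""

    completed: dict[str, str] = field(default_factory=dict)  # stage -> done|skipped
    fingerprints: dict[str, dict] = field(default_factory=dict)
    genomes: list[str] = field(default_factory=list)

    PATH = "state.json"

    def save(self, outdir: Path) -> None:
        payload = {
            "completed": self.completed,
            "fingerprints": self.fingerprints,
            "genomes": self.genomes,
        }
        with (outdir / self.PATH).open("w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, outdir: Path) -> "RunState":
        p = outdir / cls.PATH
        with p.open() as fh:
            payload = json.load(fh)
        return cls(
            completed=payload["completed"],
            fingerprints=payload["fingerprints"],
            genomes=payload["genomes"],
        )


# ---------------------------------------------------------------------------
# stage: genecalling


def _read_call_source(source, genome_id: str) -> GeneCallSet:
    caller, fmt, cpath = source
    reader = read_gff_calls if fmt == "gff" else read_tabular_calls
    return reader(cpath, genome_id, caller)


def _genecalling_one(args) -> str:
    spec, select_calls, outdir_s = args
    outdir = Path(outdir_s)
    gid = spec.genome_id
    gdir = outdir / gid
    gdir.mkdir(parents=True, exist_ok=True)
    genome = read_genome_fasta(spec.fasta, gid)
    call_sets = [_read_call_source(s, gid) for s in spec.call_sources]
    caller_order = [s[0] for s in spec.call_sources]
    rows, merged = cgc.merge_call_sets(call_sets)
    cgc.write_cgc_report(rows, caller_order, gdir / "CGC_results.txt")
    for name in MERGED_SETS:
        write_gff_calls(getattr(merged, name), gdir / f"{name}.gff")
    if select_calls in MERGED_SETS:
        selected = getattr(merged, select_calls)
    else:
        selected = next(s for s in call_sets if s.caller_id == select_calls)
    write_gff_calls(selected, gdir / "selected_calls.gff")
    genes = extract_gene_sequences(genome, selected)
    # keep genomic order for the fasta files
    ordered = {c.gene_id: genes[c.gene_id] for c in selected}
    write_fasta(ordered, gdir / f"{gid}_genes.fasta")
    proteins = {}
    for gene_id, nt in ordered.items():
        if len(nt) < 3:
            logger.warning("gene %s shorter than one codon; not translated", gene_id)
            continue
        proteins[gene_id] = translate_gene(nt, gene_id)
    write_fasta(proteins, gdir / f"{gid}_proteins.fasta")
    return gid


def stage_genecalling(config: RunConfig, outdir: Path) -> None:
    jobs = [(spec, config.select_calls, str(outdir)) for spec in config.genomes]
    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            list(pool.map(_genecalling_one, jobs))
    else:
        for job in jobs:
            _genecalling_one(job)


# ---------------------------------------------------------------------------
# stage: annotation


def _load_selected(outdir: Path, gid: str) -> GeneCallSet:
    return read_gff_calls(outdir / gid / "selected_calls.gff", gid, "selected")


def _write_annotated_gff(
    calls: GeneCallSet, annotations: dict[str, list[str]], path: Path
) -> None:
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls:
            texts = annotations.get(call.gene_id, [homology.UNANNOTATED])
            product = "|".join(texts).replace(";", ",")
            fh.write(
                f"{call.contig_id}\tphagecompare\tCDS\t{call.left}\t{call.right}"
                f"\t.\t{call.strand}\t0\tID={call.gene_id};product={product}\n"
            )


def _annotation_one(args) -> str:
    spec, config_echo, outdir_s = args
    outdir = Path(outdir_s)
    gid = spec.genome_id
    selected = _load_selected(outdir, gid)
    if spec.annotation:
        table = homology.read_annotation_table(
            spec.annotation, gid, valid_ids=set(selected.by_id())
        )
        entries = table.entries
    else:
        entries = {}
    _write_annotated_gff(
        selected, entries, outdir / gid / "sequence_annotation.gff"
    )
    record = {
        "genome_id": gid,
        "genome_fasta": spec.fasta,
        "callers": [list(s) for s in spec.call_sources],
        "annotation_table": spec.annotation,
        "n_selected_calls": len(selected),
        "n_annotated_genes": len(entries),
        **config_echo,
    }
    jdir = outdir / "JSON"
    jdir.mkdir(parents=True, exist_ok=True)
    with (jdir / f"{gid}.json").open("w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return gid


def stage_annotation(config: RunConfig, outdir: Path) -> None:
    config_echo = {
        "select_calls": config.select_calls,
        "identity_cutoff": config.min_identity,
        "coverage_cutoff": config.min_coverage,
        "levels": list(config.levels),
    }
    jobs = [(spec, config_echo, str(outdir)) for spec in config.genomes]
    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            list(pool.map(_annotation_one, jobs))
    else:
        for job in jobs:
            _annotation_one(job)


# ---------------------------------------------------------------------------
# stage: cgp


def _read_fasta_dict(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _level_sequences(
    outdir: Path, gids: list[str], level: str
) -> dict[str, dict[str, str]]:
    suffix = "genes" if level == "gene" else "proteins"
    return {
        gid: _read_fasta_dict(outdir / gid / f"{gid}_{suffix}.fasta") for gid in gids
    }


def _scheme_for(level: str) -> align.ScoringScheme:
    return align.NUCLEOTIDE_SCHEME if level == "gene" else align.PROTEIN_SCHEME


def stage_cgp(config: RunConfig, outdir: Path) -> None:
    gids = config.genome_ids
    cgp_dir = outdir / "CGP_RESULTS"
    if len(gids) < 2:
        logger.info("single genome configured; skipping Compare Gene Profiles")
        return
    cgp_dir.mkdir(parents=True, exist_ok=True)
    call_sets = {gid: _load_selected(outdir, gid) for gid in gids}
    for level in config.levels:
        scheme = _scheme_for(level)
        seqs = _level_sequences(outdir, gids, level)
        tables = cgp.compute_pair_hits(gids, seqs, scheme, workers=config.workers)
        for i, a in enumerate(gids):
            for b in gids[i + 1 :]:
                pdir = cgp_dir / f"{a}_vs_{b}" / level
                pdir.mkdir(parents=True, exist_ok=True)
                align.write_blast_tabular(tables[(a, b)], pdir / f"hits_{a}_to_{b}.tab")
                align.write_blast_tabular(tables[(b, a)], pdir / f"hits_{b}_to_{a}.tab")
                rep_ab, rep_ba = cgp.compare_binary(
                    call_sets[a], call_sets[b],
                    align.filter_hits(tables[(a, b)], config.min_identity,
                                      config.min_coverage),
                    align.filter_hits(tables[(b, a)], config.min_identity,
                                      config.min_coverage),
                    config.min_identity, config.min_coverage, level,
                )
                cgp.write_binary_report(rep_ab, pdir / f"report_{a}_to_{b}.txt")
                cgp.write_binary_report(rep_ba, pdir / f"report_{b}_to_{a}.txt")
        for gid in gids:
            sdir = cgp_dir / "self" / gid / level
            sdir.mkdir(parents=True, exist_ok=True)
            self_hits = align.all_vs_all(seqs[gid], seqs[gid], scheme)
            align.write_blast_tabular(self_hits, sdir / "self_hits.tab")
            pairs = cgp.find_paralogs(
                call_sets[gid],
                align.filter_hits(self_hits, config.min_identity,
                                  config.min_coverage),
            )
            cgp.write_paralogs(pairs, sdir / "paralogs.txt")


# ---------------------------------------------------------------------------
# stage: genomics


def stage_genomics(config: RunConfig, outdir: Path) -> None:
    gids = config.genome_ids
    if len(gids) < 2:
        logger.info("single genome configured; skipping Genomics")
        return
    gen_dir = outdir / "GENOMICS_RESULTS"
    gen_dir.mkdir(parents=True, exist_ok=True)
    cgp_dir = outdir / "CGP_RESULTS"
    reference = config.reference
    call_sets = {gid: _load_selected(outdir, gid) for gid in gids}
    tables = [
        homology.read_annotation_table(
            spec.annotation, spec.genome_id,
            valid_ids=set(call_sets[spec.genome_id].by_id()),
        )
        for spec in config.genomes
        if spec.annotation
    ]
    for level in config.levels:
        seqs = _level_sequences(outdir, gids, level)
        lengths = {gid: {k: len(v) for k, v in seqs[gid].items()} for gid in gids}
        reports = []
        for other in gids[1:]:
            # the reference is first in configured order, so pair dirs are
            # always named <reference>_vs_<other>
            pdir = cgp_dir / f"{reference}_vs_{other}" / level
            fwd = align.read_blast_tabular(
                pdir / f"hits_{reference}_to_{other}.tab", lengths[reference]
            )
            rev = align.read_blast_tabular(
                pdir / f"hits_{other}_to_{reference}.tab", lengths[other]
            )
            rep_ab, rep_ba = cgp.compare_binary(
                call_sets[reference], call_sets[other],
                align.filter_hits(fwd, config.min_identity, config.min_coverage),
                align.filter_hits(rev, config.min_identity, config.min_coverage),
                config.min_identity, config.min_coverage, level,
            )
            reports += [rep_ab, rep_ba]
        self_hits = align.read_blast_tabular(
            cgp_dir / "self" / reference / level / "self_hits.tab",
            lengths[reference],
        )
        paralogs = cgp.find_paralogs(
            call_sets[reference],
            align.filter_hits(self_hits, config.min_identity, config.min_coverage),
        )
        groups = homology.build_homology_groups(
            reference, gids, call_sets[reference], reports, paralogs, level
        )
        homology.attach_annotations(groups, tables)
        homology.write_genomics_results(
            groups, gids, gen_dir / f"homology_groups_{level}.txt"
        )


# ---------------------------------------------------------------------------
# orchestration

_STAGE_FUNCS = {
    "genecalling": stage_genecalling,
    "annotation": stage_annotation,
    "cgp": stage_cgp,
    "genomics": stage_genomics,
}

#: directories each stage owns, relative to the output root ({g} per genome)
_STAGE_DIRS = {
    "genecalling": ["{g}"],
    "annotation": ["JSON"],
    "cgp": ["CGP_RESULTS"],
    "genomics": ["GENOMICS_RESULTS"],
}


def _quarantine(config: RunConfig, outdir: Path, stage: str) -> None:
    """Move a failed stage's partial outputs aside as ``<dir>.failed``."""
    for pattern in _STAGE_DIRS[stage]:
        dirs = (
            [outdir / pattern.format(g=gid) for gid in config.genome_ids]
            if "{g}" in pattern
            else [outdir / pattern]
        )
        for d in dirs:
            if d.exists():
                target = d.with_name(d.name + ".failed")
                if target.exists():
                    shutil.rmtree(target)
                d.rename(target)
                logger.error("partial outputs of stage %s quarantined to %s",
                             stage, target)


def _run_stages(config: RunConfig, start_index: int) -> RunState:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        state = RunState.load(outdir)
    except FileNotFoundError:
        state = RunState(genomes=config.genome_ids)
    state.genomes = config.genome_ids
    fingerprints = config.stage_fingerprints()
    comparative = len(config.genome_ids) >= 2
    for stage in STAGES[start_index:]:
        if stage in ("cgp", "genomics") and not comparative:
            logger.info("stage %s skipped: fewer than two genomes", stage)
            state.completed[stage] = "skipped"
        else:
            logger.info("running stage %s", stage)
            try:
                _STAGE_FUNCS[stage](config, outdir)
            except PhageCompareError as exc:
                _quarantine(config, outdir, stage)
                raise StageError(stage, "pipeline", exc) from exc
            state.completed[stage] = "done"
        state.fingerprints[stage] = fingerprints[stage]
        state.save(outdir)
        if config.stop_after == stage:
            logger.info("stopping after stage %s as configured", stage)
            break
    return state


def run_pipeline(config: RunConfig) -> RunState:
    """Run the pipeline from the beginning (honouring ``stop_after``)."""
    return _run_stages(config, 0)


#: artifacts that must exist on disk before each checkpoint can start
def _prerequisites(config: RunConfig, checkpoint: str) -> list[Path]:
    outdir = Path(config.output_dir)
    req = []
    for gid in config.genome_ids:
        req.append(outdir / gid / "selected_calls.gff")
        req.append(outdir / gid / f"{gid}_genes.fasta")
        req.append(outdir / gid / f"{gid}_proteins.fasta")
    if checkpoint == "genomics" and len(config.genome_ids) >= 2:
        reference = config.reference
        for other in config.genome_ids[1:]:
            for level in config.levels:
                pdir = outdir / "CGP_RESULTS" / f"{reference}_vs_{other}" / level
                req.append(pdir / f"hits_{reference}_to_{other}.tab")
                req.append(pdir / f"hits_{other}_to_{reference}.tab")
        for level in config.levels:
            req.append(
                outdir / "CGP_RESULTS" / "self" / reference / level / "self_hits.tab"
            )
    return req


def resume_pipeline(config: RunConfig, state_dir=None) -> RunState:
    """Restart the pipeline at ``config.checkpoint`` reusing earlier outputs.

    Refuses when configuration fields that affect stages *before* the
    checkpoint changed since the recorded run, listing the differing fields,
    or when required upstream artifacts are missing.
    """
    if config.checkpoint is None:
        raise ConfigError("resume requested but no checkpoint configured")
    outdir = Path(state_dir) if state_dir is not None else Path(config.output_dir)
    try:
        state = RunState.load(outdir)
    except FileNotFoundError:
        raise ConfigError(f"no run state found under {outdir}") from None
    start_index = STAGES.index(config.checkpoint)
    fingerprints = config.stage_fingerprints()
    problems = []
    for stage in STAGES[:start_index]:
        if stage not in state.completed:
            problems.append(f"stage {stage!r} was never completed")
            continue
        old, new = state.fingerprints.get(stage, {}), fingerprints[stage]
        for key in sorted(set(old) | set(new)):
            if old.get(key) != new.get(key):
                problems.append(
                    f"stage {stage!r} config field {key!r} changed: "
                    f"{old.get(key)!r} -> {new.get(key)!r}"
                )
    if problems:
        raise ConfigError(
            "cannot resume; upstream configuration differs from recorded run:\n  "
            + "\n  ".join(problems)
        )
    missing = [p for p in _prerequisites(config, config.checkpoint) if not p.exists()]
    if missing:
        raise ConfigError(
            "cannot resume; missing prerequisite output(s):\n  "
            + "\n  ".join(str(p) for p in missing)
        )
    return _run_stages(config, start_index)
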