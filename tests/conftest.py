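from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from phagecompare.genecalls import write_fasta, write_gff_calls
from phagecompare.synthetic import (
    CallerNoiseModel,
    SyntheticTruth,
    make_related_genomes,
    simulate_caller,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth3() -> SyntheticTruth:
    """Three related genomes, 5% diverged, one duplication in the reference."""
    return make_related_genomes(
        n_genomes=3, n_genes=20, divergence=0.05,
        duplications_in_reference=1, seed=20210317,
    )


def write_run_setup(
    workdir: Path,
    truth: SyntheticTruth,
    n_callers: int = 2,
    noise: CallerNoiseModel | None = None,
    seed: int = 5,
    output_dir: str = "results",
    config_name: str = "run.config",
    **options: str,
) -> Path:
    """Write a complete fixture + config under ``workdir``; return config path.

    Callers are simulated on the planted truth (noise-free by default, so
    every caller reproduces the truth exactly) and the run configuration
    points at the written files.
    """
    workdir.mkdir(parents=True, exist_ok=True)
    noise = noise or CallerNoiseModel()
    caller_ids = [f"caller{chr(ord('A') + i)}" for i in range(n_callers)]
    lines = [f"output_dir = {output_dir}"]
    for key, value in options.items():
        lines.append(f"{key} = {value}")
    for k, genome in enumerate(truth.genomes):
        gid = genome.genome_id
        write_fasta(genome.sequences, workdir / f"{gid}.fasta")
        lines.append(f"genome = {gid}")
        lines.append(f"genome_fasta = {gid}.fasta")
        for i, caller in enumerate(caller_ids):
            calls, _ = simulate_caller(
                truth.true_calls[gid], genome, noise, caller,
                seed=seed + 100 * k + i,
            )
            write_gff_calls(calls, workdir / f"{gid}.{caller}.gff")
            lines.append(f"calls = {caller}:gff:{gid}.{caller}.gff")
    config = workdir / config_name
    config.write_text("\n".join(lines) + "\n")
    return config


def tree_bytes(root: Path) -> dict[str, bytes]:
    """Map of relative file path -> content for byte-level tree comparison."""
    return {
        str(p.relative_to(root)): p.read_bytes()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }
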