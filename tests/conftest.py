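"""Shared fixtures: toy cohort runs, CLI invocation, and independent oracles."""

from __future__ import annotations

import contextlib
import io
import random
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import pytest
from hypothesis import settings

from genflow.cli import main as cli_main
from genflow.model import Job
from genflow.toy import ToyCohort, make_toy_dataset, write_default_config

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# --------------------------------------------------------------------------
# toy run harness
# --------------------------------------------------------------------------

@dataclass
class ToyRun:
    """A toy cohort plus helpers to drive the CLI and execute its scripts."""

    root: Path
    sheet: Path
    config: Path
    workdir: Path
    cohort: ToyCohort
    extra_configs: list[Path] = field(default_factory=list)

    def cli(
        self,
        steps: str = "1-4",
        scheduler: str = "batch",
        force: bool = False,
        protocol: str | None = None,
        configs: list[Path] | None = None,
    ) -> tuple[int, str, str]:
        """Invoke the genflow CLI in-process; returns (exit, stdout, stderr)."""
        argv = ["toyseq", "-r", str(self.sheet), "-s", steps,
                "-j", scheduler, "-o", str(self.workdir)]
        for cfg in configs if configs is not None else [self.config, *self.extra_configs]:
            argv += ["-c", str(cfg)]
        if force:
            argv.append("-f")
        if protocol:
            argv += ["-t", protocol]
        out, err = io.StringIO(), io.StringIO()
        with contextlib.redirect_stdout(out), contextlib.redirect_stderr(err):
            code = cli_main(argv)
        return code, out.getvalue(), err.getvalue()

    def run_script(self, script: str) -> subprocess.CompletedProcess:
        path = self.root / "Commands.txt"
        path.write_text(script)
        return subprocess.run(
            ["bash", str(path)], capture_output=True, text=True
        )

    def full_run(self, steps: str = "1-4", **kwargs) -> str:
        """CLI + execute the batch script; asserts success; returns script."""
        code, script, err = self.cli(steps=steps, **kwargs)
        assert code == 0, err
        proc = self.run_script(script)
        assert proc.returncode == 0, proc.stderr
        return script

    def override_config(self, name: str, text: str) -> Path:
        """Write an extra INI layered after the default configuration."""
        path = self.root / name
        path.write_text(text)
        self.extra_configs.append(path)
        return path


def make_toy_run(
    tmp_path: Path,
    n_samples: int = 2,
    readsets_per_sample: int = 2,
    reads_per_file: int = 8,
    seed: int = 7,
) -> ToyRun:
    root = tmp_path / "toy"
    cohort = ToyCohort(
        root=root / "data",
        n_samples=n_samples,
        readsets_per_sample=readsets_per_sample,
        reads_per_file=reads_per_file,
        seed=seed,
    )
    root.mkdir(parents=True, exist_ok=True)
    sheet = make_toy_dataset(cohort)
    config = write_default_config(root / "toy.ini")
    workdir = root / "run"
    return ToyRun(root=root, sheet=sheet, config=config, workdir=workdir, cohort=cohort)


@pytest.fixture
def toy(tmp_path) -> ToyRun:
    """Default study cohort: 2 samples x 2 paired readsets, 8 reads per file."""
    return make_toy_run(tmp_path)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_edges(jobs: list[Job]) -> set[tuple[str, str]]:
    """O(n^2) pairwise output/input intersection — the DAG oracle."""
    edges = set()
    for a in jobs:
        outs = set(a.outputs)
        for b in jobs:
            if a.name != b.name and outs & set(b.inputs):
                edges.add((a.name, b.name))
    return edges


def brute_force_reachable(edges: set[tuple[str, str]], start: str) -> set[str]:
    """Transitive consumers of ``start`` by plain worklist traversal."""
    reached: set[str] = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for src, dst in edges:
            if src == node and dst not in reached:
                reached.add(dst)
                frontier.append(dst)
    return reached


def random_job_set(rng: random.Random, max_jobs: int = 50) -> list[Job]:
    """A random acyclic job set: inputs drawn from earlier jobs' outputs."""
    n = rng.randint(1, max_jobs)
    jobs: list[Job] = []
    all_outputs: list[str] = []
    for i in range(n):
        outputs = [f"f{i}_{k}" for k in range(rng.randint(1, 3))]
        n_inputs = rng.randint(0, min(4, len(all_outputs)))
        inputs = rng.sample(all_outputs, n_inputs) if n_inputs else []
        # sprinkle in external (on-disk style) inputs nobody produces
        if rng.random() < 0.3:
            inputs.append(f"external_{rng.randint(0, 5)}")
        jobs.append(
            Job(
                name=f"job{i}",
                step_name="random",
                command=f"true # {i}",
                inputs=inputs,
                outputs=outputs,
            )
        )
        all_outputs.extend(outputs)
    return jobs


def random_topological_orders(
    jobs: list[Job], edges: set[tuple[str, str]], rng: random.Random, count: int
) -> list[list[Job]]:
    """Random topological orders via Kahn's algorithm with random choice."""
    orders = []
    for _ in range(count):
        indeg = {job.name: 0 for job in jobs}
        for _, dst in edges:
            indeg[dst] += 1
        ready = [job.name for job in jobs if indeg[job.name] == 0]
        order: list[str] = []
        while ready:
            name = ready.pop(rng.randrange(len(ready)))
            order.append(name)
            for src, dst in edges:
                if src == name:
                    indeg[dst] -= 1
                    if indeg[dst] == 0:
                        ready.append(dst)
        by_name = {job.name: job for job in jobs}
        orders.append([by_name[name] for name in order])
    return orders


def execute_jobs_in_order(jobs: list[Job], workdir: Path) -> None:
    """Run job commands directly with bash, one by one, in the given order."""
    for job in jobs:
        for out in job.outputs:
            (workdir / out).parent.mkdir(parents=True, exist_ok=True)
        proc = subprocess.run(
            ["bash", "-c", job.command], cwd=workdir, capture_output=True, text=True
        )
        assert proc.returncode == 0, f"{job.name}: {proc.stderr}"


def output_snapshot(jobs: list[Job], workdir: Path) -> dict[str, bytes]:
    """Bytes of every declared output of ``jobs`` under ``workdir``."""
    snap = {}
    for job in jobs:
        for out in job.outputs:
            path = Path(out) if Path(out).is_absolute() else workdir / out
            snap[out] = path.read_bytes()
    return snap


def expected_clean_summary(run: ToyRun) -> list[str]:
    """Recompute the toy summary from the generated FASTQ files alone.

    Counts, per sample, the 4-line records across both mates of every
    readset whose header lacks the low-quality token, entirely in Python —
    independent of the pipeline's shell commands.
    """
    lines = []
    for s in range(1, run.cohort.n_samples + 1):
        sample = f"s{s}"
        kept_lines = 0
        for r in range(1, run.cohort.readsets_per_sample + 1):
            for mate in (1, 2):
                fastq = run.cohort.root / "raw" / f"{sample}_r{r}.R{mate}.fastq"
                records = fastq.read_text().splitlines()
                headers = records[0::4]
                kept_lines += 4 * sum(1 for h in headers if "LOWQ" not in h)
        lines.append(f"counts/{sample}.count.txt\t{kept_lines}")
    return sorted(lines)
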