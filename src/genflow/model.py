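"""Core workflow objects and sample-sheet parsing.

The engine is built around four objects. A :class:`Pipeline` names one or
more *protocols*, each an ordered list of :class:`Step` objects. A step is a
job factory with a *scope*: it runs once per readset, once per sample, or
once for the whole cohort. Each invocation of a step's factory yields
:class:`Job` objects — a shell command plus its declared input and output
paths, from which all inter-job dependencies are derived.

Sequencing metadata enters through a readset file: a tab-separated sheet
with one row per readset (one sequencing unit — typically a lane or library
— of a sample). Readsets sharing a sample name are aggregated into
:class:`Sample` objects. Optional design (contrast) and normal−tumour pairs
files reference those samples.
"""

from __future__ import annotations

import csv
import logging
import re
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import FormatError, GenerationError, GenFlowError

logger = logging.getLogger(__name__)

#: Columns a readset file may carry. Only the first three are mandatory.
READSET_COLUMNS = (
    "Sample",
    "Readset",
    "RunType",
    "FASTQ1",
    "FASTQ2",
    "BAM",
    "Adapter1",
    "Adapter2",
    "Library",
    "Run",
    "Lane",
)
_MANDATORY_COLUMNS = ("Sample", "Readset", "RunType")

_NAME_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_.-]")


def sanitize_name(name: str) -> str:
    """Replace characters unsafe for scheduler job names with ``_``."""
    return _NAME_SANITIZE_RE.sub("_", name)


class RunType(str, Enum):
    PAIRED_END = "PAIRED_END"
    SINGLE_END = "SINGLE_END"


class Scope(str, Enum):
    """Granularity at which a step emits jobs."""

    READSET = "READSET"
    SAMPLE = "SAMPLE"
    COHORT = "COHORT"


@dataclass
class Readset:
    """One sequencing unit of a sample: its files plus run metadata."""

    name: str
    sample_name: str
    run_type: RunType
    fastq1: str | None = None
    fastq2: str | None = None
    bam: str | None = None
    adapter1: str | None = None
    adapter2: str | None = None
    library: str | None = None
    run: str | None = None
    lane: str | None = None

    def validate(self) -> None:
        if self.fastq1 is None and self.bam is None:
            raise FormatError(
                f"readset {self.name!r}: needs at least one of FASTQ1 or BAM"
            )
        if (
            self.run_type is RunType.PAIRED_END
            and self.fastq1 is not None
            and self.fastq2 is None
        ):
            raise FormatError(
                f"readset {self.name!r}: RunType=PAIRED_END with FASTQ1 requires FASTQ2"
            )


@dataclass
class Sample:
    """A sample aggregating one or more readsets, in file order."""

    name: str
    readsets: list[Readset]


@dataclass
class Contrast:
    """A named comparison: control vs case sample groups."""

    name: str
    controls: list[str]
    cases: list[str]


@dataclass
class Pair:
    """Normal−tumour sample pairing for one patient."""

    patient: str
    normal: str
    tumour: str


@dataclass
class Job:
    """One schedulable unit: a shell command with declared inputs/outputs.

    ``dependencies`` is derived by the engine from input/output overlap and
    must not be set by step factories. All paths are kept as strings; the
    generator normalizes them relative to the working directory.
    """

    name: str
    step_name: str
    command: str
    inputs: list[str]
    outputs: list[str]
    modules: list[str] = field(default_factory=list)
    dependencies: list[str] = field(default_factory=list)
    removable_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.name = sanitize_name(self.name)
        if not self.outputs:
            raise GenerationError(f"job {self.name!r} declares no outputs")
        if not self.command.strip():
            raise GenerationError(f"job {self.name!r} has an empty command")


#: Resolver handed to job factories: ordered candidate path-lists in, the
#: first satisfiable list out (see ``genflow.dag.resolve_input``).
InputResolver = Callable[[Sequence[Sequence[str]]], list[str]]

JobFactory = Callable[[object, "object", InputResolver], list[Job]]


@dataclass
class Step:
    """A pipeline stage: a job factory with a name, position and scope."""

    name: str
    number: int
    scope: Scope
    job_factory: JobFactory


@dataclass
class Pipeline:
    """A named workflow holding one or more protocols (step-list variants)."""

    name: str
    protocols: dict[str, list[Step]]
    default_protocol: str

    def __post_init__(self) -> None:
        if self.default_protocol not in self.protocols:
            raise ValueError(
                f"default protocol {self.default_protocol!r} not among "
                f"protocols {sorted(self.protocols)}"
            )
        for proto, steps in self.protocols.items():
            numbers = [s.number for s in steps]
            if numbers != list(range(1, len(steps) + 1)):
                raise ValueError(
                    f"protocol {proto!r}: step numbers {numbers} are not "
                    "consecutive from 1"
                )
            names = [s.name for s in steps]
            if len(set(names)) != len(names):
                raise ValueError(f"protocol {proto!r}: duplicate step names")

    def steps(self, protocol: str | None = None) -> list[Step]:
        proto = protocol or self.default_protocol
        try:
            return self.protocols[proto]
        except KeyError:
            raise ValueError(
                f"unknown protocol {proto!r}; available: {sorted(self.protocols)}"
            ) from None


import os


def _resolve(cell: str, base: Path) -> str:
    """Resolve a sheet path cell relative to the sheet's own directory.

    The result is absolute (no symlink canonicalization) so it stays valid
    whatever working directory the run uses.
    """
    p = Path(cell)
    if not p.is_absolute():
        p = base / p
    return os.path.abspath(p)


def load_readsets(path: str | Path) -> list[Readset]:
    """Parse a tab-separated readset file into a list of readsets.

    Relative file paths in the sheet are resolved against the sheet's
    directory. Unknown columns are ignored with a warning.
    """
    path = Path(path)
    base = path.parent
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty readset file, no header row")
        for col in _MANDATORY_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        unknown = [c for c in reader.fieldnames if c not in READSET_COLUMNS]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, unknown)

        readsets: list[Readset] = []
        seen: set[str] = set()
        for row in reader:
            get = lambda col: (row.get(col) or "").strip() or None  # noqa: E731
            name = get("Readset")
            sample = get("Sample")
            run_type_raw = get("RunType")
            if not name or not sample or not run_type_raw:
                raise FormatError(
                    f"{path}: row {reader.line_num}: Sample, Readset and "
                    "RunType must be non-empty"
                )
            try:
                run_type = RunType(run_type_raw)
            except ValueError:
                raise FormatError(
                    f"{path}: row {reader.line_num}: invalid RunType "
                    f"{run_type_raw!r} (expected PAIRED_END or SINGLE_END)"
                ) from None
            if name in seen:
                raise FormatError(f"{path}: duplicate readset name {name!r}")
            seen.add(name)
            rs = Readset(
                name=name,
                sample_name=sample,
                run_type=run_type,
                fastq1=_resolve(get("FASTQ1"), base) if get("FASTQ1") else None,
                fastq2=_resolve(get("FASTQ2"), base) if get("FASTQ2") else None,
                bam=_resolve(get("BAM"), base) if get("BAM") else None,
                adapter1=get("Adapter1"),
                adapter2=get("Adapter2"),
                library=get("Library"),
                run=get("Run"),
                lane=get("Lane"),
            )
            rs.validate()
            readsets.append(rs)
    if not readsets:
        raise FormatError(f"{path}: no readsets")
    return readsets


def group_samples(readsets: Sequence[Readset]) -> list[Sample]:
    """Group readsets into samples, ordered by first appearance.

    The grouping is a partition: every readset lands in exactly one sample,
    and each sample's readsets keep file order.
    """
    samples: dict[str, Sample] = {}
    for rs in readsets:
        samples.setdefault(rs.sample_name, Sample(rs.sample_name, [])).readsets.append(rs)
    return list(samples.values())


def load_design(path: str | Path, known_samples: Sequence[str]) -> list[Contrast]:
    """Parse a design (contrast) file.

    Tab-separated; first column ``Sample``, then one column per contrast.
    Cell values: 0 = excluded, 1 = control, 2 = case.
    """
    path = Path(path)
    known = set(known_samples)
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty design file") from None
        if not header or header[0] != "Sample":
            raise FormatError(f"{path}: first column must be 'Sample'")
        contrast_names = header[1:]
        if not contrast_names:
            raise FormatError(f"{path}: no contrast columns")
        contrasts = [Contrast(name, [], []) for name in contrast_names]
        for row_idx, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            sample = row[0].strip()
            if sample not in known:
                raise FormatError(
                    f"{path}: row {row_idx}: sample {sample!r} not in readset file"
                )
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: row {row_idx}: expected {len(header)} columns, "
                    f"got {len(row)}"
                )
            for col_idx, cell in enumerate(row[1:], start=1):
                value = cell.strip()
                if value not in {"0", "1", "2"}:
                    raise FormatError(
                        f"{path}: row {row_idx}, column "
                        f"{header[col_idx]!r}: invalid cell {cell!r} "
                        "(expected 0, 1 or 2)"
                    )
                if value == "1":
                    contrasts[col_idx - 1].controls.append(sample)
                elif value == "2":
                    contrasts[col_idx - 1].cases.append(sample)
    for contrast in contrasts:
        if not contrast.controls and not contrast.cases:
            logger.warning(
                "%s: contrast %r has no member samples", path, contrast.name
            )
    return contrasts


def load_pairs(
    path: str | Path, known_samples: Sequence[str] | None = None
) -> list[Pair]:
    """Parse a comma-separated normal−tumour pairs file (patient,normal,tumour)."""
    path = Path(path)
    known = set(known_samples) if known_samples is not None else None
    pairs: list[Pair] = []
    with open(path, newline="") as handle:
        for row_idx, row in enumerate(csv.reader(handle), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise FormatError(
                    f"{path}: row {row_idx}: expected 3 fields "
                    f"(patient,normal,tumour), got {len(row)}"
                )
            patient, normal, tumour = (cell.strip() for cell in row)
            if normal == tumour:
                raise FormatError(
                    f"{path}: row {row_idx}: normal equals tumour ({normal!r})"
                )
            if known is not None:
                for name in (normal, tumour):
                    if name not in known:
                        raise FormatError(
                            f"{path}: row {row_idx}: sample {name!r} not in "
                            "readset file"
                        )
            pairs.append(Pair(patient, normal, tumour))
    return pairs


def generate_jobs(
    pipeline: Pipeline,
    protocol: str | None,
    selected_steps: Sequence[int],
    samples: Sequence[Sample],
    config,
    workdir: str | Path,
) -> list[Job]:
    """Run the selected steps' job factories and derive job dependencies.

    Jobs are emitted step by step in step order; within a step, entity order
    follows sample (and readset) order, so the result is deterministic for
    identical inputs. Each job's ``dependencies`` list is filled from the
    registry of outputs produced by earlier jobs.
    """
    # imported here to keep the module dependency one-way at import time
    from .dag import OutputRegistry, normalize_path, resolve_input

    if not samples:
        raise GenerationError("no samples")
    steps = pipeline.steps(protocol)
    valid_numbers = {s.number for s in steps}
    bad = sorted(set(selected_steps) - valid_numbers)
    if bad:
        raise GenerationError(
            f"selected steps {bad} not in protocol "
            f"{protocol or pipeline.default_protocol!r} (1-{len(steps)})"
        )

    workdir = str(workdir)
    registry = OutputRegistry()
    jobs: list[Job] = []
    emission_index: dict[str, int] = {}
    selected = set(selected_steps)

    for step in steps:
        if step.number not in selected:
            continue
        if step.scope is Scope.READSET:
            entities = [rs for sample in samples for rs in sample.readsets]
        elif step.scope is Scope.SAMPLE:
            entities = list(samples)
        else:  # COHORT: the full sample list, once
            entities = [list(samples)]
        for entity in entities:
            resolver: InputResolver = lambda candidates: resolve_input(
                candidates, registry, workdir
            )
            try:
                new_jobs = step.job_factory(entity, config, resolver)
            except GenFlowError as exc:
                entity_name = getattr(entity, "name", "cohort")
                raise type(exc)(
                    f"step {step.name!r}, entity {entity_name!r}: {exc}"
                ) from exc
            for job in new_jobs:
                if job.name in emission_index:
                    raise GenerationError(f"duplicate job name {job.name!r}")
                job.inputs = [normalize_path(p, workdir) for p in job.inputs]
                job.outputs = [normalize_path(p, workdir) for p in job.outputs]
                job.dependencies = sorted(
                    {registry.producer(p) for p in job.inputs if p in registry},
                    key=emission_index.__getitem__,
                )
                for out in job.outputs:
                    registry.register(out, job.name)
                emission_index[job.name] = len(jobs)
                jobs.append(job)
    return jobs
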