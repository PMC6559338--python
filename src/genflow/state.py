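"""Smart relaunch: done-markers, staleness tests, and run planning.

Completion state lives entirely on the file system. When a job finishes
successfully, the emitted script touches an empty *done-marker* whose name
embeds an MD5 digest of the exact command text:

    <state_dir>/<job name>.<md5 hex digest>.done

Because the digest is part of the filename, "has this exact command already
succeeded?" is a plain file-existence test — no marker parsing. A changed
parameter that reaches the command changes the digest, orphans the old
marker, and the job is relaunched. Environment modules are rendered into
the command text, so tool-version changes are covered transitively.

Staleness additionally compares file timestamps: a job is up to date only
if all declared outputs exist and the newest input is not newer than the
oldest output. Comparison is at whole-second resolution with ties counting
as up to date, which avoids flapping on file systems with coarse mtimes.
"""

from __future__ import annotations

import glob
import hashlib
import os
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .dag import DependencyGraph
from .model import Job

#: Marker directory name, relative to the run's output directory.
STATE_DIR_NAME = "job_state"

#: Relaunch reasons, most specific first. ``up_to_date`` appears only in the
#: skipped list of a plan.
REASON_NO_MARKER = "no_marker"
REASON_HASH_CHANGED = "hash_changed"
REASON_OUTPUT_MISSING = "output_missing"
REASON_INPUTS_NEWER = "inputs_newer"
REASON_DEPENDENCY = "dependency_relaunched"
REASON_FORCED = "forced"


def command_hash(job: Job) -> str:
    """Lowercase hex MD5 of the job's exact rendered command text (UTF-8)."""
    if not job.command:
        raise ValueError(f"job {job.name!r} has an empty command")
    return hashlib.md5(job.command.encode("utf-8")).hexdigest()


def marker_path(job: Job, state_dir: str | Path = STATE_DIR_NAME) -> str:
    """Done-marker path for the job's current command digest."""
    return str(Path(state_dir) / f"{job.name}.{command_hash(job)}.done")


def marker_contract(
    job: Job, state_dir: str | Path = STATE_DIR_NAME
) -> tuple[str, str]:
    """Return (marker path, shell epilogue) for a job.

    The epilogue captures the command's exit status and creates the marker
    only on success; emitted scripts must append it directly after the
    command. It deliberately does not ``exit`` — each scheduler dialect adds
    its own failure handling after it.
    """
    path = marker_path(job, state_dir)
    fragment = "\n".join(
        [
            "GENFLOW_EXIT=$?",
            "if [ $GENFLOW_EXIT -eq 0 ]; then",
            f"  mkdir -p {shlex.quote(str(state_dir))}",
            f"  touch {shlex.quote(path)}",
            "fi",
        ]
    )
    return path, fragment


def _mtime(path: str) -> Optional[int]:
    """Whole-second mtime, or None when the file is absent."""
    try:
        return int(os.stat(path).st_mtime)
    except OSError:
        return None


def _under(workdir: str, path: str) -> str:
    return path if os.path.isabs(path) else os.path.join(workdir, path)


def is_up_to_date(
    job: Job,
    state_dir: str | Path,
    workdir: str | Path,
) -> tuple[bool, Optional[str]]:
    """Decide whether a previously run job can be skipped.

    Up to date iff: its marker (for the *current* digest) exists, all
    declared outputs exist, and the newest input mtime is not newer than the
    oldest output mtime. The reason names the first failed test. A marker
    left by an older command digest is reported as ``hash_changed``. Inputs
    missing from disk are ignored in the timestamp comparison — if they are
    regenerated by an upstream job, dependency propagation in
    :func:`plan_run` re-plans this job anyway.
    """
    state_dir = str(state_dir)
    workdir = str(workdir)
    marker = os.path.join(workdir, marker_path(job, state_dir)) \
        if not os.path.isabs(state_dir) else marker_path(job, state_dir)
    if not os.path.exists(marker):
        pattern = os.path.join(os.path.dirname(marker), glob.escape(job.name) + ".*.done")
        if glob.glob(pattern):
            return False, REASON_HASH_CHANGED
        return False, REASON_NO_MARKER

    out_mtimes = []
    for out in job.outputs:
        mtime = _mtime(_under(workdir, out))
        if mtime is None:
            return False, REASON_OUTPUT_MISSING
        out_mtimes.append(mtime)

    in_mtimes = [m for m in (_mtime(_under(workdir, p)) for p in job.inputs) if m is not None]
    if in_mtimes and out_mtimes and max(in_mtimes) > min(out_mtimes):
        return False, REASON_INPUTS_NEWER
    return True, None


@dataclass
class Plan:
    """Outcome of run planning: what to submit, what to skip, and why.

    ``jobs`` holds every selected job in the topological order planning saw,
    so reports can describe skipped jobs too; submit ∪ skipped covers it.
    """

    submit: list[Job] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)
    jobs: list[Job] = field(default_factory=list)

    @property
    def submit_names(self) -> set[str]:
        return {job.name for job in self.submit}

    def job(self, name: str) -> Job:
        for job in self.jobs:
            if job.name == name:
                return job
        raise KeyError(name)


def plan_run(
    jobs: list[Job],
    state_dir: str | Path,
    workdir: str | Path,
    force: bool = False,
    graph: Optional[DependencyGraph] = None,
) -> Plan:
    """Decide which jobs to (re)submit.

    ``jobs`` must be topologically ordered. A job is submitted when it is
    stale in its own right, when any of its producers is being resubmitted
    (its inputs are about to be regenerated), or when ``force`` is set.
    Everything else is skipped as up to date; consumers of skipped jobs
    read those inputs from disk, so their dependency on the skipped
    producer is considered satisfied.
    """
    plan = Plan(jobs=list(jobs))
    for job in jobs:
        producers = graph.parents(job.name) if graph is not None else job.dependencies
        if force:
            reason: Optional[str] = REASON_FORCED
        else:
            fresh, reason = is_up_to_date(job, state_dir, workdir)
            if fresh:
                reason = None
            if reason is None and any(p in plan.submit_names for p in producers):
                reason = REASON_DEPENDENCY
        if reason is None:
            plan.skipped.append((job.name, "up_to_date"))
        else:
            plan.submit.append(job)
            plan.reasons[job.name] = reason
    return plan
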