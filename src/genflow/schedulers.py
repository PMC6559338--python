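"""Scheduler back-ends: render a planned job set as executable artifacts.

Four dialects are supported:

``pbs``
    One ``qsub`` per submitted job. Each submission's job id is captured
    into a shell variable; children list their submitted parents via
    ``-W depend=afterok:...`` so the cluster releases a job only after all
    of its producers succeeded.
``slurm``
    Same shape with ``sbatch --parsable`` and ``--dependency=afterok:...``.
``batch``
    A plain serial script: commands inlined one after the other, aborting at
    the first failing job so nothing downstream of a failure runs.
``daemon``
    No execution — a JSON log of the planned run (the status report plus
    each job's fully rendered command).

Every executing job block loads the job's environment modules, runs the
command, and appends the done-marker epilogue so a marker is created only
on success. Dependencies on *skipped* (up-to-date) jobs are omitted from
``afterok`` lists: their outputs already exist on disk.
"""

from __future__ import annotations

import json
import os
import re
import shlex
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from .config import ConfigStore, get_param
from .dag import DependencyGraph
from .errors import GenFlowError
from .model import Job
from .state import Plan, command_hash, marker_contract, STATE_DIR_NAME

SCHEDULER_KINDS = ("pbs", "slurm", "batch", "daemon")

_RULE = "#" + "-" * 78


class SchedulerError(GenFlowError):
    pass


# --------------------------------------------------------------------------
# status JSON contract
# --------------------------------------------------------------------------

class StatusJob(BaseModel):
    """One job record in the status report."""

    name: str
    step: str
    command_digest: str = Field(pattern=r"^[0-9a-f]{32}$")
    inputs: list[str]
    outputs: list[str]
    dependencies: list[str]
    planned_status: str = Field(pattern=r"^(submit|skipped)$")


class StatusReport(BaseModel):
    """Status JSON written for every run; the portal-facing contract."""

    pipeline: str
    protocol: str
    generated_at: str
    jobs: list[StatusJob]


def validate_status(text: str) -> StatusReport:
    """Parse and validate a status JSON document; raises on violation."""
    return StatusReport.model_validate_json(text)


def emit_status_json(
    plan: Plan,
    graph: DependencyGraph,
    pipeline_meta: dict,
    *,
    _extra_command: bool = False,
) -> str:
    """Render the run's status report as JSON.

    ``pipeline_meta`` must carry ``pipeline`` and ``protocol`` names. Job
    order and dependency lists are deterministic (emission order); only
    ``generated_at`` varies between runs.
    """
    submit = plan.submit_names
    by_name = {job.name: job for job in plan.jobs}
    records = []
    for name in graph.emission_order:
        job = by_name[name]
        record = {
            "name": name,
            "step": job.step_name,
            "command_digest": command_hash(job),
            "inputs": list(job.inputs),
            "outputs": list(job.outputs),
            "dependencies": graph.parents(name),
            "planned_status": "submit" if name in submit else "skipped",
        }
        if _extra_command:
            record["command"] = job.command
        records.append(record)
    payload = {
        "pipeline": pipeline_meta["pipeline"],
        "protocol": pipeline_meta["protocol"],
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "jobs": records,
    }
    return json.dumps(payload, indent=2) + "\n"


# --------------------------------------------------------------------------
# script emission
# --------------------------------------------------------------------------

def _shell_var(job_name: str) -> str:
    var = re.sub(r"[^A-Za-z0-9_]", "_", job_name)
    if var and var[0].isdigit():
        var = "J_" + var
    return var


def _directives(config: ConfigStore, step_name: str) -> dict:
    """Cluster resource directives for a step, with DEFAULT fallback."""
    return {
        "walltime": get_param(config, step_name, "cluster_walltime", default="24:00:00"),
        "cpu": get_param(config, step_name, "cluster_cpu", default="1"),
        "mem": get_param(config, step_name, "cluster_mem", default="4G"),
        "queue": get_param(config, step_name, "cluster_queue"),
        "email": get_param(config, step_name, "cluster_email"),
        "mail_on": get_param(config, step_name, "cluster_mail_on", default="never"),
    }


def _module_lines(job: Job, config: ConfigStore) -> list[str]:
    if get_param(config, job.step_name, "module_system", default="environment-modules") == "none":
        return []
    return [f"module load {name}" for name in job.modules]


def _job_body(job: Job, config: ConfigStore, workdir: str) -> list[str]:
    """Shell lines shared by every executing dialect: mkdir, modules,
    command, marker epilogue."""
    out_dirs = sorted(
        {str(Path(out).parent) for out in job.outputs if str(Path(out).parent) != "."}
    )
    lines: list[str] = []
    if out_dirs:
        lines.append("mkdir -p " + " ".join(shlex.quote(d) for d in out_dirs))
    lines.extend(_module_lines(job, config))
    lines.append(job.command)
    _, epilogue = marker_contract(job, STATE_DIR_NAME)
    lines.append(epilogue)
    return lines


def _afterok_parents(
    job: Job, graph: DependencyGraph, plan: Plan
) -> list[str]:
    """Parents the scheduler must wait on: DAG parents ∩ submit set."""
    submit = plan.submit_names
    skipped = {name for name, _ in plan.skipped}
    parents = []
    for parent in graph.parents(job.name):
        if parent in submit:
            parents.append(parent)
        elif parent not in skipped:
            raise SchedulerError(
                f"job {job.name!r} depends on {parent!r}, which is neither "
                "submitted nor skipped"
            )
    return parents


def _script_header(workdir: str, meta: Optional[dict]) -> list[str]:
    lines = ["#!/bin/bash", "# generated by genflow"]
    if meta:
        lines.append(
            f"# pipeline: {meta.get('pipeline', '?')}  protocol: {meta.get('protocol', '?')}"
        )
    lines += [
        f"cd {shlex.quote(str(workdir))}",
        "export LC_ALL=C",
        f"mkdir -p {shlex.quote(STATE_DIR_NAME)}",
    ]
    return lines


def _emit_batch(plan: Plan, graph, config, workdir, meta) -> str:
    lines = _script_header(workdir, meta)
    for job in plan.submit:
        lines += [
            "",
            _RULE,
            f"# JOB: {job.name} (step {job.step_name})",
            _RULE,
            f"echo {shlex.quote('genflow: running ' + job.name)} >&2",
        ]
        lines += _job_body(job, config, workdir)
        lines += [
            "if [ $GENFLOW_EXIT -ne 0 ]; then",
            f"  echo {shlex.quote('genflow: job ' + job.name + ' failed')} >&2",
            "  exit $GENFLOW_EXIT",
            "fi",
        ]
    lines += ["", "exit 0", ""]
    return "\n".join(lines)


def _emit_hpc(kind: str, plan: Plan, graph, config, workdir, meta) -> str:
    lines = _script_header(workdir, meta)
    for job in plan.submit:
        directives = _directives(config, job.step_name)
        parents = _afterok_parents(job, graph, plan)
        var = _shell_var(job.name)

        if kind == "pbs":
            args = [
                "qsub",
                "-N", shlex.quote(job.name),
                "-l", f"walltime={directives['walltime']}",
                "-l", f"nodes=1:ppn={directives['cpu']}",
                "-l", f"mem={directives['mem']}",
            ]
            if directives["queue"]:
                args += ["-q", shlex.quote(directives["queue"])]
            if directives["email"] and directives["mail_on"] != "never":
                mail_flags = "abe" if directives["mail_on"] == "all" else "ae"
                args += ["-m", mail_flags, "-M", shlex.quote(directives["email"])]
            if parents:
                ids = ":".join(f"${_shell_var(p)}" for p in parents)
                args += ["-W", f"depend=afterok:{ids}"]
        else:  # slurm
            args = [
                "sbatch",
                "--parsable",
                f"--job-name={shlex.quote(job.name)}",
                f"--time={directives['walltime']}",
                f"--mem={directives['mem']}",
                f"--cpus-per-task={directives['cpu']}",
            ]
            if directives["queue"]:
                args += [f"--partition={shlex.quote(directives['queue'])}"]
            if directives["email"] and directives["mail_on"] != "never":
                mail_type = "ALL" if directives["mail_on"] == "all" else "FAIL"
                args += [
                    f"--mail-type={mail_type}",
                    f"--mail-user={shlex.quote(directives['email'])}",
                ]
            if parents:
                ids = ":".join(f"${_shell_var(p)}" for p in parents)
                args += [f"--dependency=afterok:{ids}"]

        body = []
        if kind == "slurm":
            body.append("#!/bin/bash")
        body.append(f"cd {shlex.quote(str(workdir))}")
        body.append("export LC_ALL=C")
        body += _job_body(job, config, workdir)
        body.append("exit $GENFLOW_EXIT")

        lines += [
            "",
            _RULE,
            f"# JOB: {job.name} (step {job.step_name})",
            _RULE,
            f"{var}=$({' '.join(args)} << 'GENFLOW_JOB'",
            *body,
            "GENFLOW_JOB",
            ")",
            f'echo "genflow: submitted {job.name} as ${var}" >&2',
        ]
    lines += ["", "exit 0", ""]
    return "\n".join(lines)


def emit_script(
    kind: str,
    plan: Plan,
    graph: DependencyGraph,
    config: ConfigStore,
    workdir: str | Path,
    pipeline_meta: Optional[dict] = None,
) -> str:
    """Render the plan in the requested scheduler dialect.

    Returns the full artifact text: a POSIX shell script for ``pbs``,
    ``slurm`` and ``batch`` (``sh -n`` clean), or a JSON log for ``daemon``.
    """
    workdir = os.path.abspath(str(workdir))
    if kind == "batch":
        return _emit_batch(plan, graph, config, workdir, pipeline_meta)
    if kind in ("pbs", "slurm"):
        return _emit_hpc(kind, plan, graph, config, workdir, pipeline_meta)
    if kind == "daemon":
        meta = pipeline_meta or {"pipeline": "?", "protocol": "?"}
        return emit_status_json(plan, graph, meta, _extra_command=True)
    raise SchedulerError(
        f"unknown scheduler kind {kind!r} (expected one of {SCHEDULER_KINDS})"
    )
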