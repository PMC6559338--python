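"""Input resolution and the job dependency DAG.

Dependencies are never declared by hand: a job depends on another exactly
when one of its input paths is among the other's declared outputs. Jobs can
therefore start as soon as their producers finish, regardless of step or
sample boundaries — on a multi-sample run this yields one independent
dependency chain per sample, each completing at its own pace.

A job may offer *ordered alternatives* for an input: a list of candidate
path-lists. The first candidate whose paths are all either already present
on disk or promised by an earlier job (the output registry) is chosen. The
on-disk branch is what makes step skipping work: outputs of steps the user
chose not to run can satisfy later steps' inputs if the files already exist.
When a path is both on disk and in the registry, the registry producer wins
and the dependency edge is created (the conservative choice: the file will
be regenerated).
"""

from __future__ import annotations

import json
import os
import posixpath
from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx

from .errors import DependencyError
from .model import Job

__all__ = [
    "normalize_path",
    "OutputRegistry",
    "resolve_input",
    "DependencyGraph",
    "build_dag",
    "topological_order",
    "downstream_set",
    "export_dag",
]


def normalize_path(path: str, workdir: str) -> str:
    """Normalize a path for identity comparison.

    Paths under ``workdir`` become workdir-relative; other absolute paths
    stay absolute. Redundant separators and ``.`` components are collapsed.
    Without this, equivalent spellings of one path would silently drop
    dependency edges.
    """
    path = os.path.normpath(path)
    if os.path.isabs(path):
        workdir = os.path.normpath(workdir)
        if path == workdir or path.startswith(workdir + os.sep):
            return os.path.relpath(path, workdir)
        return path
    return posixpath.normpath(path)


class OutputRegistry:
    """Maps each declared output path to the job that produces it.

    One producer per path: two jobs declaring the same output would make the
    dependency of any consumer ambiguous, so re-registration is an error.
    """

    def __init__(self) -> None:
        self._produced: dict[str, str] = {}

    def register(self, path: str, job_name: str) -> None:
        existing = self._produced.get(path)
        if existing is not None and existing != job_name:
            raise DependencyError(
                f"duplicate producer for output {path!r}: "
                f"{existing!r} and {job_name!r}"
            )
        self._produced[path] = job_name

    def producer(self, path: str) -> str:
        return self._produced[path]

    def __contains__(self, path: str) -> bool:
        return path in self._produced

    def __len__(self) -> int:
        return len(self._produced)


def resolve_input(
    candidates: Sequence[Sequence[str]],
    registry: OutputRegistry,
    workdir: str,
) -> list[str]:
    """Choose the first satisfiable candidate path-list.

    A candidate is satisfiable when every one of its paths is either present
    on disk (relative paths are checked under ``workdir``; the existence
    test follows symlinks) or registered as the output of an earlier job.
    """
    if not candidates:
        raise DependencyError("no input candidates given")
    failures: list[str] = []
    for candidate in candidates:
        paths = [normalize_path(p, workdir) for p in candidate]
        missing = []
        for p in paths:
            on_disk = os.path.exists(p if os.path.isabs(p) else os.path.join(workdir, p))
            if not on_disk and p not in registry:
                missing.append(p)
        if not missing:
            return paths
        failures.append(
            f"candidate {paths}: not on disk nor produced by any job: {missing}"
        )
    raise DependencyError(
        "no input candidate satisfiable:\n  " + "\n  ".join(failures)
    )


@dataclass
class DependencyGraph:
    """Jobs as nodes, producer→consumer edges, with stable emission order."""

    graph: nx.DiGraph
    emission_order: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.emission_order)

    @property
    def edges(self) -> list[tuple[str, str]]:
        index = {name: i for i, name in enumerate(self.emission_order)}
        return sorted(self.graph.edges(), key=lambda e: (index[e[0]], index[e[1]]))

    def parents(self, job_name: str) -> list[str]:
        """Direct producers of ``job_name``, in emission order."""
        self._check(job_name)
        index = {name: i for i, name in enumerate(self.emission_order)}
        return sorted(self.graph.predecessors(job_name), key=index.__getitem__)

    def _check(self, job_name: str) -> None:
        if job_name not in self.graph:
            raise DependencyError(f"unknown job {job_name!r}")


def build_dag(jobs: Sequence[Job]) -> DependencyGraph:
    """Build the dependency DAG from declared inputs and outputs alone.

    An edge ``a → b`` exists iff an output of ``a`` is an input of ``b``.
    Duplicate output producers and cycles are errors.
    """
    names = [job.name for job in jobs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DependencyError(f"duplicate job names: {dupes}")

    registry = OutputRegistry()
    for job in jobs:
        for out in job.outputs:
            registry.register(out, job.name)

    graph = nx.DiGraph()
    graph.add_nodes_from(names)
    for job in jobs:
        for inp in job.inputs:
            if inp in registry:
                producer = registry.producer(inp)
                if producer != job.name:
                    graph.add_edge(producer, job.name)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise DependencyError(f"dependency cycle: {pretty}")
    return DependencyGraph(graph=graph, emission_order=names)


def topological_order(dag: DependencyGraph) -> list[str]:
    """Topological order with ties broken by original emission order."""
    index = {name: i for i, name in enumerate(dag.emission_order)}
    return list(
        nx.lexicographical_topological_sort(dag.graph, key=index.__getitem__)
    )


def downstream_set(dag: DependencyGraph, job_name: str) -> set[str]:
    """All transitive consumers of ``job_name`` (the job itself excluded).

    This is the set of jobs that must be terminated or re-run when
    ``job_name`` fails or is invalidated.
    """
    dag._check(job_name)
    return set(nx.descendants(dag.graph, job_name))


def export_dag(dag: DependencyGraph, fmt: str) -> str:
    """Render the DAG as Graphviz DOT or as a JSON graph.

    JSON schema: ``{"nodes": [name, ...], "edges": [[from, to], ...]}`` with
    nodes in emission order and edges sorted by (producer, consumer)
    emission position.
    """
    if fmt == "dot":
        lines = ["digraph genflow {"]
        for node in dag.nodes:
            lines.append(f'  "{node}";')
        for src, dst in dag.edges:
            lines.append(f'  "{src}" -> "{dst}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "json":
        payload = {"nodes": dag.nodes, "edges": [list(e) for e in dag.edges]}
        return json.dumps(payload, indent=2) + "\n"
    raise DependencyError(f"unknown export format {fmt!r} (expected dot or json)")
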