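# genflow: methods and design notes

## Scope and object model

genflow is the *engine* layer of a pipeline system: it generates
dependency-ordered executable scripts, it does not execute or monitor
cluster jobs itself. Ordering and failure propagation are delegated to the
semantics of the emitted artifact (scheduler `afterok` directives, or the
serial batch script's abort-on-failure). There is deliberately no daemon,
lock server or database: every piece of run state is a plain file, which
makes runs inspectable and portable across shared file systems.

Four objects carry the design. A `Pipeline` maps protocol names to ordered
`Step` lists (protocols share `Step` objects, so a variant workflow reuses
the steps it does not change). A `Step` is a job factory with a scope:
READSET steps run once per readset, SAMPLE steps once per sample, COHORT
steps once per run, receiving the full sample list. A `Job` is one shell
command with declared inputs, outputs, and environment modules. Job
generation is deterministic: steps are visited in step order, entities in
sample-sheet order, so identical inputs give byte-identical job lists.

## Input resolution and the dependency DAG

Dependencies are a pure function of declared I/O: edge `a → b` iff
`outputs(a) ∩ inputs(b) ≠ ∅`. Paths are normalized before intersection
(workdir-relative where possible, separators collapsed) because two
spellings of one path would otherwise silently drop an edge. Symlinks are
followed by existence tests but paths are *not* canonicalized beyond
normalization, keeping behaviour predictable on shared file systems. Two
jobs declaring the same output path is an error at generation time — the
dependency of any consumer would be ambiguous.

A job may declare ordered input alternatives (a list of candidate
path-lists). The first candidate whose paths are all either on disk under
the working directory or registered as an earlier job's output is chosen.
When a path is both on disk and registered, the registry producer wins and
the dependency edge is created — the conservative choice, since the file is
about to be regenerated. This resolution order is monotone: adding files
never moves the choice to a later candidate.

Graph algorithms (cycle detection, descendants, topological sort) are
delegated to `networkx`; the topological order breaks ties by original
emission order so output is stable. The DOT export is rendered directly —
the graph is a plain digraph of quoted node names and needs nothing more.

## Smart relaunch

A job's completion is recorded by an empty done-marker file,
`job_state/<job>.<md5(command)>.done`, touched by the emitted script only
when the command exits 0. Embedding the digest in the file name turns "has
this exact command succeeded before?" into a file-existence test — no
marker parsing, and markers from superseded commands are simply orphaned.
Modules are rendered into the command text, so tool-version changes are
covered transitively by the digest.

Staleness tests, in order of report: marker absent (`no_marker`), marker
present only for a different digest (`hash_changed`), any declared output
missing (`output_missing` — a marker can outlive deleted outputs), or
newest input newer than oldest output (`inputs_newer`). Timestamp
comparison is whole-second with ties counting as up to date, avoiding
flapping on coarse-mtime file systems. Inputs absent from disk are ignored
in the timestamp comparison; if an upstream job regenerates them, the
dependency rule below re-plans the consumer anyway.

Planning walks the topologically ordered job list once: a job is submitted
if it is stale in its own right or any producer is being resubmitted
(`dependency_relaunched`); `force` submits everything. Consumers of
*skipped* jobs read those inputs from disk, so dependency directives on
skipped producers are dropped at emission. Consequences, verified by the
test suite: a completed run re-plans to the empty set; invalidating exactly
one job re-plans exactly that job plus its downstream closure.

## Configuration

INI files merge in the user-given order, last writer wins per key, with
per-key provenance retained. Lookups consult `[section]` then `[DEFAULT]`.
Values are literal strings — no interpolation — so rendered commands and
hence their digests are stable and auditable. A duplicate key within one
file resolves to the last occurrence (standard INI reading). Section and
key names are case-sensitive. Multi-line INI values are not supported by
the trace round-trip and are out of contract.

Cluster directives live under reserved keys (`cluster_walltime`,
`cluster_cpu`, `cluster_mem`, `cluster_queue`, `cluster_email`,
`cluster_mail_on`) in per-step sections with DEFAULT fallback; engine
defaults are 24 h, 1 CPU, 4 GiB, no queue, no mail — deliberately modest
values a scheduler will accept anywhere. The effective merged configuration
is written as `<pipeline>.config.trace.ini` (sections and keys sorted,
empty non-DEFAULT sections omitted); reloading the trace as the sole
configuration reproduces the store, and the operation is idempotent after
one application.

## Scheduler emission

All dialects share one job body: `mkdir -p` for output directories, module
loads (omitted when `module_system=none`), the command, then the marker
epilogue. PBS captures `qsub` ids into shell variables named after the
sanitized job name and passes `-W depend=afterok:$PARENT...`; SLURM uses
`sbatch --parsable` and `--dependency=afterok:...`. Job scripts are passed
on stdin via quoted here-documents so command text is never re-expanded by
the submitting shell. The batch dialect evaluates each job's exit status
explicitly (not relying on `set -e`) so markers stay trustworthy, and
aborts at the first failure — the serial analogue of dependent-job
termination. The daemon dialect only writes a JSON log (the status report
plus each rendered command); it executes nothing. Every emitted script
passes `sh -n`, and stripping dialect syntax leaves the identical ordered
command sequence in all three executing dialects.

The status JSON contract is a `pydantic` model (`StatusReport`), shipped
also as a generated JSON-schema file (`src/genflow/schemas/status_schema.json`);
a test pins the file to the model. Dependency lists in the report are the
full DAG parents (not the emission-pruned ones), matching the DAG JSON
export edge for edge.

## CLI

One executable with a pipeline subcommand (`genflow toyseq ...`) rather
than one script per pipeline — equivalent, but easier to package and
extend. Step numbering is per-protocol: when `-t` selects a protocol, `-s`
indices refer to that protocol's step list. stdout carries the emitted
script and nothing else; logs and validation failures go to stderr, and
nothing is written to stdout until validation passes. Exit codes: 0
success, 2 usage, 3 validation (including unresolvable inputs, i.e. missing
files), 4 other generation errors. Validation checks root-job inputs on
disk, referenced modules against a configured `available_modules` list
(skipped under `module_system=none`), and design/pairs sample references.

## Sample sheets

The readset file is tab-separated with columns `Sample`, `Readset`,
`RunType` (mandatory) and `FASTQ1`, `FASTQ2`, `BAM`, `Adapter1`,
`Adapter2`, `Library`, `Run`, `Lane` (optional) — the minimal metadata the
engine itself needs. A readset must carry FASTQ1 or BAM, and a paired-end
readset with FASTQ1 needs FASTQ2. Readset names are unique; each readset
belongs to exactly one sample (grouping is a partition, ordered by first
appearance). Relative paths resolve against the sheet's own directory.
Design files use one column per contrast with cells 0/1/2 =
excluded/control/case — the simplest three-valued membership encoding that
supports custom sample groupings. Pairs files are `patient,normal,tumour`
CSV rows with `normal ≠ tumour`.

## The synthetic cohort and toy pipelines

The generator emulates the *shape* of a sequencing cohort — samples,
paired readsets, 4-line FASTQ records — not its content: sequences are
random 20-mers, quality strings are constant, and "low quality" is a
literal header token (`LOWQ`, tagged on both mates at rate 0.25). The
default cohort is 2 samples × 2 readsets × 8 read pairs, the smallest
shape that exercises readset aggregation, per-sample chains and a cohort
sink; everything is deterministic for a fixed seed (default 7). To
guarantee every filter job both keeps and drops records, the first read of
each file is always kept and the second always tagged. Because filtering is
textual, all expected intermediate and final numbers are recomputable in
pure Python, which the tests use as an independent oracle.

The toy steps use only portable text utilities (`paste`/`grep`/`tr` for
record filtering, `cat`, `wc`, `grep`/`tr`/`sort`, `cksum`), with `LC_ALL=C`
exported in every script for stable sort order. The merge step falls back
from cleaned per-readset files to the raw FASTQs, and the count step from
the merged-clean file to a pre-placed `merged/<sample>.merged.raw.fastq`,
so both fallback routes of ordered-candidate resolution are exercised by
running pipeline tails (`-s 2-4`, `-s 3-4`). The count step's `wc` flag and
the clean step's marker token come from configuration, so a config edit
that reaches exactly one step's command is available for invalidation
tests. Summary keys are the per-sample count-file paths — a plain
`key<TAB>value` table derived without shell substitution.

What passing these fixtures does *not* show: behaviour with real tool
command lines (quoting complexity), very large cohorts (planning is
O(jobs × edges) and has only been exercised at desk scale), actual
scheduler round-trips (`qsub`/`sbatch` are never invoked), or clock skew
between hosts sharing a file system (timestamp staleness assumes a
consistent clock at whole-second resolution).

## Verification problem sizes

The shipped verification script (`scripts/acceptance.py`) measures on: the
2×2×8 default cohort; all 16 cohort shapes with 1–4 samples × 1–4
readsets; 100 seeded random job sets of up to 50 jobs for the DAG oracle;
20 random topological execution orders; and 20 randomized configuration
layerings. These sizes make every property exhaustive or
statistically redundant at the scale where the engine's logic lives, while
the whole script completes in seconds.
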