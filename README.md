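# genflow

A workflow engine for multi-step genomics pipelines. genflow turns a
declared pipeline (an ordered list of steps, each emitting jobs per
readset, per sample, or per cohort), a readset sample sheet, and layered
INI configuration into dependency-ordered, scheduler-specific executable
scripts — with incremental *smart relaunch* and machine-readable job-status
reports.

It is aimed at people who run multi-sample sequencing analyses on HPC
batch systems and want the script-generation layer — sample aggregation,
dependency tracking, restartability, PBS/SLURM emission — without a
resident daemon or database: all run state lives on the file system.

## The model

A **readset** is one sequencing unit (lane/library) of a sample; readsets
sharing a sample name are aggregated into **samples**. A **pipeline** holds
one or more **protocols** (step-list variants, chosen with `-t`); each
**step** is a job factory with a scope (READSET, SAMPLE, COHORT). A **job**
is a shell command with declared input and output paths.

Dependencies are never written by hand. The engine builds a directed
acyclic graph with an edge `a → b` exactly when an output of `a` is an
input of `b`, so each sample forms its own dependency chain that completes
at its own pace, converging only on cohort-scope steps. A job may declare
*ordered input alternatives*: the first candidate whose paths are all
either on disk or promised by an earlier job is chosen, which is also how
skipped steps are bridged (pre-existing files satisfy later steps).

Smart relaunch combines two tests per job:

* **command digest** — `md5(command)` is embedded in the name of an empty
  *done-marker* file touched only when the job exits 0; any parameter that
  reaches the command changes the digest and orphans the marker;
* **timestamps** — a job is stale when any declared output is missing or
  the newest input is newer than the oldest output.

Stale jobs are resubmitted together with their downstream closure; nothing
else is. `-f` forces everything.

Configuration is *superposed* INI: files given with repeated `-c` flags are
merged key by key, last writer wins, with `[DEFAULT]` as the per-key
fallback section. Every run writes the fully merged effective
configuration back out as a trace file for reproducibility.

Four scheduler back-ends render a planned run: `pbs` (one `qsub` per job,
`-W depend=afterok:` on captured ids), `slurm` (`sbatch --parsable`,
`--dependency=afterok:`), `batch` (serial script that aborts at the first
failure), and `daemon` (a JSON log of the planned run, no execution).

## Worked example

The package ships a `toyseq` pipeline driven by portable text utilities
and a deterministic synthetic-cohort generator, so the whole engine can be
exercised without any bioinformatics tools:

```python
from pathlib import Path
from genflow.toy import ToyCohort, make_toy_dataset, write_default_config

sheet = make_toy_dataset(ToyCohort(root=Path("data")))  # 2 samples x 2 readsets
write_default_config(Path("toy.ini"))
```

```console
$ genflow toyseq -c toy.ini -r data/readset.tsv -s 1-4 -o run > Commands.txt
genflow: submitting 9 of 9 jobs (0 skipped as up to date)
$ bash Commands.txt
$ cat run/summary/summary.txt
counts/s1.count.txt	88
counts/s2.count.txt	104
```

The 9 jobs are 4 per-readset `clean` jobs (drop reads tagged low-quality),
2 per-sample `merge` jobs, 2 per-sample `count` jobs and 1 cohort
`summarize` job. The summary lists, per sample, the number of FASTQ lines
(4 per read, both mates) that survived filtering — here 88 of 128 raw
lines for s1 and 104 of 128 for s2. Re-running the same command now prints
a script with zero job blocks:

```console
$ genflow toyseq -c toy.ini -r data/readset.tsv -s 1-4 -o run > Commands2.txt
genflow: all 9 jobs up to date; nothing to submit
```

Touch one readset's FASTQ and only that readset's chain (its clean job,
its sample's merge and count jobs, and the cohort summarize job — 4 of 9)
is re-planned. Each run also writes `toyseq.config.trace.ini`,
`toyseq.status.json` and DOT/JSON exports of the DAG into the output
directory; `-j pbs` or `-j slurm` emits the corresponding cluster
submission script instead of the serial one.

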