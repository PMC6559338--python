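"""Synthetic cohort generator and shipped toy pipelines.

The engine is exercised end to end with a small synthetic sequencing cohort:
``n_samples`` samples × ``readsets_per_sample`` paired readsets, each a pair
of tiny FASTQ files (4-line records) plus a readset sheet referencing them.
Generation is fully deterministic for a fixed seed.

Records are synthetic: sequences are random ACGT 20-mers and a fixed
fraction of reads is tagged low-quality by the token ``LOWQ`` in the header
of both mates. "Quality filtering" in the toy pipeline is then a pure
textual rule — drop records whose header carries the token — so every
expected intermediate and final number is computable independently in
tests. To keep each run informative, the first read of every file is always
kept and the second is always tagged (files have at least two reads in the
default configuration), so every filter job both keeps and drops something.

The ``toyseq`` pipeline has two protocols sharing step objects:

========  ===========  =======  =================================================
step      name         scope    action (portable text utilities only)
========  ===========  =======  =================================================
1         clean        READSET  drop LOWQ records (paste/grep/tr round trip)
2         merge        SAMPLE   concatenate the sample's cleaned mates
3         count        SAMPLE   line-count the merged file (wc)
4         summarize    COHORT   per-sample counts as ``key<TAB>value`` lines
5         checksum     COHORT   cksum of the summary (``extended`` protocol only)
========  ===========  =======  =================================================

Steps 2 and 3 declare *ordered input alternatives*: the merge step falls
back from cleaned per-readset files to the raw FASTQs, and the count step
falls back from the merged-clean file to a pre-placed ``merged/*.raw``
file. Running a tail of the pipeline (e.g. steps 2-4 or 3-4) therefore
succeeds whenever the fallback files exist on disk.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .config import get_param
from .model import Job, Pipeline, Readset, Sample, Scope, Step

#: Header token marking a record for removal by the clean step.
LOWQ_TOKEN = "LOWQ"

#: Fraction of reads tagged low-quality by the generator.
LOWQ_RATE = 0.25

READ_LENGTH = 20


@dataclass
class ToyCohort:
    """Parameters of a synthetic cohort; deterministic for a fixed seed."""

    root: Path
    n_samples: int = 2
    readsets_per_sample: int = 2
    reads_per_file: int = 8
    seed: int = 7


def _write_fastq(path: Path, readset: str, mate: int, flags: list[bool], rng: random.Random) -> None:
    records = []
    for i, low in enumerate(flags):
        tag = LOWQ_TOKEN if low else "OK"
        seq = "".join(rng.choice("ACGT") for _ in range(READ_LENGTH))
        records += [
            f"@{readset}:read{i:03d}/{mate} {tag}",
            seq,
            "+",
            "I" * READ_LENGTH,
        ]
    path.write_text("\n".join(records) + "\n")


def make_toy_dataset(cohort: ToyCohort) -> Path:
    """Generate the cohort under ``cohort.root``; returns the readset sheet path.

    Layout: ``raw/<readset>.R1.fastq`` / ``.R2.fastq`` pairs and a
    ``readset.tsv`` referencing them by relative path. Both mates of a read
    share the same quality flag so mate files stay record-aligned after
    filtering.
    """
    root = Path(cohort.root)
    raw = root / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cohort.seed)

    rows = ["\t".join(("Sample", "Readset", "RunType", "FASTQ1", "FASTQ2", "Library"))]
    for s in range(1, cohort.n_samples + 1):
        sample = f"s{s}"
        for r in range(1, cohort.readsets_per_sample + 1):
            readset = f"{sample}_r{r}"
            flags = [rng.random() < LOWQ_RATE for _ in range(cohort.reads_per_file)]
            if flags:
                flags[0] = False
            if len(flags) > 1:
                flags[1] = True
            fq1 = raw / f"{readset}.R1.fastq"
            fq2 = raw / f"{readset}.R2.fastq"
            _write_fastq(fq1, readset, 1, flags, rng)
            _write_fastq(fq2, readset, 2, flags, rng)
            rows.append(
                "\t".join(
                    (
                        sample,
                        readset,
                        "PAIRED_END",
                        str(fq1.relative_to(root)),
                        str(fq2.relative_to(root)),
                        f"lib_{readset}",
                    )
                )
            )
    sheet = root / "readset.tsv"
    sheet.write_text("\n".join(rows) + "\n")
    return sheet


def write_default_config(path: Path) -> Path:
    """Write the configuration the toy pipeline runs with out of the box."""
    path = Path(path)
    path.write_text(
        "\n".join(
            [
                "[DEFAULT]",
                "module_system=none",
                "cluster_walltime=01:00:00",
                "cluster_cpu=1",
                "cluster_mem=2G",
                "",
                "[clean]",
                f"marker={LOWQ_TOKEN}",
                "",
                "[merge]",
                "cat_options=",
                "",
                "[count]",
                "wc_flag=-l",
                "",
            ]
        )
    )
    return path


# --------------------------------------------------------------------------
# toy pipeline paths (relative to the working directory)
# --------------------------------------------------------------------------

def clean_output(readset: Readset, mate: int) -> str:
    return f"clean/{readset.name}.R{mate}.clean.fastq"


def merged_clean(sample: Sample) -> str:
    return f"merged/{sample.name}.merged.clean.fastq"


def merged_raw(sample: Sample) -> str:
    """Pre-placed alternative input for the count step (never produced by a
    toy step; exists only if the user supplies it)."""
    return f"merged/{sample.name}.merged.raw.fastq"


def count_output(sample: Sample) -> str:
    return f"counts/{sample.name}.count.txt"


SUMMARY = "summary/summary.txt"
SUMMARY_CKSUM = "summary/summary.cksum.txt"


# --------------------------------------------------------------------------
# step factories
# --------------------------------------------------------------------------

def _q(path: str) -> str:
    return "'" + path + "'"


def _clean_factory(readset: Readset, config, resolve) -> list[Job]:
    inputs = resolve([[readset.fastq1, readset.fastq2]])
    marker = get_param(config, "clean", "marker", default=LOWQ_TOKEN)
    outputs = [clean_output(readset, 1), clean_output(readset, 2)]
    parts = []
    for src, dst in zip(inputs, outputs):
        # linearize 4-line records, drop marked ones, restore line structure
        parts.append(
            f"paste - - - - < {_q(src)} | grep -v {_q(marker)} | tr '\\t' '\\n' > {_q(dst)}"
        )
    return [
        Job(
            name=f"clean.{readset.name}",
            step_name="clean",
            command=" && ".join(parts),
            inputs=inputs,
            outputs=outputs,
        )
    ]


def _merge_factory(sample: Sample, config, resolve) -> list[Job]:
    cleaned = [clean_output(rs, mate) for rs in sample.readsets for mate in (1, 2)]
    raw = [p for rs in sample.readsets for p in (rs.fastq1, rs.fastq2)]
    inputs = resolve([cleaned, raw])
    out = merged_clean(sample)
    options = get_param(config, "merge", "cat_options", default="")
    tokens = ["cat", options, *(_q(p) for p in inputs)]
    command = " ".join(t for t in tokens if t) + f" > {_q(out)}"
    return [
        Job(
            name=f"merge.{sample.name}",
            step_name="merge",
            command=command,
            inputs=inputs,
            outputs=[out],
        )
    ]


def _count_factory(sample: Sample, config, resolve) -> list[Job]:
    inputs = resolve([[merged_clean(sample)], [merged_raw(sample)]])
    out = count_output(sample)
    flag = get_param(config, "count", "wc_flag", default="-l")
    return [
        Job(
            name=f"count.{sample.name}",
            step_name="count",
            command=f"wc {flag} < {_q(inputs[0])} > {_q(out)}",
            inputs=inputs,
            outputs=[out],
        )
    ]


def _summarize_factory(samples: list[Sample], config, resolve) -> list[Job]:
    inputs = resolve([[count_output(s) for s in samples]])
    # grep '' with /dev/null forces the file-name prefix even for a single
    # sample; tr turns "path:count" into "path<TAB>count"
    files = " ".join(_q(p) for p in inputs)
    command = f"grep '' {files} /dev/null | tr ':' '\\t' | sort > {_q(SUMMARY)}"
    return [
        Job(
            name="summarize.cohort",
            step_name="summarize",
            command=command,
            inputs=inputs,
            outputs=[SUMMARY],
        )
    ]


def _checksum_factory(samples: list[Sample], config, resolve) -> list[Job]:
    inputs = resolve([[SUMMARY]])
    return [
        Job(
            name="checksum.cohort",
            step_name="checksum",
            command=f"cksum {_q(inputs[0])} > {_q(SUMMARY_CKSUM)}",
            inputs=inputs,
            outputs=[SUMMARY_CKSUM],
        )
    ]


_BASIC_STEPS = [
    Step("clean", 1, Scope.READSET, _clean_factory),
    Step("merge", 2, Scope.SAMPLE, _merge_factory),
    Step("count", 3, Scope.SAMPLE, _count_factory),
    Step("summarize", 4, Scope.COHORT, _summarize_factory),
]

_EXTENDED_STEPS = _BASIC_STEPS + [Step("checksum", 5, Scope.COHORT, _checksum_factory)]

TOY_PROTOCOLS = ("basic", "extended")


def build_toy_pipeline(protocol: str = "basic") -> Pipeline:
    """Build the ``toyseq`` pipeline with ``protocol`` as the default.

    Both protocols share the first four Step objects — the extended protocol
    reuses them and appends a cohort checksum step.
    """
    if protocol not in TOY_PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol!r}; available: {list(TOY_PROTOCOLS)}"
        )
    return Pipeline(
        name="toyseq",
        protocols={"basic": _BASIC_STEPS, "extended": _EXTENDED_STEPS},
        default_protocol=protocol,
    )
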