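"""Sample-sheet parsing, grouping, and job generation."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import given, strategies as st

from genflow.config import load_config
from genflow.errors import FormatError, GenerationError
from genflow.model import (
    Readset,
    RunType,
    generate_jobs,
    group_samples,
    load_design,
    load_pairs,
    load_readsets,
)
from genflow.toy import build_toy_pipeline

from conftest import make_toy_run


def write_sheet(path: Path, rows: list[dict], columns=None) -> Path:
    columns = columns or ["Sample", "Readset", "RunType", "FASTQ1", "FASTQ2", "BAM"]
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(row.get(c, "") for c in columns))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadReadsets:
    def test_file_order_preserved(self, toy):
        readsets = load_readsets(toy.sheet)
        assert [rs.name for rs in readsets] == ["s1_r1", "s1_r2", "s2_r1", "s2_r2"]
        assert all(Path(rs.fastq1).is_absolute() for rs in readsets)

    # validity rule, enumerated independently over all file-presence
    # combinations: a readset needs fastq1 or bam, and a paired-end readset
    # with fastq1 also needs fastq2
    @pytest.mark.parametrize("run_type", ["PAIRED_END", "SINGLE_END"])
    @pytest.mark.parametrize("fq1", [False, True])
    @pytest.mark.parametrize("fq2", [False, True])
    @pytest.mark.parametrize("bam", [False, True])
    def test_field_presence_combinations(self, tmp_path, run_type, fq1, fq2, bam):
        row = {"Sample": "s1", "Readset": "r1", "RunType": run_type}
        if fq1:
            row["FASTQ1"] = "a.R1.fastq"
        if fq2:
            row["FASTQ2"] = "a.R2.fastq"
        if bam:
            row["BAM"] = "a.bam"
        sheet = write_sheet(tmp_path / "rs.tsv", [row])
        valid = (fq1 or bam) and not (run_type == "PAIRED_END" and fq1 and not fq2)
        if valid:
            (rs,) = load_readsets(sheet)
            assert rs.run_type is RunType(run_type)
        else:
            with pytest.raises(FormatError):
                load_readsets(sheet)

    def test_bam_route_without_fastq2(self, tmp_path):
        # paired-end metadata with only a BAM is a valid starting point
        sheet = write_sheet(
            tmp_path / "rs.tsv",
            [{"Sample": "s1", "Readset": "r1", "RunType": "PAIRED_END", "BAM": "a.bam"}],
        )
        (rs,) = load_readsets(sheet)
        assert rs.bam is not None and rs.fastq1 is None

    @pytest.mark.parametrize(
        "rows, message",
        [
            ([], "no readsets"),
            (
                [
                    {"Sample": "s1", "Readset": "r1", "RunType": "SINGLE_END", "BAM": "a"},
                    {"Sample": "s2", "Readset": "r1", "RunType": "SINGLE_END", "BAM": "b"},
                ],
                "duplicate readset",
            ),
            (
                [{"Sample": "s1", "Readset": "r1", "RunType": "nonsense", "BAM": "a"}],
                "invalid RunType",
            ),
        ],
    )
    def test_malformed_sheets(self, tmp_path, rows, message):
        sheet = write_sheet(tmp_path / "rs.tsv", rows)
        with pytest.raises(FormatError, match=message):
            load_readsets(sheet)

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "rs.tsv"
        path.write_text("Sample\tReadset\ns1\tr1\n")
        with pytest.raises(FormatError, match="RunType"):
            load_readsets(path)

    def test_unknown_column_warns_but_loads(self, tmp_path, caplog):
        sheet = write_sheet(
            tmp_path / "rs.tsv",
            [{"Sample": "s1", "Readset": "r1", "RunType": "SINGLE_END",
              "FASTQ1": "a.fastq", "Mystery": "x"}],
            columns=["Sample", "Readset", "RunType", "FASTQ1", "Mystery"],
        )
        with caplog.at_level("WARNING"):
            assert len(load_readsets(sheet)) == 1
        assert "Mystery" in caplog.text


class TestGroupSamples:
    def _readset(self, sample: str, name: str) -> Readset:
        return Readset(name=name, sample_name=sample,
                       run_type=RunType.SINGLE_END, fastq1=f"{name}.fastq")

    def test_order_of_first_appearance(self):
        readsets = [self._readset("s1", "r1"), self._readset("s2", "r2"),
                    self._readset("s1", "r3")]
        samples = group_samples(readsets)
        assert [s.name for s in samples] == ["s1", "s2"]
        assert [rs.name for rs in samples[0].readsets] == ["r1", "r3"]

    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=30))
    def test_grouping_is_a_partition(self, sample_ids):
        readsets = [self._readset(f"s{sid}", f"r{i}") for i, sid in enumerate(sample_ids)]
        samples = group_samples(readsets)
        # every readset in exactly one sample, sizes add up
        assert sum(len(s.readsets) for s in samples) == len(readsets)
        seen = [rs.name for s in samples for rs in s.readsets]
        assert len(set(seen)) == len(readsets)
        # order by first appearance; per-sample readsets keep file order
        first_seen = list(dict.fromkeys(f"s{sid}" for sid in sample_ids))
        assert [s.name for s in samples] == first_seen
        for sample in samples:
            indices = [int(rs.name[1:]) for rs in sample.readsets]
            assert indices == sorted(indices)


class TestDesignAndPairs:
    def test_contrast_cells(self, tmp_path):
        path = tmp_path / "design.tsv"
        path.write_text(
            "Sample\tKOvsWT\ns1\t1\ns2\t1\ns3\t2\ns4\t2\n"
        )
        (contrast,) = load_design(path, ["s1", "s2", "s3", "s4"])
        assert contrast.name == "KOvsWT"
        assert contrast.controls == ["s1", "s2"]
        assert contrast.cases == ["s3", "s4"]

    def test_all_zero_column_warns(self, tmp_path, caplog):
        path = tmp_path / "design.tsv"
        path.write_text("Sample\tC1\ns1\t0\ns2\t0\n")
        with caplog.at_level("WARNING"):
            (contrast,) = load_design(path, ["s1", "s2"])
        assert contrast.controls == [] and contrast.cases == []
        assert "C1" in caplog.text

    def test_invalid_cell_and_unknown_sample(self, tmp_path):
        path = tmp_path / "design.tsv"
        path.write_text("Sample\tC1\ns1\t3\n")
        with pytest.raises(FormatError, match="row 2.*C1"):
            load_design(path, ["s1"])
        path.write_text("Sample\tC1\nghost\t1\n")
        with pytest.raises(FormatError, match="ghost"):
            load_design(path, ["s1"])

    def test_pairs(self, tmp_path):
        path = tmp_path / "pairs.csv"
        path.write_text("p1,p1N,p1T\n")
        (pair,) = load_pairs(path)
        assert (pair.patient, pair.normal, pair.tumour) == ("p1", "p1N", "p1T")

        path.write_text("p1,p1N\n")
        with pytest.raises(FormatError, match="3 fields"):
            load_pairs(path)

        path.write_text("p1,a,a\n")
        with pytest.raises(FormatError, match="normal equals tumour"):
            load_pairs(path)


class TestGenerateJobs:
    def _jobs(self, run, steps=(1, 2, 3, 4), protocol="basic"):
        pipeline = build_toy_pipeline(protocol)
        samples = group_samples(load_readsets(run.sheet))
        config = load_config([run.config])
        run.workdir.mkdir(parents=True, exist_ok=True)
        return generate_jobs(pipeline, protocol, list(steps), samples, config, run.workdir)

    def test_two_by_two_yields_nine_jobs(self, toy):
        jobs = self._jobs(toy)
        assert len(jobs) == 9
        # step-by-step emission, entity order within steps
        assert [j.name for j in jobs] == [
            "clean.s1_r1", "clean.s1_r2", "clean.s2_r1", "clean.s2_r2",
            "merge.s1", "merge.s2", "count.s1", "count.s2", "summarize.cohort",
        ]

    @pytest.mark.parametrize("n_samples", [1, 3])
    @pytest.mark.parametrize("n_readsets", [1, 4])
    def test_job_count_formula(self, tmp_path, n_samples, n_readsets):
        # one readset-scope step + two sample-scope steps + one cohort step
        run = make_toy_run(tmp_path, n_samples=n_samples,
                           readsets_per_sample=n_readsets, reads_per_file=4)
        jobs = self._jobs(run)
        assert len(jobs) == n_samples * n_readsets + 2 * n_samples + 1

    def test_single_step_selection_has_no_dependencies(self, toy):
        jobs = self._jobs(toy, steps=(1,))
        assert len(jobs) == 4
        assert all(job.dependencies == [] for job in jobs)

    def test_empty_sample_list_is_an_error(self, toy):
        pipeline = build_toy_pipeline()
        config = load_config([toy.config])
        with pytest.raises(GenerationError, match="no samples"):
            generate_jobs(pipeline, "basic", [1], [], config, toy.workdir)

    def test_generation_is_deterministic(self, toy):
        first = self._jobs(toy)
        second = self._jobs(toy)
        assert [(j.name, j.command, j.inputs, j.outputs, j.dependencies) for j in first] \
            == [(j.name, j.command, j.inputs, j.outputs, j.dependencies) for j in second]

    def test_dependencies_derived_from_io(self, toy):
        jobs = self._jobs(toy)
        by_name = {j.name: j for j in jobs}
        assert by_name["merge.s1"].dependencies == ["clean.s1_r1", "clean.s1_r2"]
        assert by_name["count.s2"].dependencies == ["merge.s2"]
        assert by_name["summarize.cohort"].dependencies == ["count.s1", "count.s2"]
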