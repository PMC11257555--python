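"""Fixture generator determinism and the end-to-end pipeline + CLI."""

import filecmp
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from pedcns.cli import main
from pedcns.fixtures import generate_cohort
from pedcns.pipeline import run_pipeline

from conftest import read_tsv


class TestGeneratorDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        generate_cohort(tmp_path / "a", seed=3)
        generate_cohort(tmp_path / "b", seed=3)
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_truth_table_covers_all_events(self, cohort_dir):
        truth = cohort_dir.truth
        assert len(truth) == len(cohort_dir.plans)
        assert truth["tumor_event_id"].is_unique


class TestPipelineEndToEnd:
    def test_subtype_recovery_matches_truth(self, cohort_dir, pipeline_out):
        out, _ = pipeline_out
        subtypes = read_tsv(out / "subtypes.tsv")
        merged = cohort_dir.truth.merge(subtypes, on="tumor_event_id")
        assert len(merged) == len(cohort_dir.truth)
        assert (merged["expected_subtype"] == merged["molecular_subtype"]).all()

    def test_consensus_counts_match_generator_tally(self, cohort_dir, pipeline_out):
        out, _ = pipeline_out
        consensus = read_tsv(out / "consensus_snv.maf.tsv")
        counts = consensus.groupby("Tumor_Sample_Barcode").size()
        for row in cohort_dir.truth.itertuples():
            assert counts.get(row.sample_id, 0) == row.expected_consensus_n

    def test_tmb_matches_brute_force_tally(self, cohort_dir, pipeline_out):
        out, _ = pipeline_out
        tmb = read_tsv(out / "tmb.tsv").set_index("sample_id")
        checked = 0
        for row in cohort_dir.truth.itertuples():
            if row.expected_tmb_all == "":
                continue
            assert tmb.loc[row.sample_id, "tmb_all_per_mb"] == float(row.expected_tmb_all)
            assert tmb.loc[row.sample_id, "tmb_coding_per_mb"] == float(
                row.expected_tmb_coding
            )
            checked += 1
        assert checked > 50

    def test_gene_status_fully_resolved(self, pipeline_out):
        out, _ = pipeline_out
        gene_status = read_tsv(out / "gene_status.tsv")
        assert not gene_status.duplicated(["sample_id", "gene"]).any()

    def test_rerun_is_byte_identical(self, cohort_dir, pipeline_out, tmp_path):
        out1, _ = pipeline_out
        out2 = tmp_path / "rerun"
        run_pipeline(cohort_dir.directory, out2)
        for path in sorted(Path(out1).iterdir()):
            assert (out2 / path.name).read_bytes() == path.read_bytes(), path.name

    def test_manifest_records_stages_and_inputs(self, pipeline_out):
        _, manifest = pipeline_out
        assert manifest["stages"]["consensus_snv"]["out"] > 0
        assert manifest["stages"]["subtype"]["out"] > 0
        assert "histologies.tsv" in manifest["inputs"]


class TestCli:
    def test_make_fixtures_and_run_pipeline(self, tmp_path):
        runner = CliRunner()
        fixtures = tmp_path / "fx"
        result = runner.invoke(
            main, ["make-fixtures", "--out", str(fixtures), "--seed", "2"]
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            main,
            ["run-pipeline", "--input-dir", str(fixtures),
             "--out-dir", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        subtypes = read_tsv(tmp_path / "out" / "subtypes.tsv")
        truth = read_tsv(fixtures / "truth.tsv")
        merged = truth.merge(subtypes, on="tumor_event_id")
        assert (merged["expected_subtype"] == merged["molecular_subtype"]).all()

    def test_consensus_snv_subcommand(self, cohort_dir, tmp_path):
        runner = CliRunner()
        d = cohort_dir.directory
        out = tmp_path / "consensus.maf.tsv"
        result = runner.invoke(
            main,
            ["consensus-snv",
             "--strelka2", str(d / "strelka2.maf.tsv"),
             "--mutect2", str(d / "mutect2.maf.tsv"),
             "--lancet", str(d / "lancet.maf.tsv"),
             "--vardict", str(d / "vardict.maf.tsv"),
             "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert len(read_tsv(out)) == cohort_dir.truth["expected_consensus_n"].sum()

    def test_independent_samples_subcommand(self, cohort_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "ids.txt"
        result = runner.invoke(
            main,
            ["independent-samples",
             "--histologies", str(cohort_dir.directory / "histologies.tsv"),
             "--strategy", "WGS", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        ids = out.read_text().split()
        assert len(ids) == len(set(ids)) > 0
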