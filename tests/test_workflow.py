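"""End-to-end pair analysis, configuration, CLI plumbing."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from episeq import (
    AnalysisConfig,
    DataError,
    ParameterError,
    SimParams,
    analyze_pair,
    generate_paired_perturbation,
    generate_phase_gene_sets,
    run_pair_analysis,
    run_recovery_suite,
    write_de_table,
)
from episeq.cli import main as cli_main
from conftest import make_de_table


def _synthetic_inputs(tmp_path, seed=0, f=0.43, noise_sd=0.2):
    params = SimParams(
        n_genes=400, regulon_fraction=0.25, attenuation_f=f, noise_sd=noise_sd, seed=seed
    )
    down, up, truth = generate_paired_perturbation(params)
    write_de_table(down, tmp_path / "down.tsv")
    write_de_table(up, tmp_path / "up.tsv")
    coll, _ = generate_phase_gene_sets(5, 20, 0.0, list(down.data["gene"]), seed=seed)
    coll.to_gmt(tmp_path / "phases.gmt")
    return params, truth


class TestAnalyzePair:
    def test_noiseless_full_strength_pair_recovers_identity(self):
        params = SimParams(
            n_genes=300,
            attenuation_f=1.0,
            noise_sd=1e-9,
            noise_mode="both",
            seed=1,
        )
        down, up, truth = generate_paired_perturbation(params)
        # on the planted regulon the two tables coincide exactly
        from episeq import attenuation_fit, merge_by_gene, spearman_rho

        merged = merge_by_gene(down, up)
        fit = attenuation_fit(
            merged, truth.regulon_genes, response="upstream", predictor="downstream"
        )
        assert fit.beta_upstream == pytest.approx(1.0, abs=1e-6)
        sub = merged.data[merged.data["gene"].isin(truth.regulon_genes)]
        assert spearman_rho(
            sub["log2fc_downstream"], sub["log2fc_upstream"]
        ) == pytest.approx(1.0, abs=1e-6)
        # the padj-driven report path still runs end to end
        report = analyze_pair(down, up, select_by="downstream", n_iter=500, seed=1)
        assert report["attenuation"]["beta_upstream"] == pytest.approx(1.0, abs=0.05)

    def test_disjoint_tables_error_names_merge(self):
        a = make_de_table(["g1", "g2"], [1, 2], label="A")
        b = make_de_table(["g3", "g4"], [1, 2], label="B")
        with pytest.raises(DataError, match="zero genes"):
            analyze_pair(a, b, select_by="B")

    def test_counts_traceable_through_stages(self):
        params = SimParams(n_genes=500, seed=2)
        down, up, _ = generate_paired_perturbation(params)
        report = analyze_pair(down, up, select_by="downstream", n_iter=200, seed=2)
        c = report["counts"]
        assert c["n_merged"] == 500
        assert c["n_selected"] <= c["n_merged"]
        assert report["attenuation"]["n"] == c["n_selected"]


class TestRunPairAnalysis:
    def test_report_is_byte_identical_across_runs(self, tmp_path):
        _synthetic_inputs(tmp_path, seed=3)
        cfg = dict(
            de_a=str(tmp_path / "up.tsv"),
            de_b=str(tmp_path / "down.tsv"),
            label_a="upstream",
            label_b="downstream",
            phase_sets=str(tmp_path / "phases.gmt"),
            select_by="downstream",
            n_iter=500,
            seed=7,
        )
        run_pair_analysis(AnalysisConfig(**cfg, outdir=str(tmp_path / "o1")))
        run_pair_analysis(AnalysisConfig(**cfg, outdir=str(tmp_path / "o2")))
        r1 = (tmp_path / "o1" / "report.json").read_bytes()
        r2 = (tmp_path / "o2" / "report.json").read_bytes()
        # provenance embeds outdir; numeric payloads must be identical
        d1, d2 = json.loads(r1), json.loads(r2)
        d1["provenance"]["config"].pop("outdir")
        d2["provenance"]["config"].pop("outdir")
        d1["provenance"].pop("config_digest")
        d2["provenance"].pop("config_digest")
        assert json.dumps(d1, sort_keys=True) == json.dumps(d2, sort_keys=True)

    def test_identical_config_identical_bytes(self, tmp_path):
        _synthetic_inputs(tmp_path, seed=4)
        cfg = AnalysisConfig(
            de_a=str(tmp_path / "up.tsv"),
            de_b=str(tmp_path / "down.tsv"),
            label_a="upstream",
            label_b="downstream",
            select_by="downstream",
            n_iter=500,
            seed=5,
            outdir=str(tmp_path / "out"),
        )
        run_pair_analysis(cfg)
        first = (tmp_path / "out" / "report.json").read_bytes()
        run_pair_analysis(cfg)
        second = (tmp_path / "out" / "report.json").read_bytes()
        assert first == second

    def test_config_from_toml(self, tmp_path):
        (tmp_path / "cfg.toml").write_text(
            'de_a = "a.tsv"\nde_b = "b.tsv"\nselect_by = "B"\nalpha = 0.01\n'
        )
        cfg = AnalysisConfig.from_toml(tmp_path / "cfg.toml")
        assert cfg.alpha == 0.01
        assert cfg.n_iter == 100_000  # printed default preserved

    def test_unknown_config_key_rejected(self, tmp_path):
        (tmp_path / "cfg.toml").write_text('de_a = "a"\nde_b = "b"\ntypo_key = 1\n')
        with pytest.raises(ParameterError, match="typo_key"):
            AnalysisConfig.from_toml(tmp_path / "cfg.toml")


class TestRecoverySuite:
    def test_single_rep_single_row(self):
        table = run_recovery_suite([0.5], n_reps=1, n_genes=200, n_iter_concord=200, seed=0)
        assert len(table) == 1
        assert {"slope_mean", "ci_coverage", "phase_type1_rate"} <= set(table.columns)

    def test_n_reps_floor(self):
        with pytest.raises(ParameterError):
            run_recovery_suite([0.5], n_reps=0)

    def test_slope_tracks_planted_attenuation(self):
        table = run_recovery_suite(
            [0.3, 1.0], n_reps=5, n_genes=400, n_iter_concord=200, seed=1
        )
        slopes = dict(zip(table["attenuation_f"], table["slope_mean"]))
        assert slopes[1.0] > slopes[0.3]
        assert abs(slopes[0.3] - 0.3) < 0.1


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            cli_main, ["simulate", "--seed", "3", "--outdir", str(tmp_path / "sim")]
        )
        assert sim.exit_code == 0, sim.output
        (tmp_path / "cfg.toml").write_text(
            f'de_a = "{tmp_path / "sim" / "upstream.tsv"}"\n'
            f'de_b = "{tmp_path / "sim" / "downstream.tsv"}"\n'
            'label_a = "upstream"\nlabel_b = "downstream"\n'
            'select_by = "downstream"\nn_iter = 500\nseed = 3\n'
            f'outdir = "{tmp_path / "out"}"\n'
        )
        res = runner.invoke(cli_main, ["run", "--config", str(tmp_path / "cfg.toml")])
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "out" / "report.json").read_text())
        slope = report["attenuation"]["beta_upstream"]
        assert 0.3 < slope < 0.6  # planted default f = 0.43

    def test_edu_verb(self, tmp_path):
        (tmp_path / "counts.csv").write_text(
            "group,edu_pos,edu_neg\nWT,40,60\nStra8KO,20,80\nMeiocKO,45,55\ndKO,35,65\n"
        )
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["edu", "--counts", str(tmp_path / "counts.csv"), "--out", str(tmp_path / "edu.tsv")],
        )
        assert res.exit_code == 0, res.output
        assert "6 pairs" in res.output

    def test_input_error_exit_code(self, tmp_path):
        (tmp_path / "a.tsv").write_text("gene\tlog2fc\tpadj\ng1\t1\t0.1\n")
        (tmp_path / "b.tsv").write_text("gene\tlog2fc\tpadj\ng2\t1\t0.1\n")
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            [
                "overlap",
                "--de-a", str(tmp_path / "a.tsv"),
                "--de-b", str(tmp_path / "b.tsv"),
                "--direction", "up",
                "--out", str(tmp_path / "o.tsv"),
            ],
        )
        assert res.exit_code == 2


class TestPlots:
    def test_figures_render_to_files(self, tmp_path):
        from episeq import merge_by_gene, phase_enrichment
        from episeq.concordance import attenuation_fit
        from episeq.plots import concordance_scatter, phase_dot_whisker

        down, up, truth = generate_paired_perturbation(SimParams(n_genes=300, seed=6))
        coll, _ = generate_phase_gene_sets(3, 15, 0.0, list(down.data["gene"]), seed=6)
        results = phase_enrichment(down, coll)
        phase_dot_whisker(results, str(tmp_path / "phase.png"))
        merged = merge_by_gene(down, up)
        fit = attenuation_fit(
            merged, truth.regulon_genes, response="upstream", predictor="downstream"
        )
        concordance_scatter(merged, set(truth.regulon_genes), fit, str(tmp_path / "sc.png"))
        assert (tmp_path / "phase.png").stat().st_size > 0
        assert (tmp_path / "sc.png").stat().st_size > 0
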