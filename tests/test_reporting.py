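"""Config validation, pipeline artifacts, determinism and report plots."""

import numpy as np
import pandas as pd
import pytest

from screenopt.config import DEFAULT_CONFIG, load_config, parameter_pool, save_config
from screenopt.dataset import generate_dataset, write_dataset
from screenopt.pipeline import candidate_seed, run_pipeline
from screenopt.report import (
    plot_heatmap,
    plot_histogram_with_threshold,
    render_report,
)

SMALL_CONFIG = {
    "seed": 11,
    "parameters": {
        "electrostatic_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 3},
        "desolvation_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 3},
    },
    "matching_spheres_perturbation": {"radius": 0.4, "counts_per_step": [2, 3]},
    "search": {"n_steps": 2, "max_beam_width": 2},
    "significance": {"null_reps": 3000, "p_value": 0.05},
    "report": {"top_k": 2},
}


@pytest.fixture(scope="module")
def dataset():
    return generate_dataset(n_pos=8, ratio=12, n_clusters=2, seed=50)


@pytest.fixture(scope="module")
def completed_run(dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    result = run_pipeline(SMALL_CONFIG, dataset, out)
    return result


class TestConfig:
    def test_defaults_materialized(self):
        cfg = load_config(None)
        assert cfg["significance"]["p_value"] == 0.01
        assert cfg["matching_spheres_perturbation"]["counts_per_step"] == [10, 25, 50]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            load_config({"serach": {}})
        with pytest.raises(ValueError, match="unknown config key"):
            load_config({"search": {"top_fractoin": 0.1}})

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            load_config({"search": {"mode": "random"}})
        with pytest.raises(ValueError):
            load_config({"significance": {"p_value": 0.0}})

    def test_parameter_pool_forms(self):
        assert parameter_pool("x", {"values": [1, 2]}) == ("numeric", [1.0, 2.0])
        assert parameter_pool("x", {"choices": ["a"]}) == ("categorical", ["a"])
        kind, pool = parameter_pool("x", {"low": 0.0, "high": 1.0, "n": 3})
        assert kind == "numeric" and pool == [0.0, 0.5, 1.0]
        with pytest.raises(ValueError):
            parameter_pool("x", {"bogus": 1})

    def test_yaml_roundtrip(self, tmp_path):
        cfg = load_config({"seed": 3})
        f = tmp_path / "cfg.yaml"
        save_config(cfg, f)
        assert load_config(f) == cfg


class TestPipelineArtifacts:
    def test_all_artifacts_present(self, completed_run):
        out = completed_run.out_dir
        for name in ("results.csv", "effective-config.yaml", "report.html",
                     "screenopt.log"):
            assert (out / name).exists(), name
        assert (out / "best_retrodock_jobs" / "rank_1" / "scores.csv").exists()
        assert (out / "working").is_dir()

    def test_results_rows_match_history_and_ids_unique(self, completed_run):
        df = completed_run.results
        assert len(df) == completed_run.n_evaluated
        assert df["id"].is_unique

    def test_best_retrodock_jobs_hold_top_ranked_ids(self, completed_run):
        import json

        out = completed_run.out_dir
        df = completed_run.results
        ok = df[df["status"] == "ok"].sort_values(
            ["criterion_value", "id"], ascending=[False, True]
        )
        expected = ok["id"].head(2).tolist()
        stored = [
            json.loads((out / "best_retrodock_jobs" / f"rank_{k}" / "dockfiles.txt")
                       .read_text())["id"]
            for k in (1, 2)
        ]
        assert stored == expected

    def test_working_dir_indexed_by_results(self, completed_run):
        out = completed_run.out_dir
        for pid in completed_run.results["id"].head(10):
            assert (out / "working" / pid / "dockfiles.txt").exists()

    def test_rerun_reproduces_results_csv_bytes(self, dataset, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        run_pipeline(SMALL_CONFIG, dataset, a)
        run_pipeline(SMALL_CONFIG, dataset, b)
        assert (a / "results.csv").read_bytes() == (b / "results.csv").read_bytes()

    def test_worker_count_does_not_change_results(self, dataset, tmp_path):
        cfg8 = {**SMALL_CONFIG, "executor": {"workers": 8, "retries": 0}}
        a = tmp_path / "w1"
        b = tmp_path / "w8"
        run_pipeline(SMALL_CONFIG, dataset, a)
        run_pipeline(cfg8, dataset, b)
        ra = (a / "results.csv").read_text()
        rb = (b / "results.csv").read_text()
        assert ra == rb

    def test_dataset_file_input(self, dataset, tmp_path):
        f = tmp_path / "ds.tsv"
        write_dataset(dataset, f)
        result = run_pipeline(
            {**SMALL_CONFIG, "significance": {"null_reps": 500, "p_value": 0.05}},
            f, tmp_path / "out",
        )
        assert result.n_evaluated > 0

    def test_invalid_config_fails_before_compute(self, dataset, tmp_path):
        with pytest.raises(ValueError, match="unknown config key"):
            run_pipeline({"bogus_section": 1}, dataset, tmp_path / "x")
        assert not (tmp_path / "x" / "results.csv").exists()

    def test_candidate_seed_stable_and_bounded(self):
        s = candidate_seed(42, "abcd")
        assert s == candidate_seed(42, "abcd")
        assert 0 <= s < 2**31
        assert s != candidate_seed(43, "abcd")


class TestPlots:
    def test_histogram_counts_sum_to_models(self, completed_run):
        fig, counts = plot_histogram_with_threshold(completed_run.results,
                                                    completed_run.threshold)
        assert counts.sum() == (completed_run.results["status"] == "ok").sum()

    def test_flagged_count_matches_threshold_rule(self, completed_run):
        df = completed_run.results
        thr = df["criterion_value"].median()
        flagged = (df.loc[df.status == "ok", "criterion_value"] >= thr).sum()
        assert flagged == np.sum(df.loc[df.status == "ok", "criterion_value"] >= thr)

    def test_heatmap_cells_are_groupby_max(self, completed_run):
        df = completed_run.results
        px = "electrostatic_thin_sphere_radius"
        py = "desolvation_thin_sphere_radius"
        matrix, _ = plot_heatmap(df, px, py)
        ok = df[df["status"] == "ok"]
        brute = ok.groupby([py, px])["criterion_value"].max()
        for (y, x), v in brute.items():
            assert matrix.loc[y, x] == pytest.approx(v)

    def test_heatmap_single_valued_param_redirects_to_boxplot(self, completed_run):
        df = completed_run.results.copy()
        df["fixed"] = 1.0
        with pytest.raises(ValueError, match="boxplot"):
            plot_heatmap(df, "fixed", "desolvation_thin_sphere_radius")

    def test_report_regenerable_from_persisted_csv_alone(self, completed_run, tmp_path):
        out = completed_run.out_dir
        results = pd.read_csv(out / "results.csv")
        scores = pd.read_csv(out / "best_retrodock_jobs" / "rank_1" / "scores.csv")
        p1 = render_report(tmp_path / "r1.html", results, scores, completed_run.threshold)
        p2 = render_report(tmp_path / "r2.html", results, scores, completed_run.threshold)
        assert p1.read_text() == p2.read_text()
        html = p1.read_text()
        for heading in ("histogram", "ROC", "charge", "Energy terms", "heatmap"):
            assert heading in html

    def test_missing_scores_sections_note_not_dropped(self, completed_run, tmp_path):
        p = render_report(tmp_path / "r.html", completed_run.results, None,
                          completed_run.threshold)
        html = p.read_text()
        assert html.count("not available") >= 3
        assert "ROC" in html
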