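"""Model facade, configuration files, study outputs and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import mlcfa
from mlcfa.cli import main
from mlcfa.config import load_config


@pytest.fixture(scope="module")
def tiny_config(tmp_path_factory):
    path = tmp_path_factory.mktemp("cfg") / "study.yaml"
    path.write_text(yaml.safe_dump({
        "cn_list": [12], "cs_list": [4], "icc_list": [0.3],
        "replications": 3, "seed": 3, "specs": ["2MLR", "1MLR"],
        "compute_indices": False,
    }))
    return path


class TestModelFacade:
    def test_from_dataframe_fit_summary(self, pop03):
        cond = mlcfa.SimulationCondition(20, 5, 0.3, seed=6)
        df = mlcfa.generate_dataset(pop03, cond, 0).to_dataframe()
        model = mlcfa.MultilevelFactorModel.from_dataframe(df, spec="2MLR")
        res = model.fit()
        assert res.converged
        text = res.summary()
        assert "2MLR" in text and "lambda_w[CPCSA]" in text
        frame = res.params_frame()
        assert list(frame.columns[:4]) == ["name", "level", "kind", "estimate"]
        ci = res.conf_int()
        assert np.all(ci[:, 0] <= res.params.values)
        assert np.all(res.params.values <= ci[:, 1])
        parsed = json.loads(res.to_json())
        assert parsed["spec"] == "2MLR" and parsed["df"] == 4

    def test_csv_constructor_matches_array(self, pop03, tmp_path):
        cond = mlcfa.SimulationCondition(10, 4, 0.3, seed=6)
        sample = mlcfa.generate_dataset(pop03, cond, 0)
        path = tmp_path / "d.csv"
        sample.to_csv(path)
        a = mlcfa.MultilevelFactorModel.from_csv(path, spec="1MLR").fit()
        b = mlcfa.MultilevelFactorModel.from_sample(sample, spec="1MLR").fit()
        assert np.allclose(a.params.values, b.params.values)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            mlcfa.MultilevelFactorModel(np.zeros((5, 4)),
                                        np.array([0, 0, 0, 1, 1]))


class TestConfig:
    def test_load_and_grid(self, tiny_config):
        cfg = load_config(tiny_config)
        conds = cfg.conditions()
        assert len(conds) == 1
        assert conds[0].replications == 3
        assert cfg.population().labels == ("CPCSC", "CPCSA", "CPCAC", "CPCSW")

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("cn_list: [10]\ncs_list: [3]\nicc_list: [0.3]\n"
                        "cluster_sizes: [3]\n")
        with pytest.raises(ValueError, match="unknown configuration keys"):
            load_config(path)

    def test_missing_required_key(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("cn_list: [10]\ncs_list: [3]\n")
        with pytest.raises(ValueError, match="icc_list"):
            load_config(path)

    def test_partial_custom_population_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("cn_list: [10]\ncs_list: [3]\nicc_list: [0.3]\n"
                        "loadings_within: [1, 0.5]\n")
        with pytest.raises(ValueError, match="custom population"):
            load_config(path)


class TestRunStudy:
    def test_outputs_and_determinism(self, tiny_config, tmp_path):
        cfg = load_config(tiny_config)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        mlcfa.run_study(cfg, out1, progress=False)
        mlcfa.run_study(cfg, out2, progress=False)
        records = (out1 / "records.jsonl").read_text().splitlines()
        assert len(records) == 3 * 2  # replications x specs
        assert all(json.loads(line)["spec"] in ("2MLR", "1MLR")
                   for line in records)
        summary = out1 / "summary_12_4_0.3.csv"
        assert summary.exists()
        assert summary.read_text() == (out2 / "summary_12_4_0.3.csv").read_text()
        assert (out1 / "bias.csv").read_text() == (out2 / "bias.csv").read_text()
        assert (out1 / "fit_summary.csv").exists()


class TestCli:
    def test_fit_command(self, pop03, tmp_path):
        cond = mlcfa.SimulationCondition(15, 4, 0.3, seed=9)
        path = tmp_path / "d.csv"
        mlcfa.generate_dataset(pop03, cond, 0).to_csv(path)
        runner = CliRunner()
        out = runner.invoke(main, ["fit", "--data", str(path),
                                   "--spec", "1MLR", "--json"])
        assert out.exit_code == 0, out.output
        parsed = json.loads(out.output)
        assert parsed["spec"] == "1MLR" and parsed["converged"]

    def test_run_and_summarize_commands(self, tiny_config, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "study"
        out = runner.invoke(main, ["run", "--config", str(tiny_config),
                                   "--out", str(out_dir)])
        assert out.exit_code == 0, out.output
        res = runner.invoke(main, ["summarize", "--records",
                                   str(out_dir / "records.jsonl"),
                                   "--out", str(tmp_path / "s.csv")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "s.csv").exists()

    def test_theory_command(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(main, ["theory", "--icc-grid", "0:1:0.5",
                                   "--out", str(tmp_path / "t.csv")])
        assert out.exit_code == 0, out.output
        import pandas as pd
        table = pd.read_csv(tmp_path / "t.csv")
        assert set(table.icc) == {0.0, 0.5, 1.0}
        assert {"conflated", "pseudo_true"} <= set(table.columns)
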