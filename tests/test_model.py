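"""Model/Results surface, config loading and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from gsamda.cli import main
from gsamda.config import load_config
from gsamda.datasets import read_score_matrix
from gsamda.gat import GATParams
from gsamda.model import GSAMDA
from gsamda.sae import SAEParams


@pytest.fixture(scope="module")
def fitted(small_dataset):
    ds, _ = small_dataset
    model = GSAMDA(
        ds,
        gat_params=GATParams(embed_dim=16, epochs=30),
        sae_params=SAEParams(hidden_dim=8, epochs=30),
    )
    return model, model.fit(seed=1)


class TestModel:
    def test_scores_shape_and_bounds(self, fitted):
        _, res = fitted
        ds = res.dataset
        assert res.scores.shape == (ds.n_drugs, ds.n_microbes)
        assert (res.scores > 0).all() and (res.scores < 1).all()

    def test_known_pairs_score_above_unknown_on_average(self, fitted):
        _, res = fitted
        known = res.A_used == 1
        assert res.scores[known].mean() > res.scores[~known].mean()

    def test_summary_mentions_dimensions(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "drugs:              30" in text
        assert "topological dim l:  16" in text

    def test_rank_excludes_known(self, fitted):
        _, res = fitted
        ds = res.dataset
        drug = ds.drug_ids[int(np.argmax(res.A_used.sum(axis=1)))]
        i = ds.drug_ids.index(drug)
        known_partners = {ds.microbe_ids[j] for j in np.flatnonzero(res.A_used[i])}
        ranked = res.rank(drug, top_n=5)
        assert known_partners.isdisjoint({p for p, _ in ranked})

    def test_ranking_resolves_sigmoid_saturation_ties(self, fitted):
        # sigmoid rounds to 1.0 for inner products > ~37; ordering must
        # follow the raw inner products, which never tie there
        _, res = fitted
        np.testing.assert_allclose(
            1.0 / (1.0 + np.exp(-res.inner_products)), res.scores, atol=1e-12
        )
        ds = res.dataset
        drug = ds.drug_ids[0]
        ranked = res.rank(drug, top_n=ds.n_microbes, exclude_known=False)
        i = 0
        ips = res.inner_products[i]
        ranked_ips = [ips[ds.microbe_ids.index(p)] for p, _ in ranked]
        assert (np.diff(ranked_ips) <= 1e-12).all()

    def test_from_frame_constructor(self):
        pairs = pd.DataFrame({"drug": ["d1", "d2"], "microbe": ["m1", "m1"]})
        model = GSAMDA.from_frame(pairs)
        assert model.dataset.n_drugs == 2 and model.dataset.n_microbes == 1

    def test_a_override_shape_checked(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="A_override"):
            model.fit(A_override=np.zeros((2, 2)))

    def test_standardize_features_flag_changes_scores(self, small_dataset):
        ds, _ = small_dataset
        kwargs = dict(
            gat_params=GATParams(embed_dim=8, epochs=10),
            sae_params=SAEParams(hidden_dim=4, epochs=10),
        )
        s1 = GSAMDA(ds, **kwargs).fit(seed=2).scores
        s2 = GSAMDA(ds, standardize_features=True, **kwargs).fit(seed=2).scores
        assert not np.allclose(s1, s2)

    def test_score_tsv_roundtrip(self, fitted, tmp_path):
        _, res = fitted
        p = tmp_path / "scores.tsv"
        res.to_tsv(p)
        df = read_score_matrix(p)
        assert len(df) == res.scores.size
        assert df["score"].is_monotonic_decreasing


class TestConfig:
    def test_load_with_aliases(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "gat:\n  l: 16\n  lr: 0.005\nsae:\n  k: 4\n  beta: 0.2\n"
            "rwr:\n  phi: 0.2\ncv:\n  n_repeats: 3\nfeatures:\n  standardize: true\n"
        )
        cfg = load_config(p)
        assert cfg.gat.embed_dim == 16
        assert cfg.gat.learning_rate == 0.005
        assert cfg.sae.hidden_dim == 4
        assert cfg.sae.penalty_weight == 0.2
        assert cfg.rwr.restart_prob == 0.2
        assert cfg.cv.n_repeats == 3
        assert cfg.standardize_features is True

    def test_defaults_are_published_operating_point(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        cfg = load_config(p)
        assert cfg.gat.embed_dim == 128
        assert cfg.gat.learning_rate == 0.01
        assert cfg.sae.hidden_dim == 32
        assert cfg.sae.penalty_weight == 0.1
        assert cfg.rwr.restart_prob == 0.1
        assert cfg.cv.n_folds == 5 and cfg.cv.n_repeats == 10

    def test_unknown_key_fails_loudly(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("gat:\n  embed_dimension: 16\n")
        with pytest.raises(KeyError, match="embed_dimension"):
            load_config(p)


class TestCLI:
    def test_synth_predict_rank_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "data"
        r = runner.invoke(main, ["synth", "--preset", "small", "--seed", "3",
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "associations.tsv").exists()

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("gat:\n  l: 8\n  epochs: 5\nsae:\n  k: 4\n  epochs: 5\n")
        scores = tmp_path / "scores.tsv"
        r = runner.invoke(main, [
            "predict", "--assoc", str(out / "associations.tsv"),
            "--config", str(cfg), "--out", str(scores),
        ])
        assert r.exit_code == 0, r.output
        assert "GSAMDA association model results" in r.output
        df = read_score_matrix(scores)
        anchor = df["drug_id"].iloc[0]

        r = runner.invoke(main, [
            "rank", "--assoc", str(out / "associations.tsv"),
            "--config", str(cfg), "--anchor", anchor, "--top", "5",
        ])
        assert r.exit_code == 0, r.output
        assert len(r.output.strip().splitlines()) <= 5

    def test_evaluate_prints_metric_table(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "data"
        runner.invoke(main, ["synth", "--preset", "small", "--seed", "4",
                             "--out", str(out)])
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("gat:\n  l: 8\n  epochs: 5\nsae:\n  k: 4\n  epochs: 5\n")
        r = runner.invoke(main, [
            "evaluate", "--assoc", str(out / "associations.tsv"),
            "--config", str(cfg), "--repeats", "1", "--seed", "0",
        ])
        assert r.exit_code == 0, r.output
        assert "auc" in r.output and "mean" in r.output
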