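"""Transformer classifier: architecture, determinism, splitting, training."""

import numpy as np
import pandas as pd
import pytest

from skelseq.classifier import (
    ModelConfig,
    TrainConfig,
    TransformerSequenceClassifier,
    build_model,
    split_dataset,
)
from skelseq.nn import no_grad


def tiny_config(**kw):
    return ModelConfig.tiny(vocab_size=300, max_len=32, **kw)


def random_tokens(n, T=20, vocab=300, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, vocab, size=(n, T))


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self):
        cfg = tiny_config()
        net = build_model(cfg, seed=0)
        H, F, L, V, P, C = cfg.hidden, cfg.ffn_dim, cfg.layers, cfg.vocab_size, cfg.max_len, cfg.n_classes
        embeddings = V * H + P * H + 2 * H  # token + positional + embedding LN
        per_layer = (
            4 * (H * H + H)  # q, k, v, out projections
            + 2 * 2 * H  # two layer norms
            + (H * F + F)  # ffn in
            + (F * H + H)  # ffn out
        )
        head = H * C + C
        assert net.n_parameters() == embeddings + L * per_layer + head

    def test_logits_shape_is_batch_by_12_under_defaults(self):
        net = build_model(tiny_config(), seed=0)
        with no_grad():
            logits = net(random_tokens(5))
        assert logits.shape == (5, 12)

    def test_hidden_not_divisible_by_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden=65, heads=4)

    def test_eval_mode_deterministic(self):
        net = build_model(tiny_config(), seed=0)
        net.eval()
        X = random_tokens(3)
        with no_grad():
            a = net(X).data
            b = net(X).data
        np.testing.assert_array_equal(a, b)

    def test_default_config_is_base_architecture(self):
        cfg = ModelConfig()
        assert (cfg.layers, cfg.hidden, cfg.heads, cfg.ffn_dim) == (12, 768, 12, 3072)
        assert cfg.max_len == 512 and cfg.n_classes == 12


class TestSplit:
    @pytest.fixture(scope="class")
    def windows_df(self):
        rng = np.random.default_rng(1)
        n = 600
        return pd.DataFrame(
            {
                "label": rng.integers(1, 13, size=n),
                "f001": rng.normal(size=n),
                "window_start": np.arange(n),
                "source_id": [f"s{i % 20}" for i in range(n)],
            }
        )

    def test_70_15_15_sizes(self):
        df = pd.DataFrame(
            {
                "label": np.repeat(np.arange(1, 11), 10),
                "f001": np.zeros(100),
                "window_start": np.arange(100),
                "source_id": "s",
            }
        )
        tr, va, te = split_dataset(df, TrainConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_partition_is_exhaustive_and_disjoint(self, windows_df):
        tr, va, te = split_dataset(windows_df, TrainConfig(seed=2))
        starts = np.concatenate([p["window_start"].to_numpy() for p in (tr, va, te)])
        assert len(starts) == len(windows_df)
        assert len(np.unique(starts)) == len(windows_df)

    def test_same_seed_identical_partitions(self, windows_df):
        a = split_dataset(windows_df, TrainConfig(seed=5))
        b = split_dataset(windows_df, TrainConfig(seed=5))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_stratification_preserves_proportions(self, windows_df):
        tr, _, _ = split_dataset(windows_df, TrainConfig(seed=0))
        global_counts = windows_df["label"].value_counts()
        train_counts = tr["label"].value_counts()
        for label in global_counts.index:
            expected = 0.70 * global_counts[label]
            assert abs(train_counts.get(label, 0) - expected) <= 1.0

    def test_tiny_class_kept_whole_in_train(self, windows_df):
        df = windows_df.copy()
        df.loc[df.index[:2], "label"] = 99
        df = df[(df.label == 99) | (df.label < 5)]
        with pytest.warns(UserWarning, match="99"):
            tr, va, te = split_dataset(df, TrainConfig(seed=0))
        assert (tr["label"] == 99).sum() == 2
        assert not (va["label"] == 99).any() and not (te["label"] == 99).any()

    def test_grouped_split_keeps_sources_disjoint(self, windows_df):
        tr, va, te = split_dataset(
            windows_df, TrainConfig(seed=0, split_mode="grouped_by_source")
        )
        sets = [set(part["source_id"]) for part in (tr, va, te)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])


class TestTraining:
    def test_first_batch_loss_near_log_12(self):
        """Untrained logits are near-uniform, so CE starts at ~ln(12)."""
        X, y = random_tokens(64, seed=2), np.random.default_rng(2).integers(1, 13, 64)
        clf = TransformerSequenceClassifier(
            model_config=tiny_config(),
            train_config=TrainConfig(epochs=1, batch_size=64, learning_rate=0.0, seed=0),
        ).fit(X, y)
        assert clf.history_.train_loss.iloc[0] == pytest.approx(np.log(12), abs=0.05)

    def test_zero_epochs_returns_initialization(self):
        X, y = random_tokens(8), np.ones(8, dtype=int)
        clf = TransformerSequenceClassifier(
            model_config=tiny_config(), train_config=TrainConfig(epochs=0, seed=3)
        ).fit(X, y)
        init = build_model(tiny_config(), seed=3)
        for (name_a, p), (name_b, q) in zip(
            clf.net_.named_parameters(), init.named_parameters()
        ):
            assert name_a == name_b
            np.testing.assert_array_equal(p.data, q.data)

    def test_seeded_training_reproducible(self):
        X = random_tokens(48, seed=4)
        y = np.random.default_rng(4).integers(1, 13, 48)
        runs = []
        for _ in range(2):
            clf = TransformerSequenceClassifier(
                model_config=tiny_config(),
                train_config=TrainConfig(epochs=2, learning_rate=1e-3, seed=9),
            ).fit(X, y)
            runs.append(clf.net_.state_dict())
        for k in runs[0]:
            np.testing.assert_array_equal(runs[0][k], runs[1][k])

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TransformerSequenceClassifier(model_config=tiny_config()).fit(
                np.empty((0, 10), dtype=int), np.empty(0, dtype=int)
            )


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        X = random_tokens(40, seed=6)
        y = np.random.default_rng(6).integers(1, 13, 40)
        clf = TransformerSequenceClassifier(
            model_config=tiny_config(),
            train_config=TrainConfig(epochs=1, learning_rate=1e-3, seed=0),
        ).fit(X, y)
        return clf, X

    def test_probabilities_sum_to_one(self, fitted):
        clf, X = fitted
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_consistency(self, fitted):
        clf, X = fitted
        proba = clf.predict_proba(X)
        np.testing.assert_array_equal(clf.predict(X), clf.classes_[proba.argmax(axis=1)])

    def test_batch_size_invariance(self, fitted):
        clf, X = fitted
        one_by_one = np.vstack([clf.predict_proba(X[i : i + 1]) for i in range(8)])
        batched = clf.predict_proba(X[:8])
        np.testing.assert_allclose(one_by_one, batched, rtol=1e-5, atol=1e-7)

    def test_too_long_sequence_rejected(self, fitted):
        clf, _ = fitted
        with pytest.raises(ValueError, match="max_len"):
            clf.predict(np.zeros((1, 40), dtype=int))

    def test_save_load_roundtrip(self, fitted, tmp_path):
        clf, X = fitted
        clf.save(tmp_path / "model")
        loaded = TransformerSequenceClassifier.load(tmp_path / "model")
        np.testing.assert_allclose(
            clf.predict_proba(X[:5]), loaded.predict_proba(X[:5]), atol=1e-7
        )


class TestOverfitTinyCorpus:
    def test_overfits_200_separable_windows(self, small_corpus_df, fitted_tokenizer):
        """The tiny preset drives training accuracy to 100% on 200
        easily-separable windows within 20 epochs (from-scratch rate)."""
        tok, feat_cols = fitted_tokenizer
        rng = np.random.default_rng(0)
        sel = rng.choice(len(small_corpus_df), 200, replace=False)
        df = small_corpus_df.iloc[sel]
        X = tok.transform(df[feat_cols])
        y = df["label"].to_numpy()
        clf = TransformerSequenceClassifier(
            model_config=ModelConfig.tiny(),
            train_config=TrainConfig(epochs=20, learning_rate=1e-3, seed=1),
        ).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0
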