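"""Shared fixtures: small synthetic corpora and the (expensive) seeded
end-to-end comparison run, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from skelseq import (
    MinMaxTokenizer,
    MotionConfig,
    RunConfig,
    TrainConfig,
    ModelConfig,
    build_windows,
    generate_dataset,
)
from skelseq.gan import ConditionalTabularGAN, GANConfig
from skelseq.windowing import windows_to_frame


@pytest.fixture(scope="session")
def small_corpus_df():
    """Balanced 12-class window table (2 sequences per class, 4 s each)."""
    cfg = MotionConfig(class_counts={c: 2 for c in range(1, 13)}, seed=1)
    wins = [w for s in generate_dataset(cfg) for w in build_windows(s)]
    return windows_to_frame(wins)


@pytest.fixture(scope="session")
def fitted_tokenizer(small_corpus_df):
    feat_cols = [c for c in small_corpus_df.columns if c.startswith("f") and c[1:].isdigit()]
    return MinMaxTokenizer().fit(small_corpus_df[feat_cols]), feat_cols


@pytest.fixture(scope="session")
def toy_gan():
    """Conditional GAN trained on a 2-class, 2-feature Gaussian toy.

    Class 1 ~ N((0, 2), I), class 2 ~ N((5, -3), I); 500 rows each.
    """
    rng = np.random.default_rng(42)
    n = 500
    X = np.vstack(
        [rng.normal([0.0, 2.0], 1.0, size=(n, 2)), rng.normal([5.0, -3.0], 1.0, size=(n, 2))]
    )
    y = np.array([1] * n + [2] * n)
    gan = ConditionalTabularGAN(GANConfig(epochs=300, batch_size=64, seed=3)).fit(X, y)
    return gan, X, y


def e2e_config(workdir: str, seed: int = 11) -> RunConfig:
    """Desk-scale study conditions for the balanced-vs-unbalanced protocol:
    upfall-like imbalance, tiny encoder preset, from-scratch learning rate,
    log-frequency condition sampling and the moment-matching generator
    (see docs/methods.md on the adversarial term at this dimensionality)."""
    return RunConfig(
        workdir=workdir,
        budget_windows=4000,
        noise_sd=15.0,
        model=ModelConfig.tiny(),
        train=TrainConfig(epochs=8, learning_rate=1e-3, seed=0),
        gan=GANConfig(epochs=120, adversarial_weight=0.0, log_frequency=True, seed=0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def e2e_comparison(tmp_path_factory):
    """Both arms of the protocol on the imbalanced synthetic corpus."""
    from skelseq.pipeline import run_bert_vs_gan

    workdir = tmp_path_factory.mktemp("e2e")
    cfg = e2e_config(str(workdir))
    result = run_bert_vs_gan(cfg)
    result["config"] = cfg
    return result
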