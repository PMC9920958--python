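"""Conditional tabular GAN: VGM codec, condition sampling, planning,
distribution recovery on the Gaussian toy, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from skelseq.gan import (
    AugmentationPlan,
    ConditionalTabularGAN,
    GANConfig,
    TABLE3_FAKE_COUNTS,
    build_plan,
    diagnostics,
    encode_value,
    fit_vgm,
    generate,
    sample_condition,
)


class TestVGM:
    def test_single_gaussian_mean_recovered(self):
        rng = np.random.default_rng(0)
        enc = fit_vgm(rng.normal(5.0, 1.0, size=5000), k=10)
        dominant = enc.means_[np.argmax(enc.weights_)]
        assert dominant == pytest.approx(5.0, abs=0.1)

    def test_two_separated_gaussians_two_modes(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.5, 2000), rng.normal(10, 0.5, 2000)])
        enc = fit_vgm(x, k=10)
        heavy = enc.weights_ > 0.2
        assert heavy.sum() == 2
        assert sorted(np.round(enc.means_[heavy]).tolist()) == [0.0, 10.0]

    def test_constant_column_single_mode_decodes_constant(self):
        enc = fit_vgm(np.full(100, 3.25))
        assert enc.n_modes == 1
        alpha, beta = encode_value(3.25, enc)
        assert enc.decode(alpha, beta)[0] == pytest.approx(3.25, abs=1e-9)

    def test_alpha_zero_at_mode_mean(self):
        # separated modes so the posterior picks the matching mode surely
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.5, 1500), rng.normal(20, 0.5, 1500)])
        enc = fit_vgm(x)
        mode = int(np.argmin(np.abs(enc.means_)))
        alpha, beta = encode_value(float(enc.means_[mode]), enc)
        assert alpha == pytest.approx(0.0, abs=1e-9)
        assert beta.argmax() == mode

    def test_roundtrip_exact_when_unclipped(self):
        rng = np.random.default_rng(3)
        enc = fit_vgm(rng.normal(2.0, 1.5, 2000))
        for x in rng.normal(2.0, 1.5, 50):
            alpha, beta = encode_value(float(x), enc, rng=rng)
            mode = beta.argmax()
            if abs(x - enc.means_[mode]) <= 4 * enc.stds_[mode]:
                assert enc.decode(alpha, beta)[0] == pytest.approx(x, abs=1e-9)

    def test_far_value_clips_to_unit_alpha(self):
        enc = fit_vgm(np.random.default_rng(4).normal(0, 1, 500))
        alpha, _ = encode_value(1e6, enc)
        assert alpha == 1.0


class TestSampleCondition:
    def test_degenerate_frequency_always_selected(self):
        assert all(sample_condition([1.0, 0.0, 0.0], rng=i) == 1 for i in range(20))

    def test_even_frequencies_near_half(self):
        draws = sample_condition([1.0, 1.0], rng=0, size=10_000)
        assert np.mean(draws == 1) == pytest.approx(0.5, abs=0.02)

    def test_three_to_one_frequencies(self):
        draws = sample_condition([3.0, 1.0], rng=1, size=10_000)
        assert np.mean(draws == 1) == pytest.approx(0.75, abs=0.02)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sample_condition([0.0, 0.0])

    def test_log_frequency_flattens(self):
        draws = sample_condition({1: 1000.0, 2: 10.0}, rng=2, size=10_000, log_frequency=True)
        share = np.mean(draws == 1)
        assert 0.5 < share < 0.90  # flatter than the raw 0.99 share


class TestPlan:
    def test_table3_reproduces_published_fake_counts(self):
        counts = {c: 100 for c in range(1, 13)}
        plan = build_plan(counts, strategy="table3")
        for c, expected in TABLE3_FAKE_COUNTS.items():
            assert plan.counts[c] == expected
        assert plan.total == 84_065

    def test_balanced_classes_need_nothing(self):
        plan = build_plan({1: 100, 2: 100}, strategy="target_share", target_share=0.3)
        assert plan.total == 0

    def test_two_class_90_10_to_half(self):
        plan = build_plan({1: 90, 2: 10}, strategy="target_share", target_share=0.5)
        assert plan.counts == {1: 0, 2: 80}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPlan({1: -5})


class TestToyRecovery:
    def test_per_class_means_within_half_sigma(self, toy_gan):
        """Seeded training on the 2-class Gaussian toy recovers each
        class's feature means to within 0.5 sigma."""
        gan, X, y = toy_gan
        for c, mu in ((1, np.array([0.0, 2.0])), (2, np.array([5.0, -3.0]))):
            fake = gan.sample(c, 500)
            deviation = np.abs(fake.mean(axis=0) - mu)  # real sigma is 1
            assert (deviation < 0.5).all(), f"class {c}: {deviation}"

    def test_conditional_integrity_100_percent(self, toy_gan):
        gan, _, _ = toy_gan
        df = generate(gan, 2, 200)
        assert (df["label"] == 2).all()
        assert len(df) == 200

    def test_generate_n_zero_empty(self, toy_gan):
        gan, _, _ = toy_gan
        assert gan.sample(1, 0).shape == (0, 2)

    def test_unknown_class_rejected(self, toy_gan):
        gan, _, _ = toy_gan
        with pytest.raises(ValueError, match="unknown class"):
            gan.sample(7, 3)

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 2))
        y = np.array([1, 2] * 40)
        cfg = GANConfig(epochs=3, batch_size=16, seed=12)
        g1 = ConditionalTabularGAN(cfg).fit(X, y)
        g2 = ConditionalTabularGAN(cfg).fit(X, y)
        s1, s2 = g1.generator_.state_dict(), g2.generator_.state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])


class TestGeneratedShape:
    def test_window_scale_generation_has_153_columns(self, small_corpus_df):
        feat_cols = [c for c in small_corpus_df.columns if c.startswith("f") and c[1:].isdigit()]
        sub = small_corpus_df.iloc[:200]
        gan = ConditionalTabularGAN(GANConfig(epochs=2, vgm_modes=3, seed=0)).fit(
            sub[feat_cols].to_numpy(), sub["label"].to_numpy()
        )
        label = int(sub["label"].iloc[0])
        out = generate(gan, label, 10)
        assert out.shape == (10, 154)  # label + 153 features
        assert (out["label"] == label).all()


class TestDiagnostics:
    def test_identical_tables_zero_gaps(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        report = diagnostics(df, df)
        assert np.allclose(report["real_mean"], report["fake_mean"])
        assert np.allclose(report["cdf_max_gap"], 0.0)

    def test_constant_shift_moves_means_only(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        shifted = df + 2.5
        report = diagnostics(df, shifted)
        np.testing.assert_allclose(report["fake_mean"] - report["real_mean"], 2.5, atol=1e-9)
        np.testing.assert_allclose(report["fake_sd"], report["real_sd"], atol=1e-9)

    def test_column_mismatch_rejected(self):
        a = pd.DataFrame({"x": [1.0]})
        b = pd.DataFrame({"y": [1.0]})
        with pytest.raises(ValueError, match="columns"):
            diagnostics(a, b)

    def test_report_covers_all_features_and_plots(self, toy_gan, tmp_path):
        gan, X, y = toy_gan
        fake = np.vstack([gan.sample(1, 100), gan.sample(2, 100)])
        out = tmp_path / "diag.png"
        report = diagnostics(
            pd.DataFrame(X, columns=["f1", "f2"]),
            pd.DataFrame(fake, columns=["f1", "f2"]),
            plot_path=str(out),
        )
        assert len(report) == 2
        assert out.exists()
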