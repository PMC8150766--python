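"""Branch training, fusion and single-segment inference."""

import numpy as np
import pytest

from ieegfuse.classical import ClassicalBranchConfig, train_classical
from ieegfuse.deep import CnnConfig, activation_maps, train_cnn
from ieegfuse.fusion import FusionConfig, bce_loss, fuse, train_fusion
from ieegfuse.synthetic import SynthConfig, generate_segment
from ieegfuse.types import Label


@pytest.fixture(scope="module")
def tiny_feature_data(request):
    """Small separable feature-sequence problem (no signal processing)."""
    rng = np.random.default_rng(99)
    n = 40
    x0 = rng.normal(size=(n, 4, 70))
    x1 = rng.normal(size=(n, 4, 70)) + 1.0
    x = np.concatenate([x1, x0])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    return x, y


@pytest.fixture(scope="module")
def tiny_raw_data():
    rng = np.random.default_rng(98)
    n = 40
    x0 = rng.normal(size=(n, 320))
    t = np.arange(320)
    x1 = rng.normal(size=(n, 320)) + np.sin(2 * np.pi * t / 16)  # tone marks class 1
    x = np.concatenate([x1, x0])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    return x, y


class TestClassicalBranch:
    def test_embedding_is_128(self, tiny_feature_data):
        x, y = tiny_feature_data
        b = train_classical(x, y, x[:10], y[:10], ClassicalBranchConfig(epochs=2), seed=0)
        assert b.embed(x[:3]).shape == (3, 128)

    def test_probabilities_in_open_interval(self, tiny_feature_data):
        x, y = tiny_feature_data
        b = train_classical(x, y, x[:10], y[:10], ClassicalBranchConfig(epochs=2), seed=0)
        p = b.predict_proba(x[:8])
        assert np.all((p > 0) & (p < 1))

    def test_training_is_seed_deterministic(self, tiny_feature_data):
        x, y = tiny_feature_data
        cfg = ClassicalBranchConfig(epochs=3)
        h1 = train_classical(x, y, x[:10], y[:10], cfg, seed=5).history
        h2 = train_classical(x, y, x[:10], y[:10], cfg, seed=5).history
        assert h1 == h2

    def test_first_epoch_loss_near_chance(self, tiny_feature_data):
        x, y = tiny_feature_data
        b = train_classical(x, y, x[:10], y[:10], ClassicalBranchConfig(epochs=1), seed=0)
        assert b.history[0]["train_loss"] <= np.log(2) + 0.2

    def test_single_class_training_rejected(self, tiny_feature_data):
        x, y = tiny_feature_data
        with pytest.raises(ValueError, match="both classes"):
            train_classical(x[:40], np.ones(40), x[:10], y[:10])

    def test_non_finite_input_rejected(self, tiny_feature_data):
        x, y = tiny_feature_data
        b = train_classical(x, y, x[:10], y[:10], ClassicalBranchConfig(epochs=1), seed=0)
        bad = x[:2].copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            b.predict_proba(bad)


class TestCnnBranch:
    def test_embedding_and_activation_channels(self, tiny_raw_data):
        x, y = tiny_raw_data
        b = train_cnn(x, y, x[:10], y[:10], CnnConfig(epochs=2), seed=0)
        assert b.embed(x[:3]).shape == (3, 128)
        assert activation_maps(b, x[0], layer=1).shape[0] == 16
        assert activation_maps(b, x[0], layer=2).shape[0] == 32
        with pytest.raises(ValueError, match="layer"):
            activation_maps(b, x[0], layer=5)

    def test_seeded_history_reproducible(self, tiny_raw_data):
        x, y = tiny_raw_data
        cfg = CnnConfig(epochs=2)
        h1 = train_cnn(x, y, x[:10], y[:10], cfg, seed=3).history
        h2 = train_cnn(x, y, x[:10], y[:10], cfg, seed=3).history
        assert h1 == h2

    def test_too_short_input_rejected(self, tiny_raw_data):
        x, y = tiny_raw_data
        b = train_cnn(x, y, x[:10], y[:10], CnnConfig(epochs=1), seed=0)
        with pytest.raises(ValueError, match="short"):
            b.predict_proba(np.zeros((1, 8)))


class TestFusion:
    def test_fuse_concatenates_classical_first(self):
        a = np.zeros(128)
        b = np.arange(128.0)
        f = fuse(a, b)
        assert f.shape == (256,)
        assert np.all(f[:128] == 0) and np.all(f[128:] == b)
        assert not np.array_equal(fuse(b, a), f)

    def test_fuse_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(128), np.zeros(64))

    @pytest.mark.parametrize(
        "y,p,expected",
        [(1, 1.0, 0.0), (1, 0.5, np.log(2)), (0, 0.9, -np.log(0.1)), (0, 0.5, np.log(2))],
    )
    def test_bce_closed_forms(self, y, p, expected):
        assert bce_loss(y, p) == pytest.approx(expected, abs=1e-6)

    def test_bce_matches_formula_on_grid(self):
        ys = np.array([0.0, 1.0])
        ps = np.linspace(0.05, 0.95, 19)
        for y in ys:
            for p in ps:
                direct = -(y * np.log(p) + (1 - y) * np.log(1 - p))
                assert bce_loss(y, p) == pytest.approx(direct, abs=1e-12)

    def test_branch_weights_frozen_during_fusion(self, tiny_feature_data, tiny_raw_data):
        xs, y = tiny_feature_data
        xr, _ = tiny_raw_data
        cb = train_classical(xs, y, xs[:10], y[:10], ClassicalBranchConfig(epochs=2), seed=0)
        db = train_cnn(xr, y, xr[:10], y[:10], CnnConfig(epochs=2), seed=0)
        before_c = cb.model.state_dict()
        before_d = db.model.state_dict()
        pipe = train_fusion(
            cb, db, xs, xr, y, xs[:10], xr[:10], y[:10], FusionConfig(epochs=3), seed=0
        )
        for a, b in zip(before_c, cb.model.state_dict()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(before_d, db.model.state_dict()):
            np.testing.assert_array_equal(a, b)
        p = pipe.predict_proba(xs[:5], xr[:5])
        assert np.all((p > 0) & (p < 1))

    def test_untrained_branch_rejected(self, tiny_feature_data, tiny_raw_data):
        from ieegfuse.classical import BiLSTMAttentionModel, TrainedBranch

        xs, y = tiny_feature_data
        xr, _ = tiny_raw_data
        rng = np.random.default_rng(0)
        fresh = TrainedBranch(
            model=BiLSTMAttentionModel(70, ClassicalBranchConfig(), rng),
            mean=np.zeros(70), sd=np.ones(70),
        )
        db = train_cnn(xr, y, xr[:10], y[:10], CnnConfig(epochs=1), seed=0)
        with pytest.raises(ValueError, match="trained"):
            train_fusion(fresh, db, xs, xr, y, xs[:10], xr[:10], y[:10])


class TestSegmentInference:
    def test_predict_segment_full_pipeline(self, study_result, study_config):
        """Single-segment inference returns label, probability and 256-d feature."""
        seg = generate_segment(
            SynthConfig(
                duration=study_config.duration,
                class_label=Label.ES,
                seed=424242,
            )
        )
        pipe = study_result.pipeline
        label, p, feat = pipe.predict_segment(seg)
        assert feat.fused.shape == (256,)
        assert 0 < p < 1
        label2, p2, _ = pipe.predict_segment(seg)
        assert (label, p) == (label2, p2)
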