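import numpy as np
import pytest

from gazeperim.errors import ConfigError
from gazeperim.rnn import (
    RnnConfig,
    TwoStreamRnn,
    predict_pointwise_map,
    predict_shape,
    sample_batch,
)
from gazeperim.rnn.model import SHAPE_CLASSES
from gazeperim.rnn.train import _CLASS_INDEX, TrainingBatch, train
from gazeperim.rnn.inference import _with_gaze_offset, ensemble_windows
from gazeperim.mapping import GridSpec
from gazeperim.scotoma import ScotomaKind

DESK_CFG = RnnConfig(hidden_units=8, subsequence_len_in=1000,
                     subsequence_len_train=250, batch_size=16, rng_seed=0)


@pytest.fixture(scope="module")
def trial_pool(tiny_cohort):
    return [r for by_cond in tiny_cohort.values()
            for recs in by_cond.values() for r in recs]


class TestRnnConfig:
    def test_alpha_beta_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            RnnConfig(alpha=0.9, beta=0.2)

    def test_downsampling_must_divide(self):
        with pytest.raises(ConfigError):
            RnnConfig(subsequence_len_in=1000, subsequence_len_train=251)

    def test_standard_protocol_numbers(self):
        cfg = RnnConfig()
        assert cfg.subsequence_len_in == 1000
        assert cfg.subsequence_len_train == 250
        assert cfg.decimation == 4


class TestSampleBatch:
    def test_window_downsampled_to_250_steps(self, trial_pool):
        batch = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(0))
        assert batch.X.shape == (16, 250, 4)
        assert batch.y_s.shape == (16, 250)
        assert batch.C.shape == (16, 2)

    def test_window_duration_seconds(self):
        cfg = RnnConfig()
        assert round(cfg.subsequence_len_in / 240.0, 2) == 4.17

    def test_fixed_seed_reproducible(self, trial_pool):
        a = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(7))
        b = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(7))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y_d, b.y_d)

    def test_labels_align_with_decimated_occlusion(self, trial_pool):
        batch = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(1))
        assert set(np.unique(batch.y_s)) <= {0, 1}
        assert set(np.unique(batch.y_d)) <= {0, 1, 2, 3}

    def test_short_trials_skipped(self, tiny_cohort):
        # the 8-s tiny-cohort trials are long enough; truncated copies are not
        import dataclasses
        rec = tiny_cohort["P01"][ScotomaKind.NONE][0]
        short = dataclasses.replace(
            rec,
            config=dataclasses.replace(rec.config, duration=2.0),
            s_x=rec.s_x[:480], s_y=rec.s_y[:480], p_x=rec.p_x[:480],
            p_y=rec.p_y[:480], occluded=rec.occluded[:480])
        with pytest.raises(ConfigError):
            sample_batch([short], DESK_CFG, np.random.default_rng(0))


class TestForward:
    def test_heads_emit_distributions(self, trial_pool):
        model = TwoStreamRnn(DESK_CFG)
        batch = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(2))
        pw, sh = model.predict_proba(batch.X, batch.C)
        assert np.allclose(pw.sum(-1), 1.0, atol=1e-6)
        assert np.allclose(sh.sum(-1), 1.0, atol=1e-6)
        assert np.all(pw >= 0) and np.all(sh >= 0)

    def test_batch_permutation_equivariance(self, trial_pool):
        model = TwoStreamRnn(DESK_CFG)
        batch = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(3))
        pw, sh = model.predict_proba(batch.X, batch.C)
        perm = np.random.default_rng(0).permutation(len(batch.X))
        pw_p, sh_p = model.predict_proba(batch.X[perm], batch.C[perm])
        np.testing.assert_allclose(pw_p, pw[perm], atol=1e-5)
        np.testing.assert_allclose(sh_p, sh[perm], atol=1e-5)

    def test_zero_weights_give_uniform_distributions(self, trial_pool):
        model = TwoStreamRnn(DESK_CFG)
        for p in model.params.values():
            p[...] = 0.0
        batch = sample_batch(trial_pool, DESK_CFG, np.random.default_rng(4))
        pw, sh = model.predict_proba(batch.X, batch.C)
        assert np.allclose(pw, 0.5, atol=1e-6)
        assert np.allclose(sh, 0.25, atol=1e-6)


class TestLoss:
    def _uniform_batch(self):
        X = np.zeros((2, 6, 4), dtype=np.float32)
        C = np.zeros((2, 2), dtype=np.float32)
        y_s = np.zeros((2, 6), dtype=int)
        y_d = np.zeros(2, dtype=int)
        return X, C, y_s, y_d

    def test_uniform_prediction_loss_closed_form(self):
        cfg = RnnConfig(gru_layers=1, hidden_units=4, subsequence_len_in=24,
                        subsequence_len_train=6, rng_seed=0)
        model = TwoStreamRnn(cfg)
        for p in model.params.values():
            p[...] = 0.0
        X, C, y_s, y_d = self._uniform_batch()
        pw, sh = model.predict_proba(X, C)
        J = model.loss(pw, sh, y_s, y_d)
        assert J == pytest.approx(0.75 * np.log(2) + 0.25 * np.log(4), rel=1e-5)

    def test_perfect_prediction_loss_zero(self):
        pw = np.zeros((2, 6, 2))
        pw[..., 0] = 1.0
        sh = np.zeros((2, 4))
        sh[:, 0] = 1.0
        model = TwoStreamRnn(RnnConfig(gru_layers=1, hidden_units=4,
                                       subsequence_len_in=24,
                                       subsequence_len_train=6))
        X, C, y_s, y_d = self._uniform_batch()
        assert model.loss(pw, sh, y_s, y_d) == pytest.approx(0.0, abs=1e-9)

    def test_weighted_sum_arithmetic(self):
        # one-element batch with known per-head cross-entropies
        model_a = TwoStreamRnn(RnnConfig(gru_layers=1, hidden_units=4,
                                         alpha=0.75, beta=0.25,
                                         subsequence_len_in=24,
                                         subsequence_len_train=6))
        model_b = TwoStreamRnn(RnnConfig(gru_layers=1, hidden_units=4,
                                         alpha=0.5, beta=0.5,
                                         subsequence_len_in=24,
                                         subsequence_len_train=6))
        pw = np.full((1, 1, 2), 0.5)
        sh = np.full((1, 4), 0.25)
        y_s = np.zeros((1, 1), dtype=int)
        y_d = np.zeros(1, dtype=int)
        ce_s, ce_d = np.log(2), np.log(4)
        assert model_a.loss(pw, sh, y_s, y_d) == pytest.approx(
            0.75 * ce_s + 0.25 * ce_d, rel=1e-9)
        assert model_b.loss(pw, sh, y_s, y_d) == pytest.approx(
            0.5 * ce_s + 0.5 * ce_d, rel=1e-9)

    def test_zero_probability_clamped(self):
        model = TwoStreamRnn(RnnConfig(gru_layers=1, hidden_units=4,
                                       subsequence_len_in=24,
                                       subsequence_len_train=6))
        pw = np.zeros((1, 2, 2))
        pw[..., 1] = 1.0  # true class 0 has probability 0
        sh = np.full((1, 4), 0.25)
        J = model.loss(pw, sh, np.zeros((1, 2), dtype=int), np.zeros(1, dtype=int))
        assert np.isfinite(J)


class TestPredictShape:
    def test_unanimous_windows(self, tiny_cohort):
        model = TwoStreamRnn(DESK_CFG)
        records = tiny_cohort["P02"][ScotomaKind.CENTRAL]
        kind, probs = predict_shape(model, records, np.random.default_rng(0))
        assert kind in SHAPE_CLASSES
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-5)

    def test_ensemble_average_argmax(self):
        # average of (0.6, 0.4, 0, 0) and (0.2, 0.8, 0, 0) -> class index 1
        probs = np.array([[0.6, 0.4, 0, 0], [0.2, 0.8, 0, 0]])
        mean = probs.mean(axis=0)
        assert int(np.argmax(mean)) == 1

    def test_order_invariance(self, tiny_cohort):
        model = TwoStreamRnn(DESK_CFG)
        records = list(tiny_cohort["P03"][ScotomaKind.HEMIFIELD])
        _, p1 = predict_shape(model, records)          # deterministic windows
        _, p2 = predict_shape(model, records[::-1])
        np.testing.assert_allclose(np.sort(p1), np.sort(p2), atol=1e-6)
        np.testing.assert_allclose(p1, p2, atol=1e-6)  # mean is order-free

    def test_standard_protocol_k_is_24(self):
        from gazeperim.observer import ProtocolConfig
        assert ProtocolConfig().n_trials == 24

    def test_empty_records_rejected(self):
        model = TwoStreamRnn(DESK_CFG)
        with pytest.raises(ConfigError):
            predict_shape(model, [])


class TestPredictPointwiseMap:
    def test_always_unobstructed_model_gives_zero_map(self, tiny_cohort):
        model = TwoStreamRnn(DESK_CFG)
        for p in model.params.values():
            p[...] = 0.0
        model.pw_head.params["b"][...] = np.array([5.0, -5.0])  # class 0 wins
        records = tiny_cohort["P01"][ScotomaKind.CENTRAL]
        vfmap = predict_pointwise_map(model, records)
        assert np.all(vfmap.grid[vfmap.sampled_mask] == 0)

    def test_map_matches_ground_truth_when_flags_match(self, tiny_cohort):
        # oracle: backprojecting the true flags at the decimated indices
        from gazeperim.mapping import backproject_coords
        model = TwoStreamRnn(DESK_CFG)
        for p in model.params.values():
            p[...] = 0.0
        model.pw_head.params["b"][...] = np.array([-5.0, 5.0])  # always loss
        rec = tiny_cohort["P01"][ScotomaKind.CENTRAL][0]
        vfmap = predict_pointwise_map(model, [rec])
        idx = np.concatenate([start + 4 * np.arange(250)
                              for start in range(0, len(rec) - 999, 1000)])
        rx = rec.s_x[idx] - rec.p_x[idx]
        ry = rec.s_y[idx] - rec.p_y[idx]
        oracle = backproject_coords(np.ones(len(idx), dtype=np.uint8), rx, ry,
                                    GridSpec())
        np.testing.assert_array_equal(vfmap.counts, oracle.counts)
        np.testing.assert_array_equal(vfmap.flagged, oracle.flagged)


class TestTraining:
    def test_loss_decreases_on_tiny_problem(self, trial_pool):
        cfg = RnnConfig(hidden_units=8, batch_size=16, iterations=80,
                        subsequence_len_in=1000, subsequence_len_train=250,
                        rng_seed=1)
        result = train(trial_pool, cfg, log_every=0)
        assert len(result.loss_history) == 80
        # batch losses are noisy: compare means of the first/last ten
        assert np.mean(result.loss_history[-10:]) < np.mean(result.loss_history[:10])

    def test_missing_condition_rejected(self, tiny_cohort):
        records = tiny_cohort["P01"][ScotomaKind.NONE]
        with pytest.raises(ConfigError):
            train(records, DESK_CFG)


class TestMiscalibration:
    def test_offset_preserves_ground_truth(self, tiny_cohort):
        rec = tiny_cohort["P01"][ScotomaKind.CENTRAL][0]
        shifted = _with_gaze_offset(rec, 3.0, -2.0)
        np.testing.assert_array_equal(shifted.occluded, rec.occluded)
        np.testing.assert_allclose(shifted.p_x, rec.p_x + 3.0)

    def test_zero_offset_equals_undistorted(self, tiny_cohort):
        model = TwoStreamRnn(DESK_CFG)
        records = tiny_cohort["P01"][ScotomaKind.NONE]
        _, p0 = predict_shape(model, records)
        shifted = [_with_gaze_offset(r, 0.0, 0.0) for r in records]
        _, p1 = predict_shape(model, shifted)
        np.testing.assert_allclose(p0, p1, atol=1e-6)

    def test_chance_level_is_25_percent(self):
        assert len(SHAPE_CLASSES) == 4
        assert 100.0 / len(SHAPE_CLASSES) == 25.0
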