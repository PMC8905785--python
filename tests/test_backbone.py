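"""The slice-wise segmentation backbone: gradients, training, inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ltq
from ltq import _nn
from ltq.backbone import BackboneConfig, BackboneHandle, _backward, _forward, _init_params

from conftest import small_phantom

TINY = BackboneConfig(depth=2, base_channels=2, input_size=8, epochs=1)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """The hand-derived backprop must agree with central differences."""
        params = _init_params(TINY)
        rng = np.random.default_rng(0)
        X = rng.random((2, 1, 8, 8))
        G = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        logits, cache = _forward(params, TINY, X)
        _, dz = _nn.bce_dice_loss(logits, G)
        grads = _backward(params, TINY, cache, dz)
        for name in params:
            p, g = params[name], grads[name]
            for _ in range(2):
                idx = tuple(rng.integers(s) for s in p.shape)
                eps = 1e-6
                p[idx] += eps
                up, _ = _nn.bce_dice_loss(_forward(params, TINY, X)[0], G)
                p[idx] -= 2 * eps
                dn, _ = _nn.bce_dice_loss(_forward(params, TINY, X)[0], G)
                p[idx] += eps
                fd = (up - dn) / (2 * eps)
                assert g[idx] == pytest.approx(fd, abs=1e-7), name


def _toy_samples(n=2, shape=(4, 16, 16), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mask = np.zeros(shape, bool)
        mask[:, 4:12, 4:12] = True
        data = np.where(mask, 150.0, -50.0) + rng.normal(0, 10, shape)
        out.append(
            (ltq.CTVolume(data, (5.0, 2.0, 2.0)),
             ltq.BinaryMask(mask, (5.0, 2.0, 2.0)))
        )
    return out


class TestTraining:
    CFG = BackboneConfig(depth=2, base_channels=4, input_size=16, epochs=3, seed=3)

    def test_loss_decreases_and_trace_reproducible(self):
        samples = _toy_samples()
        h1 = ltq.train_backbone(samples, self.CFG)
        h2 = ltq.train_backbone(samples, self.CFG)
        assert h1.history.loss.iloc[-1] <= h1.history.loss.iloc[0]
        assert np.array_equal(h1.history.loss.values, h2.history.loss.values)
        for k in h1.params:
            assert np.array_equal(h1.params[k], h2.params[k])

    def test_empty_training_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ltq.train_backbone([], self.CFG)

    def test_shape_mismatch_rejected_before_training(self):
        (vol, _), = _toy_samples(1)
        bad = ltq.BinaryMask(np.zeros((3, 16, 16), bool), (5.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="mismatch"):
            ltq.train_backbone([(vol, bad)], self.CFG)

    def test_training_dice_improves_on_phantoms(self):
        samples = [
            (s.volume, s.liver_gt) for s in (small_phantom(seed=i) for i in range(3))
        ]
        cfg = BackboneConfig(
            depth=2, base_channels=6, input_size=48, epochs=5, seed=2, task="liver"
        )
        h = ltq.train_backbone(samples, cfg)
        assert h.history.dice.iloc[-1] > h.history.dice.iloc[0]
        assert h.history.loss.iloc[-1] <= h.history.loss.iloc[0]


@pytest.fixture(scope="module")
def handle():
    return ltq.train_backbone(_toy_samples(), TestTraining.CFG)


class TestPredictAndBinarize:

    def test_output_shape_and_range(self, handle):
        vol = _toy_samples(1, seed=9)[0][0]
        p = ltq.predict(handle, vol)
        assert p.shape == vol.shape
        assert p.data.min() >= 0.0 and p.data.max() <= 1.0

    def test_air_only_volume_scores_low(self, handle):
        vol = ltq.CTVolume(np.full((4, 16, 16), -1000.0), (5.0, 2.0, 2.0))
        p = ltq.predict(handle, vol)
        assert p.data.mean() < 0.5

    def test_untrained_handle_rejected(self):
        h = BackboneHandle(params={}, cfg=TINY, history=pd.DataFrame())
        vol = _toy_samples(1)[0][0]
        with pytest.raises(ValueError, match="trained"):
            ltq.predict(h, vol)

    def test_binarize_examples(self):
        pm = ltq.ProbabilityMap(np.full((1, 8, 8), 0.9), (1, 1, 1))
        assert ltq.binarize(pm, 0.5).count() == 64
        pm = ltq.ProbabilityMap(np.full((1, 8, 8), 0.1), (1, 1, 1))
        assert ltq.binarize(pm, 0.5).count() == 0
        data = np.zeros((1, 8, 8))
        data[0, 0, :3] = [0.2, 0.5, 0.8]
        got = ltq.binarize(ltq.ProbabilityMap(data, (1, 1, 1)), 0.5)
        assert not got.data[0, 0, 0] and got.data[0, 0, 1] and got.data[0, 0, 2]

    def test_binarize_threshold_validated(self):
        pm = ltq.ProbabilityMap(np.zeros((1, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError):
            ltq.binarize(pm, 1.0)

    @given(t_lo=st.floats(0.05, 0.45), t_hi=st.floats(0.55, 0.95),
           seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_binarize_monotone_in_threshold(self, t_lo, t_hi, seed):
        rng = np.random.default_rng(seed)
        pm = ltq.ProbabilityMap(rng.random((3, 8, 8)), (1, 1, 1))
        lo = ltq.binarize(pm, t_lo)
        hi = ltq.binarize(pm, t_hi)
        assert not (hi.data & ~lo.data).any()  # raising threshold never adds


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        h = ltq.train_backbone(_toy_samples(), TestTraining.CFG)
        ltq.save_backbone(h, tmp_path / "ckpt")
        back = ltq.load_backbone(tmp_path / "ckpt")
        vol = _toy_samples(1, seed=5)[0][0]
        np.testing.assert_array_equal(
            ltq.predict(h, vol).data, ltq.predict(back, vol).data
        )
        assert back.cfg == h.cfg

    def test_missing_checkpoint_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ltq.load_backbone(tmp_path / "nope")


class TestLiverDiceOnPhantoms:
    def test_mean_dice_at_least_080_on_held_out_phantoms(self):
        """A desk-scale check of segmentation quality on synthetic livers."""
        train = [small_phantom(seed=i, ldi=float([0, 10][i % 2])) for i in range(6)]
        cfg = BackboneConfig(
            depth=2, base_channels=8, input_size=48, epochs=6, seed=11, task="liver"
        )
        h = ltq.train_backbone([(s.volume, s.liver_gt) for s in train], cfg)
        dices = []
        for i in range(12):
            s = small_phantom(seed=500 + i, ldi=float([0, 5, 15][i % 3]))
            m = ltq.binarize(ltq.predict(h, s.volume), 0.5)
            inter = np.count_nonzero(m.data & s.liver_gt.data)
            dices.append(2 * inter / (m.count() + s.liver_gt.count()))
        assert float(np.mean(dices)) >= 0.80
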