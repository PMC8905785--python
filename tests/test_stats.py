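"""Segmentation metrics, fold dealing, and agreement analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ltq

from conftest import brute_force_metrics

SP = (1.0, 1.0, 1.0)


def _mask(data, role="liver"):
    return ltq.BinaryMask(data, SP, role=role)


class TestSegMetrics:
    def test_identity(self, rng):
        data = rng.random((6, 8, 8)) < 0.4
        m = ltq.seg_metrics(_mask(data), _mask(data))
        assert (m.dice, m.recall, m.precision, m.rvd, m.voe) == (1, 1, 1, 0, 0)

    def test_frozen_counts_example(self):
        # |S|=4, |GT|=6, |S n GT|=3
        s = np.zeros((1, 8, 8), bool)
        gt = np.zeros((1, 8, 8), bool)
        s.ravel()[[0, 1, 2, 10]] = True
        gt.ravel()[[0, 1, 2, 20, 21, 22]] = True
        m = ltq.seg_metrics(_mask(s), _mask(gt))
        assert m.dice == pytest.approx(0.6)
        assert m.recall == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.75)
        assert m.rvd == pytest.approx(-1 / 3)
        assert m.voe == pytest.approx(1 - 3 / 7)

    def test_disjoint_masks(self):
        s = np.zeros((1, 8, 8), bool)
        gt = np.zeros((1, 8, 8), bool)
        s[0, 0, :3] = True
        gt[0, 5, :3] = True
        m = ltq.seg_metrics(_mask(s), _mask(gt))
        assert (m.dice, m.recall, m.precision, m.voe) == (0, 0, 0, 1)

    def test_empty_gt_flagged_undefined(self):
        s = np.zeros((1, 8, 8), bool)
        s[0, 0, 0] = True
        m = ltq.seg_metrics(_mask(s), _mask(np.zeros_like(s)))
        assert not m.defined and np.isnan(m.dice)

    def test_empty_segmentation_precision_zero_with_flag(self):
        gt = np.zeros((1, 8, 8), bool)
        gt[0, 0, :4] = True
        m = ltq.seg_metrics(_mask(np.zeros_like(gt)), _mask(gt))
        assert m.precision == 0.0 and m.recall == 0.0
        assert any("empty segmentation" in f for f in m.flags)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (4, 6, 6)
        s = rng.random(shape) < rng.uniform(0.1, 0.6)
        gt = rng.random(shape) < rng.uniform(0.1, 0.6)
        if not gt.any():
            gt.ravel()[0] = True
        m = ltq.seg_metrics(_mask(s), _mask(gt))
        ref = brute_force_metrics(s, gt)
        for k in ("dice", "recall", "precision", "rvd", "voe"):
            assert getattr(m, k) == pytest.approx(ref[k]), k
        # Dice and VOE are tied by the identity dice = 2(1-voe)/(2-voe)
        assert m.dice == pytest.approx(2 * (1 - m.voe) / (2 - m.voe))


class TestMakeCvFolds:
    def test_partition_contract(self):
        cases = [(f"c{i}", float(i)) for i in range(10)]
        folds = ltq.make_cv_folds(cases, k=5, seed=1)
        assert set(folds) == {c for c, _ in cases}
        sizes = pd.Series(list(folds.values())).value_counts()
        assert sorted(sizes) == [2] * 5

    @pytest.mark.parametrize("seed", range(10))
    def test_severe_cases_never_share_a_fold(self, seed):
        ldis = [0, 0, 0, 0, 10, 10, 10, 10, 20, 20]
        cases = [(f"c{i}", float(v)) for i, v in enumerate(ldis)]
        folds = ltq.make_cv_folds(cases, k=5, seed=seed)
        severe = [folds[c] for c, v in cases if v == 20]
        assert len(set(severe)) == 2

    def test_deterministic(self):
        cases = [(f"c{i}", float(i % 4)) for i in range(12)]
        assert ltq.make_cv_folds(cases, 4, seed=7) == ltq.make_cv_folds(cases, 4, seed=7)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ltq.make_cv_folds([("a", 1.0), ("a", 2.0), ("b", 0.0)], k=2)

    def test_bounds(self):
        with pytest.raises(ValueError):
            ltq.make_cv_folds([("a", 1.0), ("b", 2.0)], k=1)
        with pytest.raises(ValueError):
            ltq.make_cv_folds([("a", 1.0), ("b", 2.0)], k=3)


class TestLdiAgreement:
    def test_exact_identity(self):
        pairs = [(1.0, 1.0), (5.0, 5.0), (12.0, 12.0), (30.0, 30.0)]
        a = ltq.ldi_agreement(pairs)
        assert a.slope == pytest.approx(1.0)
        assert a.intercept == pytest.approx(0.0, abs=1e-12)
        assert a.r_squared == pytest.approx(1.0)
        assert a.bias == 0.0 and a.loa_low == a.loa_high == 0.0

    def test_alternating_unit_differences_closed_form(self):
        # differences {+1,-1,+1,-1}: bias 0, sd = sqrt(4/3)
        pairs = [(1.0, 0.0), (4.0, 5.0), (16.0, 15.0), (29.0, 30.0)]
        a = ltq.ldi_agreement(pairs)
        sd = np.sqrt(4.0 / 3.0)
        assert a.bias == pytest.approx(0.0)
        assert a.loa_high == pytest.approx(1.96 * sd)
        assert a.loa_low == pytest.approx(-1.96 * sd)

    def test_constant_shift(self):
        pairs = [(r + 2.0, r) for r in (0.0, 5.0, 15.0, 30.0)]
        a = ltq.ldi_agreement(pairs)
        assert a.slope == pytest.approx(1.0)
        assert a.bias == pytest.approx(2.0)

    def test_bias_equals_mean_difference_exactly(self, rng):
        comp = rng.uniform(0, 30, 15)
        ref = rng.uniform(0, 30, 15)
        a = ltq.ldi_agreement(list(zip(comp, ref)))
        assert a.bias == pytest.approx(comp.mean() - ref.mean(), rel=1e-14)

    def test_degenerate_reference_flagged(self):
        a = ltq.ldi_agreement([(1.0, 5.0), (2.0, 5.0), (3.0, 5.0)])
        assert a.degenerate and np.isnan(a.slope)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ltq.ldi_agreement([(1.0, 1.0), (2.0, 2.0)])


class TestStratifiedSummary:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["reference_ldi", "dice"])

    def test_mean_of_two_cases_in_one_stratum(self):
        out = ltq.stratified_summary(self._frame([(3.0, 0.4), (4.0, 0.6)]))
        mid = out[out.stratum == "[2, 5)"].iloc[0]
        assert mid.n == 2 and mid.dice_mean == pytest.approx(0.5)

    def test_boundary_goes_to_upper_stratum(self):
        out = ltq.stratified_summary(self._frame([(2.0, 0.9)]))
        assert out[out.stratum == "[2, 5)"].iloc[0].n == 1
        assert out[out.stratum == "[0, 2)"].iloc[0].n == 0

    def test_single_case_and_empty_bins(self):
        out = ltq.stratified_summary(self._frame([(7.0, 0.8)]))
        top = out[out.stratum == ">= 5"].iloc[0]
        assert top.n == 1 and top.dice_mean == pytest.approx(0.8) and top.dice_sd == 0.0
        assert np.isnan(out[out.stratum == "[0, 2)"].iloc[0].dice_mean)
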