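"""Trauma candidate exclusion rules and the full refinement chain."""

import numpy as np
import pytest
from scipy import ndimage

import ltq
from ltq.trauma_postprocess import ExclusionParams

from conftest import inject_texture_candidates, small_phantom

SP = (1.0, 1.0, 1.0)


def _lattice_masks(trauma_data, liver_data):
    return (
        ltq.BinaryMask(trauma_data, SP, role="trauma"),
        ltq.BinaryMask(liver_data, SP, role="liver"),
    )


class TestExcludeOutsideLiver:
    def _component_case(self, n_outside):
        # one straight 10-voxel component; liver covers 10 - n_outside of it
        trauma = np.zeros((3, 12, 12), bool)
        trauma[1, 1, 1:11] = True
        liver = np.zeros_like(trauma)
        liver[1, :, : 11 - n_outside] = True
        return _lattice_masks(trauma, liver)

    def test_sixty_percent_outside_dropped(self):
        trauma, liver = self._component_case(6)
        assert ltq.exclude_outside_liver(trauma, liver, 0.5).count() == 0

    def test_exactly_half_outside_retained_whole(self):
        trauma, liver = self._component_case(5)
        out = ltq.exclude_outside_liver(trauma, liver, 0.5)
        assert np.array_equal(out.data, trauma.data)  # kept including outside part

    def test_fully_inside_untouched(self):
        trauma = np.zeros((3, 12, 12), bool)
        trauma[1, 3:6, 3:6] = True
        liver = np.ones_like(trauma)
        t, l = _lattice_masks(trauma, liver)
        assert np.array_equal(ltq.exclude_outside_liver(t, l).data, trauma)

    def test_never_adds_voxels(self, rng):
        for _ in range(10):
            t, l = _lattice_masks(
                rng.random((6, 10, 10)) < 0.2, rng.random((6, 10, 10)) < 0.5
            )
            out = ltq.exclude_outside_liver(t, l)
            assert not (out.data & ~t.data).any()

    def test_lattice_mismatch_rejected(self):
        t = ltq.BinaryMask(np.zeros((3, 10, 10), bool), SP, role="trauma")
        l = ltq.BinaryMask(np.zeros((4, 10, 10), bool), SP, role="liver")
        with pytest.raises(ValueError, match="lattice"):
            ltq.exclude_outside_liver(t, l)


class TestTTestExclusion:
    def _scene(self, comp_shift, rng, n_comp=125):
        """Liver box of N(110,10) with a 5x5x5 candidate shifted by comp_shift."""
        shape = (12, 20, 20)
        data = rng.normal(110.0, 10.0, shape)
        liver = np.zeros(shape, bool)
        liver[1:11, 1:19, 1:19] = True
        comp = np.zeros(shape, bool)
        comp[3:8, 3:8, 3:8] = True
        data[comp] = rng.normal(110.0 + comp_shift, 10.0, n_comp)
        vol = ltq.CTVolume(data, SP)
        return vol, ltq.BinaryMask(comp, SP, role="trauma"), ltq.BinaryMask(liver, SP, role="liver")

    def test_same_distribution_dropped(self, rng):
        vol, comp, liver = self._scene(0.0, rng)
        out, rep = ltq.ttest_exclusion(vol, comp, liver, tstat_threshold=5.0)
        assert out.count() == 0
        assert not rep.kept.iloc[0]

    def test_hypodense_component_retained_welch_formula(self, rng):
        vol, comp, liver = self._scene(-50.0, rng)
        out, rep = ltq.ttest_exclusion(vol, comp, liver, tstat_threshold=5.0)
        assert out.count() == comp.count()
        # cross-check the reported statistic against the textbook Welch formula
        a = vol.data[liver.data & ~comp.data]
        b = vol.data[comp.data]
        t_hand = (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        )
        assert rep.t_stat.iloc[0] == pytest.approx(t_hand, rel=1e-12)
        assert t_hand > 5.0

    def test_hyperdense_component_dropped_by_signed_rule(self, rng):
        vol, comp, liver = self._scene(+50.0, rng)
        out, rep = ltq.ttest_exclusion(vol, comp, liver, tstat_threshold=5.0)
        assert out.count() == 0 and rep.t_stat.iloc[0] < 0

    def test_tiny_component_dropped_with_reason(self, rng):
        shape = (6, 10, 10)
        data = rng.normal(110, 10, shape)
        liver = np.ones(shape, bool)
        comp = np.zeros(shape, bool)
        comp[3, 5, 5] = True
        vol = ltq.CTVolume(data, SP)
        out, rep = ltq.ttest_exclusion(
            vol, ltq.BinaryMask(comp, SP, role="trauma"),
            ltq.BinaryMask(liver, SP, role="liver"),
        )
        assert out.count() == 0
        assert rep.reason.iloc[0] == "insufficient sample"

    def test_fatty_phantom_texture_candidate_dropped(self, rng):
        s = small_phantom(seed=31, ldi=0.0, confounder="fatty")
        init = inject_texture_candidates(s, rng, n_blobs=1)
        out, rep = ltq.ttest_exclusion(s.volume, init, s.liver_gt)
        assert out.count() == 0
        assert (~rep.kept).all()

    def test_never_adds_voxels(self, rng):
        s = small_phantom(seed=32, ldi=10.0)
        init = ltq.BinaryMask(
            ndimage.binary_dilation(s.trauma_gt.data), s.spec.spacing_mm, role="trauma"
        )
        out, _ = ltq.ttest_exclusion(s.volume, init, s.liver_gt)
        assert not (out.data & ~init.data).any()


class TestPostprocessTrauma:
    def test_empty_init_short_circuits(self):
        s = small_phantom(seed=33)
        init = ltq.BinaryMask(np.zeros(s.volume.shape, bool), s.spec.spacing_mm, role="trauma")
        out = ltq.postprocess_trauma(s.volume, init, s.liver_gt)
        assert out.count() == 0

    def test_dilated_oracle_recovers_trauma(self, trauma_phantom):
        s = trauma_phantom
        init = ltq.BinaryMask(
            ndimage.binary_dilation(s.trauma_gt.data), s.spec.spacing_mm, role="trauma"
        )
        out = ltq.postprocess_trauma(s.volume, init, s.liver_gt)
        inter = np.count_nonzero(out.data & s.trauma_gt.data)
        dice = 2 * inter / (out.count() + s.trauma_gt.count())
        assert dice >= 0.85

    def test_output_subset_of_liver(self, trauma_phantom, rng):
        s = trauma_phantom
        init_data = ndimage.binary_dilation(s.trauma_gt.data, iterations=2)
        init_data |= rng.random(s.volume.shape) < 0.001
        init = ltq.BinaryMask(init_data, s.spec.spacing_mm, role="trauma")
        out = ltq.postprocess_trauma(s.volume, init, s.liver_gt)
        assert not (out.data & ~s.liver_gt.data).any()

    def test_texture_false_positives_suppressed(self, rng):
        # congestive heterogeneity is the hardest confounder: a candidate in
        # a genuinely dark patch can survive the intensity test, so a single
        # case is only required to stay below 2%; the cohort-level <1%
        # behaviour is covered by the false-positive suppression test in the
        # acceptance suite
        s = small_phantom(seed=34, ldi=0.0, confounder="congestive")
        init = inject_texture_candidates(s, rng)
        out = ltq.postprocess_trauma(s.volume, init, s.liver_gt)
        assert ltq.compute_ldi(s.liver_gt, out).ldi_pct < 2.0

    def test_report_returned_on_request(self, trauma_phantom):
        s = trauma_phantom
        init = ltq.BinaryMask(
            ndimage.binary_dilation(s.trauma_gt.data), s.spec.spacing_mm, role="trauma"
        )
        out, rep = ltq.postprocess_trauma(
            s.volume, init, s.liver_gt, return_report=True
        )
        assert {"component", "size", "t_stat", "kept", "reason"} <= set(rep.columns)
        assert rep.kept.any()


class TestExclusionParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ExclusionParams(outside_fraction_threshold=1.5)
        with pytest.raises(ValueError):
            ExclusionParams(tstat_threshold=0.0)
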