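"""Ratio traces, TIRF normalization, trace transforms, AUC."""

import numpy as np
import pytest

import translocq as tq
from translocq.quantify import EmptyRegionError

from conftest import rois_from_truth, truth_masks


def simple_trace(values, dt_s=30.0, stim=2, **kwargs):
    values = np.asarray(values, dtype=float)
    return tq.TraceSet(
        time_s=np.arange(len(values)) * dt_s,
        values=values,
        kind="pm_cyto_ratio",
        stimulus_frame=stim,
        **kwargs,
    )


class TestMaskedMean:
    def test_constant_and_checkerboard(self):
        assert tq.masked_mean(np.full((4, 4), 3.0), np.ones((4, 4), bool)) == 3.0
        checker = np.indices((4, 4)).sum(axis=0) % 2 * 2.0
        assert tq.masked_mean(checker, np.ones((4, 4), bool)) == 1.0

    def test_three_pixel_region(self):
        frame = np.zeros((3, 3))
        frame[0, :3] = [10, 20, 60]
        region = np.zeros((3, 3), bool)
        region[0, :3] = True
        assert tq.masked_mean(frame, region) == 30.0

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            tq.masked_mean(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestRatioTrace:
    def test_uniform_cell_gives_unity(self, noiseless_render):
        stack, truth = noiseless_render
        flat = tq.ImageStack(
            data=np.where(truth.cell_mask, 100.0, 0.0)[None, None].repeat(3, axis=0),
            pixel_size_nm=160,
            frame_interval_s=15,
            channel_roles=("biosensor",),
            stimulus_frame=1,
        )
        trace = tq.ratio_trace(flat, truth_masks(flat, truth), rois_from_truth(truth))
        assert np.allclose(trace.values, 1.0)

    def test_matches_synthetic_oracle(self, noiseless_render):
        stack, truth = noiseless_render
        trace = tq.ratio_trace(stack, truth_masks(stack, truth), rois_from_truth(truth))
        rel = np.abs(trace.values - truth.expected_ratio) / truth.expected_ratio
        assert rel.max() < 0.005

    def test_background_offset_invariance(self, noiseless_render):
        stack, truth = noiseless_render
        rois = rois_from_truth(truth)
        masks = truth_masks(stack, truth)
        base = tq.ratio_trace(stack, masks, rois)
        shifted = tq.ImageStack(
            data=stack.data + 37.5,
            pixel_size_nm=stack.pixel_size_nm,
            frame_interval_s=stack.frame_interval_s,
            channel_roles=stack.channel_roles,
            stimulus_frame=stack.stimulus_frame,
        )
        moved = tq.ratio_trace(shifted, masks, rois)
        assert np.allclose(base.values, moved.values, rtol=1e-10)

    def test_gain_invariance_with_zero_background(self, noiseless_scene):
        s = tq.SceneSpec(
            poisson_scale=0.0, read_sigma=0.0, background_offset=0.0, seed=7
        )
        stack, truth = tq.render_confocal_timelapse(s)
        rois = rois_from_truth(truth)
        masks = truth_masks(stack, truth)
        base = tq.ratio_trace(stack, masks, rois)
        scaled_stack = tq.ImageStack(
            data=stack.data * 4.2,
            pixel_size_nm=stack.pixel_size_nm,
            frame_interval_s=stack.frame_interval_s,
            channel_roles=stack.channel_roles,
            stimulus_frame=stack.stimulus_frame,
        )
        scaled = tq.ratio_trace(scaled_stack, masks, rois)
        assert np.allclose(base.values, scaled.values, rtol=1e-10)

    def test_empty_mask_frames_flagged_and_interpolated(self, noiseless_render):
        stack, truth = noiseless_render
        masks = truth_masks(stack, truth).copy()
        masks[5] = False
        trace = tq.ratio_trace(stack, masks, rois_from_truth(truth))
        assert trace.flagged[5] and not trace.flagged[4]
        expected = 0.5 * (trace.values[4] + trace.values[6])
        assert trace.values[5] == pytest.approx(expected)

    def test_all_frames_invalid_is_an_error(self, noiseless_render):
        stack, truth = noiseless_render
        masks = np.zeros((stack.n_frames, *stack.shape_yx), bool)
        with pytest.raises(ValueError, match="every frame"):
            tq.ratio_trace(stack, masks, rois_from_truth(truth))


class TestFootprint:
    @staticmethod
    def disc_movie(bright=200.0, n=4):
        yy, xx = np.ogrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        data = np.where(disc, bright, 5.0)[None, None].repeat(n, axis=0)
        return tq.ImageStack(
            data=data,
            pixel_size_nm=160,
            frame_interval_s=15,
            channel_roles=("biosensor",),
            stimulus_frame=2,
        ), disc

    def test_recovers_static_disc(self):
        stack, disc = self.disc_movie()
        fp = tq.footprint_roi(stack)
        iou = (fp & disc).sum() / (fp | disc).sum()
        assert iou >= 0.9

    def test_min_projection_ignores_transient_bright_frame(self):
        stack, _ = self.disc_movie()
        baseline = tq.footprint_roi(stack)
        stack.data[1] += 5000.0  # one flash frame
        assert np.array_equal(tq.footprint_roi(stack), baseline)


class TestFtFpre:
    def test_constant_movie_gives_unit_trace(self):
        stack, disc = TestFootprint.disc_movie(n=6)
        trace = tq.ft_fpre_trace(stack, disc, ~disc)
        assert np.allclose(trace.values, 1.0)

    def test_doubling_after_stimulus(self):
        stack, disc = TestFootprint.disc_movie(n=6)
        stack.data[:, :, disc] = 100.0
        stack.data[2:, :, disc] = 200.0
        stack.data[:, :, ~disc] = 0.0
        trace = tq.ft_fpre_trace(stack, disc, ~disc)
        assert np.allclose(trace.values[2:], 2.0)

    def test_prestim_mean_is_exactly_one(self):
        stack, truth = tq.render_tirf_timelapse(tq.SceneSpec(seed=13))
        trace = tq.ft_fpre_trace(stack, truth.cell_mask, truth.background_mask)
        pre = trace.values[: trace.stimulus_frame]
        assert abs(pre.mean() - 1.0) < 1e-12

    def test_noiseless_matches_ground_truth(self):
        s = tq.SceneSpec(poisson_scale=0.0, read_sigma=0.0, seed=13)
        stack, truth = tq.render_tirf_timelapse(s)
        trace = tq.ft_fpre_trace(stack, truth.cell_mask, truth.background_mask)
        rel = np.abs(trace.values - truth.ft_fpre) / truth.ft_fpre
        assert rel.max() < 0.005

    def test_nonpositive_baseline_raises(self):
        stack, disc = TestFootprint.disc_movie(bright=0.0)
        stack.data[:] = 0.0
        with pytest.raises(ValueError, match="F_pre"):
            tq.ft_fpre_trace(stack, disc, ~disc)


class TestTraceTransforms:
    def test_delta_examples(self):
        assert np.allclose(
            tq.delta_trace(simple_trace([2, 2, 2, 2])).values, 0.0
        )
        t = tq.delta_trace(simple_trace([1, 1, 1.5, 1.5]))
        assert t.values[-1] == pytest.approx(0.5)
        t = tq.delta_trace(simple_trace([0.9, 1.1, 1.6, 1.6]))
        assert t.values[-1] == pytest.approx(0.6)

    def test_delta_window_validation(self):
        with pytest.raises(ValueError):
            tq.delta_trace(simple_trace([1, 2, 3]), baseline_window=(0, 9))

    def test_max_normalize(self):
        t = tq.max_normalize(simple_trace([1, 2, 4]))
        assert np.allclose(t.values, [0.25, 0.5, 1.0])
        assert np.allclose(tq.max_normalize(simple_trace([3, 3, 3])).values, 1.0)
        already = simple_trace([0.5, 1.0, 0.25])
        assert np.allclose(tq.max_normalize(already).values, already.values)
        with pytest.raises(ValueError):
            tq.max_normalize(simple_trace([-1, -2, -3]))

    def test_auc_of_flat_trace_is_zero(self):
        assert tq.auc(simple_trace([1, 1, 1, 1, 1])) == pytest.approx(0.0)

    def test_auc_hand_trapezoid(self):
        # baseline 0, response {0,1,1,1} at dt = 0.5 min
        t = simple_trace([0, 0, 0, 1, 1, 1], dt_s=30.0, stim=2)
        assert tq.auc(t) == pytest.approx(1.25)

    def test_auc_linear_in_amplitude(self):
        a = tq.auc(simple_trace([0, 0, 0, 1, 2, 1], stim=2))
        b = tq.auc(simple_trace([0, 0, 0, 3, 6, 3], stim=2))
        assert b == pytest.approx(3 * a)

    def test_auc_window_validation(self):
        with pytest.raises(ValueError):
            tq.auc(simple_trace([1, 2, 3, 4]), response_window=(3, 2))


class TestKineticRecovery:
    def test_recovers_parameters_from_noiseless_trace(self, noiseless_render):
        stack, truth = noiseless_render
        trace = tq.ratio_trace(stack, truth_masks(stack, truth), rois_from_truth(truth))
        phi = tq.invert_ratio_to_fraction(trace.values, truth.area_ratio)
        fit = tq.fit_first_order_response(trace.time_s, phi, 120.0)
        assert fit.phi0 == pytest.approx(0.1, rel=1e-4)
        assert fit.delta_phi == pytest.approx(0.4, rel=1e-3)
        assert fit.tau_on == pytest.approx(60.0, rel=1e-3)

    def test_median_recovery_under_noise(self):
        errs_tau, errs_dphi = [], []
        for i in range(8):
            s = tq.SceneSpec(seed=500 + i)
            stack, truth = tq.render_confocal_timelapse(s)
            trace = tq.ratio_trace(
                stack, truth_masks(stack, truth), rois_from_truth(truth)
            )
            phi = tq.invert_ratio_to_fraction(trace.values, truth.area_ratio)
            fit = tq.fit_first_order_response(trace.time_s, phi, 120.0)
            errs_tau.append(abs(fit.tau_on - 60.0) / 60.0)
            errs_dphi.append(abs(fit.delta_phi - 0.4) / 0.4)
        assert np.median(errs_tau) < 0.10
        assert np.median(errs_dphi) < 0.10

    def test_ratio_inversion_round_trip(self):
        phi = np.linspace(0.0, 0.8, 9)
        ratio = 1.0 + phi / (1.0 - phi) * 6.5
        assert np.allclose(tq.invert_ratio_to_fraction(ratio, 6.5), phi)
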