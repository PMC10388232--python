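import numpy as np
import pytest

from gaitdtw.dtw import dtw_distance
from gaitdtw.gait_model import (
    GaitProfileParams,
    ImpairmentProfile,
    healthy_step,
    impaired_step,
    synth_subject_pair,
    synth_trial,
)
from gaitdtw.preprocess import detect_steps


class TestHealthyStep:
    def test_control_points(self, noiseless_params):
        """Curve passes through the loading-response peak, mid-stance
        valley and push-off peak amplitudes within 2%."""
        p = noiseless_params
        curve = healthy_step(p)
        x = np.linspace(0, 1, len(curve))
        for frac, amp in [
            (p.peak1_time_frac, p.peak1_amp),
            (p.valley_time_frac, p.valley_amp),
            (p.peak2_time_frac, p.peak2_amp),
        ]:
            value = curve[np.argmin(np.abs(x - frac))]
            assert value == pytest.approx(amp * p.body_weight, rel=0.02)
        assert curve.max() == pytest.approx(p.peak1_amp * p.body_weight, rel=0.02)

    def test_boundaries_and_length(self, noiseless_params):
        curve = healthy_step(noiseless_params)
        assert len(curve) == round(
            noiseless_params.stance_duration * noiseless_params.sample_rate
        )
        assert curve[0] == 0.0 and curve[-1] == 0.0

    def test_linear_in_body_weight(self, noiseless_params):
        c1 = healthy_step(noiseless_params)
        c2 = healthy_step(noiseless_params.replace(body_weight=1400.0))
        assert np.allclose(c2, 2 * c1)

    def test_bad_phase_ordering_rejected(self):
        with pytest.raises(ValueError):
            GaitProfileParams(peak1_time_frac=0.6, valley_time_frac=0.5)


class TestImpairedStep:
    def test_zero_severity_is_healthy(self, noiseless_params):
        imp = ImpairmentProfile.from_severity(0.0)
        assert np.array_equal(
            impaired_step(noiseless_params, imp), healthy_step(noiseless_params)
        )

    def test_severity_increases_dtw_distance(self, noiseless_params):
        ref = healthy_step(noiseless_params)
        d_mild = dtw_distance(ref, impaired_step(noiseless_params, ImpairmentProfile.from_severity(0.2)))
        d_severe = dtw_distance(ref, impaired_step(noiseless_params, ImpairmentProfile.from_severity(1.0)))
        assert d_severe > d_mild

    def test_push_off_deficit_lowers_second_peak(self, noiseless_params):
        curve = impaired_step(noiseless_params, ImpairmentProfile(push_off_atten=1.0))
        x = np.linspace(0, 1, len(curve))
        assert curve[x > 0.6].max() < curve[x < 0.5].max()

    def test_monotone_in_severity_grid(self, noiseless_params):
        """DTW distance to the healthy reference is non-decreasing over
        severities 0, 0.1, ..., 1 (noise off)."""
        ref = healthy_step(noiseless_params)
        dists = [
            dtw_distance(
                ref, impaired_step(noiseless_params, ImpairmentProfile.from_severity(s))
            )
            for s in np.arange(0.0, 1.01, 0.1)
        ]
        assert dists[0] == 0.0
        assert all(a <= b + 1e-9 for a, b in zip(dists, dists[1:]))

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_attenuation_bounds(self, bad):
        with pytest.raises(ValueError):
            ImpairmentProfile(mid_stance_atten=bad)


class TestSynthTrial:
    def test_round_trip_segmentation(self, noiseless_params):
        """Noiseless 10-step trial: the segmenter recovers exactly the
        ground-truth windows within 2 samples."""
        trial = synth_trial(noiseless_params, None, n_steps=10)
        segs = detect_steps(trial.signal)
        assert len(segs) == 10
        for seg, (t0, t1) in zip(segs, trial.true_step_windows):
            assert abs(seg.start_index - t0) <= 2
            assert abs(seg.end_index - t1) <= 2

    def test_plate_quantization_and_saturation(self, params):
        trial = synth_trial(params.replace(seed=9), None, n_steps=10)
        f = trial.signal.force
        q = params.quantization_step
        assert np.allclose(np.round(f / q) * q, f, atol=1e-9)
        assert f.max() <= params.clip_compression
        assert f.min() >= params.clip_tension

    def test_saturation_clips_extreme_forces(self):
        p = GaitProfileParams(body_weight=4000.0, noise_sd=0.0)
        trial = synth_trial(p, None, n_steps=1)
        assert trial.signal.force.max() == pytest.approx(3500.0)

    def test_same_seed_bit_identical(self, params):
        a = synth_trial(params.replace(seed=11), None, n_steps=4)
        b = synth_trial(params.replace(seed=11), None, n_steps=4)
        assert np.array_equal(a.signal.force, b.signal.force)
        assert a.true_step_windows == b.true_step_windows

    def test_windows_inside_signal_and_disjoint(self, params):
        trial = synth_trial(params, None, n_steps=5, inter_step_gap=0.4)
        prev = 0
        for start, end in trial.true_step_windows:
            assert prev <= start < end <= trial.signal.n_samples
            prev = end

    def test_noiseless_healthy_pipeline_self_distance_zero(self, noiseless_params):
        """A noiseless healthy trial segmented and compared to its own
        step gives DTW distance 0 (quantization off)."""
        p = noiseless_params.replace(quantization_step=0.0)
        trial = synth_trial(p, None, n_steps=2)
        segs = detect_steps(trial.signal)
        assert dtw_distance(segs[0].force, segs[1].force) == 0.0

    def test_quantization_perturbs_distance_at_most_n_steps(self, noiseless_params):
        """Quantizing to the plate resolution moves the DTW distance of a
        healthy step by at most n x quantization_step."""
        ref = healthy_step(noiseless_params)
        quantized = synth_trial(noiseless_params, None, n_steps=1)
        raw = synth_trial(
            noiseless_params.replace(quantization_step=0.0), None, n_steps=1
        )
        (t0, t1) = quantized.true_step_windows[0]
        d_q = dtw_distance(ref, quantized.signal.force[t0:t1])
        d_r = dtw_distance(ref, raw.signal.force[t0:t1])
        n = len(ref)
        assert abs(d_q - d_r) <= n * noiseless_params.quantization_step


class TestSubjectPair:
    def test_determinism_and_ground_truth(self, params):
        a = synth_subject_pair(params, 0.8, 0.05, n_steps=3, seed=21)
        b = synth_subject_pair(params, 0.8, 0.05, n_steps=3, seed=21)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.signal.force, tb.signal.force)
        assert a[0].impairment.severity == pytest.approx(0.8)
        assert a[1].impairment.severity == pytest.approx(0.05)

    def test_independent_noise_streams(self, params):
        before, after = synth_subject_pair(params, 0.5, 0.5, n_steps=2, seed=3)
        assert not np.array_equal(before.signal.force, after.signal.force)
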