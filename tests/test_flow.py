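import math

import numpy as np
import pytest

from barcode_screen import (
    circular_summary,
    compile_of_metrics,
    compute_flow_field,
    run_of_branch,
)
from barcode_screen.errors import ParameterError, PipelineError
from barcode_screen.fixtures import FixtureSpec, make_translating_texture
from barcode_screen.flow import FlowField


def vectors_from_angles(angles, mag=1.0):
    a = np.asarray(angles)
    return np.stack([mag * np.cos(a), mag * np.sin(a)], axis=-1)


def flow_field(v_i=1.0, theta=0.0, idx=0, vectors=None):
    if vectors is None:
        vectors = vectors_from_angles([theta], mag=v_i)[None]
    return FlowField(field_index=idx, frame_pair=(idx, idx + 1), vectors=vectors,
                     v_i=v_i, theta_i=theta, sigma_theta_i=0.0, resultant_length=1.0)


class TestCircularSummary:
    def test_coherent_flow(self):
        theta, sigma, R = circular_summary(vectors_from_angles([1.0] * 7))
        assert theta == pytest.approx(1.0)
        assert sigma == pytest.approx(0.0, abs=1e-7)
        assert R == pytest.approx(1.0)

    def test_pi_boundary_averages_to_pi_not_zero(self):
        theta, sigma, R = circular_summary(
            vectors_from_angles([math.pi - 0.1, -math.pi + 0.1]))
        assert abs(theta) == pytest.approx(math.pi)
        assert R == pytest.approx(math.cos(0.1))
        assert sigma == pytest.approx(math.sqrt(-2 * math.log(math.cos(0.1))), rel=1e-9)
        assert sigma == pytest.approx(0.1001, abs=2e-4)

    def test_isotropic_directions(self, rng):
        theta, sigma, R = circular_summary(
            vectors_from_angles(rng.uniform(-math.pi, math.pi, 1000)))
        assert R < 0.1
        assert sigma >= 2.0

    def test_magnitude_unweighted(self, rng):
        angles = rng.uniform(-1, 1, 50)
        t1, s1, r1 = circular_summary(vectors_from_angles(angles, mag=1.0))
        mags = rng.uniform(0.1, 10.0, 50)
        v = np.stack([mags * np.cos(angles), mags * np.sin(angles)], axis=-1)
        t2, s2, r2 = circular_summary(v)
        assert t2 == pytest.approx(t1) and s2 == pytest.approx(s1)

    def test_all_zero_vectors_degenerate(self):
        theta, sigma, R = circular_summary(np.zeros((5, 2)))
        assert (theta, sigma, R) == (0.0, 0.0, 0.0)

    def test_rotation_shifts_theta_only(self, rng):
        angles = rng.normal(0.3, 0.4, 200)
        t0, s0, _ = circular_summary(vectors_from_angles(angles))
        t1, s1, _ = circular_summary(vectors_from_angles(angles + 1.2))
        assert t1 == pytest.approx(t0 + 1.2, abs=1e-9)
        assert s1 == pytest.approx(s0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            circular_summary(np.zeros((0, 2)))


class TestComputeFlowField:
    @pytest.fixture
    def texture(self, rng):
        from scipy import ndimage
        t = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 3.0, mode="wrap")
        return (200 * (t - t.min()) / (t.max() - t.min())).astype(np.float32)

    @staticmethod
    def shift(im, dr, dc):
        from scipy import ndimage
        return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(im), (dr, dc))))

    def test_rightward_shift_recovered(self, texture):
        f = compute_flow_field(texture, self.shift(texture, 0, 2), p=8)
        assert f.v_i == pytest.approx(2.0, abs=0.2)
        assert abs(f.theta_i) < 0.1

    def test_identity_frames_zero_field(self, texture):
        f = compute_flow_field(texture, texture, p=8)
        assert f.v_i <= 0.05

    def test_upward_shift_is_plus_half_pi(self, texture):
        # upward = decreasing row index
        f = compute_flow_field(texture, self.shift(texture, -3, 0), p=8)
        assert f.theta_i == pytest.approx(math.pi / 2, abs=0.1)
        assert f.v_i == pytest.approx(3.0, abs=0.3)

    def test_constant_frames_low_texture_flag(self):
        a = np.full((64, 64), 100.0)
        f = compute_flow_field(a, a, p=8)
        assert f.low_texture and f.v_i == 0.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(PipelineError):
            compute_flow_field(np.zeros((32, 32)), np.zeros((32, 48)))

    def test_frame_gap_normalization(self, texture):
        # the same displacement over a gap of 2 frames is half the velocity
        b = self.shift(texture, 0, 2)
        f1 = compute_flow_field(texture, b, p=8, frame_gap=1)
        f2 = compute_flow_field(texture, b, p=8, frame_gap=2)
        assert f2.v_i == pytest.approx(f1.v_i / 2, rel=1e-9)

    def test_grid_shape(self, texture):
        f = compute_flow_field(texture, texture, p=8)
        assert f.vectors.shape == (12, 12, 2)


class TestRigidTranslationRecovery:
    """Seeded textures advected at known (speed, direction)."""

    @pytest.mark.parametrize("speed", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("octant", range(8))
    def test_speed_and_direction(self, speed, octant):
        ang = -math.pi + (octant + 0.5) * math.pi / 4
        dx, dy = speed * math.cos(ang), -speed * math.sin(ang)
        video, truth = make_translating_texture(
            FixtureSpec("translating_texture", T=5, m=96, n=96, seed=octant,
                        params={"dx": dx, "dy": dy}))
        of, _ = run_of_branch(video, k=1, p=8)
        if speed >= 1.0:
            assert abs(of.v - truth["v"]) / truth["v"] <= 0.1
        err = abs((of.theta - truth["theta"] + math.pi) % (2 * math.pi) - math.pi)
        assert err <= 0.1
        assert of.sigma_theta <= 0.2

    def test_time_reversal_flips_direction(self):
        video, truth = make_translating_texture(
            FixtureSpec("translating_texture", T=5, m=96, n=96, seed=1,
                        params={"dx": 2.0, "dy": 0.0}))
        rev = video.frames[::-1].copy()
        fwd, _ = run_of_branch(video, k=1, p=8)
        import barcode_screen as bs
        vrev = bs.VideoTensor(frames=rev, dtype_kind="f32",
                              max_representable=video.max_representable)
        bwd, _ = run_of_branch(vrev, k=1, p=8)
        err = abs((bwd.theta - (truth["theta"] + math.pi) + math.pi) % (2 * math.pi) - math.pi)
        assert err <= 0.1

    def test_rotating_the_video_rotates_theta(self):
        video, truth = make_translating_texture(
            FixtureSpec("translating_texture", T=5, m=96, n=96, seed=2,
                        params={"dx": 2.0, "dy": 0.0}))
        rot = np.stack([np.rot90(f) for f in video.frames])  # CCW 90 degrees
        import barcode_screen as bs
        vrot = bs.VideoTensor(frames=rot, dtype_kind="f32",
                              max_representable=video.max_representable)
        of0, _ = run_of_branch(video, k=1, p=8)
        of1, _ = run_of_branch(vrot, k=1, p=8)
        err = abs((of1.theta - of0.theta - math.pi / 2 + math.pi) % (2 * math.pi) - math.pi)
        assert err <= 0.1
        assert of1.v == pytest.approx(of0.v, rel=0.05)
        assert of1.sigma_theta <= of0.sigma_theta + 0.05

    def test_stride_invariance_for_constant_motion(self):
        video, _ = make_translating_texture(
            FixtureSpec("translating_texture", T=9, m=96, n=96, seed=3,
                        params={"dx": 1.0, "dy": 0.0}))
        of1, _ = run_of_branch(video, k=1, p=8)
        of2, _ = run_of_branch(video, k=2, p=8)
        assert of2.v == pytest.approx(of1.v, rel=0.1)


class TestCompileOF:
    def test_steady_motion(self):
        fields = [flow_field(v_i=1.7, idx=i) for i in range(10)]
        m = compile_of_metrics(fields, X=5)
        assert m.v == pytest.approx(1.7) and m.delta_v == pytest.approx(0.0)

    def test_slowing_down(self):
        fields = [flow_field(v_i=1.0, idx=i) for i in range(5)] + \
                 [flow_field(v_i=0.5, idx=i) for i in range(5, 10)]
        m = compile_of_metrics(fields, X=10)  # n_X = 1
        assert m.delta_v == pytest.approx(-0.5)

    def test_vertical_coherent_flow(self):
        v = vectors_from_angles([math.pi / 2] * 16).reshape(4, 4, 2)
        fields = [FlowField(i, (i, i + 1), v, 1.0, math.pi / 2, 0.0, 1.0)
                  for i in range(4)]
        m = compile_of_metrics(fields)
        assert abs(m.theta) == pytest.approx(math.pi / 2)
        assert m.sigma_theta == pytest.approx(0.0, abs=1e-7)

    def test_empty_fields_undefined_sentinels(self):
        m = compile_of_metrics([])
        assert m.undefined and math.isnan(m.v) and math.isnan(m.theta)

    def test_single_frame_video_flagged(self, rng):
        import barcode_screen as bs
        vt = bs.VideoTensor(frames=rng.uniform(0, 200, (1, 32, 32)),
                            dtype_kind="f64", max_representable=200.0)
        m, fields = run_of_branch(vt, k=1)
        assert m.undefined and fields == []


def test_calibrated_velocity_units():
    """px/frame becomes um/s when both calibrations are set."""
    video, _ = make_translating_texture(
        FixtureSpec("translating_texture", T=4, m=96, n=96, seed=4,
                    params={"dx": 2.0, "dy": 0.0}))
    import barcode_screen as bs
    cal = bs.VideoTensor(frames=video.frames, dtype_kind="f32",
                         max_representable=video.max_representable,
                         pixel_size_um=0.5, frame_interval_s=2.0)
    of_px, _ = run_of_branch(video, k=1, p=8)
    of_um, _ = run_of_branch(cal, k=1, p=8)
    assert of_um.v == pytest.approx(of_px.v * 0.25, rel=1e-9)
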