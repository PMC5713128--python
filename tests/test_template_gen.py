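import numpy as np
import pytest

from quatdba.dtw_engine import dtw_quat
from quatdba.mocap_io import MoCapRecording, read_bvh, write_bvh
from quatdba.quat_core import cost_dot, dist_geodesic, quat_mul, rotate_vector
from quatdba.synthetic_data import (
    PerturbationModel,
    builtin_kick_specs,
    make_action_instance,
)
from quatdba.template_gen import (
    SmoothingKernel,
    TemplateParams,
    build_template,
    dba_average,
    heading_correction,
    heading_quaternion,
    markley_smooth,
    save_template,
)
from conftest import random_unit_quats


def _yaw_quat(deg):
    h = np.deg2rad(deg) / 2
    return np.array([np.cos(h), 0.0, np.sin(h), 0.0])


def _forward_angle_deg(q):
    f = rotate_vector(q, np.array([1.0, 0.0, 0.0]))
    return np.degrees(np.arccos(np.clip(f[0], -1.0, 1.0)))


def _single_joint_recording(root_sig, skeleton, other=None):
    signals = {}
    n = len(root_sig)
    for j in skeleton.joints:
        if not j.has_rotation:
            continue
        if j.parent is None:
            signals[j.name] = np.asarray(root_sig, dtype=float)
        else:
            signals[j.name] = np.tile([1.0, 0, 0, 0], (n, 1)) if other is None else other
    return MoCapRecording(skeleton=skeleton, frame_time=0.01, signals=signals)


class TestHeadingCorrection:
    def test_already_forward_is_unchanged(self, skeleton):
        rec = _single_joint_recording(np.tile([1.0, 0, 0, 0], (5, 1)), skeleton)
        out = heading_correction(rec)
        np.testing.assert_allclose(out.signals["Hips"], rec.signals["Hips"], atol=1e-12)

    def test_pure_yaw_is_cancelled(self, skeleton):
        rec = _single_joint_recording(np.tile(_yaw_quat(90.0), (5, 1)), skeleton)
        out = heading_correction(rec)
        assert _forward_angle_deg(out.signals["Hips"][0]) < 0.1

    def test_non_root_joints_bit_identical(self, skeleton):
        rng = np.random.default_rng(5)
        other = random_unit_quats(rng, 5)
        rec = _single_joint_recording(np.tile(_yaw_quat(123.0), (5, 1)), skeleton, other=other)
        out = heading_correction(rec)
        for j in skeleton.joints:
            if j.parent is not None and j.has_rotation:
                assert out.signals[j.name] is rec.signals[j.name] or np.array_equal(
                    out.signals[j.name], rec.signals[j.name]
                )

    def test_yaw_pitch_mixture_matches_finer_grid(self, skeleton):
        """Coarse-grid yaw is within 0.1 deg of a 10x finer grid's optimum."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            yaw = _yaw_quat(rng.uniform(0, 360))
            p = np.deg2rad(rng.uniform(-20, 20)) / 2
            pitch = np.array([np.cos(p), 0.0, 0.0, np.sin(p)])
            root = np.tile(quat_mul(yaw, pitch), (3, 1))
            rec = _single_joint_recording(root, skeleton)
            coarse = heading_correction(rec, step_deg=0.05)
            fine = heading_correction(rec, step_deg=0.005)
            a_coarse = _forward_angle_deg(coarse.signals["Hips"][0])
            a_fine = _forward_angle_deg(fine.signals["Hips"][0])
            assert a_coarse <= a_fine + 0.1

    def test_empty_root_signal(self, skeleton):
        rec = _single_joint_recording(np.tile([1.0, 0, 0, 0], (2, 1)), skeleton)
        rec.signals["Hips"] = np.empty((0, 4))
        with pytest.raises(ValueError):
            heading_quaternion(rec)


class TestDBA:
    def test_identical_copies_returned_exactly(self, rng):
        sig = random_unit_quats(rng, 20)
        out, trace = dba_average([sig] * 10, return_trace=True)
        assert max(cost_dot(a, b) for a, b in zip(out, sig)) < 1e-12
        assert trace[-1] == pytest.approx(0.0, abs=1e-12)

    def test_single_signal_unchanged(self, rng):
        sig = random_unit_quats(rng, 7)
        np.testing.assert_array_equal(dba_average([sig]), sig)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            dba_average([])

    def test_trace_non_increasing_and_template_closer_than_inputs(self, kick_specs):
        """Averaging time-warped noisy copies lands closer to the clean
        source than the inputs are on average."""
        pert = PerturbationModel(
            time_warp_strength=0.3, noise_deg=2.0, sign_flip_prob=0.2, heading_range=(0.0, 0.0)
        )
        rng = np.random.default_rng(17)
        spec = kick_specs[2]  # a mae-like action
        clean = make_action_instance(spec, PerturbationModel.none(), np.random.default_rng(0))
        clean_sig = clean.signals["LeftThigh"]
        inputs = [
            make_action_instance(spec, pert, rng).signals["LeftThigh"] for _ in range(10)
        ]
        out, trace = dba_average(inputs, return_trace=True)
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))
        d_template = dtw_quat(out, clean_sig).normalized_distance
        d_inputs = np.mean([dtw_quat(s, clean_sig).normalized_distance for s in inputs])
        assert d_template < d_inputs

    def test_sign_flip_invariance(self, rng):
        sigs = [random_unit_quats(rng, 10) for _ in range(4)]
        base = dba_average(sigs)
        flipped = []
        for s in sigs:
            mask = rng.uniform(size=len(s)) < 0.5
            s2 = s.copy()
            s2[mask] = -s2[mask]
            flipped.append(s2)
        out = dba_average(flipped)
        assert max(cost_dot(a, b) for a, b in zip(base, out)) < 1e-12


class TestSmoothing:
    def test_constant_signal_fixed_point(self, rng):
        q = random_unit_quats(rng, 1)[0]
        sig = np.tile(q, (30, 1))
        out = markley_smooth(sig, SmoothingKernel(ws=5))
        assert max(cost_dot(a, q) for a in out) < 1e-12

    def test_ws_zero_returns_input(self, rng):
        sig = random_unit_quats(rng, 10)
        out = markley_smooth(sig, SmoothingKernel(ws=0))
        assert max(cost_dot(a, b) for a, b in zip(out, sig)) < 1e-12

    def test_alternating_signs_collapse(self, rng):
        q = random_unit_quats(rng, 1)[0]
        sig = np.array([q if i % 2 == 0 else -q for i in range(20)])
        out = markley_smooth(sig, SmoothingKernel(ws=3))
        assert max(cost_dot(a, q) for a in out) < 1e-12

    def test_length_and_norm_preserved(self, rng):
        sig = random_unit_quats(rng, 25)
        out = markley_smooth(sig, SmoothingKernel(ws=4))
        assert out.shape == sig.shape
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_noise_reduction_on_constant(self, rng):
        """<=5 deg perturbations of a constant rotation shrink after smoothing."""
        q = random_unit_quats(rng, 1)[0]
        n = 200
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        ang = rng.uniform(0, np.deg2rad(5.0), size=n)
        noise = np.column_stack([np.cos(ang / 2), axes * np.sin(ang / 2)[:, None]])
        sig = quat_mul(noise, np.tile(q, (n, 1)))
        out = markley_smooth(sig, SmoothingKernel())
        before = np.mean([dist_geodesic(s, q) for s in sig])
        after = np.mean([dist_geodesic(s, q) for s in out])
        assert after < before

    def test_negative_ws_rejected(self):
        with pytest.raises(ValueError):
            SmoothingKernel(ws=-1)


class TestBuildTemplate:
    def test_identical_recordings_give_zero_distance_template(self, clean_recording):
        tpl = build_template([clean_recording] * 3, TemplateParams(ws=0))
        for name, sig in tpl.signals.items():
            d = dtw_quat(sig, clean_recording.signals[name]).normalized_distance
            assert d == pytest.approx(0.0, abs=1e-9)

    def test_deterministic(self, kick_specs):
        pert = PerturbationModel()
        recs = [
            make_action_instance(kick_specs[0], pert, np.random.default_rng(100 + i))
            for i in range(3)
        ]
        t1 = build_template(recs)
        t2 = build_template(recs)
        for name in t1.signals:
            np.testing.assert_array_equal(t1.signals[name], t2.signals[name])

    def test_provenance_and_traces(self, kick_specs):
        pert = PerturbationModel()
        recs = [
            make_action_instance(kick_specs[1], pert, np.random.default_rng(i)) for i in range(4)
        ]
        tpl = build_template(recs, source_ids=["a", "b", "c", "d"])
        assert tpl.provenance["source_ids"] == ["a", "b", "c", "d"]
        for trace in tpl.provenance["convergence_traces"].values():
            assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_too_few_or_mismatched_inputs(self, clean_recording, kick_specs):
        with pytest.raises(ValueError):
            build_template([clean_recording])
        other = make_action_instance(kick_specs[0], PerturbationModel.none(), np.random.default_rng(0))
        other.frame_time = 0.02
        with pytest.raises(ValueError):
            build_template([clean_recording, other])

    def test_template_roundtrips_as_bvh(self, tmp_path, kick_specs):
        pert = PerturbationModel()
        recs = [
            make_action_instance(kick_specs[3], pert, np.random.default_rng(i)) for i in range(3)
        ]
        tpl = build_template(recs)
        sidecar = save_template(tpl, tmp_path / "template.bvh")
        assert sidecar.exists()
        back = read_bvh(tmp_path / "template.bvh")
        assert back.n_frames == tpl.n_frames
        for name, sig in tpl.signals.items():
            angles = [dist_geodesic(a, b) for a, b in zip(sig, back.signals[name])]
            assert max(angles) < 1e-6
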