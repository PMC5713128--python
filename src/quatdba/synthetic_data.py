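"""Synthetic motion-capture sets with the statistical structure of real takes.

Repetitions of one action differ mainly by (a) a monotone nonlinear time
warp — the proportions between movement phases vary between takes, (b)
small rotational noise on every sample, (c) an arbitrary constant heading
(subjects do not face the same direction after calibration) and (d) the
quaternion sign ambiguity of whatever produced the data.  The generator
emulates exactly these four effects on top of smooth per-joint keyframe
trajectories interpolated with slerp, on a compact y-up skeleton whose
root is the hips.

Eight built-in kick-like classes (mawashi / mae / hiza / yoko, each left
and right) ship with the package; the mae- and hiza-like classes share
the thigh trajectory on purpose and differ mainly in shin motion, so any
classifier working on these sets faces the same confusable pair a real
karate dataset contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .mocap_io import MoCapRecording, Skeleton, Joint, write_bvh
from .quat_core import canonical_sign, quat_mul

__all__ = [
    "ActionSpec",
    "PerturbationModel",
    "canonical_skeleton",
    "builtin_kick_specs",
    "make_action_instance",
    "make_dataset",
    "subject_style",
    "write_dataset",
]


@dataclass
class ActionSpec:
    """One action class: per-joint keyframe rotations at normalized times.

    ``keyframes`` maps joint name to a list of ``(t, rotvec)`` pairs with
    ``t`` strictly increasing in [0, 1] and ``rotvec`` an axis-angle
    rotation vector in radians.  Joints without keyframes stay at identity.
    """

    label: str
    keyframes: dict[str, list[tuple[float, np.ndarray]]]
    duration: float = 2.5  # seconds
    rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        for joint, kfs in self.keyframes.items():
            ts = [t for t, _ in kfs]
            if any(not 0.0 <= t <= 1.0 for t in ts):
                raise ValueError(f"{joint}: keyframe times must lie in [0, 1]")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{joint}: keyframe times must be strictly increasing")


@dataclass
class PerturbationModel:
    """Per-take distortions applied to the clean keyframe trajectory.

    * ``time_warp_strength`` s bounds the warp derivative within
      ``[(1-s)/(1+s), (1+s)/(1-s)]`` of uniform speed;
    * ``noise_deg`` caps the per-sample random-axis rotation noise;
    * ``sign_flip_prob`` is the probability that a contiguous segment of
      samples has its quaternion sign flipped (exercises double-cover
      handling downstream);
    * ``heading_range`` bounds the random constant yaw of the root.
    """

    time_warp_strength: float = 0.3
    noise_deg: float = 2.0
    sign_flip_prob: float = 0.2
    heading_range: tuple[float, float] = (0.0, 360.0)

    def __post_init__(self) -> None:
        if self.time_warp_strength < 0 or not self.time_warp_strength < 1:
            raise ValueError("time_warp_strength must be in [0, 1)")
        if self.noise_deg < 0 or self.sign_flip_prob < 0:
            raise ValueError("perturbation parameters must be non-negative")
        lo, hi = self.heading_range
        if not (0.0 <= lo <= hi <= 360.0):
            raise ValueError("heading_range must be within [0, 360]")

    @classmethod
    def none(cls) -> "PerturbationModel":
        return cls(time_warp_strength=0.0, noise_deg=0.0, sign_flip_prob=0.0, heading_range=(0.0, 0.0))


def canonical_skeleton() -> Skeleton:
    """Compact unit-proportioned y-up skeleton of the reference body model."""
    j = [
        Joint("Hips", None, np.zeros(3), ("Xposition", "Yposition", "Zposition", "Zrotation", "Xrotation", "Yrotation")),
        Joint("Chest", "Hips", np.array([0.0, 0.30, 0.0]), ("Zrotation", "Xrotation", "Yrotation")),
        Joint("Head", "Chest", np.array([0.0, 0.30, 0.0]), ("Zrotation", "Xrotation", "Yrotation"),
              end_site=np.array([0.0, 0.15, 0.0])),
        Joint("LeftThigh", "Hips", np.array([0.11, -0.05, 0.0]), ("Zrotation", "Xrotation", "Yrotation")),
        Joint("LeftLeg", "LeftThigh", np.array([0.0, -0.45, 0.0]), ("Zrotation", "Xrotation", "Yrotation")),
        Joint("LeftFoot", "LeftLeg", np.array([0.0, -0.42, 0.0]), ("Zrotation", "Xrotation", "Yrotation"),
              end_site=np.array([0.0, -0.06, 0.14])),
        Joint("RightThigh", "Hips", np.array([-0.11, -0.05, 0.0]), ("Zrotation", "Xrotation", "Yrotation")),
        Joint("RightLeg", "RightThigh", np.array([0.0, -0.45, 0.0]), ("Zrotation", "Xrotation", "Yrotation")),
        Joint("RightFoot", "RightLeg", np.array([0.0, -0.42, 0.0]), ("Zrotation", "Xrotation", "Yrotation"),
              end_site=np.array([0.0, -0.06, 0.14])),
    ]
    return Skeleton(joints=j)


def _rv(x: float, y: float, z: float, deg: float) -> np.ndarray:
    axis = np.array([x, y, z], dtype=float)
    axis /= np.linalg.norm(axis)
    return axis * np.deg2rad(deg)


def _kick_spec(side: str, kind: str) -> ActionSpec:
    """Parametric kick trajectories; ``side`` mirrors axes and joints.

    Hip flexion lifts the thigh forward (negative rotation about x for the
    bone pointing down -y), abduction swings it laterally (about z, sign
    depending on side), knee flexion folds the shin backwards.
    """
    s = 1.0 if side == "left" else -1.0
    thigh = f"{side.capitalize()}Thigh"
    shin = f"{side.capitalize()}Leg"
    other_thigh = ("Right" if side == "left" else "Left") + "Thigh"

    def flex(deg: float) -> np.ndarray:  # knee flexion about x (folds the shin back)
        return _rv(1, 0, 0, deg)

    def mix(flex_deg: float, abduct_deg: float) -> np.ndarray:
        return np.array([np.deg2rad(-flex_deg), 0.0, np.deg2rad(s * abduct_deg)])

    zero = np.zeros(3)
    common = {
        "Hips": [(0.0, zero), (0.5, _rv(0, 1, 0, s * (10.0 if kind != "mawashi" else 35.0))), (1.0, zero)],
        "Chest": [(0.0, zero), (0.5, _rv(1, 0, 0, -6.0)), (1.0, zero)],
        other_thigh: [(0.0, zero), (0.5, _rv(1, 0, 0, 6.0)), (1.0, zero)],
    }
    if kind == "mae":  # front kick: chamber, brief knee extension, re-chamber
        kfs = {
            thigh: [(0.0, zero), (0.4, mix(75, 0)), (0.6, mix(75, 0)), (1.0, zero)],
            shin: [(0.0, zero), (0.3, flex(100)), (0.5, flex(55)), (0.7, flex(100)), (1.0, zero)],
        }
        duration = 2.2
    elif kind == "hiza":  # knee strike: same thigh path, knee stays folded
        kfs = {
            thigh: [(0.0, zero), (0.4, mix(75, 0)), (0.6, mix(75, 0)), (1.0, zero)],
            shin: [(0.0, zero), (0.3, flex(100)), (0.5, flex(95)), (0.7, flex(100)), (1.0, zero)],
        }
        duration = 2.0
    elif kind == "mawashi":  # roundhouse: flexion + moderate abduction, extension
        kfs = {
            thigh: [(0.0, zero), (0.35, mix(55, 45)), (0.6, mix(60, 40)), (1.0, zero)],
            shin: [(0.0, zero), (0.3, flex(110)), (0.5, flex(20)), (0.7, flex(110)), (1.0, zero)],
        }
        duration = 2.8
    elif kind == "yoko":  # side kick: dominant abduction, late extension
        kfs = {
            thigh: [(0.0, zero), (0.45, mix(15, 80)), (0.6, mix(10, 80)), (1.0, zero)],
            shin: [(0.0, zero), (0.35, flex(95)), (0.55, flex(10)), (0.75, flex(95)), (1.0, zero)],
        }
        duration = 2.6
    else:
        raise ValueError(f"unknown kick kind {kind!r}")
    kfs.update(common)
    return ActionSpec(label=f"{kind}_{side}", keyframes=kfs, duration=duration)


def builtin_kick_specs() -> list[ActionSpec]:
    """The eight built-in kick-like classes (4 kinds x left/right)."""
    return [_kick_spec(side, kind) for kind in ("mawashi", "mae", "hiza", "yoko") for side in ("left", "right")]


# ---------------------------------------------------------------------------
# instance generation
# ---------------------------------------------------------------------------


def _random_time_warp(n: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Monotone warp of [0, 1]: normalized cumulative sum of positive speeds.

    The speed profile is ``1 + strength * smooth``, with ``smooth`` a
    low-frequency random signal in [-1, 1]; monotonicity holds by
    construction and the warp derivative (relative to uniform speed) stays
    within ``[(1-s)/(1+s), (1+s)/(1-s)]``.
    """
    if strength == 0.0 or n < 3:
        return np.linspace(0.0, 1.0, n)
    t = np.linspace(0.0, 2.0 * np.pi, n)
    n_harm = 3
    smooth = np.zeros(n)
    for h in range(1, n_harm + 1):
        smooth += rng.uniform(-1, 1) * np.sin(h * t + rng.uniform(0, 2 * np.pi)) / h
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth /= peak
    speed = 1.0 + strength * smooth
    warp = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]))])
    return warp / warp[-1]


def _slerp_trajectory(kfs: list[tuple[float, np.ndarray]], times: np.ndarray) -> np.ndarray:
    """Slerp through axis-angle keyframes; hold the end poses outside range."""
    ts = np.array([t for t, _ in kfs])
    rots = Rotation.from_rotvec(np.array([rv for _, rv in kfs]))
    if len(ts) == 1:
        q = np.roll(rots.as_quat(), 1, axis=-1)
        return np.tile(q[0], (len(times), 1))
    slerp = Slerp(ts, rots)
    clipped = np.clip(times, ts[0], ts[-1])
    q = np.roll(slerp(clipped).as_quat(), 1, axis=-1)
    return canonical_sign(q)


def _noise_quats(n: int, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.uniform(0.0, np.deg2rad(max_deg), size=n)
    half = angles / 2.0
    return np.column_stack([np.cos(half), axes * np.sin(half)[:, None]])


def _flip_segments(sig: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Flip the quaternion sign of random contiguous chunks (~0.2-0.6 s)."""
    out = sig.copy()
    i = 0
    n = len(sig)
    while i < n:
        seg = int(rng.integers(20, 61))
        if rng.uniform() < prob:
            out[i : i + seg] = -out[i : i + seg]
        i += seg
    return out


def make_action_instance(
    spec: ActionSpec,
    pert: PerturbationModel,
    rng: np.random.Generator,
    duration_scale: float = 1.0,
    style: dict[str, np.ndarray] | None = None,
) -> MoCapRecording:
    """Generate one perturbed take of an action.

    Order of effects: slerp through the keyframes at the (monotonically)
    warped times, compose per-sample rotation noise, flip quaternion signs
    on random segments, and pre-rotate the root by a random constant
    heading.  ``style`` optionally pre-composes a fixed per-joint rotation
    offset (a "subject" idiosyncrasy shared across takes).  Deterministic
    given the generator state.
    """
    skeleton = canonical_skeleton()
    n = max(2, int(round(spec.duration * duration_scale * spec.rate)))
    warp = _random_time_warp(n, pert.time_warp_strength, rng)
    heading_lo, heading_hi = pert.heading_range
    yaw = np.deg2rad(rng.uniform(heading_lo, heading_hi)) if heading_hi > heading_lo else np.deg2rad(heading_lo)
    q_heading = np.array([np.cos(yaw / 2.0), 0.0, np.sin(yaw / 2.0), 0.0])
    identity_kfs = [(0.0, np.zeros(3)), (1.0, np.zeros(3))]
    signals: dict[str, np.ndarray] = {}
    for joint in skeleton.joints:
        if not joint.has_rotation:
            continue
        kfs = spec.keyframes.get(joint.name, identity_kfs)
        sig = _slerp_trajectory(kfs, warp)
        if style and joint.name in style:
            sig = quat_mul(style[joint.name], sig)
        if pert.noise_deg > 0:
            sig = quat_mul(_noise_quats(n, pert.noise_deg, rng), sig)
        if joint.name == "Hips":
            sig = quat_mul(q_heading, sig)
        if pert.sign_flip_prob > 0:
            sig = _flip_segments(sig, pert.sign_flip_prob, rng)
        signals[joint.name] = sig
    return MoCapRecording(
        skeleton=skeleton,
        frame_time=1.0 / spec.rate,
        signals=signals,
        root_translation=None,
    )


def subject_style(
    rng: np.random.Generator,
    magnitude_deg: float,
    joints: tuple[str, ...] = ("LeftThigh", "LeftLeg", "RightThigh", "RightLeg"),
) -> dict[str, np.ndarray]:
    """Per-joint constant flexion offsets modeling a subject's style.

    Inter-subject differences in kicks are dominated by sagittal-plane
    amplitude: how high the hip flexes (kick height, flexibility) and how
    deep the knee folds or extends, with the knee-extension depth the
    least constrained (largest-range) component.  Each listed joint
    therefore gets a constant rotation about its flexion axis (local x)
    with a signed magnitude ``magnitude_deg * c_j * u_j``, where ``u_j ~
    U(-1, 1)`` is drawn from ``rng`` and ``c_j`` is 1 for shins and 1/2
    for thighs.  Drawing the ``u_j`` once and scaling by
    ``magnitude_deg`` lets an offset sweep reuse the same style
    directions at growing magnitudes (the degradation is then monotone in
    the magnitude).
    """
    style = {}
    for j in joints:
        scale = 0.5 if j.endswith("Thigh") else 1.0
        half = np.deg2rad(magnitude_deg * scale * rng.uniform(-1.0, 1.0)) / 2.0
        style[j] = np.array([np.cos(half), np.sin(half), 0.0, 0.0])
    return style


def make_dataset(
    specs: list[ActionSpec],
    n_per_class: int,
    pert: PerturbationModel | None = None,
    seed: int = 0,
    duration_jitter: float = 0.1,
    style: dict[str, np.ndarray] | None = None,
) -> dict[str, list[MoCapRecording]]:
    """Generate ``n_per_class`` takes of every action class.

    Take lengths vary through a +-``duration_jitter`` duration scaling
    (clipped to keep every take within 2-4 s at the base rate).  The
    dataset is bit-identical for a fixed seed.
    """
    if pert is None:
        pert = PerturbationModel()
    rng = np.random.default_rng(seed)
    dataset: dict[str, list[MoCapRecording]] = {}
    for spec in specs:
        takes = []
        for _ in range(n_per_class):
            scale = 1.0 + duration_jitter * rng.uniform(-1.0, 1.0)
            scale = float(np.clip(scale, 2.0 / spec.duration, 4.0 / spec.duration))
            takes.append(make_action_instance(spec, pert, rng, duration_scale=scale, style=style))
        dataset[spec.label] = takes
    return dataset


def write_dataset(dataset: dict[str, list[MoCapRecording]], out_dir: str | Path) -> list[Path]:
    """Write a dataset as one directory of BVH files per class."""
    out_dir = Path(out_dir)
    written = []
    for label, takes in dataset.items():
        class_dir = out_dir / label
        class_dir.mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(takes):
            path = class_dir / f"{label}_{i:02d}.bvh"
            write_bvh(rec, path)
            written.append(path)
    return written
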