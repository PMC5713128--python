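"""BVH reading/writing and the hierarchical kinematic model.

The skeleton is a tree of named joints rooted at ``Hips``.  Each joint
holds the *local* rotation of the bone attached to it, relative to its
parent; the root holds the global body rotation.  Positions follow the
usual BVH forward-kinematics rules in a right-handed, y-up world frame.

Euler channels in files are converted to unit quaternions on read (using
the channel order the file declares) and back to Euler angles on write.
Root translation channels are parsed and carried through I/O but ignored
by every analysis stage — the motion model is rotation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .quat_core import euler_array_to_quat, quat_mul, quat_to_euler_array, rotate_vector

__all__ = [
    "BVHParseError",
    "SkeletonMismatchError",
    "Joint",
    "Skeleton",
    "MoCapRecording",
    "read_bvh",
    "write_bvh",
    "forward_kinematics",
    "joint_positions",
]

_ROT_TOKENS = {"Xrotation": "X", "Yrotation": "Y", "Zrotation": "Z"}
_POS_TOKENS = ("Xposition", "Yposition", "Zposition")

#: Joints of the reference 17-sensor body model (root = Hips).
REFERENCE_BODY_JOINTS = (
    "Hips",
    "Chest",
    "LeftThigh",
    "RightThigh",
    "LeftLeg",
    "RightLeg",
    "LeftFoot",
    "RightFoot",
)


class BVHParseError(ValueError):
    """Malformed BVH content; the message names the offending line."""


class SkeletonMismatchError(ValueError):
    """Operation across recordings whose skeletons differ."""


@dataclass
class Joint:
    name: str
    parent: str | None
    offset: np.ndarray  # (3,) in skeleton length units
    channels: tuple[str, ...] = ()
    end_site: np.ndarray | None = None  # retained for rendering, unused by analysis

    @property
    def rotation_order(self) -> str:
        """Intrinsic Euler order implied by the rotation channels, e.g. 'ZXY'."""
        return "".join(_ROT_TOKENS[c] for c in self.channels if c in _ROT_TOKENS)

    @property
    def has_rotation(self) -> bool:
        return any(c in _ROT_TOKENS for c in self.channels)

    @property
    def has_translation(self) -> bool:
        return any(c in _POS_TOKENS for c in self.channels)


@dataclass
class Skeleton:
    """Tree of joints; exactly one root, which must be named ``Hips``."""

    joints: list[Joint]

    def __post_init__(self) -> None:
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise ValueError("joint names must be unique")
        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1:
            raise ValueError("skeleton must have exactly one root")
        if roots[0].name != "Hips":
            raise ValueError("root joint must be named Hips")
        known = set(names)
        for j in self.joints:
            if j.parent is not None and j.parent not in known:
                raise ValueError(f"joint {j.name} has unknown parent {j.parent}")

    def __getitem__(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    @property
    def root(self) -> Joint:
        return next(j for j in self.joints if j.parent is None)

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def children(self, name: str) -> list[Joint]:
        return [j for j in self.joints if j.parent == name]

    def same_structure(self, other: "Skeleton", atol: float = 1e-9) -> bool:
        if self.joint_names != other.joint_names:
            return False
        return all(
            a.parent == b.parent and np.allclose(a.offset, b.offset, atol=atol)
            for a, b in zip(self.joints, other.joints)
        )


@dataclass
class MoCapRecording:
    """Skeleton plus per-joint unit-quaternion rotation signals.

    ``signals`` maps joint name to an ``(n, 4)`` w-first quaternion array;
    the root's signal is the global body rotation, all others are local
    rotations relative to the parent.  All signals share one length and the
    fixed frame time.
    """

    skeleton: Skeleton
    frame_time: float
    signals: dict[str, np.ndarray]
    root_translation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        lengths = {len(s) for s in self.signals.values()}
        if len(lengths) > 1:
            raise ValueError("all joint signals must have equal length")
        if lengths and min(lengths) < 1:
            raise ValueError("signals must have length >= 1")
        for j in self.skeleton.joints:
            if j.has_rotation and j.name not in self.signals:
                raise ValueError(f"missing rotation signal for joint {j.name}")
        if self.root_translation is not None:
            self.root_translation = np.asarray(self.root_translation, dtype=float)
            if len(self.root_translation) != self.n_frames:
                raise ValueError("root_translation length mismatch")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.frame_time


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


class _Tokens:
    """Line-aware token stream so parse errors can name their line."""

    def __init__(self, text: str):
        self.items: list[tuple[str, int]] = []
        for ln, line in enumerate(text.splitlines(), start=1):
            for tok in line.split():
                self.items.append((tok, ln))
        self.pos = 0

    def peek(self) -> str | None:
        return self.items[self.pos][0] if self.pos < len(self.items) else None

    @property
    def line(self) -> int:
        idx = min(self.pos, len(self.items) - 1)
        return self.items[idx][1] if self.items else 0

    def next(self, expect: str | None = None) -> str:
        if self.pos >= len(self.items):
            raise BVHParseError(f"line {self.line}: unexpected end of file")
        tok, ln = self.items[self.pos]
        self.pos += 1
        if expect is not None and tok != expect:
            raise BVHParseError(f"line {ln}: expected {expect!r}, got {tok!r}")
        return tok

    def next_float(self) -> float:
        tok = self.next()
        try:
            return float(tok)
        except ValueError as exc:
            raise BVHParseError(f"line {self.line}: expected a number, got {tok!r}") from exc

    def next_int(self) -> int:
        tok = self.next()
        try:
            return int(tok)
        except ValueError as exc:
            raise BVHParseError(f"line {self.line}: expected an integer, got {tok!r}") from exc


def _parse_joint(tokens: _Tokens, name: str, parent: str | None, joints: list[Joint]) -> None:
    tokens.next("{")
    tokens.next("OFFSET")
    offset = np.array([tokens.next_float() for _ in range(3)])
    channels: tuple[str, ...] = ()
    if tokens.peek() == "CHANNELS":
        tokens.next("CHANNELS")
        n = tokens.next_int()
        chans = []
        for _ in range(n):
            tok = tokens.next()
            if tok not in _ROT_TOKENS and tok not in _POS_TOKENS:
                raise BVHParseError(f"line {tokens.line}: unknown channel token {tok!r}")
            chans.append(tok)
        channels = tuple(chans)
    joint = Joint(name=name, parent=parent, offset=offset, channels=channels)
    joints.append(joint)
    while True:
        tok = tokens.next()
        if tok == "}":
            return
        if tok == "JOINT":
            child = tokens.next()
            _parse_joint(tokens, child, name, joints)
        elif tok == "End":
            tokens.next("Site")
            tokens.next("{")
            tokens.next("OFFSET")
            joint.end_site = np.array([tokens.next_float() for _ in range(3)])
            tokens.next("}")
        else:
            raise BVHParseError(f"line {tokens.line}: unexpected token {tok!r} in joint body")


def read_bvh(path: str | Path, aliases: dict[str, str] | None = None) -> MoCapRecording:
    """Parse a BVH file into a :class:`MoCapRecording`.

    Euler channels are converted to quaternions per frame using the channel
    order the file declares.  ``aliases`` optionally maps vendor joint names
    onto the canonical model names (e.g. ``{"LeftUpLeg": "LeftThigh"}``).
    """
    text = Path(path).read_text()
    tokens = _Tokens(text)
    tokens.next("HIERARCHY")
    tokens.next("ROOT")
    root_name = tokens.next()
    joints: list[Joint] = []
    _parse_joint(tokens, root_name, None, joints)
    if aliases:
        table = dict(aliases)
        for j in joints:
            j.name = table.get(j.name, j.name)
            if j.parent is not None:
                j.parent = table.get(j.parent, j.parent)
    tokens.next("MOTION")
    tokens.next("Frames:")
    n_frames = tokens.next_int()
    if n_frames < 1:
        raise BVHParseError(f"line {tokens.line}: frame count must be >= 1")
    tokens.next("Frame")
    tokens.next("Time:")
    frame_time = tokens.next_float()
    n_channels = sum(len(j.channels) for j in joints)
    data = np.empty((n_frames, n_channels))
    for f in range(n_frames):
        for c in range(n_channels):
            if tokens.peek() is None:
                raise BVHParseError(
                    f"line {tokens.line}: motion data ended early "
                    f"(expected {n_frames} frames of {n_channels} channels)"
                )
            data[f, c] = tokens.next_float()
    if tokens.peek() is not None:
        raise BVHParseError(f"line {tokens.line}: trailing data after declared frame count")

    skeleton = Skeleton(joints=joints)
    signals: dict[str, np.ndarray] = {}
    root_translation = None
    col = 0
    for j in joints:
        rot_cols, rot_axes, pos_cols = [], [], []
        for ch in j.channels:
            if ch in _ROT_TOKENS:
                rot_cols.append(col)
                rot_axes.append(_ROT_TOKENS[ch])
            else:
                pos_cols.append(col)
            col += 1
        if pos_cols and j.parent is None:
            # BVH order of position channels may be arbitrary; map onto xyz
            axes = [ch[0] for ch in j.channels if ch in _POS_TOKENS]
            trans = np.zeros((n_frames, 3))
            for a, c in zip(axes, pos_cols):
                trans[:, "XYZ".index(a)] = data[:, c]
            root_translation = trans
        if rot_cols:
            order = "".join(rot_axes)
            signals[j.name] = euler_array_to_quat(data[:, rot_cols], order)
    return MoCapRecording(
        skeleton=skeleton,
        frame_time=frame_time,
        signals=signals,
        root_translation=root_translation,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _write_joint(lines: list[str], skeleton: Skeleton, joint: Joint, depth: int) -> None:
    pad = "  " * depth
    kw = "ROOT" if joint.parent is None else "JOINT"
    lines.append(f"{pad}{kw} {joint.name}")
    lines.append(f"{pad}{{")
    ox, oy, oz = joint.offset
    lines.append(f"{pad}  OFFSET {ox:.6f} {oy:.6f} {oz:.6f}")
    if joint.channels:
        lines.append(f"{pad}  CHANNELS {len(joint.channels)} " + " ".join(joint.channels))
    children = skeleton.children(joint.name)
    for child in children:
        _write_joint(lines, skeleton, child, depth + 1)
    if not children:
        end = joint.end_site if joint.end_site is not None else np.zeros(3)
        lines.append(f"{pad}  End Site")
        lines.append(f"{pad}  {{")
        lines.append(f"{pad}    OFFSET {end[0]:.6f} {end[1]:.6f} {end[2]:.6f}")
        lines.append(f"{pad}  }}")
    lines.append(f"{pad}}}")


def write_bvh(rec: MoCapRecording, path: str | Path) -> None:
    """Write a recording as BVH, emitting rotations as Euler angles in each
    joint's declared channel order.  A missing root translation is written
    as zeros."""
    if not rec.signals:
        raise ValueError("recording has no signals to write")
    lines = ["HIERARCHY"]
    _write_joint(lines, rec.skeleton, rec.skeleton.root, 0)
    n = rec.n_frames
    lines.append("MOTION")
    lines.append(f"Frames: {n}")
    lines.append(f"Frame Time: {rec.frame_time:.7f}")

    columns: list[np.ndarray] = []
    for j in rec.skeleton.joints:
        rot_axes = [a for a in (_ROT_TOKENS.get(c) for c in j.channels) if a]
        euler = None
        if rot_axes:
            euler = quat_to_euler_array(rec.signals[j.name], "".join(rot_axes))
            euler = np.atleast_2d(euler)
        ri = 0
        for ch in j.channels:
            if ch in _ROT_TOKENS:
                columns.append(euler[:, ri])
                ri += 1
            else:
                if j.parent is None and rec.root_translation is not None:
                    columns.append(rec.root_translation[:, "XYZ".index(ch[0])])
                else:
                    columns.append(np.zeros(n))
    frame_data = np.column_stack(columns) if columns else np.zeros((n, 0))
    for f in range(n):
        lines.append(" ".join(f"{v:.6f}" for v in frame_data[f]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def joint_positions(rec: MoCapRecording) -> dict[str, np.ndarray]:
    """Global 3-D positions of every joint at every frame.

    Returns a map joint name -> ``(n_frames, 3)``.  The root sits at its
    translation (or the origin); every child is its parent's position plus
    the parent's global rotation applied to the child's offset.  Rotations
    are isometries, so bone lengths are preserved at every frame.
    """
    n = rec.n_frames
    identity = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    glob_rot: dict[str, np.ndarray] = {}
    pos: dict[str, np.ndarray] = {}
    for j in rec.skeleton.joints:
        local = rec.signals.get(j.name, identity)
        if j.parent is None:
            glob_rot[j.name] = local
            pos[j.name] = (
                rec.root_translation.copy()
                if rec.root_translation is not None
                else np.zeros((n, 3))
            )
        else:
            parent_rot = glob_rot[j.parent]
            pos[j.name] = pos[j.parent] + rotate_vector(parent_rot, np.tile(j.offset, (n, 1)))
            glob_rot[j.name] = quat_mul(parent_rot, local)
    return pos


def forward_kinematics(rec: MoCapRecording, frame: int) -> dict[str, np.ndarray]:
    """Global joint positions at one frame (y-up, right-handed)."""
    if not 0 <= frame < rec.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {rec.n_frames})")
    all_pos = joint_positions(rec)
    return {name: p[frame] for name, p in all_pos.items()}
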