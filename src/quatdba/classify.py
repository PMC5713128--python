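"""Angle-based kick features and the DTW nearest-template classifier.

A per-frame body coordinate frame is spanned from joint positions
(recovered by forward kinematics from the hierarchical model):

    X = LeftThigh - RightThigh,  Y = Chest - Hips,  Z = X x Y

Four limb vectors describe the thighs and shins:

    V1 = LeftLeg - LeftThigh,   V2 = LeftLeg - LeftFoot,
    V3 = RightLeg - RightThigh, V4 = RightLeg - RightFoot

The feature vector F1..F12 collects the angles (degrees, in [0, 180],
via arccos of the normalized dot product) between each frame axis and
each limb vector, ordered (X,V1),(Y,V1),(Z,V1),(X,V2),... .  Being
angles between position differences, the features are invariant to
global translation, global rotation and uniform skeleton scaling.

Classification DTW-aligns a recording's feature sequence against each
class template's feature sequence with Euclidean per-frame cost; the
class with the smallest normalized distance wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtw_engine import dtw_multichannel, dtw_quat
from .mocap_io import MoCapRecording, joint_positions
from .template_gen import TemplateParams, build_template

__all__ = [
    "DegenerateFrameError",
    "FeatureSequence",
    "TemplateLibrary",
    "body_frame",
    "limb_vectors",
    "angle_features",
    "classify",
    "leave_one_out",
    "cross_subject",
]

_FRAME_AXES = ("X", "Y", "Z")
_LIMBS = ("V1", "V2", "V3", "V4")
_EPS = 1e-9


class DegenerateFrameError(ValueError):
    """A frame/limb vector had (near-)zero length; the message names it."""


@dataclass
class FeatureSequence:
    """Per-frame 12-vector of angle features (degrees in [0, 180])."""

    values: np.ndarray  # (n, 12)
    frame_time: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 12:
            raise ValueError("feature values must be (n, 12)")


@dataclass
class TemplateLibrary:
    """Per-class template feature sequences (plus optional template recordings
    for the experimental per-joint quaternion mode)."""

    features: dict[str, FeatureSequence]
    recordings: dict[str, MoCapRecording] | None = None

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise ValueError("template library is empty")

    @classmethod
    def from_recordings(cls, templates: dict[str, MoCapRecording]) -> "TemplateLibrary":
        return cls(
            features={label: angle_features(rec) for label, rec in templates.items()},
            recordings=dict(templates),
        )


def body_frame(positions: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unnormalized body-frame axes from one frame's joint positions."""
    x = np.asarray(positions["LeftThigh"], float) - np.asarray(positions["RightThigh"], float)
    y = np.asarray(positions["Chest"], float) - np.asarray(positions["Hips"], float)
    z = np.cross(x, y)
    for name, v in (("X", x), ("Y", y), ("Z", z)):
        if np.linalg.norm(v) < _EPS:
            raise DegenerateFrameError(f"body-frame vector {name} is degenerate (zero length)")
    return x, y, z


def limb_vectors(positions: dict[str, np.ndarray]) -> tuple[np.ndarray, ...]:
    """Thigh and shin vectors V1..V4 from one frame's joint positions."""
    p = {k: np.asarray(v, float) for k, v in positions.items()}
    vs = (
        p["LeftLeg"] - p["LeftThigh"],
        p["LeftLeg"] - p["LeftFoot"],
        p["RightLeg"] - p["RightThigh"],
        p["RightLeg"] - p["RightFoot"],
    )
    for name, v in zip(_LIMBS, vs):
        if np.linalg.norm(v) < _EPS:
            raise DegenerateFrameError(f"limb vector {name} is degenerate (zero length)")
    return vs


def _angles_deg(a: np.ndarray, b: np.ndarray, names: tuple[str, str]) -> np.ndarray:
    """Per-frame angle between two (n, 3) vector signals, degrees in [0, 180]."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    for name, norms in zip(names, (na, nb)):
        bad = np.nonzero(norms < _EPS)[0]
        if len(bad):
            raise DegenerateFrameError(
                f"vector {name} is degenerate (zero length) at frame {int(bad[0])}"
            )
    cos = np.einsum("ij,ij->i", a, b) / (na * nb)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def angle_features(rec: MoCapRecording) -> FeatureSequence:
    """Compute the F1..F12 angle features for every frame of a recording."""
    pos = joint_positions(rec)
    missing = [j for j in ("Hips", "Chest", "LeftThigh", "RightThigh", "LeftLeg", "RightLeg", "LeftFoot", "RightFoot") if j not in pos]
    if missing:
        raise ValueError(f"skeleton lacks joints required by the feature set: {missing}")
    frame = {
        "X": pos["LeftThigh"] - pos["RightThigh"],
        "Y": pos["Chest"] - pos["Hips"],
    }
    frame["Z"] = np.cross(frame["X"], frame["Y"])
    limbs = {
        "V1": pos["LeftLeg"] - pos["LeftThigh"],
        "V2": pos["LeftLeg"] - pos["LeftFoot"],
        "V3": pos["RightLeg"] - pos["RightThigh"],
        "V4": pos["RightLeg"] - pos["RightFoot"],
    }
    cols = []
    for limb in _LIMBS:
        for axis in _FRAME_AXES:
            cols.append(_angles_deg(frame[axis], limbs[limb], (axis, limb)))
    return FeatureSequence(values=np.column_stack(cols), frame_time=rec.frame_time)


def classify(
    rec: MoCapRecording,
    lib: TemplateLibrary,
    mode: str = "features",
) -> tuple[str, dict[str, float]]:
    """Assign a recording to the nearest-template class.

    ``mode="features"`` (the standard path) runs multichannel DTW with
    Euclidean cost on the 12 angle features.  ``mode="quat-joints"`` is an
    experimental alternative summing per-joint quaternion DTWNDs against
    the template recordings.  Ties go to the lexicographically first label
    with a warning.
    """
    if mode == "features":
        feats = angle_features(rec)
        distances = {
            label: dtw_multichannel(feats.values, tpl.values).normalized_distance
            for label, tpl in sorted(lib.features.items())
        }
    elif mode == "quat-joints":
        if lib.recordings is None:
            raise ValueError("quat-joints mode needs template recordings in the library")
        distances = {}
        for label, tpl in sorted(lib.recordings.items()):
            distances[label] = float(
                sum(
                    dtw_quat(tpl.signals[j], rec.signals[j]).normalized_distance
                    for j in tpl.signals
                )
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    best = min(distances.values())
    winners = sorted(label for label, d in distances.items() if d == best)
    if len(winners) > 1:
        warnings.warn(f"classification tie between {winners}; choosing {winners[0]}", RuntimeWarning)
    return winners[0], distances


def _confusion_frame(labels: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((len(labels), len(labels)), dtype=int), index=labels, columns=labels
    )


def leave_one_out(
    recs: dict[str, list[MoCapRecording]],
    params: TemplateParams | None = None,
    mode: str = "features",
) -> pd.DataFrame:
    """Leave-one-out protocol: per class, hold out each take in turn.

    For every held-out recording, its own class's template is rebuilt from
    the remaining takes while the other classes keep templates built from
    all of their takes; the held-out recording is then classified against
    the full library.  Returns the confusion matrix (rows = true class,
    columns = predicted class).
    """
    if params is None:
        params = TemplateParams()
    labels = sorted(recs)
    full_templates = {
        label: build_template(recs[label], params, source_ids=[f"{label}_{i}" for i in range(len(recs[label]))])
        for label in labels
    }
    confusion = _confusion_frame(labels)
    for label in labels:
        takes = recs[label]
        for held in range(len(takes)):
            rest = [r for i, r in enumerate(takes) if i != held]
            templates = dict(full_templates)
            templates[label] = build_template(rest, params)
            lib = TemplateLibrary.from_recordings(templates)
            predicted, _ = classify(takes[held], lib, mode=mode)
            confusion.loc[label, predicted] += 1
    return confusion


def cross_subject(
    recs_a: dict[str, list[MoCapRecording]],
    recs_b: dict[str, list[MoCapRecording]],
    params: TemplateParams | None = None,
    mode: str = "features",
) -> tuple[pd.DataFrame, float]:
    """Cross-subject protocol: A's templates classify B's takes and vice versa.

    Returns the pooled confusion matrix and the overall recognition rate
    (pooled correct / total).
    """
    if params is None:
        params = TemplateParams()
    if sorted(recs_a) != sorted(recs_b):
        raise ValueError("the two populations must share the same class labels")
    labels = sorted(recs_a)
    confusion = _confusion_frame(labels)
    for train, test in ((recs_a, recs_b), (recs_b, recs_a)):
        templates = {label: build_template(train[label], params) for label in labels}
        lib = TemplateLibrary.from_recordings(templates)
        for label in labels:
            for rec in test[label]:
                predicted, _ = classify(rec, lib, mode=mode)
                confusion.loc[label, predicted] += 1
    total = int(confusion.to_numpy().sum())
    correct = int(np.trace(confusion.to_numpy()))
    return confusion, correct / total
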