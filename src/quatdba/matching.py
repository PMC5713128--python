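"""Template-vs-recording comparison matrices and DTW visualization data.

Three complementary views of a DTW alignment between two joint signals:

* the *mapping plot* — both quaternion trajectories drawn as 3-D
  polylines (time plus two projected Euler components) with a red
  correspondence segment per warping-path pair;
* the *distance plot* — signal 1 as a straight line of anchors, signal 2
  offset perpendicular by the DTW cost to its matched anchor;
* the *alignment plot* — the raw warping path (index vs index).

All builders are pure functions of the warping path and the signals, so
the emitted data (JSON/CSV) is bit-reproducible; image rendering is an
optional cosmetic layer on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import numpy as np

from .dtw_engine import WarpingPath, dtw_quat, matching_vectors
from .mocap_io import MoCapRecording, SkeletonMismatchError
from .quat_core import quat_to_euler_array

__all__ = [
    "MappingPlotData",
    "DistancePlotData",
    "joint_distance_matrix",
    "mapping_plot_data",
    "distance_plot_data",
    "extreme_correspondences",
    "render_mapping_plot",
    "render_distance_plot",
    "render_alignment_plot",
]


@dataclass
class MappingPlotData:
    """3-D polylines of both signals plus per-pair correspondence segments.

    ``polyline1``/``polyline2`` have columns (time index, coord A, coord B)
    where the coords are two selected Euler components of the quaternion
    trajectory; ``segments`` is ``(L, 2)`` of (i, j) path pairs and
    ``segment_costs`` the per-pair DTW cost.
    """

    polyline1: np.ndarray
    polyline2: np.ndarray
    segments: np.ndarray
    segment_costs: np.ndarray
    components: tuple[str, str]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "components": list(self.components),
                "polyline1": self.polyline1.tolist(),
                "polyline2": self.polyline2.tolist(),
                "segments": self.segments.tolist(),
                "segment_costs": self.segment_costs.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class DistancePlotData:
    """Signal 1 on a straight line; signal 2 offset by DTW cost.

    ``anchors`` are the n signal-1 points (index, 0); ``points`` the m
    signal-2 points (index, offset) where the offset is the quaternion DTW
    cost between sample j of signal 2 and its matched signal-1 sample;
    ``segments`` connect every warping-path pair.
    """

    anchors: np.ndarray
    points: np.ndarray
    segments: np.ndarray
    segment_costs: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return self.points[:, 1]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "anchors": self.anchors.tolist(),
                "points": self.points.tolist(),
                "segments": self.segments.tolist(),
                "segment_costs": self.segment_costs.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def joint_distance_matrix(template: MoCapRecording, recs: list[MoCapRecording], rec_ids=None) -> pd.DataFrame:
    """DTWND between the template and each recording, per joint.

    Returns a complete DataFrame with one row per recording and one column
    per joint signal; cell (r, j) is the normalized DTW distance between
    the template's and recording r's joint-j quaternion signals under the
    ``1 - |dot|`` cost.
    """
    for r in recs:
        if not template.skeleton.same_structure(r.skeleton):
            raise SkeletonMismatchError("recording skeleton differs from template")
    if rec_ids is None:
        rec_ids = [f"recording_{i}" for i in range(len(recs))]
    joints = list(template.signals)
    values = np.zeros((len(recs), len(joints)))
    for ri, rec in enumerate(recs):
        for ji, joint in enumerate(joints):
            values[ri, ji] = dtw_quat(template.signals[joint], rec.signals[joint]).normalized_distance
    return pd.DataFrame(values, index=rec_ids, columns=joints)


def _project(sig: np.ndarray, components: tuple[str, str], order: str) -> np.ndarray:
    euler = np.atleast_2d(quat_to_euler_array(sig, order))
    axis_cols = {axis: k for k, axis in enumerate(order)}
    cols = [euler[:, axis_cols[c]] for c in components]
    t = np.arange(len(sig), dtype=float)
    return np.column_stack([t, *cols])


def mapping_plot_data(
    sig1: np.ndarray,
    sig2: np.ndarray,
    components: tuple[str, str] = ("X", "Z"),
    order: str = "ZXY",
    path: WarpingPath | None = None,
) -> MappingPlotData:
    """DTW signal mapping: one correspondence segment per path pair.

    The projection coordinates are two Euler components of each trajectory
    (default X and Z rotation); segment costs sum to the DTW total cost.
    """
    if path is None:
        path = dtw_quat(sig1, sig2)
    return MappingPlotData(
        polyline1=_project(sig1, components, order),
        polyline2=_project(sig2, components, order),
        segments=path.pairs.copy(),
        segment_costs=path.costs.copy(),
        components=components,
    )


def distance_plot_data(sig1: np.ndarray, sig2: np.ndarray, path: WarpingPath | None = None) -> DistancePlotData:
    """Distance plot: signal-2 points offset by cost to their matched anchor."""
    if path is None:
        path = dtw_quat(sig1, sig2)
    mv = matching_vectors(path)
    sig1 = np.asarray(sig1, dtype=float)
    sig2 = np.asarray(sig2, dtype=float)
    offsets = 1.0 - np.abs(np.einsum("ij,ij->i", sig2, sig1[mv.map2to1]))
    offsets = np.clip(offsets, 0.0, None)
    offsets[offsets < 1e-12] = 0.0  # snap dot-product round-off so identical samples sit at 0
    anchors = np.column_stack([np.arange(path.n, dtype=float), np.zeros(path.n)])
    points = np.column_stack([np.arange(path.m, dtype=float), offsets])
    return DistancePlotData(
        anchors=anchors,
        points=points,
        segments=path.pairs.copy(),
        segment_costs=path.costs.copy(),
    )


def extreme_correspondences(dpd: DistancePlotData, k: int = 3) -> list[tuple[int, int, float, str]]:
    """Most and least distant corresponding points of a distance plot.

    Finds strict local maxima and minima of the offset sequence (plateaus
    count once, at their first index; endpoints are compared one-sided),
    keeps the top ``k`` of each kind, and reports
    ``(frame1, frame2, cost, kind)`` with ``kind`` in {"max", "min"} so the
    matched frames can be rendered side by side.
    """
    off = dpd.offsets
    # compress equal runs; an all-equal sequence has no strict extrema
    starts = [0]
    for i in range(1, len(off)):
        if off[i] != off[starts[-1]]:
            starts.append(i)
    comp = off[starts]
    if len(comp) < 2:
        return []
    maxima: list[int] = []
    minima: list[int] = []
    for ci in range(len(comp)):
        left = comp[ci - 1] if ci > 0 else None
        right = comp[ci + 1] if ci < len(comp) - 1 else None
        is_max = (left is None or comp[ci] > left) and (right is None or comp[ci] > right)
        is_min = (left is None or comp[ci] < left) and (right is None or comp[ci] < right)
        if is_max:
            maxima.append(starts[ci])
        elif is_min:
            minima.append(starts[ci])
    map2to1 = np.zeros(len(dpd.points), dtype=np.int64)
    for i, j in dpd.segments:
        map2to1[j] = i
    out: list[tuple[int, int, float, str]] = []
    maxima.sort(key=lambda j: -off[j])
    minima.sort(key=lambda j: off[j])
    for j in maxima[:k]:
        out.append((int(map2to1[j]), int(j), float(off[j]), "max"))
    for j in minima[:k]:
        out.append((int(map2to1[j]), int(j), float(off[j]), "min"))
    return out


# ---------------------------------------------------------------------------
# optional rendering (cosmetic; the reproducible surface is the data)
# ---------------------------------------------------------------------------


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def render_mapping_plot(mpd: MappingPlotData, path: str | Path) -> None:
    plt = _pyplot()
    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot(*mpd.polyline1.T, color="green", label="signal 1")
    ax.plot(*mpd.polyline2.T, color="blue", label="signal 2")
    for (i, j) in mpd.segments:
        p1, p2 = mpd.polyline1[i], mpd.polyline2[j]
        ax.plot([p1[0], p2[0]], [p1[1], p2[1]], [p1[2], p2[2]], color="red", linewidth=0.4)
    ax.set_xlabel("frame")
    ax.set_ylabel(f"{mpd.components[0]} rotation [deg]")
    ax.set_zlabel(f"{mpd.components[1]} rotation [deg]")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_distance_plot(dpd: DistancePlotData, path: str | Path) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    for (i, j) in dpd.segments:
        ax.plot(
            [dpd.anchors[i, 0], dpd.points[j, 0]],
            [dpd.anchors[i, 1], dpd.points[j, 1]],
            color="red",
            linewidth=0.4,
        )
    ax.plot(dpd.anchors[:, 0], dpd.anchors[:, 1], color="green", label="signal 1")
    ax.plot(dpd.points[:, 0], dpd.points[:, 1], color="blue", label="signal 2")
    ax.set_xlabel("frame")
    ax.set_ylabel("DTW cost to matched point")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_alignment_plot(path_obj: WarpingPath, path: str | Path) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(path_obj.pairs[:, 0], path_obj.pairs[:, 1], color="black")
    ax.set_xlabel("signal 1 index")
    ax.set_ylabel("signal 2 index")
    fig.savefig(path, dpi=120)
    plt.close(fig)
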