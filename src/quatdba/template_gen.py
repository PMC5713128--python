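"""Template generation: heading correction, quaternion DBA, manifold smoothing.

The full-body template of an action is built per joint: every source
recording is first heading-corrected (a yaw-only rotation of the root
signal so all takes face the same direction), each joint's quaternion
signal is averaged with DTW barycenter averaging where the per-slot
barycenter is Markley's eigenvector mean, and the averaged signal is
smoothed with a Gaussian-weighted Markley mean over a sliding window.
The result is a normal recording (writable as BVH) tagged with
provenance: source ids, parameters, and per-joint convergence traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dtw_engine import dtw_from_cost_matrix, quat_cost_matrix
from .mocap_io import MoCapRecording, SkeletonMismatchError, write_bvh
from .quat_core import markley_average_stack, quat_mul

__all__ = [
    "SmoothingKernel",
    "Template",
    "TemplateParams",
    "heading_quaternion",
    "heading_correction",
    "dba_average",
    "markley_smooth",
    "build_template",
    "save_template",
]


@dataclass(frozen=True)
class SmoothingKernel:
    """Symmetric Gaussian window for manifold smoothing.

    ``ws`` is the half-width in samples (the window covers ``j-ws .. j+ws``,
    i.e. ``2*ws + 1`` samples); ``sigma`` defaults to ``ws / 3`` so the
    window edge sits at three standard deviations.
    """

    ws: int = 10
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.ws < 0:
            raise ValueError("kernel half-width ws must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def weights(self) -> np.ndarray:
        """Gaussian weights over offsets ``-ws .. ws`` (peak at center)."""
        if self.ws == 0:
            return np.ones(1)
        sigma = self.sigma if self.sigma is not None else self.ws / 3.0
        k = np.arange(-self.ws, self.ws + 1, dtype=float)
        return np.exp(-0.5 * (k / sigma) ** 2)


@dataclass
class TemplateParams:
    """Tunables of the template pipeline (all exposed through the CLI/YAML)."""

    iterations: int = 10
    tolerance: float = 1e-10
    ws: int = 10
    sigma: float | None = None
    heading_step_deg: float = 0.05
    band: int | None = None  # optional Sakoe-Chiba constraint for the DBA DTWs

    def kernel(self) -> SmoothingKernel:
        return SmoothingKernel(ws=self.ws, sigma=self.sigma)


@dataclass
class Template(MoCapRecording):
    """An averaged, smoothed recording plus provenance of how it was built."""

    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# heading correction
# ---------------------------------------------------------------------------

_FORWARD = np.array([1.0, 0.0, 0.0])


def heading_quaternion(rec: MoCapRecording, step_deg: float = 0.05) -> tuple[np.ndarray, float]:
    """Yaw-only quaternion that best realigns the body's forward direction.

    The forward direction is the first-frame root rotation applied to
    ``[1, 0, 0]``; candidate yaws on a ``step_deg`` grid over [0, 360)
    are scored by the angle between the re-rotated forward vector and
    ``[1, 0, 0]``, and the minimizer (first on ties) wins.  Returns the
    w-first quaternion and the yaw in degrees.
    """
    root = rec.signals[rec.skeleton.root.name]
    if len(root) == 0:
        raise ValueError("root signal is empty")
    w, x, y, z = root[0]
    # rotate [1,0,0] by the first root sample (expanded Hamilton sandwich)
    fx = 1.0 - 2.0 * (y * y + z * z)
    fy = 2.0 * (x * y + w * z)
    fz = 2.0 * (x * z - w * y)
    yaws = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    # rotation about +y: x' = cos*fx + sin*fz  (score = angle to [1,0,0], so
    # maximizing x' minimizes the angle)
    fx_rot = np.cos(yaws) * fx + np.sin(yaws) * fz
    best = int(np.argmax(fx_rot))
    yaw = yaws[best]
    phi = np.array([np.cos(yaw / 2.0), 0.0, np.sin(yaw / 2.0), 0.0])
    return phi, float(np.rad2deg(yaw))


def heading_correction(rec: MoCapRecording, step_deg: float = 0.05) -> MoCapRecording:
    """Apply the optimal yaw to every root sample; other joints untouched."""
    phi, _ = heading_quaternion(rec, step_deg)
    root_name = rec.skeleton.root.name
    signals = {name: sig for name, sig in rec.signals.items()}
    signals[root_name] = quat_mul(phi, rec.signals[root_name])
    return MoCapRecording(
        skeleton=rec.skeleton,
        frame_time=rec.frame_time,
        signals=signals,
        root_translation=None if rec.root_translation is None else rec.root_translation.copy(),
    )


# ---------------------------------------------------------------------------
# DBA averaging
# ---------------------------------------------------------------------------


def _align_all(template: np.ndarray, signals: list[np.ndarray], band: int | None):
    paths = [dtw_from_cost_matrix(quat_cost_matrix(template, s), band) for s in signals]
    objective = float(sum(p.normalized_distance**2 for p in paths))
    return paths, objective


def dba_average(
    signals: list[np.ndarray],
    iterations: int = 10,
    tolerance: float = 1e-10,
    band: int | None = None,
    return_trace: bool = False,
    init: np.ndarray | None = None,
):
    """DTW barycenter averaging of quaternion signals with Markley means.

    The template is initialized as the medoid (the input minimizing the
    summed DTWND to all others; ties go to the lowest index).  Each
    iteration DTW-aligns every input to the current template, pools for
    each template index all input samples the warping paths match to it,
    and replaces that sample with their uniform-weight Markley average.
    Iteration stops after ``iterations`` rounds, when the objective
    ``sum_i DTWND(template, sig_i)^2`` improves by less than ``tolerance``,
    or — since the Markley mean is not the exact Fréchet mean of the DTW
    cost — when an update would increase the objective, in which case the
    update is rolled back.  The recorded objective trace is therefore
    non-increasing by construction.

    ``init`` overrides the medoid initialization with an explicit starting
    signal (used by :func:`build_template`, which needs one body-level
    medoid so that every joint's template has the same length).
    """
    if len(signals) == 0:
        raise ValueError("need at least one signal")
    signals = [np.asarray(s, dtype=float) for s in signals]
    for s in signals:
        if len(s) == 0:
            raise ValueError("signals must be non-empty")
    if len(signals) == 1 and init is None:
        out = signals[0].copy()
        return (out, [0.0]) if return_trace else out

    if init is not None:
        template = np.asarray(init, dtype=float).copy()
    else:
        # medoid initialization: input-order-invariant up to the lowest-index tie
        k = len(signals)
        nd = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                d = dtw_from_cost_matrix(quat_cost_matrix(signals[a], signals[b]), band).normalized_distance
                nd[a, b] = nd[b, a] = d
        medoid = int(np.argmin(nd.sum(axis=1)))
        template = signals[medoid].copy()

    paths, objective = _align_all(template, signals, band)
    trace = [objective]
    for _ in range(iterations):
        length = len(template)
        m = np.zeros((length, 4, 4))
        counts = np.zeros(length, dtype=np.int64)
        for path, sig in zip(paths, signals):
            qs = sig[path.pairs[:, 1]]
            np.add.at(m, path.pairs[:, 0], qs[:, :, None] * qs[:, None, :])
            np.add.at(counts, path.pairs[:, 0], 1)
        # DTW boundary conditions guarantee every template index is matched
        assert np.all(counts > 0)
        candidate = markley_average_stack(m)
        new_paths, new_objective = _align_all(candidate, signals, band)
        if new_objective > objective:
            break  # roll back: keep the current template
        template, paths = candidate, new_paths
        improvement = objective - new_objective
        objective = new_objective
        trace.append(objective)
        if improvement < tolerance:
            break
    return (template, trace) if return_trace else template


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def markley_smooth(sig: np.ndarray, kernel: SmoothingKernel | None = None) -> np.ndarray:
    """Gaussian-weighted Markley smoothing of a quaternion signal.

    Output sample ``j`` is the Markley average of input samples in the
    window ``[j-ws, j+ws]`` weighted by the Gaussian kernel; at the
    boundaries the window is truncated (a kernel rescaling would not change
    the dominant eigenvector).  Output signs are chained for continuity:
    the first sample is aligned with the first input sample, each later
    sample with its predecessor.
    """
    if kernel is None:
        kernel = SmoothingKernel()
    sig = np.asarray(sig, dtype=float)
    n = len(sig)
    ws = kernel.ws
    weights = kernel.weights
    outer = sig[:, :, None] * sig[:, None, :]
    m = np.zeros((n, 4, 4))
    for k in range(-ws, ws + 1):
        g = weights[k + ws]
        if k < 0:
            m[-k:] += g * outer[:k]
        elif k > 0:
            m[:-k] += g * outer[k:]
        else:
            m += g * outer
    out = markley_average_stack(m)
    # sign continuity chain
    if float(np.dot(out[0], sig[0])) < 0:
        out[0] = -out[0]
    for j in range(1, n):
        if float(np.dot(out[j], out[j - 1])) < 0:
            out[j] = -out[j]
    return out


# ---------------------------------------------------------------------------
# full-body template
# ---------------------------------------------------------------------------


def build_template(
    recs: list[MoCapRecording],
    params: TemplateParams | None = None,
    source_ids: list[str] | None = None,
) -> Template:
    """Average a set of same-action recordings into a full-body template.

    Pipeline: heading-correct each recording, DBA-average every joint
    signal independently (the root's global rotation included), smooth each
    averaged signal with the Gaussian Markley kernel, and assemble the
    result on the shared skeleton.  Deterministic given inputs and params.
    """
    if params is None:
        params = TemplateParams()
    if len(recs) < 2:
        raise ValueError("need at least two recordings to build a template")
    skeleton = recs[0].skeleton
    for r in recs[1:]:
        if not skeleton.same_structure(r.skeleton):
            raise SkeletonMismatchError("recordings do not share a skeleton")
        if not np.isclose(r.frame_time, recs[0].frame_time):
            raise ValueError("recordings have unequal frame rates")
    if source_ids is None:
        source_ids = [f"recording_{i}" for i in range(len(recs))]

    corrected = [heading_correction(r, params.heading_step_deg) for r in recs]
    kernel = params.kernel()

    # one body-level medoid (lowest summed per-joint DTWND to the other
    # takes) so every joint's averaged signal has the same length
    k = len(corrected)
    joint_names = list(corrected[0].signals)
    nd = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = sum(
                dtw_from_cost_matrix(
                    quat_cost_matrix(corrected[a].signals[name], corrected[b].signals[name]),
                    params.band,
                ).normalized_distance
                for name in joint_names
            )
            nd[a, b] = nd[b, a] = d
    medoid = int(np.argmin(nd.sum(axis=1)))

    signals: dict[str, np.ndarray] = {}
    traces: dict[str, list[float]] = {}
    for name in joint_names:
        avg, trace = dba_average(
            [r.signals[name] for r in corrected],
            iterations=params.iterations,
            tolerance=params.tolerance,
            band=params.band,
            return_trace=True,
            init=corrected[medoid].signals[name],
        )
        signals[name] = markley_smooth(avg, kernel)
        traces[name] = trace
    provenance = {
        "source_ids": list(source_ids),
        "iterations": params.iterations,
        "tolerance": params.tolerance,
        "smoothing_ws": params.ws,
        "smoothing_sigma": params.sigma if params.sigma is not None else params.ws / 3.0,
        "convergence_traces": traces,
    }
    return Template(
        skeleton=skeleton,
        frame_time=recs[0].frame_time,
        signals=signals,
        root_translation=None,
        provenance=provenance,
    )


def save_template(template: Template, bvh_path: str | Path) -> Path:
    """Write a template as BVH plus a JSON provenance sidecar."""
    bvh_path = Path(bvh_path)
    write_bvh(template, bvh_path)
    sidecar = bvh_path.with_suffix(".json")
    sidecar.write_text(json.dumps(template.provenance, indent=2))
    return sidecar
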