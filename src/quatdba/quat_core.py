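"""Quaternion algebra, Euler conversions, rotation distances and Markley averaging.

Conventions
-----------
* Quaternions are plain :class:`numpy.ndarray` objects in **scalar-first**
  order ``[w, x, y, z]`` (``w`` is the real part).  Everything in this
  package uses this layout; conversion to SciPy's scalar-last layout happens
  only inside this module.
* A quaternion and its negation encode the same 3-D rotation (the double
  cover of SO(3)).  Every distance function here returns 0 for the pair
  ``(q, -q)``.
* Angles exchanged with files and users are degrees; internal math is
  radians.

The Markley average of a weighted quaternion set is the dominant
eigenvector of ``M = sum_i w_i q_i q_i^T``: it is norm-preserving and
invariant to the sign of every input, which makes it the right mean for
orientation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerAngles",
    "EULER_ORDERS",
    "normalize",
    "quat_mul",
    "conjugate",
    "quat_log",
    "rotate_vector",
    "canonical_sign",
    "cost_dot",
    "dist_geodesic",
    "dist_tangent",
    "dist_rotangle",
    "markley_average",
    "euler_to_quat",
    "quat_to_euler",
    "euler_array_to_quat",
    "quat_to_euler_array",
]

#: The six intrinsic Tait-Bryan axis orders accepted for Euler conversions.
EULER_ORDERS = ("XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX")

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class EulerAngles:
    """Euler rotation in degrees with an intrinsic axis order.

    ``rx``/``ry``/``rz`` are the rotations about the X/Y/Z axes; ``order``
    states the (intrinsic) order in which they are applied, e.g. ``"ZXY"``
    means first Z, then X, then Y — the common BVH channel convention.
    """

    rx: float
    ry: float
    rz: float
    order: str = "ZXY"

    def __post_init__(self) -> None:
        if self.order not in EULER_ORDERS:
            raise ValueError(f"unknown Euler order {self.order!r}")

    def as_ordered(self) -> np.ndarray:
        """Angles as a length-3 array following ``order``."""
        by_axis = {"X": self.rx, "Y": self.ry, "Z": self.rz}
        return np.array([by_axis[a] for a in self.order], dtype=float)


def _require_finite(*qs: np.ndarray) -> None:
    for q in qs:
        if not np.all(np.isfinite(q)):
            raise ValueError("quaternion has non-finite components")


def normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q`` scaled to unit norm (works on ``(..., 4)`` stacks)."""
    q = np.asarray(q, dtype=float)
    _require_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a * b`` for ``(..., 4)`` stacks, w-first."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_log(q: np.ndarray) -> np.ndarray:
    """Log map of a unit quaternion to its axis times half-angle 3-vector.

    The input is first canonicalized to the ``w >= 0`` hemisphere so that
    ``q`` and ``-q`` map to the same tangent vector.
    """
    q = np.asarray(q, dtype=float)
    _require_finite(q)
    q = np.where(q[..., :1] < 0, -q, q)
    w = np.clip(q[..., 0], -1.0, 1.0)
    v = q[..., 1:]
    vn = np.linalg.norm(v, axis=-1, keepdims=True)
    half = np.arccos(w)[..., None]
    scale = np.where(vn > 1e-12, half / np.maximum(vn, 1e-300), 1.0)
    return v * scale


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply the rotation(s) ``q`` (w-first, ``(..., 4)``) to 3-vector(s) ``v``."""
    q = np.asarray(q, dtype=float)
    rot = Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1))
    out = rot.apply(np.asarray(v, dtype=float))
    return out[0] if q.ndim == 1 and np.asarray(v).ndim == 1 else out


def canonical_sign(q: np.ndarray) -> np.ndarray:
    """Flip sign so w >= 0; on w == 0 fall back to x >= 0, then y, then z."""
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q).copy()
    sign = np.zeros(q2.shape[0])
    for k in range(4):
        comp = q2[:, k]
        sign = np.where(sign == 0, np.sign(comp), sign)
    sign = np.where(sign == 0, 1.0, sign)
    q2 *= sign[:, None]
    return q2[0] if single else q2


# ---------------------------------------------------------------------------
# distance functions
# ---------------------------------------------------------------------------


def cost_dot(x: np.ndarray, y: np.ndarray) -> float:
    """DTW cost ``1 - |x . y|`` (4-D dot product).

    In [0, 1]; zero iff x and y are the same rotation (the absolute value
    collapses the double cover); 1 iff the 4-vectors are orthogonal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _require_finite(x, y)
    return max(0.0, float(1.0 - abs(float(np.dot(x, y)))))


def dist_geodesic(x: np.ndarray, y: np.ndarray) -> float:
    """Length of the shorter geodesic between the two rotations.

    Equals the rotation angle taking x to y (in [0, pi]); computed as
    ``2 * arccos(|x . y|)``, i.e. twice the smaller of the two log norms of
    the sign representatives of ``x^-1 y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _require_finite(x, y)
    return float(2.0 * np.arccos(np.clip(abs(float(np.dot(x, y))), 0.0, 1.0)))


def dist_tangent(x: np.ndarray, y: np.ndarray) -> float:
    """Distance ``||log(x) - log(y)||`` in the tangent space at identity.

    Both arguments are canonicalized to the w >= 0 hemisphere first so the
    distance is sign-invariant.
    """
    return float(np.linalg.norm(quat_log(x) - quat_log(y)))


def dist_rotangle(x: np.ndarray, y: np.ndarray, mode: str = "angle") -> float:
    """Distance built from the real part of the concatenation ``x * conj(y)``.

    ``mode="angle"`` (default) returns ``2*arccos(clip(|re(x * conj(y))|))``,
    the angle of the relative rotation.  ``mode="as-printed"`` returns
    ``|re(x * conj(y))|`` itself, which is 1 (not 0) for identical rotations;
    it is kept for completeness but is not a metric.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _require_finite(x, y)
    re = abs(float(quat_mul(x, conjugate(y))[0]))
    if mode == "as-printed":
        return re
    if mode == "angle":
        return float(2.0 * np.arccos(np.clip(re, 0.0, 1.0)))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Markley averaging
# ---------------------------------------------------------------------------

_EIG_TIE_TOL = 1e-12


def markley_average(qs: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted quaternion mean as the dominant eigenvector of sum w_i q_i q_i^T.

    Parameters
    ----------
    qs : (n, 4) array of unit quaternions (w-first).
    weights : (n,) non-negative array; ``None`` means uniform.  At least one
        weight must be strictly positive.

    Returns
    -------
    (4,) unit quaternion with canonical sign (w >= 0; ties resolved on
    x, then y, then z).

    Notes
    -----
    Because ``q q^T == (-q)(-q)^T`` the result is invariant to the sign of
    every input.  A (near-)degenerate top eigenvalue means the maximizer is
    not unique; any maximizing eigenvector is returned and a warning is
    emitted.
    """
    qs = np.atleast_2d(np.asarray(qs, dtype=float))
    _require_finite(qs)
    if qs.shape[0] == 0:
        raise ValueError("need at least one quaternion")
    if weights is None:
        w = np.ones(qs.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (qs.shape[0],):
            raise ValueError("weights length must match quaternion count")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("at least one weight must be strictly positive")
    m = np.einsum("i,ij,ik->jk", w, qs, qs)
    vals, vecs = np.linalg.eigh(m)
    if vals[-1] - vals[-2] < _EIG_TIE_TOL * max(vals[-1], 1.0):
        warnings.warn(
            "Markley average: top eigenvalue is (near-)degenerate; "
            "returning one of the maximizing eigenvectors",
            RuntimeWarning,
            stacklevel=2,
        )
    return canonical_sign(vecs[:, -1])


def markley_average_stack(ms: np.ndarray) -> np.ndarray:
    """Dominant eigenvectors of a stack of 4x4 accumulator matrices.

    Vectorized helper for the averaging/smoothing loops: ``ms`` has shape
    ``(n, 4, 4)``; returns ``(n, 4)`` canonical-sign unit quaternions.
    """
    _, vecs = np.linalg.eigh(ms)
    return canonical_sign(vecs[..., -1])


# ---------------------------------------------------------------------------
# Euler conversions (via scipy.spatial.transform)
# ---------------------------------------------------------------------------


def euler_array_to_quat(angles_deg: np.ndarray, order: str = "ZXY") -> np.ndarray:
    """Convert ``(..., 3)`` Euler angles (degrees, columns follow ``order``)
    to w-first quaternions."""
    if order not in EULER_ORDERS:
        raise ValueError(f"unknown Euler order {order!r}")
    rot = Rotation.from_euler(order, np.asarray(angles_deg, dtype=float), degrees=True)
    q = np.roll(np.atleast_2d(rot.as_quat()), 1, axis=-1)
    q = canonical_sign(q)
    return q[0] if np.asarray(angles_deg).ndim == 1 else q


def quat_to_euler_array(q: np.ndarray, order: str = "ZXY") -> np.ndarray:
    """Convert w-first quaternions to Euler angles in degrees (columns in
    ``order``).  Gimbal-lock frames are resolved by zeroing the third angle
    (SciPy's convention); the associated warning is suppressed."""
    if order not in EULER_ORDERS:
        raise ValueError(f"unknown Euler order {order!r}")
    q = np.asarray(q, dtype=float)
    rot = Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        ang = rot.as_euler(order, degrees=True)
    ang = np.atleast_2d(ang)
    # wrap outer angles to [-180, 180); scipy keeps the middle in [-90, 90]
    for k in (0, 2):
        ang[:, k] = ((ang[:, k] + 180.0) % 360.0) - 180.0
    return ang[0] if q.ndim == 1 else ang


def euler_to_quat(e: EulerAngles) -> np.ndarray:
    """Quaternion (w-first) of an :class:`EulerAngles` rotation."""
    return euler_array_to_quat(e.as_ordered(), e.order)


def quat_to_euler(q: np.ndarray, order: str = "ZXY") -> EulerAngles:
    """Euler angles of a unit quaternion in the given intrinsic order."""
    ang = quat_to_euler_array(q, order)
    by_axis = dict(zip(order, ang))
    return EulerAngles(rx=float(by_axis["X"]), ry=float(by_axis["Y"]), rz=float(by_axis["Z"]), order=order)
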