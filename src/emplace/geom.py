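"""Rigid-transform utilities: unit-quaternion poses and rotation metrics.

Quaternions are stored scalar-first (w, x, y, z) and kept normalized.
A :class:`Pose` acts on coordinates as ``x' = R x + t`` (rotation about the
origin followed by translation), all in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


def _as_unit_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    n = np.linalg.norm(q)
    if not np.isfinite(n) or n == 0:
        raise ValueError("quaternion has zero or non-finite norm")
    return q / n


@dataclass(frozen=True)
class Pose:
    """A rigid transform: unit quaternion (w, x, y, z) plus translation (Å)."""

    quaternion: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        q = _as_unit_quat(self.quaternion)
        object.__setattr__(self, "quaternion", tuple(q))
        t = np.asarray(self.translation, dtype=float)
        if t.shape != (3,) or not np.all(np.isfinite(t)):
            raise ValueError("translation must be a finite 3-vector")
        object.__setattr__(self, "translation", tuple(t))

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w])  # scipy is scalar-last

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.matrix.T + np.asarray(self.translation)

    def compose(self, other: "Pose") -> "Pose":
        """Return the pose equivalent to applying `other` first, then `self`."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation) + np.asarray(self.translation)
        return Pose(quaternion=quat_from_rotation(r), translation=tuple(t))

    def inverse(self) -> "Pose":
        rinv = self.rotation.inv()
        t = -rinv.apply(np.asarray(self.translation))
        return Pose(quaternion=quat_from_rotation(rinv), translation=tuple(t))

    @staticmethod
    def identity() -> "Pose":
        return Pose()

    @staticmethod
    def from_rotation(r: Rotation, translation=(0.0, 0.0, 0.0)) -> "Pose":
        return Pose(quaternion=quat_from_rotation(r), translation=tuple(translation))


def quat_from_rotation(r: Rotation) -> tuple[float, float, float, float]:
    x, y, z, w = r.as_quat()
    if w < 0:  # canonical hemisphere, for reproducible serialization
        w, x, y, z = -w, -x, -y, -z
    return (float(w), float(x), float(y), float(z))


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Haar-uniform random rotation (Shoemake's method via scipy)."""
    return Rotation.random(random_state=rng)


def rotation_angle_deg(q1, q2) -> float:
    """Geodesic angle in degrees between two unit quaternions: 2 arccos|q1·q2|."""
    q1 = _as_unit_quat(q1)
    q2 = _as_unit_quat(q2)
    d = min(1.0, abs(float(np.dot(q1, q2))))
    return float(np.degrees(2.0 * np.arccos(d)))


def axis_angle_quat(axis, angle_deg: float) -> tuple[float, float, float, float]:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    r = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return quat_from_rotation(r)
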