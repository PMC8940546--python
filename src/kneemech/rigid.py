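"""Minimal rigid-body transforms (rotation + translation) in mm."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p_world = R @ p_body + t``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def about_axis(point: np.ndarray, direction: np.ndarray, angle_deg: float) -> "RigidTransform":
        """Rotation by ``angle_deg`` about the line through ``point`` along ``direction``."""
        point = np.asarray(point, dtype=float)
        direction = np.asarray(direction, dtype=float)
        n = np.linalg.norm(direction)
        if n == 0.0:
            raise ValueError("rotation axis direction must be non-zero")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * direction / n).as_matrix()
        return RigidTransform(rotation=rot, translation=point - rot @ point)

    @staticmethod
    def translation_of(vector: np.ndarray) -> "RigidTransform":
        return RigidTransform(translation=np.asarray(vector, dtype=float))
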