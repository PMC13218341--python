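"""Shared geometric primitives: triangulated surfaces and similarity poses.

All modules use a right-handed shank-fixed frame: +X anterior, +Y lateral,
+Z proximal (along the long axis of the bone). Lengths are millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class SurfaceMesh:
    """A triangulated surface in mm coordinates.

    Vertices keep their construction order so that meshes built on the same
    parametric grid stay in point correspondence (vertex i means the same
    anatomical location on every mesh of a population).
    """

    vertices: np.ndarray  # (N, 3) float
    faces: np.ndarray     # (M, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        # process=False keeps vertex order (correspondence semantics).
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def enclosed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (mm^3)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2]))) / 6.0

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def z_extent(self) -> float:
        return float(self.vertices[:, 2].max() - self.vertices[:, 2].min())

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, pose: "Pose") -> "SurfaceMesh":
        return SurfaceMesh(pose.apply(self.vertices), self.faces.copy())


@dataclass
class Pose:
    """Similarity transform x -> scale * R @ x + t."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) @ self.rotation / self.scale

    @staticmethod
    def identity() -> "Pose":
        return Pose()


def procrustes_pose(source: np.ndarray, target: np.ndarray,
                    allow_scale: bool = False) -> Pose:
    """Least-squares similarity pose mapping ``source`` onto ``target``.

    Closed-form Kabsch/Umeyama solution for min ||s R source + t - target||^2
    over rotations (det +1), translation, and optionally isotropic scale.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError("point sets must have matching shapes")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    s0 = src - mu_s
    t0 = tgt - mu_t
    cov = t0.T @ s0 / len(src)
    U, D, Vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, sgn])
    R = U @ S @ Vt
    if allow_scale:
        var_s = (s0 ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(D) @ S) / var_s) if var_s > 0 else 1.0
    else:
        scale = 1.0
    t = mu_t - scale * R @ mu_s
    return Pose(scale=scale, rotation=R, translation=t)
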