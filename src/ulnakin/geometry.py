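"""Core mesh and rigid-body primitives for wrist-bone kinematics.

Everything downstream (landmark detection, the four ulnar-sided parameters,
sequence tracking) is built on the small set of types defined here:

* :class:`TriangleMesh` — a closed triangle surface of a single bone in
  millimetre coordinates, tagged with its bone label.
* :class:`RigidTransform` — a proper rigid motion (rotation + translation).
* :class:`AnatomicalFrame` — the orthonormal wrist coordinate frame
  (radial→ulnar, palmar→dorsal, proximal→distal) that hosts every sign
  convention in the package.

Conventions
-----------
All coordinates are millimetres.  Frames are right-handed after side
normalization: left wrists are mirrored across the sagittal plane into the
right-hand convention before any measurement, so "dorsal positive" means the
same thing for every wrist.  In the canonical synthetic pose the axes are
``e_ru = +x`` (radial→ulnar), ``e_pd = +y`` (palmar→dorsal, i.e. dorsal is
+y) and ``e_lon = +z`` (proximal→distal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import trimesh

BONE_LABELS = ("radius", "ulna", "lunate", "triquetrum", "capitate")

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when an operation receives geometry it cannot act on."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` in mm.

    ``rotation`` must be orthonormal with determinant +1 (within 1e-9);
    reflections are rejected so that handedness is preserved through every
    pose chain.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (|R R^T - I| = {err:g})")
        det = np.linalg.det(R)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det:g} != +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        M = np.asarray(matrix, dtype=float)
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_rad: float, center: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rotation of ``angle_rad`` about ``axis`` through ``center``."""
        a = unit(np.asarray(axis, dtype=float))
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        if center is None:
            t = np.zeros(3)
        else:
            c = np.asarray(center, dtype=float)
            t = c - R @ c
        return cls(R, t)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-15:
        raise DegenerateGeometryError("cannot normalize zero vector")
    return v / n


# ---------------------------------------------------------------------------
# Triangle meshes
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Closed triangle surface of one wrist bone, mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    bone_label: str = "radius"

    def __post_init__(self) -> None:
        V = np.ascontiguousarray(np.asarray(self.vertices, dtype=float).reshape(-1, 3))
        F = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64).reshape(-1, 3))
        if V.shape[0] < 4:
            raise ValueError("mesh needs at least 4 vertices")
        if not np.all(np.isfinite(V)):
            raise ValueError("non-finite vertex coordinates")
        if F.size and (F.min() < 0 or F.max() >= V.shape[0]):
            raise ValueError("face index out of range")
        if self.bone_label not in BONE_LABELS:
            raise ValueError(f"unknown bone label {self.bone_label!r}")
        self.vertices = V
        self.faces = F
        self._trimesh_cache: trimesh.Trimesh | None = None

    # -- interop -----------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh_cache is None:
            self._trimesh_cache = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh_cache

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, bone_label: str) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), bone_label)

    # -- queries -----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) triangle corner array."""
        return self.vertices[self.faces]

    def boundary_vertex_mask(self) -> np.ndarray:
        """True for vertices on an open (single-face) edge."""
        edges = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        mask = np.zeros(self.n_vertices, dtype=bool)
        open_edges = uniq[counts == 1]
        if open_edges.size:
            mask[np.unique(open_edges)] = True
        return mask

    def validity_report(self) -> dict:
        """Watertightness / openness diagnostics (meshes are intended closed)."""
        tm = self.to_trimesh()
        n_open = int(self.boundary_vertex_mask().sum())
        return {
            "watertight": bool(tm.is_watertight),
            "n_open_edge_vertices": n_open,
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
        }

    # -- manipulation ------------------------------------------------------
    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces, self.bone_label)

    def mirrored(self, plane_point: np.ndarray, plane_normal: np.ndarray) -> "TriangleMesh":
        """Reflect across a plane, flipping face winding to keep outward normals."""
        p0 = np.asarray(plane_point, dtype=float)
        n = unit(plane_normal)
        d = (self.vertices - p0) @ n
        V = self.vertices - 2.0 * d[:, None] * n
        F = self.faces[:, [0, 2, 1]]
        return TriangleMesh(V, F, self.bone_label)


# ---------------------------------------------------------------------------
# Anatomical frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal wrist coordinate frame.

    ``e_ru`` points radial→ulnar, ``e_pd`` palmar→dorsal, ``e_lon``
    proximal→distal.  After side normalization every frame is right-handed:
    ``e_ru × e_pd = e_lon``.
    """

    origin: np.ndarray
    e_ru: np.ndarray
    e_pd: np.ndarray
    e_lon: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        axes = [np.asarray(a, dtype=float).reshape(3) for a in (self.e_ru, self.e_pd, self.e_lon)]
        M = np.stack(axes)
        if np.abs(M @ M.T - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("frame axes not orthonormal within 1e-9")
        if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
            raise ValueError("frame is left-handed; mirror to right-hand convention first")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "e_ru", axes[0])
        object.__setattr__(self, "e_pd", axes[1])
        object.__setattr__(self, "e_lon", axes[2])

    @classmethod
    def canonical(cls, origin: np.ndarray | None = None, side: str = "right") -> "AnatomicalFrame":
        o = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
        return cls(o, np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]), side)

    def transformed(self, transform: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(
            transform.apply(self.origin),
            transform.apply_vector(self.e_ru),
            transform.apply_vector(self.e_pd),
            transform.apply_vector(self.e_lon),
            self.side,
        )


# ---------------------------------------------------------------------------
# Principal axes and frame construction
# ---------------------------------------------------------------------------


def principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the vertex covariance, largest first.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvectors in rows.
    """
    P = np.asarray(points, dtype=float)
    C = np.cov(P.T)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order].T


def principal_longitudinal_axis(
    mesh: TriangleMesh | np.ndarray,
    frame: AnatomicalFrame | None = None,
    min_elongation: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant principal axis of an elongated bone.

    Returns ``(point_on_axis, unit_direction)``.  The direction is oriented
    distally (positive projection on ``frame.e_lon``) when a frame is given;
    otherwise the sign is fixed deterministically by the largest component.

    Raises :class:`DegenerateGeometryError` for near-isotropic vertex clouds
    (largest principal extent < ``min_elongation`` × second largest).
    """
    pts = mesh.vertices if isinstance(mesh, TriangleMesh) else np.asarray(mesh, dtype=float)
    w, V = principal_axes(pts)
    if np.sqrt(w[0]) < min_elongation * np.sqrt(max(w[1], 1e-30)):
        raise DegenerateGeometryError(
            "mesh is not elongated enough for a longitudinal axis "
            f"(extent ratio {np.sqrt(w[0] / max(w[1], 1e-30)):.2f} < {min_elongation})"
        )
    d = V[0]
    if frame is not None:
        if np.dot(d, frame.e_lon) < 0:
            d = -d
    else:
        k = int(np.argmax(np.abs(d)))
        if d[k] < 0:
            d = -d
    return pts.mean(axis=0), d


def build_radius_frame(
    radius: TriangleMesh,
    ulna: TriangleMesh,
    side: str = "right",
    distal_hint: np.ndarray | None = None,
) -> AnatomicalFrame:
    """Geometric surrogate for the automatic radius coordinate system.

    The longitudinal axis is the radius' dominant principal axis, oriented
    distally by ``distal_hint`` (e.g. a carpal centroid); the radial→ulnar
    axis is the ulna-ward direction orthogonalized against it; palmar→dorsal
    completes the right-handed triad.  Left wrists must be mirrored to the
    right-hand convention before calling (see :func:`mirror_to_right`).
    """
    centroid = radius.centroid()
    _, V = principal_axes(radius.vertices)
    e_lon = V[0]
    if distal_hint is not None:
        if np.dot(np.asarray(distal_hint, dtype=float) - centroid, e_lon) < 0:
            e_lon = -e_lon
    toward_ulna = ulna.centroid() - centroid
    e_ru = toward_ulna - np.dot(toward_ulna, e_lon) * e_lon
    e_ru = unit(e_ru)
    e_pd = np.cross(e_lon, e_ru)
    return AnatomicalFrame(centroid, e_ru, e_pd, e_lon, side="right")


def mirror_to_right(
    meshes: Iterable[TriangleMesh],
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
) -> list[TriangleMesh]:
    """Mirror a left wrist's bones across the sagittal plane.

    All measurements use the right-hand convention; a left wrist is reflected
    once, up front, so the dorsal-positive sign conventions apply unchanged.
    """
    return [m.mirrored(plane_point, plane_normal) for m in meshes]
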