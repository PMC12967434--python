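"""Automatic detection of the ulnar-sided anatomical landmarks.

All four wrist parameters are functions of a small set of named points:

* the most distal point of the ulnar head articular surface (styloid
  excluded) and the most distal point of the radial sigmoid notch — for
  3-D ulnar variance;
* the palmar-radial corner, palmar and dorsal margins of the sigmoid
  notch, and the most palmar point of the ulnar head — for the modified
  radioulnar line;
* the ulnar epicentre (longitudinal ulnar axis ∩ distal cortex) and the
  notch midpoint — for the epicentre method;
* the ulnar styloid tip — for the axial forearm-rotation angle.

The radius-side landmarks here are a geometric surrogate for
statistical-shape-model landmarking: the sigmoid notch is found as the
largest connected high-curvature region on the ulnar-distal aspect of the
radius, and the margins/corner are rim extremes in the anatomical frame.
Externally supplied landmarks (JSON) bypass detection entirely.

All detectors are deterministic (ties broken by lowest vertex index) and
equivariant under joint rigid motion of mesh and frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .curvature import curvature
from .geometry import (
    AnatomicalFrame,
    DegenerateGeometryError,
    RigidTransform,
    TriangleMesh,
    principal_axes,
)

_TIE_TOL = 1e-9


class LandmarkDetectionError(DegenerateGeometryError):
    pass


# ---------------------------------------------------------------------------
# Landmark container
# ---------------------------------------------------------------------------

_LANDMARK_BONES = {
    "distal_ulnar_point": "ulna",
    "sigmoid_distal_point": "radius",
    "palmar_radial_corner": "radius",
    "palmar_margin": "radius",
    "dorsal_margin": "radius",
    "notch_midpoint": "radius",
    "ulnar_epicentre": "ulna",
    "ulnar_styloid_tip": "ulna",
    "ulnar_head_palmar_point": "ulna",
}


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points (mm, world coordinates)."""

    distal_ulnar_point: np.ndarray
    sigmoid_distal_point: np.ndarray
    palmar_radial_corner: np.ndarray
    palmar_margin: np.ndarray
    dorsal_margin: np.ndarray
    notch_midpoint: np.ndarray
    ulnar_epicentre: np.ndarray
    ulnar_styloid_tip: np.ndarray
    ulnar_head_palmar_point: np.ndarray
    source: str = "auto"

    def __post_init__(self) -> None:
        for name in _LANDMARK_BONES:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"non-finite landmark {name}")
            object.__setattr__(self, name, p)
        mid = 0.5 * (self.palmar_margin + self.dorsal_margin)
        if np.abs(mid - self.notch_midpoint).max() > 1e-9:
            raise ValueError("notch_midpoint must be the margin midpoint (within 1e-9)")
        if np.linalg.norm(self.palmar_margin - self.dorsal_margin) <= 0:
            raise ValueError("sigmoid notch width must be positive")
        if self.source not in ("auto", "provided"):
            raise ValueError("source must be 'auto' or 'provided'")

    @property
    def notch_width(self) -> float:
        return float(np.linalg.norm(self.palmar_margin - self.dorsal_margin))

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        kwargs = {n: transform.apply(getattr(self, n)) for n in _LANDMARK_BONES}
        return LandmarkSet(source=self.source, **kwargs)

    def transformed_per_bone(
        self, radius_transform: RigidTransform, ulna_transform: RigidTransform
    ) -> "LandmarkSet":
        """Transport each landmark by its host bone's pose."""
        kwargs = {}
        for name, bone in _LANDMARK_BONES.items():
            tf = radius_transform if bone == "radius" else ulna_transform
            kwargs[name] = tf.apply(getattr(self, name))
        return LandmarkSet(source=self.source, **kwargs)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path, frame_id: str = "world") -> None:
        records = [
            {
                "bone": bone,
                "name": name,
                "xyz_mm": [float(x) for x in getattr(self, name)],
                "frame_id": frame_id,
            }
            for name, bone in _LANDMARK_BONES.items()
        ]
        Path(path).write_text(
            json.dumps({"source": self.source, "landmarks": records}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        doc = json.loads(Path(path).read_text())
        points = {rec["name"]: np.array(rec["xyz_mm"], dtype=float) for rec in doc["landmarks"]}
        missing = set(_LANDMARK_BONES) - set(points)
        if missing:
            raise LandmarkDetectionError(f"landmark file missing {sorted(missing)}")
        return cls(source=doc.get("source", "provided"), **points)


# ---------------------------------------------------------------------------
# Detection configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkConfig:
    """Tunable thresholds of the landmark detectors.

    ``styloid_cylinder_radius``: radius (mm) of the exclusion cylinder around
    the styloid process when looking for the distal articular point; 4 mm
    matches a typical styloid base.  ``curvature_threshold``: per-vertex
    curvature (1/mm) above which radius vertices count as sigmoid notch.
    ``notch_distal_fraction`` / ``head_window_fraction``: longitudinal search
    windows (fractions of bone extent) for the notch and the ulnar head.
    """

    styloid_cylinder_radius: float = 4.0
    curvature_threshold: float = 0.1
    curvature_kind: str = "mean"
    notch_distal_fraction: float = 0.25
    head_window_fraction: float = 0.2
    rim_band: float = 1.5
    tip_band: float = 0.5


def _lowest_index_argmax(values: np.ndarray, warn_label: str | None = None) -> int:
    """Deterministic argmax: ties (within 1e-9) resolved to lowest index."""
    m = values.max()
    ties = np.flatnonzero(values >= m - _TIE_TOL)
    if ties.size > 1 and warn_label:
        warnings.warn(
            f"{ties.size} tied maxima for {warn_label}; using lowest vertex index",
            RuntimeWarning,
            stacklevel=3,
        )
    return int(ties[0])


# ---------------------------------------------------------------------------
# Ulna landmarks
# ---------------------------------------------------------------------------


def styloid_tip(ulna: TriangleMesh, frame: AnatomicalFrame) -> np.ndarray:
    """Most distal ulna vertex (the styloid process tip)."""
    proj = ulna.vertices @ frame.e_lon
    return ulna.vertices[_lowest_index_argmax(proj)].copy()


def distal_ulnar_articular_point(
    ulna: TriangleMesh,
    frame: AnatomicalFrame,
    styloid_cylinder_radius: float = 4.0,
    tip_band: float = 0.5,
) -> np.ndarray:
    """Most distal point of the ulnar head once the styloid is removed.

    Vertices inside a cylinder of the given radius — axis through the
    styloid tip plateau, parallel to the longitudinal axis — are excluded;
    the most distal survivor is returned.
    """
    V = ulna.vertices
    proj = V @ frame.e_lon
    # anchor the exclusion axis at the centroid of the distal-most plateau
    # so a flat styloid tip does not bias the axis to one side
    plateau = proj >= proj.max() - tip_band
    anchor = V[plateau].mean(axis=0)
    lateral = (V - anchor) - np.outer((V - anchor) @ frame.e_lon, frame.e_lon)
    keep = np.linalg.norm(lateral, axis=1) >= styloid_cylinder_radius
    if not np.any(keep):
        raise LandmarkDetectionError(
            "styloid exclusion cylinder removed the entire distal surface; "
            "reduce styloid_cylinder_radius"
        )
    kept_idx = np.flatnonzero(keep)
    k = _lowest_index_argmax(proj[keep], warn_label="distal ulnar articular point")
    return V[kept_idx[k]].copy()


def ulnar_longitudinal_axis(
    ulna: TriangleMesh, frame: AnatomicalFrame, shaft_fraction: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal ulnar axis fitted to the shaft (proximal portion).

    Fitting on the proximal ``shaft_fraction`` of the bone keeps the head
    and styloid from tilting the axis.  Returns (point, distal unit dir).
    """
    V = ulna.vertices
    proj = V @ frame.e_lon
    cut = proj.min() + shaft_fraction * (proj.max() - proj.min())
    shaft = V[proj <= cut]
    if shaft.shape[0] < 10:
        shaft = V
    _, axes = principal_axes(shaft)
    d = axes[0]
    if np.dot(d, frame.e_lon) < 0:
        d = -d
    return shaft.mean(axis=0), d


def _line_mesh_intersections(
    point: np.ndarray, direction: np.ndarray, tris: np.ndarray
) -> np.ndarray:
    """Parameters t of line ``point + t*direction`` hitting triangles."""
    A, B, C = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = B - A
    e2 = C - A
    h = np.cross(np.broadcast_to(direction, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = point - A
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = (q @ direction) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    return t[hit]


def ulnar_epicentre(ulna: TriangleMesh, frame: AnatomicalFrame) -> np.ndarray:
    """Intersection of the ulnar longitudinal axis with the distal cortex."""
    p, d = ulnar_longitudinal_axis(ulna, frame)
    ts = _line_mesh_intersections(p, d, ulna.triangles())
    if ts.size == 0:
        raise LandmarkDetectionError("ulnar longitudinal axis does not intersect the mesh")
    return p + float(ts.max()) * d


def ulnar_head_palmar_point(
    ulna: TriangleMesh,
    frame: AnatomicalFrame,
    head_window_fraction: float = 0.2,
    styloid_cylinder_radius: float = 4.0,
    tip_band: float = 0.5,
) -> np.ndarray:
    """Most palmar vertex of the distal ulnar head (styloid excluded)."""
    V = ulna.vertices
    proj = V @ frame.e_lon
    lo = proj.max() - head_window_fraction * (proj.max() - proj.min())
    window = proj >= lo
    plateau = proj >= proj.max() - tip_band
    anchor = V[plateau].mean(axis=0)
    lateral = (V - anchor) - np.outer((V - anchor) @ frame.e_lon, frame.e_lon)
    window &= np.linalg.norm(lateral, axis=1) >= styloid_cylinder_radius
    if not np.any(window):
        raise LandmarkDetectionError("empty ulnar head window")
    idx = np.flatnonzero(window)
    k = _lowest_index_argmax(-(V[idx] @ frame.e_pd), warn_label="ulnar head palmar point")
    return V[idx[k]].copy()


# ---------------------------------------------------------------------------
# Radius landmarks
# ---------------------------------------------------------------------------


def sigmoid_notch_region(
    radius: TriangleMesh,
    frame: AnatomicalFrame,
    curvature_threshold: float = 0.1,
    curvature_kind: str = "mean",
    notch_distal_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid-notch vertex set and its most distal point.

    Vertices on the ulnar-facing distal portion of the radius whose
    (concave-positive) curvature exceeds the threshold are classified as
    notch and the largest connected component is kept.  The component is
    then extended by its bounding marginal crest — adjacent vertices with
    strongly *negative* (convex) curvature — because the palmar and dorsal
    margins of the sigmoid notch are the convex lips delimiting the facet,
    and the facet's extreme points lie on those crests.  The most distal
    vertex of the extended region is returned.
    """
    V = radius.vertices
    lon = V @ frame.e_lon
    ru = V @ frame.e_ru
    window = lon >= lon.max() - notch_distal_fraction * (lon.max() - lon.min())
    window &= ru >= 0.5 * (ru.min() + ru.max())

    field = curvature(radius, kind=curvature_kind, direction=frame.e_lon)
    vals = np.where(np.isnan(field.values), -np.inf, field.values)
    selected = window & (vals > curvature_threshold)
    if not np.any(selected):
        raise LandmarkDetectionError(
            "no vertices exceed the curvature threshold inside the notch window; "
            "lower curvature_threshold or widen the window"
        )

    # largest connected component on the mesh edge graph
    F = radius.faces
    edges = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    in_sel = selected[edges[:, 0]] & selected[edges[:, 1]]
    e = edges[in_sel]
    n = V.shape[0]
    graph = coo_matrix((np.ones(e.shape[0]), (e[:, 0], e[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    sel_idx = np.flatnonzero(selected)
    comp_of_sel = labels[sel_idx]
    best_label = np.bincount(comp_of_sel).argmax()
    region = sel_idx[comp_of_sel == best_label]

    # extend to the bounding marginal crest: neighbours of the facet with
    # convex curvature beyond the same magnitude threshold
    in_region = np.zeros(n, dtype=bool)
    in_region[region] = True
    crest = np.zeros(n, dtype=bool)
    touch = in_region[edges[:, 0]] & ~in_region[edges[:, 1]]
    crest[edges[touch, 1]] = True
    touch = in_region[edges[:, 1]] & ~in_region[edges[:, 0]]
    crest[edges[touch, 0]] = True
    crest &= window & (vals < -curvature_threshold)
    region = np.flatnonzero(in_region | crest)

    k = _lowest_index_argmax(lon[region], warn_label="sigmoid distal point")
    return region, V[region[k]].copy()


def _lex_select(
    V: np.ndarray,
    candidates: np.ndarray,
    keys: list[np.ndarray],
    tol: float = 1e-6,
) -> int:
    """Lexicographic minimization over candidate indices with tolerance ties."""
    idx = candidates
    for key in keys:
        k = key[idx]
        idx = idx[k <= k.min() + tol]
    return int(idx[0])


def sigmoid_notch_margins(
    radius: TriangleMesh,
    frame: AnatomicalFrame,
    notch_region: np.ndarray,
    rim_band: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Palmar/dorsal notch margins, palmar-radial corner and notch midpoint.

    Geometric surrogate for statistical-shape-model landmarking: the margins
    are the palmar-most and dorsal-most vertices of the detected notch
    region; the palmar-radial corner is the palmar-most vertex of the distal
    radius rim radial to the notch (ties resolved radially, then distally).
    """
    if notch_region is None or len(notch_region) == 0:
        raise LandmarkDetectionError("empty notch region")
    V = radius.vertices
    pd = V @ frame.e_pd
    ru = V @ frame.e_ru
    lon = V @ frame.e_lon

    region = np.asarray(notch_region, dtype=np.int64)
    # pd extremes; ties resolved toward the notch's longitudinal mid-level
    lon_mid = np.full_like(lon, lon[region].mean())
    palmar_margin = V[_lex_select(V, region, [pd, np.abs(lon - lon_mid)])].copy()
    dorsal_margin = V[_lex_select(V, region, [-pd, np.abs(lon - lon_mid)])].copy()

    rim = np.flatnonzero(lon >= lon.max() - rim_band)
    radial_of_notch = rim[ru[rim] < ru[region].min()]
    if radial_of_notch.size == 0:
        raise LandmarkDetectionError("no distal-rim vertices radial to the notch")
    corner_idx = _lex_select(V, radial_of_notch, [pd, ru, -lon])
    palmar_radial_corner = V[corner_idx].copy()

    midpoint = 0.5 * (palmar_margin + dorsal_margin)
    return palmar_margin, dorsal_margin, palmar_radial_corner, midpoint


# ---------------------------------------------------------------------------
# Full detection
# ---------------------------------------------------------------------------


def detect_landmarks(
    radius: TriangleMesh,
    ulna: TriangleMesh,
    frame: AnatomicalFrame,
    config: LandmarkConfig | None = None,
) -> LandmarkSet:
    """Run every detector and assemble the full landmark set."""
    cfg = config or LandmarkConfig()
    region, sigmoid_distal = sigmoid_notch_region(
        radius,
        frame,
        curvature_threshold=cfg.curvature_threshold,
        curvature_kind=cfg.curvature_kind,
        notch_distal_fraction=cfg.notch_distal_fraction,
    )
    palmar, dorsal, corner, midpoint = sigmoid_notch_margins(
        radius, frame, region, rim_band=cfg.rim_band
    )
    return LandmarkSet(
        distal_ulnar_point=distal_ulnar_articular_point(
            ulna, frame, cfg.styloid_cylinder_radius, cfg.tip_band
        ),
        sigmoid_distal_point=sigmoid_distal,
        palmar_radial_corner=corner,
        palmar_margin=palmar,
        dorsal_margin=dorsal,
        notch_midpoint=midpoint,
        ulnar_epicentre=ulnar_epicentre(ulna, frame),
        ulnar_styloid_tip=styloid_tip(ulna, frame),
        ulnar_head_palmar_point=ulnar_head_palmar_point(
            ulna, frame, cfg.head_window_fraction, cfg.styloid_cylinder_radius, cfg.tip_band
        ),
        source="auto",
    )
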