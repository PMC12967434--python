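"""Parametric synthetic wrist with exact analytic ground truth.

The generator builds five simplified, watertight bone surfaces in the
canonical right-wrist frame (radial→ulnar = +x, palmar→dorsal = +y,
proximal→distal = +z) and poses them through flexion–extension (FE),
radioulnar deviation (RUD) and pronation–supination (PS) trajectories:

* **radius** — a gridded box with an ellipsoidal concavity carved into
  its ulnar face (the sigmoid notch); the grid lines pass exactly through
  the notch margins, the distal notch apex and the palmar-radial corner,
  so every radius landmark coincides with a mesh vertex.
* **ulna** — shaft cylinder + spherical head + styloid peg.  The head
  sphere has a vertex at its distal pole (distal articular point and
  epicentre), at its palmar equator point, and along each carpal approach
  direction; the styloid tip cap has an exact on-axis centre vertex.
* **lunate / triquetrum** — spheres whose poles point back along their
  approach direction toward the ulnar head, so prescribed ulnocarpal
  gaps are realized exactly by vertex pairs.
* **capitate** — a capped cylinder along the longitudinal axis.

Every landmark and parameter value is therefore known in closed form
from the construction; the detectors and the pipeline are validated
against these values, never the other way round.  Motion is prescribed
through coupling functions — ulnar-variance drift, dorso-palmar DRUJ
translation and carpal gap trajectories versus wrist angle — and the
per-frame ground-truth parameter series follows analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .geometry import AnatomicalFrame, RigidTransform, TriangleMesh
from .landmarks import LandmarkSet
from .parameters import MovementLabel, epicentre_3d, mru_3d, ulnar_variance_3d
from .pipeline import BONES, DynamicSequence, FrameTarget


# ---------------------------------------------------------------------------
# Mesh builders (all watertight, with exactly-placed key vertices)
# ---------------------------------------------------------------------------


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``direction`` (unit)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    c = float(z @ d)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def uv_sphere(
    radius: float,
    center: np.ndarray,
    pole_direction: np.ndarray = (0.0, 0.0, 1.0),
    polar_step_deg: float = 5.0,
    azimuth_step_deg: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Latitude–longitude sphere with exact pole vertices.

    Ring polar angles are multiples of ``polar_step_deg`` and azimuths
    multiples of ``azimuth_step_deg`` (measured from +x), so vertices exist
    exactly along any direction whose spherical angles are grid multiples.
    """
    polars = np.deg2rad(np.arange(polar_step_deg, 180.0, polar_step_deg))
    azims = np.deg2rad(np.arange(0.0, 360.0, azimuth_step_deg))
    n_az = azims.size
    verts = [np.array([0.0, 0.0, radius])]
    for th in polars:
        ring = np.column_stack(
            [
                radius * np.sin(th) * np.cos(azims),
                radius * np.sin(th) * np.sin(azims),
                np.full(n_az, radius * np.cos(th)),
            ]
        )
        verts.append(ring)
    verts.append(np.array([[0.0, 0.0, -radius]]))
    V = np.vstack([verts[0][None, :] if verts[0].ndim == 1 else verts[0], *verts[1:]])

    faces = []
    def ring_start(k: int) -> int:  # ring index k (0-based) start vertex
        return 1 + k * n_az

    # top fan
    for j in range(n_az):
        faces.append([0, ring_start(0) + j, ring_start(0) + (j + 1) % n_az])
    # quads between rings
    for k in range(polars.size - 1):
        a, b = ring_start(k), ring_start(k + 1)
        for j in range(n_az):
            j2 = (j + 1) % n_az
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    # bottom fan
    south = V.shape[0] - 1
    a = ring_start(polars.size - 1)
    for j in range(n_az):
        faces.append([south, a + (j + 1) % n_az, a + j])

    R = _rotation_to(pole_direction)
    V = V @ R.T + np.asarray(center, dtype=float)
    return V, np.asarray(faces, dtype=np.int64)


def capped_cylinder(
    radius: float,
    z_bottom: float,
    z_top: float,
    center_xy: tuple[float, float] = (0.0, 0.0),
    sections: int = 24,
    z_step: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed cylinder along z with exact on-axis cap-centre vertices.

    The top cap centre is vertex 0, so distal-tip detection with a
    lowest-index tie-break lands exactly on the axis.  The wall carries
    intermediate vertex rings roughly every ``z_step`` mm, which keeps
    axis fits and surface registration well conditioned.
    """
    cx, cy = center_xy
    ang = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring = np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
    n_seg = max(1, int(round((z_top - z_bottom) / z_step)))
    z_levels = np.linspace(z_top, z_bottom, n_seg + 1)
    rings = [np.column_stack([ring, np.full(sections, z)]) for z in z_levels]
    V = np.vstack([[cx, cy, z_top], *rings, [cx, cy, z_bottom]])
    south = V.shape[0] - 1
    faces = []

    def start(k: int) -> int:
        return 1 + k * sections

    for j in range(sections):
        faces.append([0, start(0) + j, start(0) + (j + 1) % sections])
    for k in range(n_seg):
        a, b = start(k), start(k + 1)
        for j in range(sections):
            j2 = (j + 1) % sections
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    a = start(n_seg)
    for j in range(sections):
        faces.append([south, a + (j + 1) % sections, a + j])
    return V, np.asarray(faces, dtype=np.int64)


def _refined_coords(lo: float, hi: float, base_step: float, required: list[float]) -> np.ndarray:
    """Monotone coordinate list from lo to hi including required values."""
    pts = set(np.round(np.arange(lo, hi + 1e-9, base_step), 9))
    pts.add(round(hi, 9))
    for r in required:
        if lo - 1e-9 <= r <= hi + 1e-9:
            pts.add(round(r, 9))
    return np.array(sorted(pts))


def gridded_box(
    x_coords: np.ndarray, y_coords: np.ndarray, z_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight box surface on a structured (possibly non-uniform) grid."""

    def face(U: np.ndarray, Vc: np.ndarray, w: float, axes: tuple[int, int, int], flip: bool):
        uu, vv = np.meshgrid(U, Vc, indexing="ij")
        P = np.zeros((uu.size, 3))
        P[:, axes[0]] = uu.ravel()
        P[:, axes[1]] = vv.ravel()
        P[:, axes[2]] = w
        nu, nv = U.size, Vc.size
        idx = np.arange(nu * nv).reshape(nu, nv)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[1:, 1:].ravel()
        d = idx[:-1, 1:].ravel()
        F = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
        if flip:
            F = F[:, ::-1]
        return P, F

    panels = [
        face(y_coords, z_coords, x_coords[0], (1, 2, 0), flip=True),   # -x
        face(y_coords, z_coords, x_coords[-1], (1, 2, 0), flip=False), # +x
        face(x_coords, z_coords, y_coords[0], (0, 2, 1), flip=False),  # -y
        face(x_coords, z_coords, y_coords[-1], (0, 2, 1), flip=True),  # +y
        face(x_coords, y_coords, z_coords[0], (0, 1, 2), flip=True),   # -z
        face(x_coords, y_coords, z_coords[-1], (0, 1, 2), flip=False), # +z
    ]
    verts = []
    faces = []
    offset = 0
    for P, F in panels:
        verts.append(P)
        faces.append(F + offset)
        offset += P.shape[0]
    V = np.vstack(verts)
    F = np.vstack(faces)
    # merge exactly coincident vertices (panel edges share grid coordinates)
    Vu, inverse = np.unique(V, axis=0, return_inverse=True)
    F = inverse[F]
    return Vu, F


# ---------------------------------------------------------------------------
# Wrist parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WristParams:
    """Geometry of one synthetic wrist (mm, canonical right-wrist frame).

    Defaults place the static wrist at the cohort's neutral medians:
    ulnar variance −0.4 mm, ulnocarpal gaps 3.2 mm (lunate) and 6.9 mm
    (triquetrum), epicentre centred in the notch (0 %).
    """

    seed: int = 0
    side: str = "right"
    # radius
    radius_width_ru: float = 28.0
    radius_width_pd: float = 24.0
    radius_length: float = 70.0
    notch_width: float = 18.0           # W, palmar-dorsal chord of the notch
    notch_depth: float = 1.0            # carve depth at the deepest point
    notch_depth_semiaxis: float = 6.0   # ellipsoid semi-axis into the bone
    notch_lon_semiaxis: float = 5.0     # ellipsoid semi-axis along e_lon
    notch_center_depth: float = 10.0    # distance of notch centre below distal rim
    # static parameter prescriptions
    uv3d: float = -0.4
    gap_lunate: float = 3.2
    gap_triquetrum: float = 6.9
    druj_gap: float = 0.5
    # ulna
    head_radius: float = 10.0
    shaft_radius: float = 7.0
    shaft_length: float = 80.0
    styloid_length: float = 3.5
    styloid_radius: float = 1.2
    styloid_offset: float = 5.0
    # carpals; approach directions are (polar, azimuth) from the head centre,
    # on the head sphere's angular grid so the contact vertex is exact
    lunate_radius: float = 5.0
    lunate_polar_deg: float = 15.0
    lunate_azimuth_deg: float = 180.0
    triquetrum_radius: float = 6.0
    triquetrum_polar_deg: float = 65.0
    triquetrum_azimuth_deg: float = 300.0
    capitate_radius: float = 5.5
    capitate_length: float = 24.0
    capitate_gap: float = 1.0
    # mesh resolution
    polar_step_deg: float = 5.0
    azimuth_step_deg: float = 10.0
    box_step: float = 2.0
    notch_step: float = 0.5

    def __post_init__(self) -> None:
        if self.notch_width <= 0:
            raise ValueError("notch width must be positive")
        if self.notch_depth >= self.notch_depth_semiaxis:
            raise ValueError("notch deeper than its carving ellipsoid")
        if self.notch_depth >= self.radius_width_ru:
            raise ValueError("notch deeper than the bone")
        if min(self.gap_lunate, self.gap_triquetrum, self.druj_gap) < 0:
            raise ValueError("gaps must be non-negative")
        s = self._rim_scale()
        if not (0 < s < 1):
            raise ValueError("infeasible notch depth/semiaxis combination")
        for ang, step in (
            (self.lunate_polar_deg, self.polar_step_deg),
            (self.triquetrum_polar_deg, self.polar_step_deg),
            (self.lunate_azimuth_deg, self.azimuth_step_deg),
            (self.triquetrum_azimuth_deg, self.azimuth_step_deg),
        ):
            if abs(ang / step - round(ang / step)) > 1e-9:
                raise ValueError("carpal approach angles must lie on the sphere grid")

    def _rim_scale(self) -> float:
        return float(np.sqrt(1.0 - (1.0 - self.notch_depth / self.notch_depth_semiaxis) ** 2))

    @property
    def curvature_at_notch_pole(self) -> float:
        """Analytic mean curvature (1/mm) at the deepest notch point."""
        s = self._rim_scale()
        b = (self.notch_width / 2.0) / s
        a = self.notch_depth_semiaxis
        c = self.notch_lon_semiaxis
        return 0.5 * (a / b**2 + a / c**2)

    @classmethod
    def randomized(cls, seed: int) -> "WristParams":
        """Plausible anatomical variation for one seeded wrist instance."""
        rng = np.random.default_rng(seed)
        return cls(
            seed=seed,
            radius_width_ru=rng.uniform(25, 31),
            radius_width_pd=rng.uniform(21, 27),
            radius_length=rng.uniform(62, 78),
            notch_width=rng.uniform(16, 20),
            notch_depth=rng.uniform(0.8, 1.3),
            uv3d=rng.uniform(-2.0, 1.5),
            gap_lunate=rng.uniform(2.2, 3.6),
            gap_triquetrum=rng.uniform(5.5, 8.5),
            head_radius=rng.uniform(9.0, 11.0),
            shaft_length=rng.uniform(72, 88),
            styloid_length=rng.uniform(2.5, 3.5),
            capitate_length=rng.uniform(21, 27),
        )


@dataclass
class SyntheticWrist:
    """Generated bones with their exact construction ground truth."""

    params: WristParams
    meshes: dict[str, TriangleMesh]
    frame: AnatomicalFrame
    landmarks: LandmarkSet
    static_parameters: dict[str, float]
    head_center: np.ndarray
    carpal_directions: dict[str, np.ndarray]


def _direction(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th, az = np.deg2rad(polar_deg), np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.cos(az), np.sin(th) * np.sin(az), np.cos(th)])


def generate_wrist(params: WristParams | None = None) -> SyntheticWrist:
    """Build the five bone meshes and their exact ground truth."""
    p = params or WristParams()
    s = p._rim_scale()
    b_pd = (p.notch_width / 2.0) / s          # ellipsoid semi-axis along e_pd
    rim_lon = p.notch_lon_semiaxis * s        # notch half-extent along e_lon
    cz = -p.notch_center_depth                # notch centre (distal rim at z=0)
    half_pd = p.radius_width_pd / 2.0

    # --- radius: gridded box with the notch carved into the +x face -------
    xs = _refined_coords(-p.radius_width_ru, 0.0, p.box_step, [])
    ys = _refined_coords(
        -half_pd, half_pd, p.box_step,
        list(np.arange(-p.notch_width / 2, p.notch_width / 2 + 1e-9, p.notch_step))
        + [-p.notch_width / 2, 0.0, p.notch_width / 2],
    )
    zs = _refined_coords(
        -p.radius_length, 0.0, p.box_step,
        list(np.arange(cz - rim_lon, cz + rim_lon + 1e-9, p.notch_step))
        + [cz - rim_lon, cz, cz + rim_lon],
    )
    V, F = gridded_box(xs, ys, zs)
    on_face = V[:, 0] == 0.0
    rho2 = (V[:, 1] / b_pd) ** 2 + ((V[:, 2] - cz) / p.notch_lon_semiaxis) ** 2
    carve = on_face & (rho2 < s**2)
    cx = p.notch_depth_semiaxis - p.notch_depth  # ellipsoid centre x
    V = V.copy()
    V[carve, 0] = cx - p.notch_depth_semiaxis * np.sqrt(1.0 - rho2[carve])
    radius_mesh = TriangleMesh(V, F, "radius")

    # --- ulna: shaft + head + styloid -------------------------------------
    sigmoid_distal = np.array([0.0, 0.0, cz + rim_lon])
    head_c = np.array(
        [p.head_radius + p.druj_gap, 0.0, p.uv3d + sigmoid_distal[2] - p.head_radius]
    )
    Vh, Fh = uv_sphere(
        p.head_radius, head_c, (0, 0, 1), p.polar_step_deg, p.azimuth_step_deg
    )
    Vs, Fs = capped_cylinder(
        p.shaft_radius, head_c[2] - p.shaft_length, head_c[2], (head_c[0], head_c[1])
    )
    styl_tip_z = head_c[2] + p.head_radius + p.styloid_length
    Vy, Fy = capped_cylinder(
        p.styloid_radius, head_c[2], styl_tip_z, (head_c[0] + p.styloid_offset, head_c[1])
    )
    # styloid first so its tip-centre vertex has the lowest index at max z
    Vu = np.vstack([Vy, Vh, Vs])
    Fu = np.vstack([Fy, Fh + Vy.shape[0], Fs + Vy.shape[0] + Vh.shape[0]])
    ulna_mesh = TriangleMesh(Vu, Fu, "ulna")

    # --- carpals ----------------------------------------------------------
    d_l = _direction(p.lunate_polar_deg, p.lunate_azimuth_deg)
    d_t = _direction(p.triquetrum_polar_deg, p.triquetrum_azimuth_deg)
    lun_c = head_c + (p.head_radius + p.gap_lunate + p.lunate_radius) * d_l
    tri_c = head_c + (p.head_radius + p.gap_triquetrum + p.triquetrum_radius) * d_t
    Vl, Fl = uv_sphere(p.lunate_radius, lun_c, -d_l, p.polar_step_deg, p.azimuth_step_deg)
    Vt, Ft = uv_sphere(p.triquetrum_radius, tri_c, -d_t, p.polar_step_deg, p.azimuth_step_deg)
    cap_z0 = lun_c[2] + p.lunate_radius + p.capitate_gap
    Vc, Fc = capped_cylinder(
        p.capitate_radius, cap_z0, cap_z0 + p.capitate_length, (lun_c[0], lun_c[1])
    )

    meshes = {
        "radius": radius_mesh,
        "ulna": ulna_mesh,
        "lunate": TriangleMesh(Vl, Fl, "lunate"),
        "triquetrum": TriangleMesh(Vt, Ft, "triquetrum"),
        "capitate": TriangleMesh(Vc, Fc, "capitate"),
    }

    frame = AnatomicalFrame.canonical(origin=np.array([0.0, 0.0, cz]), side="right")
    landmarks = LandmarkSet(
        distal_ulnar_point=head_c + np.array([0, 0, p.head_radius]),
        sigmoid_distal_point=sigmoid_distal,
        palmar_radial_corner=np.array([-p.radius_width_ru, -half_pd, 0.0]),
        palmar_margin=np.array([0.0, -p.notch_width / 2, cz]),
        dorsal_margin=np.array([0.0, p.notch_width / 2, cz]),
        notch_midpoint=np.array([0.0, 0.0, cz]),
        ulnar_epicentre=head_c + np.array([0, 0, p.head_radius]),
        ulnar_styloid_tip=np.array([head_c[0] + p.styloid_offset, head_c[1], styl_tip_z]),
        ulnar_head_palmar_point=head_c + np.array([0, -p.head_radius, 0]),
        source="auto",
    )
    static_parameters = {
        "uv3d_mm": ulnar_variance_3d(
            landmarks.distal_ulnar_point, landmarks.sigmoid_distal_point, frame
        ),
        "ucp_l_mm": p.gap_lunate,
        "ucp_t_mm": p.gap_triquetrum,
        "mru3d_pct": mru_3d(landmarks, frame),
        "epi3d_pct": epicentre_3d(landmarks, frame),
    }
    wrist = SyntheticWrist(
        p, meshes, frame, landmarks, static_parameters, head_c,
        {"lunate": d_l, "triquetrum": d_t},
    )
    if p.side == "left":
        wrist = _mirror_wrist(wrist)
    return wrist


def _mirror_wrist(wrist: SyntheticWrist) -> SyntheticWrist:
    """Left-side twin: reflect across the sagittal plane through the origin."""
    origin = wrist.frame.origin
    n = wrist.frame.e_ru
    meshes = {k: m.mirrored(origin, n) for k, m in wrist.meshes.items()}

    def refl_point(q: np.ndarray) -> np.ndarray:
        return q - 2.0 * float((q - origin) @ n) * n

    def refl_vec(v: np.ndarray) -> np.ndarray:
        return v - 2.0 * float(v @ n) * n

    lm = wrist.landmarks
    from .landmarks import _LANDMARK_BONES

    kwargs = {name: refl_point(getattr(lm, name)) for name in _LANDMARK_BONES}
    return SyntheticWrist(
        wrist.params,
        meshes,
        wrist.frame,  # measurement frame remains the right-hand convention
        LandmarkSet(source="auto", **kwargs),
        wrist.static_parameters,
        refl_point(wrist.head_center),
        {k: refl_vec(v) for k, v in wrist.carpal_directions.items()},
    )


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------


def _linear(slope: float) -> Callable[[float], float]:
    return lambda theta: slope * theta


@dataclass(frozen=True)
class MotionParams:
    """One movement trajectory and its kinematic coupling functions.

    ``amplitude`` is (most negative, most positive) wrist angle in degrees;
    signs follow the movement convention (flexion / ulnar deviation /
    pronation negative).  Coupling functions map wrist angle (deg) to:
    ``uv_drift`` — change of ulnar variance (mm); ``dp_translation`` —
    dorsal displacement of the ulna relative to the radius (mm);
    ``gap_lunate_delta`` / ``gap_triquetrum_delta`` — change of the
    ulnocarpal gaps (mm) relative to the wrist's own neutral gaps, zero at
    the neutral angle.
    Defaults emulate the healthy-cohort excursions (e.g. a dorso-palmar
    DRUJ sweep of ≈15 % of notch width during PS, strong triquetral
    approach in ulnar deviation).
    """

    movement: MovementLabel
    amplitude: tuple[float, float]
    n_frames: int = 21
    frame_rate: float = 10.0
    uv_drift: Callable[[float], float] = staticmethod(lambda th: 0.0)
    dp_translation: Callable[[float], float] = staticmethod(lambda th: 0.0)
    gap_lunate_delta: Callable[[float], float] = staticmethod(lambda th: 0.0)
    gap_triquetrum_delta: Callable[[float], float] = staticmethod(lambda th: 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "movement", MovementLabel(self.movement))
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        lo, hi = self.amplitude
        if not (lo <= 0.0 <= hi):
            raise ValueError("amplitude must bracket the neutral angle 0")
        if max(abs(lo), abs(hi)) > 90:
            raise ValueError("amplitude outside the feasible joint range")

    @classmethod
    def default(cls, movement: MovementLabel, n_frames: int = 21) -> "MotionParams":
        movement = MovementLabel(movement)
        if movement is MovementLabel.FE:
            return cls(
                movement, (-40.0, 60.0), n_frames,
                uv_drift=lambda th: 0.3 * np.sin(np.deg2rad(1.5 * th)),
                dp_translation=_linear(-0.01386),
                gap_lunate_delta=lambda th: -0.01 * th,
                gap_triquetrum_delta=lambda th: -0.016 * th - 1.5e-4 * th**2,
            )
        if movement is MovementLabel.RUD:
            return cls(
                movement, (-25.0, 10.0), n_frames,
                uv_drift=_linear(0.0114),
                dp_translation=_linear(-0.0478),
                gap_lunate_delta=lambda th: -0.0114 * th,
                gap_triquetrum_delta=lambda th: 0.1257 * th,
            )
        return cls(
            movement, (-50.0, 50.0), n_frames,
            uv_drift=lambda th: -1.1 * (th / 50.0) ** 2,
            dp_translation=_linear(-0.02736),
            gap_triquetrum_delta=lambda th: 0.019 * th,
        )


def angle_sweep(amplitude: tuple[float, float], n_frames: int) -> np.ndarray:
    """Neutral → positive extreme → negative extreme → neutral."""
    lo, hi = amplitude
    legs = [(0.0, hi), (hi, lo), (lo, 0.0)]
    travel = [abs(b - a) for a, b in legs]
    total = sum(travel) or 1.0
    counts = [max(1, int(round((n_frames - 1) * t / total))) for t in travel]
    while sum(counts) > n_frames - 1:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_frames - 1:
        counts[int(np.argmax(travel))] += 1
    theta = [0.0]
    for (a, b), c in zip(legs, counts):
        theta.extend(np.linspace(a, b, c + 1)[1:])
    return np.asarray(theta)


def simulate_motion(
    wrist: SyntheticWrist, motion: MotionParams
) -> tuple[DynamicSequence, "object"]:
    """Pose the wrist through a trajectory; return sequence + ground truth.

    The returned ground-truth series (DataFrame with the standard columns)
    is computed analytically from the prescribed poses and the construction
    landmarks — never from the mesh-based detectors.
    """
    import pandas as pd

    p = wrist.params
    mv = motion.movement
    theta = angle_sweep(motion.amplitude, motion.n_frames)
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.array([0.0, 1.0, 0.0])
    ex = np.array([1.0, 0.0, 0.0])

    g_l0 = p.gap_lunate
    g_t0 = p.gap_triquetrum

    poses: list[dict[str, RigidTransform]] = []
    rows = []
    cap_centroid = wrist.meshes["capitate"].centroid()
    for i, th in enumerate(theta):
        uv_d = float(motion.uv_drift(th))
        dp = float(motion.dp_translation(th))
        dl = float(motion.gap_lunate_delta(th))
        dt = float(motion.gap_triquetrum_delta(th))
        identity = RigidTransform.identity()
        if mv is MovementLabel.PS:
            rot = RigidTransform.from_axis_angle(ez, np.deg2rad(-th), center=wrist.head_center)
            e_pd_rot = rot.apply_vector(ey)
            radius_tf = RigidTransform(np.eye(3), -dp * e_pd_rot - uv_d * ez).compose(rot)
            lun_tf = rot.compose(RigidTransform(np.eye(3), dl * wrist.carpal_directions["lunate"]))
            tri_tf = rot.compose(
                RigidTransform(np.eye(3), dt * wrist.carpal_directions["triquetrum"])
            )
            cap_tf = rot
        else:
            axis = ex if mv is MovementLabel.FE else ey
            cap_tf = RigidTransform.from_axis_angle(axis, np.deg2rad(-th), center=cap_centroid)
            radius_tf = RigidTransform(np.eye(3), -dp * ey - uv_d * ez)
            lun_tf = RigidTransform(np.eye(3), dl * wrist.carpal_directions["lunate"])
            tri_tf = RigidTransform(np.eye(3), dt * wrist.carpal_directions["triquetrum"])
        poses.append(
            {
                "radius": radius_tf,
                "ulna": identity,
                "lunate": lun_tf,
                "triquetrum": tri_tf,
                "capitate": cap_tf,
            }
        )
        lm_f = wrist.landmarks.transformed_per_bone(radius_tf, identity)
        frame_f = wrist.frame.transformed(radius_tf)
        rows.append(
            {
                "frame": i,
                "time_s": i / motion.frame_rate,
                "movement": mv.value,
                "wrist_angle_deg": th,
                "uv3d_mm": wrist.static_parameters["uv3d_mm"] + uv_d,
                "ucp_l_mm": g_l0 + dl,
                "ucp_t_mm": g_t0 + dt,
                "mru3d_pct": mru_3d(lm_f, frame_f),
                "epi3d_pct": epicentre_3d(lm_f, frame_f),
            }
        )
    truth = pd.DataFrame(rows)
    for col, dcol in {"uv3d_mm": "d_uv3d_mm", "mru3d_pct": "d_mru3d_pct", "epi3d_pct": "d_epi3d_pct"}.items():
        truth[dcol] = truth[col] - truth.at[0, col]

    seq = DynamicSequence(
        movement=mv,
        static_meshes=dict(wrist.meshes),
        static_frame=wrist.frame,
        static_landmarks=wrist.landmarks,
        poses=poses,
        frame_rate=motion.frame_rate,
        side=p.side,
        wrist_id=f"synthetic-{p.seed}",
    )
    return seq, truth


def make_targets(seq: DynamicSequence) -> DynamicSequence:
    """Replace supplied poses with per-frame surface targets (for ICP tests)."""
    if seq.poses is None:
        raise ValueError("sequence has no poses to realize")
    targets = []
    for fr in seq.poses:
        frame_targets = {}
        for bone in BONES:
            posed = seq.static_meshes[bone].transformed(fr[bone])
            normals = np.asarray(posed.to_trimesh().vertex_normals, dtype=float)
            frame_targets[bone] = FrameTarget(posed.vertices, normals)
        targets.append(frame_targets)
    return DynamicSequence(
        movement=seq.movement,
        static_meshes=seq.static_meshes,
        static_frame=seq.static_frame,
        static_landmarks=seq.static_landmarks,
        poses=None,
        targets=targets,
        frame_rate=seq.frame_rate,
        side=seq.side,
        wrist_id=seq.wrist_id,
    )


def degrade(
    seq: DynamicSequence,
    vertex_jitter_sigma: float = 0.25,
    decimation_fraction: float = 0.0,
    seed: int = 0,
) -> DynamicSequence:
    """Seeded degradation of frame targets (ground truth untouched).

    Adds Gaussian jitter (mm) to target points and optionally drops a
    fraction of them, emulating dynamic-scan surface quality.
    """
    if vertex_jitter_sigma < 0:
        raise ValueError("jitter sigma must be non-negative")
    if not 0 <= decimation_fraction < 1:
        raise ValueError("decimation fraction must be in [0, 1)")
    src = seq if seq.targets is not None else make_targets(seq)
    rng = np.random.default_rng(seed)
    targets = []
    for fr in src.targets:
        frame_targets = {}
        for bone in BONES:
            tgt = fr[bone]
            pts = tgt.points
            normals = tgt.normals
            if decimation_fraction > 0:
                n_keep = int(round(pts.shape[0] * (1 - decimation_fraction)))
                if n_keep < 100:
                    raise ValueError(f"decimation leaves {n_keep} < 100 points for {bone}")
                keep = rng.choice(pts.shape[0], size=n_keep, replace=False)
                keep.sort()
                pts = pts[keep]
                normals = None if normals is None else normals[keep]
            if vertex_jitter_sigma > 0:
                pts = pts + rng.normal(0.0, vertex_jitter_sigma, pts.shape)
            frame_targets[bone] = FrameTarget(pts, normals)
        targets.append(frame_targets)
    return DynamicSequence(
        movement=src.movement,
        static_meshes=src.static_meshes,
        static_frame=src.static_frame,
        static_landmarks=src.static_landmarks,
        poses=None,
        targets=targets,
        frame_rate=src.frame_rate,
        side=src.side,
        wrist_id=src.wrist_id,
    )
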