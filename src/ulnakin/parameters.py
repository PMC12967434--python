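"""The four ulnar-sided wrist parameters, wrist angles and delta values.

Ulnocarpal impaction is quantified by

* **3-D ulnar variance** (``uv3d``, mm): proximo-distal height difference
  between the most distal point of the ulnar head articular surface and
  the most distal point of the radial sigmoid notch, measured along the
  radius' longitudinal axis.  Positive = ulna longer (ulna-plus).
* **ulnocarpal proximity** (``ucp``, mm): shortest 3-D surface distance
  from the ulna to the lunate (UcP-L) or triquetrum (UcP-T), with the
  closest-point site pair reported so location drift is observable.

DRUJ stability is quantified by

* **3-D modified radioulnar line** (``mru3d``, %): protrusion of the most
  palmar ulnar-head point past the palmar-radial line, as a percentage of
  sigmoid notch width.
* **3-D epicentre** (``epi3d``, %): offset of the ulnar epicentre's
  projection onto the notch chord from the notch midpoint, as a
  percentage of notch width.

Sign convention for both DRUJ metrics: dorsal dislocation of the radius
relative to the ulna is positive.  With landmarks in world coordinates
that means values are positive when the *ulna* sits palmar to its
radius-referenced landmark (head point palmar to the palmar-radial line;
epicentre projected toward the palmar margin).  A pure dorsal translation
of the ulna by ``t`` with the radius fixed therefore changes both metrics
by ``-100·t/W``.

All projections use the radius frame: the DRUJ metrics describe the
position of the radius relative to the ulna, and ulnar variance is
referenced to the sigmoid notch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .distance import min_distance
from .geometry import AnatomicalFrame, TriangleMesh, unit
from .landmarks import LandmarkSet


class MovementLabel(str, Enum):
    """Wrist movement; fixes the wrist-angle definition and sign convention.

    FE: sagittal capitoradial angle, flexion negative / extension positive.
    RUD: coronal capitoradial angle, ulnar deviation negative / radial positive.
    PS: axial ulnoradial angle, pronation negative / supination positive.
    """

    FE = "FE"
    RUD = "RUD"
    PS = "PS"


@dataclass(frozen=True)
class ParameterSample:
    """All parameters at one dynamic frame."""

    frame_index: int
    wrist_angle: float
    uv3d: float
    ucp_l: float
    ucp_t: float
    mru3d: float
    epi3d: float
    ucp_l_site: tuple[np.ndarray, np.ndarray] | None = None
    ucp_t_site: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.ucp_l < 0 or self.ucp_t < 0:
            raise ValueError("ulnocarpal proximity must be non-negative")
        for v in (self.mru3d, self.epi3d, self.uv3d, self.wrist_angle):
            if not np.isfinite(v):
                raise ValueError("non-finite parameter value")


# ---------------------------------------------------------------------------
# The four parameters
# ---------------------------------------------------------------------------


def ulnar_variance_3d(
    distal_ulnar_point: np.ndarray,
    sigmoid_distal_point: np.ndarray,
    radius_frame: AnatomicalFrame,
) -> float:
    """Height difference (mm) along the longitudinal axis, ulna-plus positive."""
    d = np.asarray(distal_ulnar_point, dtype=float) - np.asarray(
        sigmoid_distal_point, dtype=float
    )
    return float(d @ radius_frame.e_lon)


def ulnocarpal_proximity(
    ulna: TriangleMesh, carpal: TriangleMesh
) -> tuple[float, np.ndarray, np.ndarray]:
    """Shortest ulna-to-carpal surface distance and its site pair (mm)."""
    if carpal.bone_label not in ("lunate", "triquetrum"):
        raise ValueError("carpal must be the lunate or triquetrum")
    d, pa, pb = min_distance(ulna, carpal)
    if d == 0.0:
        warnings.warn(
            f"ulna and {carpal.bone_label} surfaces touch or interpenetrate",
            RuntimeWarning,
            stacklevel=2,
        )
    return d, pa, pb


def _axial(point: np.ndarray, frame: AnatomicalFrame) -> np.ndarray:
    """Project a point into the axial plane of the radius frame (drop e_lon)."""
    p = np.asarray(point, dtype=float)
    return p - (p @ frame.e_lon) * frame.e_lon


def mru_3d(landmarks: LandmarkSet, frame: AnatomicalFrame) -> float:
    """Modified radioulnar line metric (%), radius-dorsal positive.

    Axial-view construction: the head point and the palmar-radial line are
    projected into the axial plane of the radius frame, where protrusion is
    the perpendicular distance from the most palmar ulnar-head point to the
    line, positive when the head point lies palmar to it; expressed as a
    percentage of notch width.  (Working axially keeps a purely longitudinal
    offset between the head and the line from inflating the protrusion.)
    """
    W = landmarks.notch_width
    if W <= 0:
        raise ValueError("zero sigmoid notch width")
    a = _axial(landmarks.palmar_radial_corner, frame)
    b = _axial(landmarks.palmar_margin, frame)
    p = _axial(landmarks.ulnar_head_palmar_point, frame)
    d = unit(b - a)
    rel = p - a
    perp = rel - (rel @ d) * d
    dist = float(np.linalg.norm(perp))
    if dist > 0 and perp @ frame.e_pd > 0:
        dist = -dist  # head point dorsal to the line -> radius relatively palmar
    return 100.0 * dist / W


def epicentre_3d(landmarks: LandmarkSet, frame: AnatomicalFrame) -> float:
    """Epicentre metric (%), radius-dorsal positive.

    Axial-view construction: the epicentre is projected orthogonally onto
    the palmar-dorsal notch chord in the axial plane of the radius frame;
    the signed offset of that projection from the notch midpoint (positive
    toward the palmar margin) is expressed as a percentage of notch width.
    """
    W = landmarks.notch_width
    if W <= 0:
        raise ValueError("zero sigmoid notch width")
    toward_palmar = unit(
        _axial(landmarks.palmar_margin - landmarks.dorsal_margin, frame)
    )
    rel = _axial(landmarks.ulnar_epicentre - landmarks.notch_midpoint, frame)
    offset = float(rel @ toward_palmar)
    value = 100.0 * offset / W
    if abs(offset) > 1.5 * W:
        warnings.warn(
            f"epicentre projection {value:.0f}% of notch width from midpoint: "
            "gross dislocation or landmark failure",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# Wrist angles
# ---------------------------------------------------------------------------


def _signed_plane_angle(
    u: np.ndarray, v: np.ndarray, normal: np.ndarray, min_projection_deg: float = 5.0
) -> float:
    """Signed angle from u to v after projecting both into the plane ⟂ normal."""
    n = unit(normal)

    def proj(x: np.ndarray, name: str) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = x - (x @ n) * n
        if np.linalg.norm(p) < np.linalg.norm(x) * np.sin(np.radians(min_projection_deg)):
            warnings.warn(
                f"{name} axis nearly perpendicular to measurement plane",
                RuntimeWarning,
                stacklevel=4,
            )
        return p

    pu = proj(u, "reference")
    pv = proj(v, "moving")
    return float(np.degrees(np.arctan2(n @ np.cross(pu, pv), pu @ pv)))


def wrist_angle(
    movement: MovementLabel,
    frame: AnatomicalFrame,
    capitate_axis: np.ndarray | None = None,
    ulna_axis: np.ndarray | None = None,
) -> float:
    """Signed wrist angle (degrees) for the given movement.

    FE / RUD: capitoradial angle — the capitate long axis against the radius
    long axis, projected into the sagittal / coronal plane of the radius
    frame.  PS: ulnoradial angle — the ulnar axis (epicentre→styloid)
    against the radius mediolateral axis in the axial plane.

    Signs: extension, radial deviation and supination positive; flexion,
    ulnar deviation and pronation negative.
    """
    movement = MovementLabel(movement)
    if movement in (MovementLabel.FE, MovementLabel.RUD):
        if capitate_axis is None:
            raise ValueError(f"{movement.value} wrist angle needs the capitate axis")
        if movement is MovementLabel.FE:
            # sagittal plane: dorsal tilt of the capitate is extension (+)
            return _signed_plane_angle(frame.e_lon, capitate_axis, -frame.e_ru)
        # coronal plane: radial tilt (+)
        return _signed_plane_angle(frame.e_lon, capitate_axis, -frame.e_pd)
    if ulna_axis is None:
        raise ValueError("PS wrist angle needs the ulnar axis (epicentre to styloid)")
    return _signed_plane_angle(frame.e_ru, ulna_axis, frame.e_lon)


def ulnar_axial_axis(landmarks: LandmarkSet) -> np.ndarray:
    """Ulnar axis for the PS angle: epicentre toward styloid tip."""
    return landmarks.ulnar_styloid_tip - landmarks.ulnar_epicentre


# ---------------------------------------------------------------------------
# Time series helpers
# ---------------------------------------------------------------------------

SERIES_COLUMNS = [
    "frame",
    "time_s",
    "movement",
    "wrist_angle_deg",
    "uv3d_mm",
    "ucp_l_mm",
    "ucp_t_mm",
    "mru3d_pct",
    "epi3d_pct",
]
DELTA_COLUMNS = {"uv3d_mm": "d_uv3d_mm", "mru3d_pct": "d_mru3d_pct", "epi3d_pct": "d_epi3d_pct"}


def neutral_frame_index(series: pd.DataFrame) -> int:
    """Frame with minimum |wrist angle|; ties go to the earliest frame."""
    if len(series) == 0:
        raise ValueError("empty parameter series")
    return int(series["wrist_angle_deg"].abs().idxmin())


def delta_series(series: pd.DataFrame, neutral: int | None = None) -> pd.DataFrame:
    """Append delta columns: each parameter minus its neutral-frame value.

    The delta at the neutral frame is exactly 0 by construction.
    """
    if len(series) == 0:
        raise ValueError("empty parameter series")
    out = series.copy()
    k = neutral_frame_index(series) if neutral is None else neutral
    for col, dcol in DELTA_COLUMNS.items():
        out[dcol] = out[col] - out.at[k, col]
    return out


def classify_uv(uv3d: float) -> str:
    """Classify ulnar variance: |uv| < 1 mm is neutral; boundaries are outward."""
    if not np.isfinite(uv3d):
        raise ValueError("non-finite ulnar variance")
    if uv3d <= -1.0:
        return "negative"
    if uv3d >= 1.0:
        return "positive"
    return "neutral"
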