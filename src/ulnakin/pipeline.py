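"""End-to-end per-sequence driver and cohort summaries.

A dynamic acquisition is modelled as one static, high-quality set of bone
surfaces plus a sequence of frames.  Each frame either carries per-bone
rigid poses directly, or per-bone target point clouds to which the static
bones are registered (ICP, each frame initialized from the previous
frame's pose).  Landmarks are detected once on the static bones and
transported by each bone's per-frame transform — never re-detected per
frame — which mirrors the static-segmentation-plus-registration design
and removes per-frame detection noise.

Cohort reporting pools one value per wrist per angle bin (that wrist's
mean within the bin), takes median/IQR across wrists, and masks bins
visited by fewer than ``min_count`` wrists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AnatomicalFrame, RigidTransform, TriangleMesh
from .landmarks import LandmarkSet
from .parameters import (
    DELTA_COLUMNS,
    MovementLabel,
    delta_series,
    epicentre_3d,
    mru_3d,
    ulnar_axial_axis,
    ulnar_variance_3d,
    ulnocarpal_proximity,
    wrist_angle,
)
from .registration import rigid_register

BONES = ("radius", "ulna", "lunate", "triquetrum", "capitate")

# dynamic-scan voxel size; a registration residual above twice the voxel
# diagonal marks a frame as unreliable
VOXEL_MM = (0.59, 0.59, 0.50)
RESIDUAL_FLAG_MM = 2.0 * float(np.linalg.norm(VOXEL_MM))

PARAM_COLUMNS = ("uv3d_mm", "ucp_l_mm", "ucp_t_mm", "mru3d_pct", "epi3d_pct")


@dataclass(frozen=True)
class FrameTarget:
    """Surface samples of one bone in one dynamic frame (points + normals)."""

    points: np.ndarray
    normals: np.ndarray | None = None


@dataclass
class DynamicSequence:
    """One wrist, one movement: static bones plus per-frame poses or targets."""

    movement: MovementLabel
    static_meshes: dict[str, TriangleMesh]
    static_frame: AnatomicalFrame
    static_landmarks: LandmarkSet
    poses: list[dict[str, RigidTransform]] | None = None
    targets: list[dict[str, FrameTarget]] | None = None
    frame_rate: float = 10.0
    side: str = "right"
    wrist_id: str = "wrist"

    def __post_init__(self) -> None:
        self.movement = MovementLabel(self.movement)
        missing = set(BONES) - set(self.static_meshes)
        if missing:
            raise ValueError(f"static meshes missing bones: {sorted(missing)}")
        if self.poses is None and self.targets is None:
            raise ValueError("sequence needs per-frame poses or targets")
        frames = self.poses if self.poses is not None else self.targets
        for i, fr in enumerate(frames):
            if set(fr) < set(BONES):
                raise ValueError(f"frame {i} does not pose all five bones")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.poses if self.poses is not None else self.targets)


def track_sequence(
    seq: DynamicSequence,
    max_iterations: int = 100,
    tolerance: float = 1e-4,
) -> tuple[list[dict[str, RigidTransform]], list[bool]]:
    """Per-bone rigid transform chain across the sequence.

    Supplied poses pass through unchanged.  Otherwise each bone's static
    surface is ICP-registered to the frame's target points, initialized
    from the previous frame's pose.  Returns the transforms and a per-frame
    flag marking residuals above twice the voxel diagonal.
    """
    if seq.poses is not None:
        return [dict(fr) for fr in seq.poses], [False] * len(seq.poses)

    transforms: list[dict[str, RigidTransform]] = []
    flags: list[bool] = []
    previous = {b: RigidTransform.identity() for b in BONES}
    for fr in seq.targets:
        current: dict[str, RigidTransform] = {}
        bad = False
        for bone in BONES:
            tgt = fr[bone]
            res = rigid_register(
                seq.static_meshes[bone].vertices,
                tgt.points,
                init=previous[bone],
                target_normals=tgt.normals,
                max_iterations=max_iterations,
                tolerance=tolerance,
            )
            current[bone] = res.transform
            if res.rms > RESIDUAL_FLAG_MM:
                bad = True
        transforms.append(current)
        flags.append(bad)
        previous = current
    return transforms, flags


def capitate_long_axis(capitate: TriangleMesh, frame: AnatomicalFrame) -> np.ndarray:
    """Static capitate long axis, oriented distally."""
    from .geometry import principal_longitudinal_axis

    _, d = principal_longitudinal_axis(capitate, frame)
    return d


def evaluate_sequence(
    seq: DynamicSequence,
    transforms: list[dict[str, RigidTransform]] | None = None,
) -> pd.DataFrame:
    """Per-frame wrist angle, the four parameters and their deltas.

    Landmark or distance failures at a frame produce missing samples (NaN
    rows), not aborts.  Returns the parameter time series as a DataFrame
    with the standard CSV columns.
    """
    if transforms is None:
        transforms, _ = track_sequence(seq)
    lm0 = seq.static_landmarks
    frame0 = seq.static_frame
    cap_axis0 = capitate_long_axis(seq.static_meshes["capitate"], frame0)

    rows = []
    for i, tf in enumerate(transforms):
        row = {
            "frame": i,
            "time_s": i / seq.frame_rate,
            "movement": seq.movement.value,
        }
        try:
            lm = lm0.transformed_per_bone(tf["radius"], tf["ulna"])
            fr = frame0.transformed(tf["radius"])
            ulna_mesh = seq.static_meshes["ulna"].transformed(tf["ulna"])
            lun = seq.static_meshes["lunate"].transformed(tf["lunate"])
            tri = seq.static_meshes["triquetrum"].transformed(tf["triquetrum"])
            cap_axis = tf["capitate"].apply_vector(cap_axis0)

            row["wrist_angle_deg"] = wrist_angle(
                seq.movement, fr, capitate_axis=cap_axis, ulna_axis=ulnar_axial_axis(lm)
            )
            row["uv3d_mm"] = ulnar_variance_3d(lm.distal_ulnar_point, lm.sigmoid_distal_point, fr)
            d_l, *_ = ulnocarpal_proximity(ulna_mesh, lun)
            d_t, *_ = ulnocarpal_proximity(ulna_mesh, tri)
            row["ucp_l_mm"] = d_l
            row["ucp_t_mm"] = d_t
            row["mru3d_pct"] = mru_3d(lm, fr)
            row["epi3d_pct"] = epicentre_3d(lm, fr)
        except Exception as exc:  # propagate as a missing sample, keep going
            warnings.warn(f"frame {i}: {exc}", RuntimeWarning, stacklevel=2)
            for col in ("wrist_angle_deg",) + PARAM_COLUMNS:
                row.setdefault(col, np.nan)
        rows.append(row)
    series = pd.DataFrame(rows)
    valid = series["wrist_angle_deg"].notna()
    if valid.any():
        series = delta_series(series, neutral=int(series.loc[valid, "wrist_angle_deg"].abs().idxmin()))
    return series


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and IQR bounds; linear-interpolation quartile rule."""
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class CohortSummary:
    """Per-angle-bin median/IQR of one parameter across wrists.

    ``table`` columns: bin_center, median, q1, q3, n_wrists, masked.
    Masked bins (fewer than ``min_count`` contributing wrists) carry NaN
    summaries but keep their counts.
    """

    parameter: str
    movement: MovementLabel
    bin_width: float
    min_count: int
    table: pd.DataFrame

    def mask_edges(self) -> tuple[float, float] | None:
        """Angle interval covered by at least ``min_count`` wrists."""
        ok = self.table[~self.table["masked"]]
        if ok.empty:
            return None
        half = self.bin_width / 2
        return float(ok["bin_center"].min() - half), float(ok["bin_center"].max() + half)


def bin_by_angle(
    series_list: list[pd.DataFrame],
    parameter: str,
    movement: MovementLabel,
    bin_width: float = 5.0,
    min_count: int = 22,
) -> CohortSummary:
    """Pooled per-bin median/IQR across wrists.

    Each wrist contributes at most one value per bin: its mean parameter
    value over the frames falling in that bin.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not series_list:
        raise ValueError("at least one wrist series required")
    per_wrist = []
    for w, s in enumerate(series_list):
        s = s.dropna(subset=["wrist_angle_deg", parameter])
        if s.empty:
            continue
        b = np.floor(s["wrist_angle_deg"] / bin_width).astype(int)
        g = s.groupby(b)[parameter].mean()
        per_wrist.append(pd.DataFrame({"bin": g.index, "value": g.values, "wrist": w}))
    pooled = pd.concat(per_wrist, ignore_index=True)
    rows = []
    for b, grp in pooled.groupby("bin"):
        n = grp["wrist"].nunique()
        masked = n < min_count
        med, q1, q3 = (np.nan, np.nan, np.nan) if masked else _quartiles(grp["value"].values)
        rows.append(
            {
                "bin_center": (b + 0.5) * bin_width,
                "median": med,
                "q1": q1,
                "q3": q3,
                "n_wrists": n,
                "masked": masked,
            }
        )
    table = pd.DataFrame(rows).sort_values("bin_center", ignore_index=True)
    return CohortSummary(parameter, MovementLabel(movement), bin_width, min_count, table)


def motion_range(values: np.ndarray | pd.Series) -> float:
    """Range of a per-wrist trajectory: max minus min."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty series")
    return float(v.max() - v.min())


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> tuple[str, float]:
    """Shapiro–Wilk gate deciding the reporting style for a sample.

    Returns ``("report_median_iqr" | "report_mean_sd", p_value)``.
    Non-normal samples (p < alpha) are reported as median/IQR; degenerate
    or out-of-range samples default to median/IQR with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3 or v.size > 5000:
        warnings.warn(
            f"sample size {v.size} outside Shapiro-Wilk range; reporting median/IQR",
            RuntimeWarning,
            stacklevel=2,
        )
        return "report_median_iqr", np.nan
    if np.ptp(v) == 0:
        warnings.warn("constant sample; reporting median/IQR", RuntimeWarning, stacklevel=2)
        return "report_median_iqr", np.nan
    p = float(stats.shapiro(v).pvalue)
    return ("report_median_iqr" if p < alpha else "report_mean_sd"), p
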