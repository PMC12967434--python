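"""Rigid point-set registration (iterative closest point).

Static-scan bone surfaces are aligned to each dynamic frame by rigid ICP,
initialized from the previous frame's pose so each step only has to absorb
the inter-frame motion.  The metric is point-to-plane when target normals
are available (the usual case: targets are meshed surfaces), falling back
to point-to-point otherwise.  Correspondences with residuals above
``reject_factor`` times the median are dropped each iteration, which keeps
partially overlapping or locally noisy surfaces from skewing the fit.

The solver is deterministic: identical inputs and initialization give an
identical transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DegenerateGeometryError, RigidTransform


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms: float
    n_iterations: int
    converged: bool


def _check_not_collinear(points: np.ndarray, name: str) -> None:
    P = np.asarray(points, dtype=float)
    if P.shape[0] < 3:
        raise DegenerateGeometryError(f"{name} needs at least 3 points")
    C = np.cov(P.T)
    w = np.linalg.eigvalsh(C)
    if w[1] <= 1e-12 * max(w[2], 1e-30):
        raise DegenerateGeometryError(f"{name} points are (near-)collinear")


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping corresponding source->target."""
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    cs, ct = S.mean(axis=0), T.mean(axis=0)
    H = (S - cs).T @ (T - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ct - R @ cs)


def _point_to_plane_step(
    moved: np.ndarray, targets: np.ndarray, normals: np.ndarray
) -> RigidTransform:
    """One linearized point-to-plane update (small-angle Gauss-Newton)."""
    r = np.einsum("ij,ij->i", moved - targets, normals)
    A = np.hstack([np.cross(moved, normals), normals])
    x, *_ = np.linalg.lstsq(A, -r, rcond=None)
    omega, dt = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-15:
        return RigidTransform(np.eye(3), dt)
    return RigidTransform(
        RigidTransform.from_axis_angle(omega / angle, angle).rotation, dt
    )


def rigid_register(
    source: np.ndarray,
    target: np.ndarray,
    init: RigidTransform | None = None,
    target_normals: np.ndarray | None = None,
    max_iterations: int = 100,
    tolerance: float = 1e-4,
    reject_factor: float = 3.0,
    reject_warmup: int = 5,
) -> RegistrationResult:
    """ICP alignment of ``source`` points onto ``target`` points.

    Parameters
    ----------
    source, target
        (n, 3) point sets in mm; at least 3 non-collinear points each.
    init
        Plausible initial transform (e.g. the previous frame's pose);
        identity by default.
    target_normals
        Per-target-point unit normals; enables the point-to-plane metric.
    max_iterations, tolerance
        Iteration cap and convergence threshold on the RMS change (mm).
    reject_factor, reject_warmup
        Correspondences with residuals above ``reject_factor`` × median
        residual are excluded from each update, but only after
        ``reject_warmup`` unrejected iterations: trimming before the fit
        has settled can lock flat-faced surfaces into a slid local
        minimum whose trimmed residual looks deceptively small.

    Returns the final transform with its RMS residual.  Non-convergence
    within ``max_iterations`` emits a warning and returns the best estimate.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    _check_not_collinear(S, "source")
    _check_not_collinear(T, "target")
    current = RigidTransform.identity() if init is None else init
    tree = cKDTree(T)
    use_plane = target_normals is not None
    if use_plane:
        N = np.asarray(target_normals, dtype=float)
        if N.shape != T.shape:
            raise ValueError("target_normals must match target shape")

    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        moved = current.apply(S)
        dist, idx = tree.query(moved)
        if it > reject_warmup:
            med = np.median(dist)
            keep = dist <= max(reject_factor * med, 1e-12)
            if keep.sum() < 3:
                keep = np.ones_like(keep)
        else:
            keep = np.ones(dist.shape, dtype=bool)
        m, tgt = moved[keep], T[idx[keep]]
        if use_plane:
            step = _point_to_plane_step(m, tgt, N[idx[keep]])
        else:
            step = kabsch(m, tgt)
        current = step.compose(current)
        moved = current.apply(S)
        dist, _ = tree.query(moved)
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if abs(prev_rms - rms) < tolerance:
            converged = True
            break
        prev_rms = rms
    if not converged:
        warnings.warn(
            f"ICP did not converge in {max_iterations} iterations (rms {rms:.4f} mm)",
            RuntimeWarning,
            stacklevel=2,
        )
    return RegistrationResult(current, rms, it, converged)
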