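"""Model-to-X-ray registration and two-view reference reconstruction.

The preprocedural centerline model lives in its own (CT-derived) frame and
must be mapped into X-ray system coordinates before localization. With
fiducial markers reconstructed in both frames the map is fit by
least-squares point-set registration: a rigid or similarity transform via
the orthogonal-Procrustes (Umeyama) construction, or a full affine map when
at least four non-coplanar pairs are available. Three fiducials exactly
determine a similarity transform, which is the default mode.

Two-view epipolar triangulation — the midpoint of the common perpendicular
between the back-projection rays of the same marker in two sufficiently
separated views — provides the reference 3D reconstruction against which
single-view localization is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .evaluation import ErrorSummary, ed3d, summarize
from .geometry import Ray


class RegistrationError(ValueError):
    pass


class DegenerateGeometryError(RegistrationError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ scale · R x + t, with R a proper rotation (no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise RegistrationError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise RegistrationError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise RegistrationError("reflections are not allowed (det must be +1)")
        if not (self.scale > 0):
            raise RegistrationError(f"scale must be > 0, got {self.scale}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass(frozen=True)
class AffineTransform:
    """x ↦ A x + t with unconstrained 3×3 A."""

    matrix: np.ndarray
    translation: np.ndarray

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ np.asarray(self.matrix).T + np.asarray(self.translation)
        return out[0] if np.asarray(points).ndim == 1 else out

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.matrix
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class FiducialPair:
    model_point_mm: np.ndarray
    xr_point_mm: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.model_point_mm, dtype=float)
        x = np.asarray(self.xr_point_mm, dtype=float)
        if m.shape != (3,) or x.shape != (3,) or not (
            np.all(np.isfinite(m)) and np.all(np.isfinite(x))
        ):
            raise RegistrationError("fiducial points must be finite 3-vectors")
        object.__setattr__(self, "model_point_mm", m)
        object.__setattr__(self, "xr_point_mm", x)


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) == 0:
        raise RegistrationError("no fiducial pairs given")
    X = np.array([p.model_point_mm for p in pairs])
    Y = np.array([p.xr_point_mm for p in pairs])
    return X, Y


def fit_point_transform(pairs, mode: str = "similarity"):
    """Least-squares point-set registration of fiducial pairs.

    Parameters
    ----------
    pairs : sequence of FiducialPair
    mode : {"rigid", "similarity", "affine"}
        Rigid and similarity use the Umeyama closed form (≥3 non-collinear
        pairs; similarity adds an isotropic scale); affine solves the full
        linear least-squares problem (≥4 non-coplanar pairs).

    Returns
    -------
    (transform, residuals_mm) where residuals are per-pair Euclidean
    distances after mapping the model points into X-ray space.
    """
    X, Y = _pair_arrays(pairs)
    n = len(X)
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    if mode in ("rigid", "similarity"):
        if n < 3:
            raise RegistrationError(f"{mode} registration needs >= 3 pairs, got {n}")
        if np.linalg.matrix_rank(Xc, tol=1e-9) < 2:
            raise RegistrationError("fiducials are collinear: rotation is underdetermined")
        cov = Yc.T @ Xc / n
        U, D, Vt = np.linalg.svd(cov)
        S = np.eye(3)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            S[2, 2] = -1.0
        R = U @ S @ Vt
        if mode == "similarity":
            var_x = (Xc**2).sum() / n
            scale = float(np.trace(np.diag(D) @ S) / var_x)
        else:
            scale = 1.0
        t = Y.mean(0) - scale * R @ X.mean(0)
        tf = RigidTransform(rotation=R, translation=t, scale=scale)
    elif mode == "affine":
        if n < 4:
            raise RegistrationError(f"affine registration needs >= 4 pairs, got {n}")
        if np.linalg.matrix_rank(Xc, tol=1e-9) < 3:
            raise RegistrationError("fiducials are coplanar: affine map is underdetermined")
        H = np.hstack([X, np.ones((n, 1))])
        sol, *_ = np.linalg.lstsq(H, Y, rcond=None)
        tf = AffineTransform(matrix=sol[:3].T, translation=sol[3])
    else:
        raise RegistrationError(f"unknown mode {mode!r}")
    residuals = np.linalg.norm(tf.apply(X) - Y, axis=1)
    return tf, residuals


def triangulate_two_views(ray_a: Ray, ray_b: Ray) -> tuple[np.ndarray, float]:
    """Closest-approach triangulation of two back-projection rays.

    Returns the midpoint of the common perpendicular segment and its
    length (``gap_mm``, zero for exactly intersecting rays). Rays closer
    than about 0.00006° to parallel are rejected as degenerate.
    """
    da, db = ray_a.direction, ray_b.direction
    cross = np.cross(da, db)
    sin_angle = float(np.linalg.norm(cross))
    if sin_angle <= 1e-6:
        angle_deg = float(np.degrees(np.arcsin(min(sin_angle, 1.0))))
        raise DegenerateGeometryError(
            f"rays are near-parallel (inter-ray angle {angle_deg:.2e} deg)"
        )
    w = ray_b.origin_mm - ray_a.origin_mm
    # solve [da, -db] [ta, tb]^T = w in the least-squares sense
    A = np.column_stack([da, -db])
    ta, tb = np.linalg.lstsq(A, w, rcond=None)[0]
    pa = ray_a.point_at(float(ta))
    pb = ray_b.point_at(float(tb))
    return (pa + pb) / 2.0, float(np.linalg.norm(pa - pb))


def registration_error(pairs, transform) -> ErrorSummary:
    """Fiducial registration error: 3D distances between mapped model
    fiducials and their reconstructed X-ray positions, summarized as
    mean/std/median/max."""
    X, Y = _pair_arrays(pairs)
    return summarize(ed3d(transform.apply(X), Y))


# ---------------------------------------------------------------------------
# file I/O

def read_fiducials_csv(path) -> list[FiducialPair]:
    """CSV with columns set (model|xr), label, x, y, z; paired by label."""
    import csv as _csv

    model, xr = {}, {}
    with open(path, newline="") as fh:
        rd = _csv.DictReader(fh)
        for ln, row in enumerate(rd, start=2):
            which = row.get("set", "").strip()
            if which not in ("model", "xr"):
                raise RegistrationError(
                    f"{path}: row {ln}: 'set' must be model or xr, got {which!r}"
                )
            p = np.array([float(row[k]) for k in ("x", "y", "z")])
            (model if which == "model" else xr)[row["label"]] = p
    labels = sorted(model)
    if sorted(xr) != labels:
        raise RegistrationError(
            f"{path}: model/xr label mismatch: {sorted(model)} vs {sorted(xr)}"
        )
    return [FiducialPair(model[l], xr[l], label=l) for l in labels]


def save_transform(transform, path) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix_4x4_row_major": transform.as_matrix().tolist()}, fh, indent=2)
        fh.write("\n")


def load_transform(path) -> AffineTransform:
    with open(path) as fh:
        m = np.array(json.load(fh)["matrix_4x4_row_major"])
    return AffineTransform(matrix=m[:3, :3], translation=m[:3, 3])
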