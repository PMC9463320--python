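"""Accuracy metrics: 3D Euclidean distance, iso-center-plane 2D distance,
and mean/std/median/max summaries.

With phantom ground truth available, accuracy is the 3D Euclidean distance
(3D-ED) between localized and reference positions. Without 3D ground truth
(patient-like data), accuracy is assessed in 2D: both the localized 3D
point and the originally picked pixel are projected onto the plane through
the iso-center parallel to the image plane, and their in-plane distance
(2D-ED, in mm at iso-center scale) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ProjectionGeometry, WorkingPoint2D, to_isocenter_plane


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorSummary:
    mean_mm: float
    std_mm: float
    median_mm: float
    max_mm: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise EvaluationError("summary needs at least one sample")
        for name in ("mean_mm", "std_mm", "median_mm", "max_mm"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be >= 0")
        if self.max_mm + 1e-12 < max(self.median_mm, self.mean_mm):
            raise EvaluationError("max must dominate mean and median")

    def as_dict(self) -> dict:
        return {
            "mean_mm": self.mean_mm,
            "std_mm": self.std_mm,
            "median_mm": self.median_mm,
            "max_mm": self.max_mm,
            "n": self.n,
        }

    def __str__(self) -> str:
        return (
            f"m = {self.mean_mm:.2f} mm, std = {self.std_mm:.2f} mm, "
            f"mdn = {self.median_mm:.2f} mm, max = {self.max_mm:.2f} mm (n = {self.n})"
        )


def ed3d(points_a, points_b) -> np.ndarray:
    """Pairwise 3D Euclidean distances between two equal-length point lists."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape or a.shape[1] != 3:
        raise EvaluationError(f"point lists must match in shape, got {a.shape} vs {b.shape}")
    return np.linalg.norm(a - b, axis=1)


def ed2d_isocenter(
    geom: ProjectionGeometry, localized_3d, picked_2d
) -> np.ndarray:
    """2D distances on the iso-center plane between localized 3D points and
    picked pixels, both mapped through the same projection geometry."""
    pts = np.atleast_2d(np.asarray(localized_3d, dtype=float))
    picked = list(picked_2d)
    if len(pts) != len(picked):
        raise EvaluationError(
            f"length mismatch: {len(pts)} localized vs {len(picked)} picked"
        )
    out = np.empty(len(pts))
    for i, (p3, p2) in enumerate(zip(pts, picked)):
        if not isinstance(p2, WorkingPoint2D):
            p2 = WorkingPoint2D(row_px=float(p2[0]), col_px=float(p2[1]))
        a = to_isocenter_plane(geom, p3)
        b = to_isocenter_plane(geom, p2)
        out[i] = np.linalg.norm(a - b)
    return out


def summarize(distances) -> ErrorSummary:
    """Mean, sample standard deviation (n−1; zero for a single sample),
    median (midpoint convention for even n), and maximum."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise EvaluationError("cannot summarize an empty sample")
    if not np.all(np.isfinite(d)):
        raise EvaluationError("non-finite distance in sample")
    return ErrorSummary(
        mean_mm=float(d.mean()),
        std_mm=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        median_mm=float(np.median(d)),
        max_mm=float(d.max()),
        n=int(d.size),
    )
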