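"""C-arm projection geometry.

The X-ray chain is modeled as a pinhole camera rotating about a fixed
iso-center. The frame is right-handed with origin at the iso-center:
+x patient-left, +y patient-posterior (source to detector at identity
angulation), +z patient-cranial. The primary angulation (LAO positive,
RAO negative) rotates the chain about +z; the secondary angulation
(cranial positive, caudal negative) rotates about the already-rotated
x-axis. Angles are degrees at the interface, lengths millimetres.

At zero angulation the source sits at ``(0, -SOD, 0)`` and the detector
center at ``(0, SID - SOD, 0)``; SOD is the source-to-isocenter distance
and SID the source-to-detector distance, so SID/SOD is the geometric
magnification at the iso-center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Invalid pose parameters or degenerate projection."""


class DegenerateProjectionError(GeometryError):
    """Point at or behind the source plane cannot be projected."""


def _vec3(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} must be a finite 3-vector, got {x!r}")
    return a


@dataclass(frozen=True)
class CArmPose:
    """Acquisition geometry as reported by the X-ray system.

    Parameters
    ----------
    primary_angle_deg : float
        LAO positive, RAO negative.
    secondary_angle_deg : float
        Cranial positive, caudal negative.
    sod_mm, sid_mm : float
        Source-to-isocenter and source-to-detector distances.
    pixel_spacing_mm : (float, float)
        Detector pixel pitch, (row, col).
    detector_size_px : (int, int)
        Detector size in pixels, (rows, cols).
    """

    primary_angle_deg: float
    secondary_angle_deg: float
    sod_mm: float
    sid_mm: float
    pixel_spacing_mm: tuple[float, float] = (0.37, 0.37)
    detector_size_px: tuple[int, int] = (512, 512)

    def __post_init__(self):
        if not np.isfinite(self.primary_angle_deg):
            raise GeometryError("primary_angle_deg must be finite")
        if not np.isfinite(self.secondary_angle_deg):
            raise GeometryError("secondary_angle_deg must be finite")
        if not (self.sod_mm > 0):
            raise GeometryError(f"sod_mm must be > 0, got {self.sod_mm}")
        if not (self.sid_mm > self.sod_mm):
            raise GeometryError(
                f"sid_mm must exceed sod_mm, got sid_mm={self.sid_mm} "
                f"sod_mm={self.sod_mm}"
            )
        if len(self.pixel_spacing_mm) != 2 or any(
            not (s > 0) for s in self.pixel_spacing_mm
        ):
            raise GeometryError(
                f"pixel_spacing_mm must be two positive values, "
                f"got {self.pixel_spacing_mm}"
            )
        if len(self.detector_size_px) != 2 or any(
            int(n) < 2 for n in self.detector_size_px
        ):
            raise GeometryError(
                f"detector_size_px must be at least (2, 2), "
                f"got {self.detector_size_px}"
            )


@dataclass(frozen=True)
class WorkingPoint2D:
    """A picked device position in pixel coordinates (0-based, pixel centers)."""

    row_px: float
    col_px: float

    def __post_init__(self):
        if not (np.isfinite(self.row_px) and np.isfinite(self.col_px)):
            raise GeometryError("pixel coordinates must be finite")


@dataclass(frozen=True)
class DetectorPoint3D:
    """The 3D embedding of a picked pixel on the physical detector plane."""

    point_mm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point_mm", _vec3(self.point_mm, "point_mm"))


@dataclass(frozen=True)
class Ray:
    """A half-line from ``origin_mm`` along the unit ``direction``."""

    origin_mm: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin_mm", _vec3(self.origin_mm, "origin_mm"))
        d = _vec3(self.direction, "direction")
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("ray direction must be nonzero")
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin_mm + t * self.direction

    def distance_to(self, p) -> float:
        """Perpendicular distance from a 3D point to the (infinite) line."""
        w = np.asarray(p, dtype=float) - self.origin_mm
        return float(np.linalg.norm(np.cross(w, self.direction)))


@dataclass(frozen=True)
class ProjectionGeometry:
    """Derived source position and detector frame for one pose."""

    source_mm: np.ndarray
    detector_origin_mm: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    normal: np.ndarray
    pose: CArmPose
    isocenter_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def sod_mm(self) -> float:
        return float(np.linalg.norm(self.source_mm - self.isocenter_mm))

    @property
    def sid_mm(self) -> float:
        return float(np.dot(self.detector_origin_mm - self.source_mm, self.normal))

    @property
    def center_px(self) -> tuple[float, float]:
        rows, cols = self.pose.detector_size_px
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)


def pose_to_geometry(pose: CArmPose, table_offset_mm=None) -> ProjectionGeometry:
    """Derive the source position and detector frame from an angulated pose.

    ``table_offset_mm`` translates the iso-center (and the whole imaging
    chain with it); residual table offsets are normally absorbed by
    registration, so the default is zero.
    """
    iso = np.zeros(3) if table_offset_mm is None else _vec3(table_offset_mm, "table_offset_mm")
    rot = Rotation.from_euler(
        "ZX", [pose.primary_angle_deg, pose.secondary_angle_deg], degrees=True
    )
    # identity-pose frame: viewing axis +y, image columns +x, image rows -z
    normal = rot.apply([0.0, 1.0, 0.0])
    u_axis = rot.apply([1.0, 0.0, 0.0])
    v_axis = rot.apply([0.0, 0.0, -1.0])
    source = iso - pose.sod_mm * normal
    detector_origin = source + pose.sid_mm * normal
    return ProjectionGeometry(
        source_mm=source,
        detector_origin_mm=detector_origin,
        u_axis=u_axis,
        v_axis=v_axis,
        normal=normal,
        pose=pose,
        isocenter_mm=iso,
    )


def project_point(geom: ProjectionGeometry, p3d) -> WorkingPoint2D:
    """Perspective projection of a 3D point onto the detector, in pixels.

    The point must lie strictly between the source and the detector along
    the viewing axis (positive depth smaller than SID).
    """
    p = _vec3(p3d, "p3d")
    depth = float(np.dot(p - geom.source_mm, geom.normal))
    if depth <= 1e-9:
        raise DegenerateProjectionError(
            f"point at depth {depth:.3g} mm is at or behind the source plane"
        )
    q = geom.source_mm + (geom.sid_mm / depth) * (p - geom.source_mm)
    d = q - geom.detector_origin_mm
    sr, sc = geom.pose.pixel_spacing_mm
    cr, cc = geom.center_px
    return WorkingPoint2D(
        row_px=cr + float(np.dot(d, geom.v_axis)) / sr,
        col_px=cc + float(np.dot(d, geom.u_axis)) / sc,
    )


def pixel_to_detector_point(geom: ProjectionGeometry, p2d: WorkingPoint2D) -> DetectorPoint3D:
    """Embed a pixel in 3D on the physical detector plane."""
    sr, sc = geom.pose.pixel_spacing_mm
    cr, cc = geom.center_px
    p = (
        geom.detector_origin_mm
        + (p2d.col_px - cc) * sc * geom.u_axis
        + (p2d.row_px - cr) * sr * geom.v_axis
    )
    return DetectorPoint3D(point_mm=p)


def pixel_to_ray(geom: ProjectionGeometry, p2d: WorkingPoint2D) -> Ray:
    """Back-projection ray from the source through the pixel's detector point."""
    dp = pixel_to_detector_point(geom, p2d)
    return Ray(origin_mm=geom.source_mm, direction=dp.point_mm - geom.source_mm)


def to_isocenter_plane(geom: ProjectionGeometry, p) -> np.ndarray:
    """Map a 3D point or a pixel onto the iso-center plane parallel to the image.

    Returns in-plane (u, v) millimetre coordinates. A 3D point is centrally
    projected through the source onto the plane; a pixel's detector point is
    scaled toward the source by SOD/SID, which lands on the same plane.
    """
    if isinstance(p, WorkingPoint2D):
        q3 = pixel_to_detector_point(geom, p).point_mm
        q = geom.source_mm + (geom.sod_mm / geom.sid_mm) * (q3 - geom.source_mm)
    else:
        p = _vec3(p, "p")
        depth = float(np.dot(p - geom.source_mm, geom.normal))
        if depth <= 1e-9:
            raise DegenerateProjectionError(
                f"point at depth {depth:.3g} mm cannot be mapped to the iso-center plane"
            )
        q = geom.source_mm + (geom.sod_mm / depth) * (p - geom.source_mm)
    d = q - geom.isocenter_mm
    return np.array([np.dot(d, geom.u_axis), np.dot(d, geom.v_axis)])


# ---------------------------------------------------------------------------
# configuration I/O

_POSE_KEYS = (
    "primary_angle_deg",
    "secondary_angle_deg",
    "sod_mm",
    "sid_mm",
    "pixel_spacing_mm",
    "detector_size_px",
)


def pose_to_dict(pose: CArmPose) -> dict:
    return {
        "primary_angle_deg": pose.primary_angle_deg,
        "secondary_angle_deg": pose.secondary_angle_deg,
        "sod_mm": pose.sod_mm,
        "sid_mm": pose.sid_mm,
        "pixel_spacing_mm": list(pose.pixel_spacing_mm),
        "detector_size_px": list(pose.detector_size_px),
    }


def pose_from_dict(cfg: dict) -> CArmPose:
    missing = [k for k in _POSE_KEYS[:4] if k not in cfg]
    if missing:
        raise GeometryError(f"geometry config missing keys: {missing}")
    kwargs = {k: cfg[k] for k in _POSE_KEYS if k in cfg}
    for k in ("pixel_spacing_mm", "detector_size_px"):
        if k in kwargs:
            kwargs[k] = tuple(kwargs[k])
    return CArmPose(**kwargs)


def load_pose(path) -> CArmPose:
    """Read a geometry JSON config."""
    with open(path) as fh:
        return pose_from_dict(json.load(fh))


def save_pose(pose: CArmPose, path) -> None:
    with open(path, "w") as fh:
        json.dump(pose_to_dict(pose), fh, indent=2)
        fh.write("\n")


def pose_from_dicom(dataset) -> CArmPose:
    """Map DICOM XA positioner tags onto a pose.

    Accepts a ``pydicom`` dataset or a path. Uses PositionerPrimaryAngle,
    PositionerSecondaryAngle, DistanceSourceToPatient (SOD),
    DistanceSourceToDetector (SID), ImagerPixelSpacing, Rows, Columns.
    """
    import pydicom

    ds = dataset if hasattr(dataset, "get") and not isinstance(dataset, (str, bytes)) else pydicom.dcmread(str(dataset))
    try:
        spacing = tuple(float(s) for s in ds.ImagerPixelSpacing)
    except AttributeError:
        spacing = (0.37, 0.37)
    try:
        size = (int(ds.Rows), int(ds.Columns))
    except AttributeError:
        size = (512, 512)
    try:
        return CArmPose(
            primary_angle_deg=float(ds.PositionerPrimaryAngle),
            secondary_angle_deg=float(ds.PositionerSecondaryAngle),
            sod_mm=float(ds.DistanceSourceToPatient),
            sid_mm=float(ds.DistanceSourceToDetector),
            pixel_spacing_mm=spacing,
            detector_size_px=size,
        )
    except AttributeError as exc:
        raise GeometryError(f"DICOM dataset lacks positioner geometry: {exc}") from exc
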