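"""Synthetic vascular phantom: a digital stand-in for a printed aortic model.

The generator builds a parametric aortic-arch centerline (a circular arc in
a tilted plane) with a carotid-like branch, places radio-opaque markers at
predefined arc positions — optionally displaced radially by up to the
vessel radius, emulating a guidewire that does not run down the vessel
center — and projects them through the C-arm model with optional pixel
quantization and picking noise. It can also render marker trajectories as
Gaussian-blob image sequences for tracking experiments, and produce paired
two-view datasets for epipolar reference reconstruction.

The default carotid radius of 3.2 mm matches the expected maximal
intrinsic localization inaccuracy for the common carotid artery, so the
radial-offset error bound is exercised at clinically meaningful scale.
All randomness (marker azimuths, picking noise, image noise) is seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .centerline import CenterlineBranch, CenterlineTree
from .geometry import (
    CArmPose,
    ProjectionGeometry,
    WorkingPoint2D,
    pose_to_geometry,
    project_point,
)


class PhantomError(ValueError):
    pass


def default_pose(
    primary_angle_deg: float = 0.0, secondary_angle_deg: float = 0.0
) -> CArmPose:
    """TAVR-plausible acquisition geometry: SOD 750, SID 1000, 512^2 @ 0.37 mm."""
    return CArmPose(
        primary_angle_deg=primary_angle_deg,
        secondary_angle_deg=secondary_angle_deg,
        sod_mm=750.0,
        sid_mm=1000.0,
        pixel_spacing_mm=(0.37, 0.37),
        detector_size_px=(512, 512),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic arch + carotid-branch phantom."""

    arch_radius_mm: float = 35.0
    arch_span_deg: float = 180.0
    arch_tilt_deg: float = 20.0
    branch_length_mm: float = 80.0
    branch_angle_deg: float = 25.0
    branch_attach_frac: float = 0.6
    vessel_radius_mm: dict = field(
        default_factory=lambda: {"arch": 12.0, "carotid": 3.2}
    )
    marker_arc_positions_mm: tuple = (10.0, 17.5, 25.0, 32.5, 40.0)
    marker_radial_offset_mm: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    native_spacing_mm: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.arch_radius_mm <= 0 or self.branch_length_mm <= 0:
            raise PhantomError("arch radius and branch length must be positive")
        if not (0 < self.arch_span_deg <= 360):
            raise PhantomError(f"arch_span_deg out of range: {self.arch_span_deg}")
        if not (0 <= self.branch_attach_frac <= 1):
            raise PhantomError("branch_attach_frac must be in [0, 1]")
        if any(r <= 0 for r in self.vessel_radius_mm.values()):
            raise PhantomError("vessel radii must be positive")
        if len(self.marker_radial_offset_mm) != len(self.marker_arc_positions_mm):
            raise PhantomError("one radial offset per marker arc position required")
        for s in self.marker_arc_positions_mm:
            if not (0 <= s <= self.branch_length_mm):
                raise PhantomError(
                    f"marker arc position {s} outside branch length "
                    f"{self.branch_length_mm}"
                )
        rmax = self.vessel_radius_mm["carotid"]
        for r in self.marker_radial_offset_mm:
            if abs(r) > rmax:
                raise PhantomError(
                    f"radial offset {r} exceeds carotid vessel radius {rmax}"
                )
        if self.native_spacing_mm <= 0:
            raise PhantomError("native_spacing_mm must be positive")


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, d)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def make_phantom(spec: PhantomSpec):
    """Build the phantom centerline tree and its markers.

    Returns ``(tree, marker_points_mm, marker_truth)`` where
    ``marker_truth`` is a list of ``(branch_id, arc_position_mm)`` naming
    the on-centerline location each marker belongs to. Deterministic for a
    fixed spec (marker azimuths drawn from ``spec.seed``).
    """
    tilt = np.radians(spec.arch_tilt_deg)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, -np.sin(tilt), np.cos(tilt)])  # tilted "up" in arch plane
    # plane normal oriented detector-ward: with the default tilt the branch
    # then runs nearly perpendicular to the central ray at identity
    # angulation — the constellation clinicians choose, since centerlines
    # oblique to the beam amplify the intrinsic (vessel-radius) error
    n_plane = np.cross(e2, e1)

    # arch: circular arc about the iso-center, apex at +e2
    half = np.radians(spec.arch_span_deg) / 2.0
    arc_len = spec.arch_radius_mm * 2 * half
    n_arch = max(int(np.ceil(arc_len / spec.native_spacing_mm)) + 1, 2)
    phi = np.linspace(-half, half, n_arch)
    arch_pts = spec.arch_radius_mm * (
        np.outer(np.sin(phi), e1) + np.outer(np.cos(phi), e2)
    )
    arch = CenterlineBranch(
        "arch",
        arch_pts,
        radius_mm=np.full(n_arch, spec.vessel_radius_mm["arch"]),
    )

    # branch: straight segment leaving the arch at the attachment point,
    # rotated out of the arch plane by branch_angle from the radial direction
    attach_idx = int(round(spec.branch_attach_frac * (n_arch - 1)))
    p_attach = arch_pts[attach_idx]
    radial = p_attach / np.linalg.norm(p_attach)
    beta = np.radians(spec.branch_angle_deg)
    d = np.cos(beta) * radial + np.sin(beta) * n_plane
    d /= np.linalg.norm(d)
    n_br = max(int(np.ceil(spec.branch_length_mm / spec.native_spacing_mm)) + 1, 2)
    t = np.linspace(0.0, spec.branch_length_mm, n_br)
    branch_pts = p_attach + np.outer(t, d)
    carotid = CenterlineBranch(
        "carotid",
        branch_pts,
        radius_mm=np.full(n_br, spec.vessel_radius_mm["carotid"]),
        parent=("arch", attach_idx),
    )
    tree = CenterlineTree([arch, carotid])

    rng = np.random.default_rng(spec.seed)
    eperp1, eperp2 = _perp_basis(d)
    markers, truth = [], []
    for s, r in zip(spec.marker_arc_positions_mm, spec.marker_radial_offset_mm):
        azimuth = rng.uniform(0.0, 2 * np.pi)
        base = carotid.point_at_arclen(s)
        markers.append(base + r * (np.cos(azimuth) * eperp1 + np.sin(azimuth) * eperp2))
        truth.append(("carotid", float(s)))
    return tree, np.array(markers), truth


def truth_points(tree: CenterlineTree, marker_truth) -> np.ndarray:
    """On-centerline 3D points for a list of (branch_id, arc_position_mm)."""
    return np.array([tree[b].point_at_arclen(s) for b, s in marker_truth])


def project_markers(
    geom: ProjectionGeometry,
    markers,
    quantize: bool = False,
    noise_px: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> list[WorkingPoint2D]:
    """Forward-project markers to working points, with optional seeded
    Gaussian pixel noise (manual-picking error) and integer quantization."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    for m in np.atleast_2d(np.asarray(markers, dtype=float)):
        p = project_point(geom, m)
        r, c = p.row_px, p.col_px
        if noise_px > 0:
            r += rng.normal(0.0, noise_px)
            c += rng.normal(0.0, noise_px)
        if quantize:
            r, c = float(np.rint(r)), float(np.rint(c))
        out.append(WorkingPoint2D(row_px=r, col_px=c))
    return out


def render_frames(
    geom: ProjectionGeometry,
    marker_trajectory_mm,
    image_size: tuple[int, int] | None = None,
    blob_sigma_px: float = 2.0,
    noise_std: float = 0.0,
    seed: int | None = None,
):
    """Render a marker trajectory as a Gaussian-blob image sequence.

    Returns ``(stack, truth_px, out_of_view)``: a float image stack, the
    ground-truth (row, col) pixel track, and a per-frame flag set when the
    blob falls entirely outside the detector (the frame is then background
    noise only).
    """
    traj = np.atleast_2d(np.asarray(marker_trajectory_mm, dtype=float))
    size = tuple(image_size) if image_size else tuple(geom.pose.detector_size_px)
    rng = np.random.default_rng(seed)
    stack = np.zeros((len(traj), *size))
    truth_px = np.zeros((len(traj), 2))
    out_of_view = np.zeros(len(traj), dtype=bool)
    margin = 4 * blob_sigma_px
    half = int(np.ceil(6 * blob_sigma_px))  # blob support; beyond is ~0
    for k, p in enumerate(traj):
        wp = project_point(geom, p)
        truth_px[k] = (wp.row_px, wp.col_px)
        if (
            wp.row_px < -margin
            or wp.col_px < -margin
            or wp.row_px > size[0] - 1 + margin
            or wp.col_px > size[1] - 1 + margin
        ):
            out_of_view[k] = True
        else:
            r0 = max(int(np.floor(wp.row_px)) - half, 0)
            r1 = min(int(np.ceil(wp.row_px)) + half + 1, size[0])
            c0 = max(int(np.floor(wp.col_px)) - half, 0)
            c1 = min(int(np.ceil(wp.col_px)) + half + 1, size[1])
            rr = np.arange(r0, r1)[:, None]
            cc = np.arange(c0, c1)[None, :]
            stack[k, r0:r1, c0:c1] = np.exp(
                -((rr - wp.row_px) ** 2 + (cc - wp.col_px) ** 2)
                / (2 * blob_sigma_px**2)
            )
        if noise_std > 0:
            stack[k] += rng.normal(0.0, noise_std, size)
    return stack, truth_px, out_of_view


def view_separation_deg(pose_a: CArmPose, pose_b: CArmPose) -> float:
    """Angle between the two viewing (source-to-detector) axes."""
    na = pose_to_geometry(pose_a).normal
    nb = pose_to_geometry(pose_b).normal
    return float(np.degrees(np.arccos(np.clip(np.dot(na, nb), -1.0, 1.0))))


def make_two_view_dataset(
    markers,
    pose_a: CArmPose,
    pose_b: CArmPose,
    quantize: bool = False,
    noise_px: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Consistent two-view projections of the same markers for epipolar
    reference reconstruction.

    Pose pairs separated by less than 5° are refused (triangulation would
    be ill-conditioned); below 30° a warning is emitted, since clinical
    two-view registration uses at least 30° of angular distance.
    """
    sep = view_separation_deg(pose_a, pose_b)
    if sep < 5.0:
        raise PhantomError(
            f"view separation {sep:.2f} deg < 5 deg: triangulation ill-conditioned"
        )
    if sep < 30.0:
        warnings.warn(
            f"view separation {sep:.1f} deg is below the recommended 30 deg",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    geom_a = pose_to_geometry(pose_a)
    geom_b = pose_to_geometry(pose_b)
    return {
        "geom_a": geom_a,
        "geom_b": geom_b,
        "points_a": project_markers(geom_a, markers, quantize, noise_px, rng),
        "points_b": project_markers(geom_b, markers, quantize, noise_px, rng),
        "separation_deg": sep,
    }


def make_superimposed_scene():
    """Deterministic two-branch scene whose branches superimpose in projection.

    A short trunk splits into the true branch and a decoy branch placed
    deeper along the viewing axis; the decoy is the true branch's
    perspective-scaled copy, so at identity angulation both project onto
    exactly the same image curve. The decoy is sampled five times more
    finely, so once integer pixel quantization perturbs the picked points,
    an unconstrained search tends to jump to the decoy while the geodesic
    continuity window (through the far junction) excludes it.

    Returns ``(tree, geom, pixels, markers_mm, truth_branch_id)`` with 20
    quantized working points advancing monotonically along the true branch.
    """
    pose = default_pose()
    geom = pose_to_geometry(pose)
    sod = pose.sod_mm

    trunk = CenterlineBranch(
        "trunk", np.column_stack([np.zeros(16), np.zeros(16), np.linspace(-15, 0, 16)])
    )
    t_true = np.arange(0.0, 40.0 + 1e-9, 1.0)
    true_br = CenterlineBranch(
        "carotid",
        np.column_stack([np.zeros_like(t_true), np.zeros_like(t_true), t_true]),
        parent=("trunk", 15),
    )
    depth = 40.0
    k = (sod + depth) / sod  # perspective scale placing the decoy on the same rays
    t_decoy = np.arange(0.0, 40.0 * k + 1e-9, 0.2)
    decoy = CenterlineBranch(
        "decoy",
        np.column_stack(
            [np.zeros_like(t_decoy), np.full_like(t_decoy, depth), t_decoy]
        ),
        parent=("trunk", 15),
    )
    tree = CenterlineTree([trunk, true_br, decoy])

    arc = 8.0 + 1.5 * np.arange(20)
    markers = np.column_stack([np.zeros(20), np.zeros(20), arc])
    pixels = project_markers(geom, markers, quantize=True)
    return tree, geom, pixels, markers, "carotid"
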