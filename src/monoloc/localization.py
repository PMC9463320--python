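"""Single-projection 3D localization on a co-registered centerline.

A pixel picked in one monoplane projection constrains the device to the
back-projection ray through the X-ray source s and the pixel's detector
embedding p′. Assuming the device travels inside a vessel whose centerline
C is registered to the X-ray frame, its 3D position is taken as the
centerline point c whose own projection ray (c − s) is most parallel to
the working-point ray, i.e.

    p3d = argmin over c in C of  || (c − s) × (p′ − s) ||²

Because ||(c−s)×(p′−s)|| = ||c−s||·||p′−s||·sin θ and ||p′−s|| is constant
over c, this argmin coincides with minimizing the perpendicular distance
from c to the ray — an equivalence asserted in the test suite rather than
substituted here; the objective is evaluated exactly as written.

Superimposed or view-parallel centerlines make the minimum ambiguous: a
near-tie on another branch is flagged, and sequential localization can be
restricted to a geodesic neighborhood of the previous position so the
device path stays continuous along the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import CenterlineTree, neighborhood
from .geometry import (
    ProjectionGeometry,
    WorkingPoint2D,
    pixel_to_detector_point,
    pixel_to_ray,
)


class LocalizationError(ValueError):
    pass


@dataclass(frozen=True)
class LocalizationResult:
    """Selected centerline point for one working point."""

    point_mm: np.ndarray
    branch_id: str
    index: int
    objective: float
    perp_dist_mm: float
    ambiguous: bool = False
    n_candidates: int = 0

    def __post_init__(self):
        object.__setattr__(self, "point_mm", np.asarray(self.point_mm, dtype=float))
        if self.objective < 0 or self.perp_dist_mm < 0:
            raise LocalizationError("objective and perpendicular distance must be >= 0")


def localize(
    geom: ProjectionGeometry,
    p2d: WorkingPoint2D,
    tree: CenterlineTree,
    candidates=None,
    ambiguity_tol: float = 0.01,
) -> LocalizationResult:
    """Select the centerline point whose projection ray best aligns with
    the working point's ray.

    The tree must already be registered into X-ray coordinates; this is the
    caller's responsibility and is not (cannot be) checked here.

    Parameters
    ----------
    candidates : optional iterable of (branch_id, index)
        Restrict the search to a subset of tree points (the continuity
        window); defaults to every point of every branch.
    ambiguity_tol : float
        Relative tolerance on the objective: if the best point on any other
        branch comes within this factor of the minimum, ``ambiguous`` is
        set. Near-ties on the same branch are benign (adjacent samples) and
        not flagged.

    Ties on the objective are broken by smaller perpendicular distance to
    the ray, then by lower (branch_id, index), so output is deterministic.
    """
    if candidates is None:
        pts, labels = tree.all_points()
    else:
        labels = sorted(candidates)
        if not labels:
            raise LocalizationError("empty candidate set")
        pts = np.array([tree[b].points_mm[i] for b, i in labels])

    s = geom.source_mm
    p_prime = pixel_to_detector_point(geom, p2d).point_mm
    ray_vec = p_prime - s
    cross = np.cross(pts - s, ray_vec)
    objective = np.einsum("ij,ij->i", cross, cross)
    perp = np.sqrt(objective) / np.linalg.norm(ray_vec)

    best_obj = objective.min()
    tied = np.flatnonzero(objective == best_obj)
    if len(tied) > 1:
        order = sorted(tied, key=lambda i: (perp[i], labels[i]))
        k = order[0]
    else:
        k = int(tied[0])

    bid, idx = labels[k]
    ambiguous = False
    other = np.fromiter(
        (labels[i][0] != bid for i in range(len(labels))), dtype=bool, count=len(labels)
    )
    if other.any():
        best_other = objective[other].min()
        ambiguous = bool(best_other <= best_obj * (1.0 + ambiguity_tol))

    return LocalizationResult(
        point_mm=pts[k],
        branch_id=bid,
        index=int(idx),
        objective=float(best_obj),
        perp_dist_mm=float(perp[k]),
        ambiguous=ambiguous,
        n_candidates=len(labels),
    )


def localize_sequence(
    geom_per_frame,
    points2d,
    tree: CenterlineTree,
    window_mm: float = 10.0,
    init: LocalizationResult | None = None,
    ambiguity_tol: float = 0.01,
) -> list[LocalizationResult]:
    """Localize an ordered working-point sequence with continuity restriction.

    The first point is localized over the full tree, or — when ``init``
    gives an operator-approved previous position — over its geodesic
    neighborhood. Every subsequent point searches only the points within
    ``window_mm`` along the tree of the previous result, which keeps the
    device path continuous and rejects superimposed-but-distant branches.

    ``geom_per_frame`` is a single geometry (static C-arm) or one per frame.
    """
    points2d = list(points2d)
    if not points2d:
        raise LocalizationError("empty working-point sequence")
    if not (window_mm > 0):
        raise LocalizationError(f"window_mm must be > 0, got {window_mm}")
    if isinstance(geom_per_frame, ProjectionGeometry):
        geoms = [geom_per_frame] * len(points2d)
    else:
        geoms = list(geom_per_frame)
        if len(geoms) != len(points2d):
            raise LocalizationError(
                f"{len(geoms)} geometries for {len(points2d)} points"
            )

    results: list[LocalizationResult] = []
    prev = init
    for geom, p2d in zip(geoms, points2d):
        if prev is None:
            cand = None
        else:
            cand = neighborhood(tree, prev.branch_id, prev.index, window_mm)
            if not cand:
                raise LocalizationError(
                    f"empty continuity neighborhood around ({prev.branch_id}, "
                    f"{prev.index}); increase window_mm (currently {window_mm} mm)"
                )
        res = localize(geom, p2d, tree, candidates=cand, ambiguity_tol=ambiguity_tol)
        results.append(res)
        prev = res
    return results


def branch_accuracy(results, truth_branch_ids) -> float:
    """Fraction of localizations assigned to the true vessel branch."""
    results = list(results)
    truth = list(truth_branch_ids)
    if not results:
        raise LocalizationError("no results to score")
    if len(results) != len(truth):
        raise LocalizationError(
            f"length mismatch: {len(results)} results vs {len(truth)} truths"
        )
    hits = sum(r.branch_id == t for r, t in zip(results, truth))
    return hits / len(results)


def brute_force_nearest(
    geom: ProjectionGeometry, p2d: WorkingPoint2D, tree: CenterlineTree
) -> tuple[str, int, float]:
    """Independent point-to-ray nearest-candidate search (test oracle).

    Minimizes the perpendicular distance from each tree point to the
    back-projection ray directly, without the cross-product objective.
    Same tie-breaking as :func:`localize`.
    """
    ray = pixel_to_ray(geom, p2d)
    pts, labels = tree.all_points()
    w = pts - ray.origin_mm
    along = w @ ray.direction
    d = np.linalg.norm(w - np.outer(along, ray.direction), axis=1)
    best = d.min()
    tied = np.flatnonzero(d == best)
    k = min(tied, key=lambda i: labels[i]) if len(tied) > 1 else int(tied[0])
    return labels[k][0], labels[k][1], float(best)
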