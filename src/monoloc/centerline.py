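"""Branched vascular centerline trees.

A tree is a list of branches, each an ordered polyline of 3D points with
optional per-point vessel radii. A branch may declare a parent attachment
``(parent_branch_id, attachment_index)``; junction edges connect the parent
point at the attachment index to the child's first point. Geodesic
(along-tree) distance is the metric used for the localization continuity
window, so vessels that merely superimpose in projection — but are far
apart along the tree — are excluded from the candidate set.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra


class CenterlineError(ValueError):
    pass


class ParseError(CenterlineError):
    pass


def _cumulative_arclen(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class CenterlineBranch:
    """One vessel branch: an ordered 3D polyline with arc-length parameter."""

    branch_id: str
    points_mm: np.ndarray
    radius_mm: np.ndarray | None = None
    parent: tuple[str, int] | None = None
    cum_arclen_mm: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise CenterlineError(
                f"branch {self.branch_id!r}: points must be (N, 3), "
                f"got shape {self.points_mm.shape}"
            )
        if len(self.points_mm) < 2:
            raise CenterlineError(f"branch {self.branch_id!r}: need at least 2 points")
        if not np.all(np.isfinite(self.points_mm)):
            raise CenterlineError(f"branch {self.branch_id!r}: non-finite point")
        self.cum_arclen_mm = _cumulative_arclen(self.points_mm)
        if np.any(np.diff(self.cum_arclen_mm) <= 0):
            raise CenterlineError(
                f"branch {self.branch_id!r}: zero-length segment (duplicate points)"
            )
        if self.radius_mm is not None:
            self.radius_mm = np.asarray(self.radius_mm, dtype=float)
            if self.radius_mm.shape != (len(self.points_mm),):
                raise CenterlineError(
                    f"branch {self.branch_id!r}: radius must have one value per point"
                )

    @property
    def length_mm(self) -> float:
        return float(self.cum_arclen_mm[-1])

    @property
    def n_points(self) -> int:
        return len(self.points_mm)

    def point_at_arclen(self, s: float) -> np.ndarray:
        """Linearly interpolated point at arc-length position ``s``."""
        s = float(np.clip(s, 0.0, self.length_mm))
        return np.array(
            [np.interp(s, self.cum_arclen_mm, self.points_mm[:, k]) for k in range(3)]
        )

    def tangent_at_arclen(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.cum_arclen_mm, s) - 1, 0, self.n_points - 2))
        d = self.points_mm[i + 1] - self.points_mm[i]
        return d / np.linalg.norm(d)


@dataclass
class CenterlineTree:
    branches: list[CenterlineBranch]

    def __post_init__(self):
        ids = [b.branch_id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise CenterlineError(f"duplicate branch ids: {ids}")
        self._by_id = {b.branch_id: b for b in self.branches}
        for b in self.branches:
            if b.parent is not None:
                pid, idx = b.parent
                if pid not in self._by_id:
                    raise CenterlineError(
                        f"branch {b.branch_id!r}: unknown parent {pid!r}"
                    )
                if not (0 <= int(idx) < self._by_id[pid].n_points):
                    raise CenterlineError(
                        f"branch {b.branch_id!r}: attachment index {idx} out of "
                        f"range for parent {pid!r}"
                    )
        self._graph_cache = None

    def __getitem__(self, branch_id: str) -> CenterlineBranch:
        return self._by_id[branch_id]

    @property
    def branch_ids(self) -> list[str]:
        return [b.branch_id for b in self.branches]

    @property
    def total_length_mm(self) -> float:
        return sum(b.length_mm for b in self.branches)

    def all_points(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """All tree points stacked, with their (branch_id, index) labels."""
        pts = np.vstack([b.points_mm for b in self.branches])
        labels = [
            (b.branch_id, i) for b in self.branches for i in range(b.n_points)
        ]
        return pts, labels

    # -- geodesic structure -------------------------------------------------

    def _point_graph(self):
        """Sparse weighted adjacency over all points; cached."""
        if self._graph_cache is not None:
            return self._graph_cache
        offsets, n = {}, 0
        for b in self.branches:
            offsets[b.branch_id] = n
            n += b.n_points
        rows, cols, w = [], [], []
        for b in self.branches:
            o = offsets[b.branch_id]
            seg = np.diff(b.cum_arclen_mm)
            idx = np.arange(b.n_points - 1)
            rows.extend(o + idx)
            cols.extend(o + idx + 1)
            w.extend(seg)
            if b.parent is not None:
                pid, ai = b.parent
                pnode = offsets[pid] + int(ai)
                gap = float(
                    np.linalg.norm(self._by_id[pid].points_mm[int(ai)] - b.points_mm[0])
                )
                rows.append(pnode)
                cols.append(o)
                w.append(max(gap, 1e-12))
        g = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
        self._graph_cache = (g, offsets)
        return self._graph_cache

    def node_of(self, branch_id: str, index: int) -> int:
        _, offsets = self._point_graph()
        b = self._by_id[branch_id]
        if not (0 <= index < b.n_points):
            raise CenterlineError(
                f"index {index} out of range for branch {branch_id!r} "
                f"({b.n_points} points)"
            )
        return offsets[branch_id] + index


def _walk_resample(points: np.ndarray, spacing: float):
    """Place points along a polyline so consecutive samples are exactly
    ``spacing`` apart (Euclidean), walking segment by segment.

    Returns the new points and their arc-length parameters on the original
    polyline. Placing by chord rather than interpolated arc length makes
    the operation exactly idempotent: a polyline whose vertices are already
    uniformly spaced resamples to itself.
    """
    cum = _cumulative_arclen(points)
    out = [points[0]]
    params = [0.0]
    seg = 0
    t0 = 0.0  # parameter within current segment [0, 1)
    while True:
        last = out[-1]
        hit = None
        s, t = seg, t0
        while s < len(points) - 1:
            a, b = points[s], points[s + 1]
            d = b - a
            # solve |a + t d - last|^2 = spacing^2 for t in (t, 1]
            w = a - last
            aa = float(d @ d)
            bb = 2.0 * float(w @ d)
            cc = float(w @ w) - spacing**2
            disc = bb * bb - 4 * aa * cc
            if disc >= 0:
                root = (-bb + np.sqrt(disc)) / (2 * aa)
                if t < root <= 1.0 + 1e-12:
                    hit = (s, min(root, 1.0))
                    break
            s, t = s + 1, 0.0
        if hit is None:
            break
        seg, t0 = hit
        a, b = points[seg], points[seg + 1]
        out.append(a + t0 * (b - a))
        params.append(cum[seg] + t0 * (cum[seg + 1] - cum[seg]))
    # keep the original endpoint; the final segment may be shorter
    if np.linalg.norm(points[-1] - out[-1]) > 1e-9:
        out.append(points[-1])
        params.append(float(cum[-1]))
    else:
        out[-1] = points[-1]
        params[-1] = float(cum[-1])
    if len(out) < 2:
        out = [points[0], points[-1]]
        params = [0.0, float(cum[-1])]
    return np.asarray(out), np.asarray(params)


def resample(tree: CenterlineTree, spacing_mm: float = 0.5) -> CenterlineTree:
    """Re-parameterize every branch at uniform spacing along the curve.

    Consecutive resampled points are exactly ``spacing_mm`` apart; both
    endpoints are preserved, so the last segment may be shorter. Radii,
    when present, are linearly interpolated; parent attachment indices are
    remapped to the nearest resampled arc-length position.
    """
    if not (spacing_mm > 0):
        raise CenterlineError(f"spacing_mm must be > 0, got {spacing_mm}")
    new_branches = []
    arclens: dict[str, np.ndarray] = {}
    for b in tree.branches:
        pts, params = _walk_resample(b.points_mm, spacing_mm)
        rad = (
            np.interp(params, b.cum_arclen_mm, b.radius_mm)
            if b.radius_mm is not None
            else None
        )
        arclens[b.branch_id] = params
        new_branches.append(
            CenterlineBranch(b.branch_id, pts, radius_mm=rad, parent=b.parent)
        )
    # remap attachment indices onto the resampled parent
    for b, src in zip(new_branches, tree.branches):
        if b.parent is not None:
            pid, ai = b.parent
            s = tree[pid].cum_arclen_mm[int(ai)]
            b.parent = (pid, int(np.argmin(np.abs(arclens[pid] - s))))
    return CenterlineTree(new_branches)


def neighborhood(
    tree: CenterlineTree, branch_id: str, index: int, window_mm: float
) -> set[tuple[str, int]]:
    """All points within geodesic distance ``window_mm`` of a query point.

    Distance is measured along the tree, crossing junctions through their
    attachment edges; the query point itself is always included.
    """
    if window_mm < 0:
        raise CenterlineError(f"window_mm must be >= 0, got {window_mm}")
    g, offsets = tree._point_graph()
    src = tree.node_of(branch_id, index)
    tol = 1e-9 * (1.0 + window_mm)  # absorbs the epsilon-weight junction edges
    dist = dijkstra(g, directed=False, indices=src, limit=window_mm + tol)
    reachable = np.flatnonzero(np.isfinite(dist))
    bounds = sorted(offsets.items(), key=lambda kv: kv[1])
    out = set()
    for node in reachable:
        if dist[node] <= window_mm + tol:
            for bid, off in reversed(bounds):
                if node >= off:
                    out.add((bid, int(node - off)))
                    break
    return out


# ---------------------------------------------------------------------------
# file formats

def write_centerline_csv(tree: CenterlineTree, path) -> None:
    has_radius = any(b.radius_mm is not None for b in tree.branches)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        header = ["branch_id", "x", "y", "z"] + (["radius"] if has_radius else [])
        wr.writerow(header)
        for b in tree.branches:
            for i, p in enumerate(b.points_mm):
                row = [b.branch_id, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))]
                if has_radius:
                    r = b.radius_mm[i] if b.radius_mm is not None else ""
                    row.append(repr(float(r)) if r != "" else "")
                wr.writerow(row)


def read_centerline_csv(path) -> CenterlineTree:
    order: list[str] = []
    pts: dict[str, list] = {}
    rads: dict[str, list] = {}
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd, None)
        if header is None or header[:4] != ["branch_id", "x", "y", "z"]:
            raise ParseError(f"{path}: expected header branch_id,x,y,z[,radius]")
        has_radius = len(header) > 4 and header[4] == "radius"
        for ln, row in enumerate(rd, start=2):
            if not row:
                continue
            if len(row) < 4 or any(c.strip() == "" for c in row[1:4]):
                raise ParseError(f"{path}: row {ln}: missing coordinate in {row!r}")
            try:
                xyz = [float(c) for c in row[1:4]]
            except ValueError as exc:
                raise ParseError(f"{path}: row {ln}: {exc}") from exc
            bid = row[0]
            if bid not in pts:
                order.append(bid)
                pts[bid] = []
                rads[bid] = []
            pts[bid].append(xyz)
            if has_radius and len(row) > 4 and row[4].strip() != "":
                rads[bid].append(float(row[4]))
    branches = [
        CenterlineBranch(
            bid,
            np.array(pts[bid]),
            radius_mm=np.array(rads[bid]) if rads[bid] else None,
        )
        for bid in order
    ]
    return CenterlineTree(branches)


def write_centerline_json(tree: CenterlineTree, path) -> None:
    doc = {
        "branches": [
            {
                "branch_id": b.branch_id,
                "points": b.points_mm.tolist(),
                "radius": None if b.radius_mm is None else b.radius_mm.tolist(),
                "parent": None if b.parent is None else [b.parent[0], int(b.parent[1])],
            }
            for b in tree.branches
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_centerline_json(path) -> CenterlineTree:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        branches = [
            CenterlineBranch(
                d["branch_id"],
                np.array(d["points"], dtype=float),
                radius_mm=None if d.get("radius") is None else np.array(d["radius"]),
                parent=None if d.get("parent") is None else (d["parent"][0], int(d["parent"][1])),
            )
            for d in doc["branches"]
        ]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed centerline JSON: {exc}") from exc
    return CenterlineTree(branches)


def write_centerline_vtk(tree: CenterlineTree, path) -> None:
    """Write legacy ASCII VTK polydata: one polyline cell per branch.

    Parent topology is not representable in VTK polylines and is dropped;
    use the CSV/JSON dialects when junction structure matters.
    """
    pts, _ = tree.all_points()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncenterline tree\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        ncells = len(tree.branches)
        total = sum(b.n_points + 1 for b in tree.branches)
        fh.write(f"LINES {ncells} {total}\n")
        off = 0
        for b in tree.branches:
            ids = " ".join(str(off + i) for i in range(b.n_points))
            fh.write(f"{b.n_points} {ids}\n")
            off += b.n_points
        if any(b.radius_mm is not None for b in tree.branches):
            fh.write(f"POINT_DATA {len(pts)}\n")
            fh.write("SCALARS Radius double 1\nLOOKUP_TABLE default\n")
            for b in tree.branches:
                r = b.radius_mm if b.radius_mm is not None else np.zeros(b.n_points)
                for v in r:
                    fh.write(f"{float(v)!r}\n")


def read_centerline_vtk(path) -> CenterlineTree:
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    it = iter(enumerate(tokens_lines, start=1))

    def next_content():
        for ln, line in it:
            s = line.strip()
            if s:
                return ln, s
        return None, None

    ln, s = next_content()  # version line
    if s is None or not s.startswith("# vtk"):
        raise ParseError(f"{path}: not a legacy VTK file")
    next_content()  # title
    ln, s = next_content()
    if s != "ASCII":
        raise ParseError(f"{path}: line {ln}: only ASCII VTK supported, got {s!r}")
    ln, s = next_content()
    if s != "DATASET POLYDATA":
        raise ParseError(f"{path}: line {ln}: expected DATASET POLYDATA, got {s!r}")
    ln, s = next_content()
    if s is None or not s.startswith("POINTS"):
        raise ParseError(f"{path}: line {ln}: expected POINTS section")
    npts = int(s.split()[1])
    vals: list[float] = []
    while len(vals) < 3 * npts:
        ln, s = next_content()
        if s is None:
            raise ParseError(f"{path}: truncated POINTS section")
        vals.extend(float(t) for t in s.split())
    pts = np.array(vals).reshape(npts, 3)
    ln, s = next_content()
    if s is None or not s.startswith("LINES"):
        raise ParseError(f"{path}: line {ln}: expected LINES section")
    ncells = int(s.split()[1])
    cells = []
    for _ in range(ncells):
        ln, s = next_content()
        if s is None:
            raise ParseError(f"{path}: truncated LINES section")
        nums = [int(t) for t in s.split()]
        if len(nums) != nums[0] + 1:
            raise ParseError(f"{path}: line {ln}: malformed polyline cell {s!r}")
        cells.append(nums[1:])
    radius = None
    ln, s = next_content()
    if s is not None and s.startswith("POINT_DATA"):
        ln, s = next_content()
        if s is None or not s.startswith("SCALARS"):
            raise ParseError(f"{path}: line {ln}: expected SCALARS after POINT_DATA")
        next_content()  # LOOKUP_TABLE
        rvals: list[float] = []
        while len(rvals) < npts:
            ln, s = next_content()
            if s is None:
                raise ParseError(f"{path}: truncated SCALARS section")
            rvals.extend(float(t) for t in s.split())
        radius = np.array(rvals)
    branches = []
    for k, ids in enumerate(cells):
        branches.append(
            CenterlineBranch(
                f"branch{k}",
                pts[ids],
                radius_mm=None if radius is None else radius[ids],
            )
        )
    return CenterlineTree(branches)


_READERS = {
    "csv": read_centerline_csv,
    "json": read_centerline_json,
    "vtk": read_centerline_vtk,
}
_WRITERS = {
    "csv": write_centerline_csv,
    "json": write_centerline_json,
    "vtk": write_centerline_vtk,
}


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = str(path).rsplit(".", 1)[-1].lower()
    if suffix in _READERS:
        return suffix
    raise CenterlineError(f"cannot infer centerline format from {path!r}")


def read_centerline(path, format: str | None = None) -> CenterlineTree:
    return _READERS[_infer_format(path, format)](path)


def write_centerline(tree: CenterlineTree, path, format: str | None = None) -> None:
    _WRITERS[_infer_format(path, format)](tree, path)
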