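"""Delaunay triangle patches over facial landmarks, tracked through time.

The landmark set of a reference frame is triangulated once (Delaunay, so no
landmark falls inside any triangle's circumcircle and the minimum angle is
maximized); the same vertex triples are then rasterized on every frame, so a
triangle keeps its identity and covers the same piece of skin as the face
deforms.  Per-frame pixel counts ``N = (N_1 ... N_K)`` of each patch are the
raw material for the size-stability selection stage.

Rasterization uses half-open (top-left style) edge ownership: a pixel center
on an edge shared by two triangles is assigned to exactly one of them, so
the patches partition the landmark convex hull with no overlaps or gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .containers import FrameStack, LandmarkTrack

__all__ = [
    "TriangleMesh",
    "PatchTrack",
    "PatchTrackSet",
    "triangulate",
    "rasterize",
    "rasterize_labels",
    "rasterize_hull",
    "track_patches",
    "grid_mesh_tracks",
]


@dataclass
class TriangleMesh:
    """Fixed triangulation topology: one row of landmark indices per triangle."""

    vertex_ids: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)
        if self.vertex_ids.ndim != 2 or self.vertex_ids.shape[1] != 3:
            raise ValueError("vertex_ids must be (M, 3)")

    @property
    def n_triangles(self) -> int:
        return self.vertex_ids.shape[0]


@dataclass
class PatchTrack:
    """One triangle's per-frame pixel counts and validity."""

    triangle_id: int
    counts: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.counts)


@dataclass
class PatchTrackSet:
    """Result of tracking a mesh across a clip.

    ``label_maps`` is ``(T, H, W)`` int16 with each pixel's triangle id
    (-1 where no patch); it is shared by the skin-filtering and
    trace-extraction stages so rasterization happens once.
    """

    mesh: TriangleMesh
    tracks: list
    label_maps: np.ndarray
    landmarks: LandmarkTrack = None

    @property
    def counts(self) -> np.ndarray:
        """(n_triangles, T) pixel-count matrix."""
        return np.stack([t.counts for t in self.tracks])


def triangulate(landmarks: np.ndarray) -> TriangleMesh:
    """Delaunay-triangulate a landmark set.

    Raises
    ------
    ValueError
        If fewer than 3 landmarks are given or all are collinear.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) landmarks")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:  # collinear or otherwise degenerate input
        raise ValueError(f"landmarks cannot be triangulated: {exc}") from exc
    simplices = np.sort(tri.simplices, axis=1)
    order = np.lexsort((simplices[:, 2], simplices[:, 1], simplices[:, 0]))
    return TriangleMesh(simplices[order])


def _edge_owns(ax, ay, bx, by) -> bool:
    """Half-open edge-ownership rule for boundary pixels (direction-asymmetric,
    so an edge shared by two triangles is owned by exactly one of them)."""
    return ay < by or (ay == by and ax > bx)


def _triangle_pixels(v: np.ndarray, width: int, height: int):
    """Pixel centers strictly inside the triangle plus owned boundary pixels.

    Returns (ys, xs) integer arrays; empty for degenerate triangles.
    """
    (x0, y0), (x1, y1), (x2, y2) = v
    cross = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
    if cross == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if cross < 0:  # orient consistently so interiors have positive edge funcs
        x1, y1, x2, y2 = x2, y2, x1, y1
    lo_x = max(int(np.floor(min(x0, x1, x2))), 0)
    hi_x = min(int(np.ceil(max(x0, x1, x2))), width - 1)
    lo_y = max(int(np.floor(min(y0, y1, y2))), 0)
    hi_y = min(int(np.ceil(max(y0, y1, y2))), height - 1)
    if lo_x > hi_x or lo_y > hi_y:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    xs = np.arange(lo_x, hi_x + 1)
    ys = np.arange(lo_y, hi_y + 1)
    px, py = np.meshgrid(xs, ys)
    inside = np.ones(px.shape, dtype=bool)
    for (ax, ay), (bx, by) in (
        ((x0, y0), (x1, y1)),
        ((x1, y1), (x2, y2)),
        ((x2, y2), (x0, y0)),
    ):
        e = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        if _edge_owns(ax, ay, bx, by):
            inside &= e >= 0
        else:
            inside &= e > 0
    iy, ix = np.nonzero(inside)
    return iy + lo_y, ix + lo_x


def rasterize_labels(
    mesh: TriangleMesh, landmarks: np.ndarray, frame_size: tuple[int, int]
) -> np.ndarray:
    """Assign each pixel of a (width, height) frame to a triangle id.

    Returns an ``(H, W)`` int16 map; -1 where no patch.  Pixels claimed by
    an earlier triangle id are never overwritten, so assignments are
    guaranteed disjoint even under floating-point edge ties.
    """
    width, height = frame_size
    pts = np.asarray(landmarks, dtype=float)
    labels = np.full((height, width), -1, dtype=np.int16)
    for tid, verts in enumerate(mesh.vertex_ids):
        ys, xs = _triangle_pixels(pts[verts], width, height)
        if len(ys) == 0:
            continue
        free = labels[ys, xs] == -1
        labels[ys[free], xs[free]] = tid
    return labels


def rasterize(
    mesh: TriangleMesh, landmarks: np.ndarray, frame_size: tuple[int, int]
) -> list:
    """Per-triangle pixel sets for one frame.

    Returns a list (one entry per triangle) of ``(ys, xs)`` index-array
    pairs; a degenerate or fully off-frame triangle yields empty arrays.
    """
    labels = rasterize_labels(mesh, landmarks, frame_size)
    flat = labels.reshape(-1)
    width = labels.shape[1]
    out = []
    for tid in range(mesh.n_triangles):
        idx = np.flatnonzero(flat == tid)
        out.append((idx // width, idx % width))
    return out


def rasterize_hull(landmarks: np.ndarray, frame_size: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels inside the landmark convex hull, using the same
    half-open boundary rule as triangle rasterization."""
    pts = np.asarray(landmarks, dtype=float)
    hull = ConvexHull(pts)
    poly = pts[hull.vertices]
    # normalize winding so interiors have positive edge functions
    area2 = np.sum(
        poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1]
    )
    if area2 < 0:
        poly = poly[::-1]
    width, height = frame_size
    px, py = np.meshgrid(np.arange(width), np.arange(height))
    inside = np.ones(px.shape, dtype=bool)
    n = len(poly)
    for k in range(n):
        ax, ay = poly[k]
        bx, by = poly[(k + 1) % n]
        e = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        if _edge_owns(ax, ay, bx, by):
            inside &= e >= 0
        else:
            inside &= e > 0
    return inside


def _interpolate_gaps(points: np.ndarray, max_gap: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN landmark frames by per-point linear interpolation.

    Gaps of at most ``max_gap`` missing frames (with valid frames on both
    sides) are filled; longer gaps and missing ends stay invalid.
    Returns (filled points, per-frame validity mask).
    """
    pts = points.copy()
    n_frames = pts.shape[0]
    valid = np.isfinite(pts).all(axis=(1, 2))
    filled = valid.copy()
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        return pts, filled
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            w = (np.arange(a + 1, b) - a) / (b - a)
            pts[a + 1 : b] = (1 - w)[:, None, None] * pts[a] + w[:, None, None] * pts[b]
            filled[a + 1 : b] = True
    return pts, filled


def track_patches(
    frame_stack: FrameStack, landmark_track: LandmarkTrack, max_gap: int = 5
) -> PatchTrackSet:
    """Build the mesh on the first valid frame and rasterize it on every frame.

    Frames with missing landmarks are linearly interpolated across gaps of
    at most ``max_gap`` frames; frames that remain unfilled get empty
    patches (count 0, valid False).  A patch partially pushed off-frame
    simply loses pixels — the resulting count fluctuation is exactly the
    instability signal the selection stage consumes.

    Raises
    ------
    ValueError
        If fewer than half the frames have landmarks.
    """
    n_frames = frame_stack.n_frames
    if landmark_track.n_frames != n_frames:
        raise ValueError("landmark track length does not match frame count")
    pts, frame_valid = _interpolate_gaps(landmark_track.points, max_gap=max_gap)
    if landmark_track.valid_frames().mean() < 0.5:
        raise ValueError("fewer than 50% of frames have landmarks")
    first = int(np.flatnonzero(frame_valid)[0])
    mesh = triangulate(pts[first])
    width, height = frame_stack.frame_size
    label_maps = np.full((n_frames, height, width), -1, dtype=np.int16)
    counts = np.zeros((mesh.n_triangles, n_frames), dtype=int)
    for t in range(n_frames):
        if not frame_valid[t]:
            continue
        labels = rasterize_labels(mesh, pts[t], (width, height))
        label_maps[t] = labels
        flat = labels.reshape(-1)
        c = np.bincount(flat[flat >= 0], minlength=mesh.n_triangles)
        counts[:, t] = c
    tracks = [
        PatchTrack(tid, counts[tid], frame_valid & (counts[tid] > 0))
        for tid in range(mesh.n_triangles)
    ]
    return PatchTrackSet(mesh, tracks, label_maps, LandmarkTrack(pts))


def grid_mesh_tracks(
    frame_stack: FrameStack, box: tuple[float, float, float, float], n_cells: int = 6
) -> PatchTrackSet:
    """Fixed rectangular grid patches over a bounding box (x0, y0, x1, y1).

    This is the non-adaptive patch scheme used as an ablation baseline: the
    box is split into ``n_cells x n_cells`` static cells (each cell split in
    two triangles so downstream code sees ordinary patch tracks).
    """
    x0, y0, x1, y1 = box
    xs = np.linspace(x0, x1, n_cells + 1)
    ys = np.linspace(y0, y1, n_cells + 1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.reshape(-1), gy.reshape(-1)], axis=1)
    tris = []
    for r in range(n_cells):
        for c in range(n_cells):
            a = r * (n_cells + 1) + c
            b = a + 1
            d = a + n_cells + 1
            e = d + 1
            tris.append((a, b, d))
            tris.append((b, e, d))
    mesh = TriangleMesh(np.array(tris))
    width, height = frame_stack.frame_size
    labels = rasterize_labels(mesh, pts, (width, height))
    n_frames = frame_stack.n_frames
    label_maps = np.broadcast_to(labels, (n_frames, height, width)).copy()
    flat = labels.reshape(-1)
    c = np.bincount(flat[flat >= 0], minlength=mesh.n_triangles)
    counts = np.repeat(c[:, None], n_frames, axis=1)
    valid = np.ones(n_frames, dtype=bool)
    tracks = [
        PatchTrack(tid, counts[tid], valid & (counts[tid] > 0))
        for tid in range(mesh.n_triangles)
    ]
    track_pts = np.repeat(pts[None], n_frames, axis=0)
    return PatchTrackSet(mesh, tracks, label_maps, LandmarkTrack(track_pts))
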