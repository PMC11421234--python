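"""Luminal geometry: false-lumen derivation, true-lumen centerline, and
orthogonal analysis planes.

The centerline follows the path of TL flow: the TL mask is skeletonized in
3D, the longest geodesic path through the skeleton is taken (the two skeleton
voxels with maximal geodesic separation define its ends, which suppresses
short side branches), the path is smoothed with a 5 mm moving average and
resampled to 1 mm arc-length spacing.  Unit tangents come from central
differences of the resampled points and define an orthogonal analysis plane
at every millimeter.

Each luminal voxel is matched to the plane whose center point is nearest in
Euclidean distance (ties broken toward the more proximal plane); the matched
plane's tangent is that voxel's forward-flow direction.  Distance to the
plane center, rather than point-to-plane distance, keeps the matching
well-behaved in curved segments where a voxel can lie between the infinite
planes of several centerline points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .core import LumenMasks, VoxelGrid

__all__ = [
    "CenterlinePlanes",
    "VoxelPlaneAssignment",
    "RegionLabels",
    "derive_false_lumen",
    "extract_centerline",
    "assign_voxels_to_planes",
    "split_regions",
]

# region label codes
TL_PROXIMAL = 1
TL_DISTAL = 2
FL_PROXIMAL = 3
FL_DISTAL = 4
TL_ARCH = 5  # TL voxels proximal to the first landmark (not a reported region)


@dataclass
class CenterlinePlanes:
    """Ordered centerline points (world mm), unit tangents, arc length (mm)."""

    points: np.ndarray  # (N, 3)
    tangents: np.ndarray  # (N, 3), unit norm
    arc_length: np.ndarray  # (N,), increasing from the proximal end

    def __post_init__(self) -> None:
        n = len(self.points)
        if n < 2:
            raise ValueError("centerline needs at least 2 points")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit vectors")
        gaps = np.diff(self.arc_length)
        if np.any(gaps <= 0):
            raise ValueError("arc length must be strictly increasing")
        spacing = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(spacing < 0.5) or np.any(spacing > 1.5):
            raise ValueError("consecutive plane spacing outside [0.5, 1.5] mm")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1] - self.arc_length[0])


@dataclass
class VoxelPlaneAssignment:
    """Per-luminal-voxel matched plane index and forward direction."""

    plane_index: np.ndarray  # (n_luminal,)
    forward_direction: np.ndarray  # (n_luminal, 3) matched plane tangents
    voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray]  # into the grid

    def arc_length_of(self, centerline: CenterlinePlanes) -> np.ndarray:
        return centerline.arc_length[self.plane_index]


@dataclass
class RegionLabels:
    """Per-voxel region codes and the combined descending-aorta flag.

    ``labels`` is an int array on the grid: 0 outside the lumen, otherwise
    one of TL_PROXIMAL, TL_DISTAL, FL_PROXIMAL, FL_DISTAL, TL_ARCH.
    ``combined_dao`` flags the FL plus the TL distal to the subclavian-level
    landmark — the region over which descending-aorta energy loss is pooled.
    """

    labels: np.ndarray
    combined_dao: np.ndarray

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


def derive_false_lumen(
    whole: np.ndarray, tl: np.ndarray, static_tissue: np.ndarray | None = None
) -> LumenMasks:
    """FL = whole-aorta minus TL; fails loudly if TL leaves the aorta."""
    whole = np.asarray(whole, dtype=bool)
    tl = np.asarray(tl, dtype=bool)
    outside = tl & ~whole
    if np.any(outside):
        raise ValueError(
            f"TL mask extends outside the whole-aorta mask by {int(outside.sum())} voxels"
        )
    fl = whole & ~tl
    return LumenMasks(whole=whole, tl=tl, fl=fl, static_tissue=static_tissue)


def _skeleton_longest_path(skel: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Indices (n, 3) of the longest geodesic path through a 3D skeleton."""
    vox = np.argwhere(skel)
    n = len(vox)
    if n < 2:
        raise ValueError("skeleton degenerate: fewer than 2 voxels")
    tree = cKDTree(vox * np.asarray(spacing))
    pairs = tree.query_pairs(r=np.linalg.norm(spacing) + 1e-9, output_type="ndarray")
    # keep only 26-neighbour pairs (index offset <= 1 per axis)
    off = np.abs(vox[pairs[:, 0]] - vox[pairs[:, 1]])
    adj = pairs[np.all(off <= 1, axis=1)]
    w = np.linalg.norm((vox[adj[:, 0]] - vox[adj[:, 1]]) * np.asarray(spacing), axis=1)
    graph = coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([adj[:, 0], adj[:, 1]]),
          np.concatenate([adj[:, 1], adj[:, 0]]))),
        shape=(n, n),
    ).tocsr()

    def farthest(src: int) -> tuple[int, np.ndarray]:
        dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
        dist[np.isinf(dist)] = -1.0
        return int(np.argmax(dist)), pred

    a, _ = farthest(0)
    b, pred = farthest(a)
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            raise ValueError("skeleton path reconstruction failed")
        path.append(int(p))
    return vox[np.array(path[::-1])]


def _recenter_in_lumen(points: np.ndarray, mask: np.ndarray, grid: VoxelGrid,
                       slab_half_mm: float = 1.6) -> np.ndarray:
    """Snap each path point to the centroid of the luminal cross-section.

    The cross-section at a point is the set of mask voxels within a thin slab
    orthogonal to the local path direction and within a radius bounded by the
    lumen caliber, which corrects the lateral bias a discrete skeleton (or
    distance-transform ridge) can carry.
    """
    from scipy import ndimage

    vox_world = (
        np.asarray(grid.origin)
        + np.argwhere(mask) * np.asarray(grid.spacing)
    )
    r_max = 3.0 * float(ndimage.distance_transform_edt(
        mask, sampling=grid.spacing).max())
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    out = points.copy()
    for i, (p, t) in enumerate(zip(points, tangents)):
        rel = vox_world - p
        near = np.abs(rel @ t) <= slab_half_mm
        near &= np.einsum("ij,ij->i", rel, rel) <= r_max**2
        if near.sum() >= 3:
            out[i] = vox_world[near].mean(axis=0)
    return out


def _dedupe_points(points: np.ndarray, min_step: float) -> np.ndarray:
    """Drop points closer than ``min_step`` to the previously kept point."""
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) >= min_step:
            keep.append(i)
    last = len(points) - 1
    if keep[-1] != last and np.linalg.norm(points[last] - points[keep[-1]]) > 1e-9:
        keep.append(last)
    return points[keep]


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(points, ((pad, pad), (0, 0)), mode="edge")
    return np.stack(
        [np.convolve(padded[:, a], kernel, mode="valid")[: len(points)]
         for a in range(3)],
        axis=1,
    )


def _inside_mask(point: np.ndarray, mask: np.ndarray, grid: VoxelGrid) -> bool:
    idx = np.round((point - np.asarray(grid.origin)) / np.asarray(grid.spacing))
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        return False
    i, j, k = idx.astype(int)
    return bool(mask[i, j, k])


def _extend_to_mask_end(points: np.ndarray, mask: np.ndarray, grid: VoxelGrid,
                        step_mm: float = 0.5) -> np.ndarray:
    """Prepend curvature-following extrapolated points until leaving the mask.

    Skeletonization retreats roughly one lumen radius from the vessel ends;
    this walks the path back out to the mask boundary, continuing the local
    turn rate so curved segments stay on their arc.
    """
    # estimate the end direction and turn rate from chords over the last
    # ~12 mm of the path; chords average out voxel-scale jitter
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )
    win = min(12.0, arc[-1] / 2.0)
    i_half = int(np.searchsorted(arc, win / 2.0))
    i_full = int(np.searchsorted(arc, win))
    i_half = max(i_half, 1)
    i_full = max(i_full, i_half + 1)
    v_new = points[0] - points[i_half]
    v_old = points[i_half] - points[i_full]
    n_new, n_old = np.linalg.norm(v_new), np.linalg.norm(v_old)
    if n_new < 1e-9 or n_old < 1e-9:
        return points
    v_new, v_old = v_new / n_new, v_old / n_old
    axis = np.cross(v_old, v_new)
    sin_phi = np.linalg.norm(axis)
    turn_per_mm = 0.0
    if sin_phi > 1e-12:
        axis = axis / sin_phi
        phi = np.arcsin(np.clip(sin_phi, 0.0, 1.0))
        turn_per_mm = phi / max(arc[i_half], 1e-9)

    def rotate(vec: np.ndarray, angle: float) -> np.ndarray:
        if turn_per_mm == 0.0:
            return vec
        # Rodrigues rotation about the estimated osculating axis
        return (
            vec * np.cos(angle)
            + np.cross(axis, vec) * np.sin(angle)
            + axis * (axis @ vec) * (1.0 - np.cos(angle))
        )

    direction = v_new
    pt = points[0].copy()
    prepend = []
    for _ in range(int(np.ceil(np.max(mask.shape) * np.max(grid.spacing) / step_mm))):
        direction = rotate(direction, turn_per_mm * step_mm)
        pt = pt + direction * step_mm
        if not _inside_mask(pt, mask, grid):
            break
        prepend.append(pt.copy())
    if not prepend:
        return points
    return np.vstack([np.array(prepend[::-1]), points])


def extract_centerline(
    tl_mask: np.ndarray,
    grid: VoxelGrid,
    plane_spacing: float = 1.0,
    smoothing_window_mm: float = 5.0,
    orient_ascending_axis: int = 2,
) -> CenterlinePlanes:
    """Skeletonize the TL and build orthogonal planes at ~1 mm spacing.

    ``orient_ascending_axis`` selects which world axis increases from the
    proximal to the distal end (default z); the path is flipped if needed so
    arc length runs proximal -> distal.
    """
    tl_mask = np.asarray(tl_mask, dtype=bool)
    _, n_comp = _label_components(tl_mask)
    if n_comp != 1:
        raise ValueError(f"TL mask must be one connected component, found {n_comp}")
    skel = skeletonize(tl_mask)
    if skel.sum() < 2:
        # parallel thinning deletes symmetric voxel pairs simultaneously and
        # can erode an even-diameter tube completely; fall back to the ridge
        # of the Euclidean distance transform, which is the same medial locus
        skel = _distance_ridge(tl_mask)
    path_idx = _skeleton_longest_path(skel, grid.spacing)
    pts = np.asarray(grid.origin) + path_idx * np.asarray(grid.spacing)

    if len(pts) > 8:
        pts = pts[2:-2]  # endpoint voxels of a discrete path are the noisiest
    step = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    window = max(1, int(round(smoothing_window_mm / max(step, 1e-6))))
    smooth = _moving_average(pts, window)
    smooth = _recenter_in_lumen(smooth, tl_mask, grid)
    smooth = _dedupe_points(smooth, min_step=0.25 * float(np.min(grid.spacing)))
    if len(smooth) >= 3:
        smooth = _extend_to_mask_end(smooth, tl_mask, grid)
        smooth = _extend_to_mask_end(smooth[::-1], tl_mask, grid)[::-1]

    seg = np.linalg.norm(np.diff(smooth, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] < 5.0:
        raise ValueError(f"centerline path too short ({arc[-1]:.1f} mm < 5 mm)")

    # smoothing-spline fit removes residual voxel-scale jitter that a moving
    # average alone leaves in the tangents
    from scipy.interpolate import splev, splprep

    u = arc / arc[-1]
    k = min(3, len(smooth) - 1)
    tck, _ = splprep(smooth.T, u=u, s=len(smooth) * 4.0, k=k)
    u_fine = np.linspace(0.0, 1.0, max(2000, len(smooth) * 4))
    fine = np.stack(splev(u_fine, tck), axis=1)
    arc_fine = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(fine, axis=0), axis=1))]
    )
    total = arc_fine[-1]
    n_planes = int(np.floor(total / plane_spacing)) + 1
    s_new = np.linspace(0.0, total, n_planes)
    u_new = np.interp(s_new, arc_fine, u_fine)
    resampled = np.stack(splev(u_new, tck), axis=1)
    tangents = np.stack(splev(u_new, tck, der=1), axis=1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    if resampled[-1, orient_ascending_axis] < resampled[0, orient_ascending_axis]:
        resampled = resampled[::-1]
        tangents = -tangents[::-1]
    return CenterlinePlanes(points=resampled, tangents=tangents, arc_length=s_new)


def _distance_ridge(mask: np.ndarray) -> np.ndarray:
    """Voxels on the plateau of the Euclidean distance transform.

    Local maxima (3x3x3 neighborhood, plateau-tolerant) of the distance to
    the background, dilated by one voxel within the mask to keep the ridge
    connected through discrete plateaus.
    """
    from scipy import ndimage

    edt = ndimage.distance_transform_edt(mask)
    deep = edt >= 0.5 * edt.max()
    return deep & (edt >= ndimage.maximum_filter(edt, size=3) - 1e-9)


def _label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    from scipy import ndimage

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    return ndimage.label(mask, structure=structure)


def assign_voxels_to_planes(
    masks: LumenMasks, centerline: CenterlinePlanes, grid: VoxelGrid
) -> VoxelPlaneAssignment:
    """Match every TL and FL voxel to its nearest plane center.

    Nearest by Euclidean distance to the plane's centerline point; exact ties
    go to the more proximal (lower-index) plane.
    """
    lum = masks.whole
    idx = np.nonzero(lum)
    pts = np.asarray(grid.origin) + np.stack(idx, axis=1) * np.asarray(grid.spacing)
    tree = cKDTree(centerline.points)
    k = min(4, len(centerline))
    dist, cand = tree.query(pts, k=k)
    if k == 1:
        dist, cand = dist[:, None], cand[:, None]
    # proximal tie-break: among candidates within 1e-9 of the minimum
    # distance, take the smallest plane index
    tied = dist <= dist[:, :1] + 1e-9
    cand_masked = np.where(tied, cand, len(centerline))
    plane_index = cand_masked.min(axis=1)
    return VoxelPlaneAssignment(
        plane_index=plane_index,
        forward_direction=centerline.tangents[plane_index],
        voxel_indices=idx,
    )


def split_regions(
    masks: LumenMasks,
    centerline: CenterlinePlanes,
    assignment: VoxelPlaneAssignment,
    proximal_landmark_fraction: float,
    distal_landmark_fraction: float,
) -> RegionLabels:
    """Label proximal/distal TL and FL regions and the combined DAo.

    Landmarks are arc-length fractions of the centerline: the first marks the
    left-subclavian-level start of the descending TL (proximal TL region runs
    from there to the second landmark, the superior-pulmonary-vein level;
    distal TL from the second landmark onward).  The FL is bisected at the
    midpoint of its own assigned-plane arc-length range.  The combined DAo is
    the FL plus the TL distal to the first landmark.
    """
    for f in (proximal_landmark_fraction, distal_landmark_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"landmark fraction {f} outside the centerline range")
    if proximal_landmark_fraction > distal_landmark_fraction:
        raise ValueError("proximal landmark must not lie beyond the distal landmark")
    total = centerline.arc_length[-1]
    s_prox = proximal_landmark_fraction * total
    s_dist = distal_landmark_fraction * total

    s_vox = assignment.arc_length_of(centerline)
    ii = assignment.voxel_indices
    is_tl = masks.tl[ii]
    is_fl = masks.fl[ii]

    labels_flat = np.zeros(len(s_vox), dtype=np.int8)
    labels_flat[is_tl & (s_vox < s_prox)] = TL_ARCH
    labels_flat[is_tl & (s_vox >= s_prox) & (s_vox < s_dist)] = TL_PROXIMAL
    labels_flat[is_tl & (s_vox >= s_dist)] = TL_DISTAL

    if np.any(is_fl):
        s_fl = s_vox[is_fl]
        s_mid = 0.5 * (s_fl.min() + s_fl.max())
        fl_lab = np.where(s_fl < s_mid, FL_PROXIMAL, FL_DISTAL)
        labels_flat[is_fl] = fl_lab

    labels = np.zeros(masks.whole.shape, dtype=np.int8)
    labels[ii] = labels_flat
    combined = np.zeros(masks.whole.shape, dtype=bool)
    combined[ii] = is_fl | (is_tl & (s_vox >= s_prox))
    return RegionLabels(labels=labels, combined_dao=combined)
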