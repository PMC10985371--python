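"""Consensus "typical cone" shapes and per-cone taper statistics.

All crystalline cones of one eye are centered on their centers of mass,
rotated so their radial axis points along +z (proximal tip toward −z), and
overlaid on a common voxel grid.  Voxels occupied by at least a fraction
``overlap_threshold`` (default 25%) of the cones form the consensus shape —
an average 3D cone that suppresses per-cone segmentation noise.  From an
aligned shape we measure:

* **length** — z-extent times the voxel size;
* **cone ratio** — equivalent-circle diameter of the slice 10% of the length
  up from the proximal (bottom) end, divided by the maximum slice diameter
  (smaller = more sharply tapered tip);
* **aspect ratio** — maximum slice diameter divided by length.

Slice "diameter" is the equivalent-circle diameter ``2·sqrt(area/π)`` of the
slice's voxel area, which is robust to ragged voxel edges; the maximum
caliper width is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .segmentation import ConeObject

__all__ = [
    "TypicalCone",
    "BoundarySurface",
    "rotation_to_z",
    "align_cone",
    "consensus_shape",
    "surface_voxels",
    "boundary_surface",
    "cone_length",
    "slice_equivalent_diameters",
    "cone_ratio",
    "aspect_ratio",
    "per_cone_metrics",
]


@dataclass
class TypicalCone:
    """Consensus cone shape of one eye, on the canonical (axis = +z) grid."""

    consensus_voxels: np.ndarray  # (m, 3) int offsets, (x, y, z) voxel units
    boundary_points: np.ndarray  # surface voxels of the consensus set
    length_um: float
    cone_ratio: float
    aspect_ratio: float
    n_cones_overlaid: int
    overlap_threshold: float


@dataclass
class BoundarySurface:
    """Alpha-shape wrap of a voxel object: surface voxels plus a triangle mesh."""

    surface_voxels: np.ndarray  # (m, 3) int
    vertices: np.ndarray  # (p, 3) float, voxel units
    faces: np.ndarray  # (q, 3) int indices into vertices
    enclosed_volume_voxels: float  # volume of the alpha complex, in voxel³


def rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping a unit vector onto +z.

    The antipodal case (axis ≈ −z) has no unique minimal rotation; by
    convention it rotates 180° about +x.
    """
    a = np.asarray(axis, dtype=np.float64)
    nrm = np.linalg.norm(a)
    if nrm < 1e-12:
        raise ValueError("radial axis has zero norm")
    a = a / nrm
    z = np.array([0.0, 0.0, 1.0])
    c = float(a @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # 180° about +x
    k = np.cross(a, z)
    s = np.linalg.norm(k)
    k = k / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def align_cone(
    cone: ConeObject,
    radial_axis: np.ndarray,
    *,
    rotate: bool = True,
) -> np.ndarray:
    """Map a cone's voxels into the canonical frame (COM at origin, axis = +z).

    Voxel centers are translated so the center of mass is the origin, rotated
    by the minimal rotation taking the outward ``radial_axis`` to +z (so the
    proximal tip points toward −z), and resampled to the common grid by
    nearest-voxel (inverse-mapping) assignment: a canonical-grid voxel is kept
    when its center, rotated back into the source frame, falls inside an
    occupied source voxel.  This leaves no resampling holes.  Returns integer
    offsets ``(x, y, z)`` in voxel units.  With ``rotate=False`` only the
    centering is applied (plain overlay mode).
    """
    idx = np.asarray(cone.voxel_indices, dtype=np.int64)
    src = idx[:, ::-1]  # (x, y, z) integer voxel coordinates
    com = src.mean(axis=0) + 0.5  # center of mass of voxel centers
    Rm = rotation_to_z(radial_axis) if rotate else np.eye(3)

    # target bounding box from the forward-rotated source voxel centers
    rot = (src + 0.5 - com) @ Rm.T
    lo = np.floor(rot.min(axis=0)).astype(np.int64) - 1
    hi = np.ceil(rot.max(axis=0)).astype(np.int64) + 1

    smin = src.min(axis=0)
    dims = src.max(axis=0) - smin + 1
    occupied = np.zeros(dims, dtype=bool)
    occupied[tuple((src - smin).T)] = True

    grids = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    targets = np.stack(grids, axis=-1).reshape(-1, 3)
    back = targets @ Rm + com  # R is orthogonal: R.T applied via right-mult
    src_idx = np.floor(back).astype(np.int64) - smin
    inside = np.all((src_idx >= 0) & (src_idx < dims), axis=1)
    hit = np.zeros(len(targets), dtype=bool)
    hit[inside] = occupied[tuple(src_idx[inside].T)]
    return targets[hit]


def _encode(offsets: np.ndarray, lo: np.ndarray, dims: np.ndarray) -> np.ndarray:
    rel = offsets - lo
    return (rel[:, 0] * dims[1] + rel[:, 1]) * dims[2] + rel[:, 2]


def consensus_shape(
    aligned_cones: list[np.ndarray],
    overlap_threshold: float = 0.25,
    voxel_size_um: float = 1.0,
) -> TypicalCone:
    """Overlay aligned cones and keep voxels shared by ≥ threshold of them.

    The count cutoff is ``ceil(threshold × N)`` (with a floor of one cone), so
    "at least 25%" stays exact for small N: two disjoint shapes at 0.25 keep
    their union (ceil(0.5) = 1).  Raising the threshold never adds voxels, and
    N identical copies reproduce the input shape at any threshold ≤ 1.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must lie in (0, 1]")
    if len(aligned_cones) == 0:
        raise ValueError("need at least one aligned cone")
    n = len(aligned_cones)
    allpts = np.vstack(aligned_cones)
    lo = allpts.min(axis=0)
    dims = allpts.max(axis=0) - lo + 1
    codes = np.concatenate([_encode(a, lo, dims) for a in aligned_cones])
    uniq, counts = np.unique(codes, return_counts=True)
    # guard the cutoff against float artifacts like 0.1 * 10 = 1.0000000000000002
    cutoff = max(1, math.ceil(overlap_threshold * n - 1e-9))
    kept_codes = uniq[counts >= cutoff]
    x, rem = np.divmod(kept_codes, dims[1] * dims[2])
    y, z = np.divmod(rem, dims[2])
    kept = np.column_stack([x, y, z]) + lo
    return TypicalCone(
        consensus_voxels=kept,
        boundary_points=surface_voxels(kept),
        length_um=cone_length(kept, voxel_size_um),
        cone_ratio=cone_ratio(kept, voxel_size_um),
        aspect_ratio=aspect_ratio(kept, voxel_size_um),
        n_cones_overlaid=n,
        overlap_threshold=overlap_threshold,
    )


def surface_voxels(voxel_set: np.ndarray) -> np.ndarray:
    """Voxels of the set having at least one 6-neighbor outside the set."""
    vox = np.asarray(voxel_set, dtype=np.int64)
    if len(vox) == 0:
        raise ValueError("empty voxel set")
    lo = vox.min(axis=0) - 1
    dims = vox.max(axis=0) - lo + 2
    occupied = set(_encode(vox, lo, dims).tolist())
    on_surface = np.zeros(len(vox), dtype=bool)
    for axis in range(3):
        for step in (-1, 1):
            shift = np.zeros(3, dtype=np.int64)
            shift[axis] = step
            codes = _encode(vox + shift, lo, dims)
            on_surface |= np.fromiter(
                (c not in occupied for c in codes.tolist()), bool, len(vox)
            )
    return vox[on_surface]


def _tet_circumradii(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p0 = pts[tets[:, 0]]
    rhs_pts = pts[tets[:, 1:]]
    A = 2.0 * (rhs_pts - p0[:, None, :])
    b = np.sum(rhs_pts**2, axis=2) - np.sum(p0**2, axis=1)[:, None]
    det = np.linalg.det(A)
    radii = np.full(len(tets), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - p0[ok], axis=1)
    return radii


def boundary_surface(voxel_set: np.ndarray, alpha_voxels: float = 3.0) -> BoundarySurface:
    """Boundary of a voxel object: surface voxels plus an alpha-shape mesh.

    The mesh is the boundary of the alpha complex of the voxel centers
    (Delaunay tetrahedra with circumradius ≤ ``alpha_voxels``); its enclosed
    volume is the summed volume of the kept tetrahedra, which for a dense
    voxel object tracks the voxel count closely.
    """
    vox = np.asarray(voxel_set, dtype=np.float64)
    surf = surface_voxels(voxel_set)
    if len(vox) < 5:
        return BoundarySurface(surf, vox, np.empty((0, 3), dtype=int), 0.0)
    tri = Delaunay(vox)
    radii = _tet_circumradii(tri.points, tri.simplices)
    kept = tri.simplices[radii <= alpha_voxels]
    if len(kept) == 0:
        return BoundarySurface(surf, tri.points, np.empty((0, 3), dtype=int), 0.0)
    faces = np.vstack(
        [kept[:, [0, 1, 2]], kept[:, [0, 1, 3]], kept[:, [0, 2, 3]], kept[:, [1, 2, 3]]]
    )
    faces_sorted = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces_sorted, axis=0, return_counts=True)
    boundary_faces = uniq[counts == 1]
    a = tri.points[kept[:, 1]] - tri.points[kept[:, 0]]
    b = tri.points[kept[:, 2]] - tri.points[kept[:, 0]]
    c = tri.points[kept[:, 3]] - tri.points[kept[:, 0]]
    volume = float(np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))).sum() / 6.0)
    return BoundarySurface(surf, tri.points, boundary_faces, volume)


def cone_length(voxel_set: np.ndarray, voxel_size_um: float) -> float:
    """Length along the canonical axis: z-extent in voxels × voxel size."""
    z = np.asarray(voxel_set)[:, 2]
    if len(z) == 0:
        raise ValueError("empty voxel set")
    return float((z.max() - z.min() + 1) * voxel_size_um)


def slice_equivalent_diameters(
    voxel_set: np.ndarray, voxel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-z-slice equivalent-circle diameters 2·sqrt(area/π), bottom to top.

    Returns ``(z_indices, diameters_um)`` for every slice in the z-extent
    (empty slices get diameter 0).
    """
    vox = np.asarray(voxel_set, dtype=np.int64)
    z = vox[:, 2]
    zmin, zmax = int(z.min()), int(z.max())
    counts = np.bincount(z - zmin, minlength=zmax - zmin + 1)
    areas = counts * voxel_size_um**2
    diam = 2.0 * np.sqrt(areas / math.pi)
    return np.arange(zmin, zmax + 1), diam


def cone_ratio(voxel_set: np.ndarray, voxel_size_um: float = 1.0) -> float:
    """Taper statistic: slice diameter 10% up from the bottom / maximum diameter.

    The bottom is the proximal (−z) end in the canonical frame.  A cylinder
    scores 1; a cone tapering linearly to a point scores 0.10.
    """
    zs, diam = slice_equivalent_diameters(voxel_set, voxel_size_um)
    n_slices = len(zs)
    station = min(int(round(0.10 * n_slices)), n_slices - 1)
    if diam[station] == 0:
        raise ValueError(
            f"empty slice at the 10% station (z index {zs[station]})"
        )
    return float(diam[station] / diam.max())


def aspect_ratio(voxel_set: np.ndarray, voxel_size_um: float = 1.0) -> float:
    """Maximum slice equivalent diameter divided by cone length."""
    length = cone_length(voxel_set, voxel_size_um)
    if length <= 0:
        raise ValueError("cone length must be positive")
    _, diam = slice_equivalent_diameters(voxel_set, voxel_size_um)
    return float(diam.max() / length)


def per_cone_metrics(
    cones: list[ConeObject],
    axes: np.ndarray,
    voxel_size_um: float,
    *,
    rotate: bool = True,
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Length, cone ratio and aspect ratio for each individual cone.

    Cones whose alignment or slicing fails (zero-norm axis, empty station
    slice) are skipped and reported as ``(label, reason)`` pairs.
    """
    rows, failures = [], []
    for cone, axis in zip(cones, np.asarray(axes, dtype=np.float64)):
        try:
            aligned = align_cone(cone, axis, rotate=rotate)
            rows.append(
                {
                    "cone_label": cone.label,
                    "length_um": cone_length(aligned, voxel_size_um),
                    "cone_ratio": cone_ratio(aligned, voxel_size_um),
                    "aspect_ratio": aspect_ratio(aligned, voxel_size_um),
                }
            )
        except ValueError as exc:
            failures.append((cone.label, str(exc)))
    columns = ["cone_label", "length_um", "cone_ratio", "aspect_ratio"]
    return pd.DataFrame(rows, columns=columns), failures
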