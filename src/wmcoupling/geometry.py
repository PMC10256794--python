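"""Contact geometry: distances, voxel-sphere ROIs, streamline counting.

The structural network edge weight is the number of streamlines that
interconnect a pair of contact-centred sphere ROIs.  A streamline is
treated as *passing through* an ROI if any of its (densified) points
falls within the ROI radius of the contact centre — the pass-through
convention, applied symmetrically to both endpoints and interior points.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .datatypes import (
    ConnectivityMatrix,
    ContactSet,
    StreamlineSet,
    WmCouplingError,
)

__all__ = [
    "euclidean_distance_matrix",
    "sphere_offsets",
    "sphere_voxels",
    "mm_to_voxel",
    "count_streamline_connections",
    "densify_polyline",
    "GeometryError",
]

#: Default ROI radius for streamline counting: one 2 mm voxel.
DEFAULT_SC_ROI_RADIUS_MM = 2.0


class GeometryError(WmCouplingError):
    """Invalid geometric input (degenerate grid, bad neighborhood size...)."""


def euclidean_distance_matrix(contacts: ContactSet) -> ConnectivityMatrix:
    """Pairwise straight-line distances (mm) between contacts.

    Used to regress the distance confound out of every edge vector
    before coupling statistics.
    """
    if len(contacts) < 2:
        raise GeometryError("need at least 2 contacts for a distance matrix")
    d = squareform(pdist(contacts.coords))
    return ConnectivityMatrix(values=d, nodes=contacts.ids, modality="distance")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (fixed convention)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def mm_to_voxel(points_mm: np.ndarray, voxel_mm: float, grid_origin: np.ndarray) -> np.ndarray:
    """Map mm coordinates to integer voxel indices on a regular grid."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    return _round_half_away((pts - np.asarray(grid_origin, dtype=float)) / voxel_mm)


def sphere_offsets(neighborhood: int) -> np.ndarray:
    """Integer voxel offsets of a sphere ROI around its centre voxel.

    7  = centre + 6 face neighbors (radius one voxel);
    19 = centre + 6 face + 12 edge neighbors (3 mm radius at 2 mm voxels);
    27 = the full 3x3x3 cube.
    """
    if neighborhood not in (7, 19, 27):
        raise GeometryError(f"neighborhood must be 7, 19 or 27, got {neighborhood}")
    grid = np.array(
        [[dx, dy, dz] for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    )
    manhattan = np.abs(grid).sum(axis=1)
    if neighborhood == 7:
        keep = manhattan <= 1
    elif neighborhood == 19:
        keep = manhattan <= 2  # cube minus the 8 corners
    else:
        keep = np.ones(len(grid), dtype=bool)
    return grid[keep]


def sphere_voxels(
    center_mm: np.ndarray,
    neighborhood: int,
    voxel_mm: float,
    grid_origin: np.ndarray = (0.0, 0.0, 0.0),
    grid_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Voxel indices of a sphere ROI centred at ``center_mm``.

    The centre voxel is the nearest grid voxel (round-half-away-from-zero
    per axis).  If ``grid_shape`` is given, out-of-grid voxels are
    dropped with a warning (edge contacts keep their in-grid voxels; a
    contact with under half its ROI in-grid is flagged in the warning).
    """
    center = mm_to_voxel(center_mm, voxel_mm, grid_origin)[0]
    vox = center[None, :] + sphere_offsets(neighborhood)
    if grid_shape is not None:
        inside = np.all((vox >= 0) & (vox < np.asarray(grid_shape)), axis=1)
        if not inside.all():
            n_in = int(inside.sum())
            msg = f"sphere ROI at {tuple(center)}: {len(vox) - n_in} voxels outside grid"
            if n_in < len(vox) / 2:
                msg += " (fewer than half the ROI voxels are in-grid)"
            warnings.warn(msg, stacklevel=2)
            vox = vox[inside]
        if len(vox) == 0:
            raise GeometryError(f"sphere ROI at {tuple(center)} fully outside grid")
    return vox


def densify_polyline(line: np.ndarray, step_mm: float = 0.5) -> np.ndarray:
    """Insert points along each segment so consecutive points are <= step_mm apart."""
    line = np.asarray(line, dtype=float)
    out = [line[:1]]
    for a, b in zip(line[:-1], line[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n = max(1, int(np.ceil(length / step_mm)))
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a[None, :] + t * seg[None, :])
    return np.vstack(out)


def count_streamline_connections(
    streamlines: StreamlineSet,
    contacts: ContactSet,
    roi_radius_mm: float = DEFAULT_SC_ROI_RADIUS_MM,
    densify_step_mm: float | None = 0.5,
) -> ConnectivityMatrix:
    """Structural connectivity as interconnecting streamline counts.

    A streamline connects the unordered pair (i, j) when at least one of
    its points lies within ``roi_radius_mm`` of contact i and at least
    one within the radius of contact j.  Each streamline increments
    every pair it connects by exactly 1.  Polylines are densified at
    ``densify_step_mm`` before the point-in-sphere test (pass ``None``
    to test vertices only).

    An empty streamline set yields the all-zero matrix.
    """
    if not roi_radius_mm > 0:
        raise GeometryError("roi_radius_mm must be positive")
    n = len(contacts)
    sc = np.zeros((n, n))
    for line in streamlines.streamlines:
        pts = densify_polyline(line, densify_step_mm) if densify_step_mm else line
        near = cdist(pts, contacts.coords).min(axis=0) <= roi_radius_mm
        hit = np.flatnonzero(near)
        for a in range(len(hit)):
            for b in range(a + 1, len(hit)):
                sc[hit[a], hit[b]] += 1
                sc[hit[b], hit[a]] += 1
    return ConnectivityMatrix(values=sc, nodes=contacts.ids, modality="sc")
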