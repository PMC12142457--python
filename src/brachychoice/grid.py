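"""Voxel grid definition and low-level geometry primitives.

Axis convention throughout the package: array axis 0 is superior-inferior
(z), axis 1 anterior-posterior (y), axis 2 left-right (x).  World
coordinates of points are written ``(x, y, z)`` in millimetres, matching the
order used by DICOM contour data; grid attributes (``spacing``, ``shape``,
``origin``) are in array-axis order ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MalformedTandem

#: Default grid of the classifier input: 2 mm isotropic, 165 x 176 x 176
#: voxels (SI x AP x LR), i.e. a 330 x 352 x 352 mm field of view.
DEFAULT_SPACING = (2.0, 2.0, 2.0)
DEFAULT_SHAPE = (165, 176, 176)


@dataclass(frozen=True)
class GridSpec:
    """A regular voxel grid in patient (mm) coordinates.

    Parameters
    ----------
    spacing : tuple of float
        Voxel spacing (dz, dy, dx) in mm.
    shape : tuple of int
        Number of voxels along (SI, AP, LR).
    origin : tuple of float
        World coordinates (z, y, x) in mm of the *center* of voxel (0, 0, 0).
    """

    spacing: tuple = DEFAULT_SPACING
    shape: tuple = DEFAULT_SHAPE
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one array axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def z_coords(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y_coords(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def x_coords(self) -> np.ndarray:
        return self.axis_coords(2)

    def voxel_centers_xyz(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) array of voxel-center world coordinates in (x, y, z) order.

        With ``mask`` given, only centers of True voxels (C-order).
        """
        if mask is None:
            zz, yy, xx = np.meshgrid(
                self.z_coords, self.y_coords, self.x_coords, indexing="ij"
            )
            return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        idx = np.argwhere(mask)
        z = self.origin[0] + idx[:, 0] * self.spacing[0]
        y = self.origin[1] + idx[:, 1] * self.spacing[1]
        x = self.origin[2] + idx[:, 2] * self.spacing[2]
        return np.column_stack([x, y, z])

    def world_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices (z, y, x) for world points (x, y, z)."""
        pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        zyx = pts[:, ::-1]
        idx = np.rint((zyx - np.asarray(self.origin)) / np.asarray(self.spacing))
        return idx.astype(int)

    @classmethod
    def centered_on(cls, center_xyz, spacing=DEFAULT_SPACING, shape=DEFAULT_SHAPE):
        """Grid whose window center coincides with a world point (x, y, z)."""
        center_zyx = np.asarray(center_xyz, dtype=float)[::-1]
        half = (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
        return cls(tuple(spacing), tuple(shape), tuple(center_zyx - half))


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points.

    ``points`` is (N, 2); ``polygon`` is (M, 2) with M >= 3, implicitly
    closed.  A horizontal ray is cast toward +x; a point is inside when it
    crosses the boundary an odd number of times.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for xa, ya, xb, yb in zip(x1, y1, x2, y2):
        straddles = (ya > y) != (yb > y)
        if not straddles.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = xa + (y - ya) * (xb - xa) / (yb - ya)
        inside ^= straddles & (x < x_cross)
    return inside


def validate_polyline(polyline: np.ndarray, require_monotone_z: bool = True) -> np.ndarray:
    """Validate a 3D polyline in (x, y, z) mm; returns it as a float array."""
    line = np.asarray(polyline, dtype=float)
    if line.ndim != 2 or line.shape[1] != 3 or line.shape[0] < 2:
        raise MalformedTandem("tandem polyline needs >= 2 three-dimensional points")
    if not np.isfinite(line).all():
        raise MalformedTandem("tandem polyline contains non-finite coordinates")
    if require_monotone_z:
        dz = np.diff(line[:, 2])
        if not ((dz > 0).all() or (dz < 0).all()):
            raise MalformedTandem(
                "tandem points must be strictly ordered along the SI axis"
            )
    return line


def point_to_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each 3D point to a polyline.

    Closed-form point-to-segment distance, minimized over all segments.
    ``points`` is (N, 3) in (x, y, z) mm; returns (N,) distances in mm.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.zeros(0)
    line = validate_polyline(polyline, require_monotone_z=False)
    a = line[:-1]  # (S, 3)
    d = line[1:] - a  # segment vectors
    seg_len2 = (d * d).sum(axis=1)  # (S,)
    # t = clamp(<p - a, d> / |d|^2, 0, 1), per point per segment
    diff = pts[:, None, :] - a[None, :, :]  # (N, S, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nsk,sk->ns", diff, d) / seg_len2[None, :]
    t = np.nan_to_num(t)  # zero-length segments degrade to the endpoint
    t = np.clip(t, 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = ((pts[:, None, :] - closest) ** 2).sum(axis=2)
    return np.sqrt(dist2.min(axis=1))
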