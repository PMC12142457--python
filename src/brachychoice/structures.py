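"""Structure sets: reading, rasterization, and label-volume composition.

A :class:`StructureSet` holds planar closed contours (mm coordinates) for
the clinical target volumes and organs at risk, plus the digitized central
tandem polyline.  Two on-disk forms are supported: DICOM RTSTRUCT (via
pydicom) and a plain JSON contour format emitted by the phantom generator,
so that synthetic fixtures need no binary DICOM files.

Label codes in the composed volume: 0 background, 1 CTV (HR-CTV union
IR-CTV), 2 central tandem (5 mm diameter tube), 3 any OAR.  At overlapping
voxels the precedence is tandem > CTV > OAR: the tandem anchors both
distance channels and must stay visible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import (
    DegenerateContour,
    MalformedTandem,
    MissingTandem,
    MissingTarget,
)
from .grid import GridSpec, point_to_polyline_distance, points_in_polygon, validate_polyline

logger = logging.getLogger(__name__)

LABEL_BACKGROUND = 0
LABEL_CTV = 1
LABEL_TANDEM = 2
LABEL_OAR = 3

#: Default diameter (mm) of the tandem tube in the label volume.
TANDEM_DIAMETER_MM = 5.0

SYED = 1
TANDO = 0
LABEL_NAMES = {SYED: "Syed", TANDO: "T&O"}


class StructureRole(str, Enum):
    HR_CTV = "HR_CTV"
    IR_CTV = "IR_CTV"
    BLADDER = "BLADDER"
    RECTUM = "RECTUM"
    SIGMOID = "SIGMOID"
    SMALL_BOWEL = "SMALL_BOWEL"
    LARGE_BOWEL = "LARGE_BOWEL"


OAR_ROLES = (
    StructureRole.BLADDER,
    StructureRole.RECTUM,
    StructureRole.SIGMOID,
    StructureRole.SMALL_BOWEL,
    StructureRole.LARGE_BOWEL,
)

#: Institution-style structure names mapped to roles; the special value
#: "TANDEM" routes a structure's contour points to the tandem polyline.
DEFAULT_ALIASES = {
    "HR-CTV": "HR_CTV",
    "HRCTV": "HR_CTV",
    "CTV_HR": "HR_CTV",
    "HR_CTV": "HR_CTV",
    "IR-CTV": "IR_CTV",
    "IRCTV": "IR_CTV",
    "CTV_IR": "IR_CTV",
    "IR_CTV": "IR_CTV",
    "BLADDER": "BLADDER",
    "RECTUM": "RECTUM",
    "SIGMOID": "SIGMOID",
    "SMALL BOWEL": "SMALL_BOWEL",
    "SMALL_BOWEL": "SMALL_BOWEL",
    "SMALLBOWEL": "SMALL_BOWEL",
    "BOWEL_SMALL": "SMALL_BOWEL",
    "LARGE BOWEL": "LARGE_BOWEL",
    "LARGE_BOWEL": "LARGE_BOWEL",
    "LARGEBOWEL": "LARGE_BOWEL",
    "BOWEL_LARGE": "LARGE_BOWEL",
    "TANDEM": "TANDEM",
    "CENTRAL TANDEM": "TANDEM",
    "TANDEM_CENTRAL": "TANDEM",
}


@dataclass
class ContourSlice:
    """One planar closed polygon: a z plane (mm) plus (x, y) vertices (mm)."""

    z: float
    points: np.ndarray  # (M, 2)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise DegenerateContour(
                f"contour at z={self.z} has fewer than 3 vertices"
            )
        if not (np.isfinite(self.points).all() and np.isfinite(self.z)):
            raise DegenerateContour("contour has non-finite coordinates")


@dataclass
class Structure:
    name: str
    role: StructureRole
    slices: list  # list[ContourSlice]


@dataclass
class StructureSet:
    """Named contour stacks plus the tandem polyline, in physical mm."""

    patient_id: str
    insertion_id: str
    structures: list = field(default_factory=list)
    tandem: np.ndarray | None = None  # (N, 3) of (x, y, z) mm
    true_label: int | None = None  # 1 Syed, 0 T&O

    def __post_init__(self):
        if self.tandem is not None:
            self.tandem = validate_polyline(self.tandem)

    def validate(self) -> "StructureSet":
        if self.tandem is None:
            raise MissingTandem(f"{self.insertion_id}: no tandem polyline")
        validate_polyline(self.tandem)
        if not any(s.role == StructureRole.HR_CTV for s in self.structures):
            raise MissingTarget(f"{self.insertion_id}: no HR-CTV structure")
        return self

    def by_role(self, role: StructureRole) -> list:
        return [s for s in self.structures if s.role == role]

    def slices_for(self, role: StructureRole) -> list:
        out = []
        for s in self.by_role(role):
            out.extend(s.slices)
        return out


@dataclass
class LabelVolume:
    """Integer label array over a grid; codes {0, 1, 2, 3} as above."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("label array shape does not match grid")
        if not np.isin(np.unique(self.values), [0, 1, 2, 3]).all():
            raise ValueError("label codes must be within {0,1,2,3}")

    def count(self, code: int) -> int:
        return int((self.values == code).sum())

    def to_nifti(self, path) -> None:
        """Write as int16 NIfTI for visual inspection (RAS-ish affine)."""
        import nibabel as nib

        # nibabel expects (x, y, z) fastest-to-slowest; our array is (z, y, x)
        data = np.ascontiguousarray(self.values.astype(np.int16).transpose(2, 1, 0))
        affine = np.diag([self.grid.spacing[2], self.grid.spacing[1], self.grid.spacing[0], 1.0])
        affine[:3, 3] = [self.grid.origin[2], self.grid.origin[1], self.grid.origin[0]]
        nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _resolve_role(name: str, alias_table: dict) -> str | None:
    key = name.strip().upper()
    return alias_table.get(key)


def read_structure_set(path, alias_table: dict | None = None) -> StructureSet:
    """Read an RTSTRUCT or phantom-format JSON file into a StructureSet.

    ``alias_table`` maps institution-style structure names (case-insensitive)
    to role names; unrecognized structures are logged and skipped.  Raises
    :class:`MissingTarget` / :class:`MissingTandem` when the HR-CTV or the
    tandem is absent and :class:`MalformedTandem` when the tandem polyline is
    not strictly ordered along the SI axis.
    """
    path = str(path)
    aliases = dict(DEFAULT_ALIASES)
    if alias_table:
        aliases.update({k.strip().upper(): v for k, v in alias_table.items()})
    with open(path, "rb") as fh:
        head = fh.read(512)
    if head.lstrip().startswith(b"{"):
        return _read_phantom_json(path, aliases)
    return _read_rtstruct(path, aliases)


def _read_phantom_json(path, aliases) -> StructureSet:
    with open(path) as fh:
        doc = json.load(fh)
    structures = []
    for rec in doc.get("structures", []):
        role_name = rec.get("role") or _resolve_role(rec["name"], aliases)
        if role_name is None or role_name == "TANDEM":
            logger.info("skipping unrecognized structure %r", rec.get("name"))
            continue
        slices = [ContourSlice(s["z"], np.asarray(s["points"])) for s in rec["slices"]]
        structures.append(Structure(rec.get("name", role_name), StructureRole(role_name), slices))
    tandem = doc.get("tandem")
    if tandem is None:
        raise MissingTandem(f"{path}: no tandem record")
    label = doc.get("true_label")
    ss = StructureSet(
        patient_id=str(doc.get("patient_id", "")),
        insertion_id=str(doc.get("insertion_id", "")),
        structures=structures,
        tandem=np.asarray(tandem, dtype=float),
        true_label=None if label is None else int(label),
    )
    return ss.validate()


def write_structure_set(ss: StructureSet, path) -> None:
    """Write a StructureSet in the phantom JSON contour format."""
    doc = {
        "patient_id": ss.patient_id,
        "insertion_id": ss.insertion_id,
        "true_label": ss.true_label,
        "tandem": np.asarray(ss.tandem, dtype=float).tolist(),
        "structures": [
            {
                "name": s.name,
                "role": s.role.value,
                "slices": [
                    {"z": float(c.z), "points": np.asarray(c.points, dtype=float).tolist()}
                    for c in s.slices
                ],
            }
            for s in ss.structures
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _read_rtstruct(path, aliases) -> StructureSet:
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    roi_names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        roi_names[int(roi.ROINumber)] = str(roi.ROIName)
    structures = []
    tandem = None
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = roi_names.get(number, f"ROI {number}")
        role_name = _resolve_role(name, aliases)
        if role_name is None:
            logger.info("skipping unrecognized structure %r", name)
            continue
        contours = getattr(rc, "ContourSequence", [])
        if role_name == "TANDEM":
            pts = []
            for c in contours:
                data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
                pts.append(data)
            if pts:
                tandem = np.vstack(pts)
            continue
        slices = []
        for c in contours:
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if len(data) < 3:
                raise DegenerateContour(f"{name}: planar contour with <3 vertices")
            slices.append(ContourSlice(float(np.mean(data[:, 2])), data[:, :2]))
        structures.append(Structure(name, StructureRole(role_name), slices))
    if tandem is None:
        raise MissingTandem(f"{path}: no tandem structure found")
    ss = StructureSet(
        patient_id=str(getattr(ds, "PatientID", "")),
        insertion_id=str(getattr(ds, "SeriesInstanceUID", "") or getattr(ds, "SOPInstanceUID", "")),
        structures=structures,
        tandem=tandem,
    )
    return ss.validate()


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _slice_thickness(z_values: np.ndarray, grid: GridSpec) -> float:
    """Native slice spacing, estimated from the contour planes themselves."""
    uniq = np.unique(z_values)
    if len(uniq) >= 2:
        return float(np.median(np.diff(uniq)))
    return float(grid.spacing[0])


def rasterize_structure(slices, grid: GridSpec) -> np.ndarray:
    """Rasterize planar closed polygons onto a grid (boolean mask).

    A voxel is inside iff its center is inside a polygon (even-odd rule) of
    the nearest contour plane, and its center z lies within that plane's
    thickness band (half the native slice spacing above and below).
    """
    slices = list(slices)
    if not slices:
        return np.zeros(grid.shape, dtype=bool)
    for c in slices:
        if not isinstance(c, ContourSlice):
            raise TypeError("slices must be ContourSlice instances")
        if len(c.points) < 3:
            raise DegenerateContour("polygon with <3 vertices")
    z_planes = np.asarray([c.z for c in slices])
    band = _slice_thickness(z_planes, grid) / 2.0
    uniq_z = np.unique(z_planes)

    mask = np.zeros(grid.shape, dtype=bool)
    zc = grid.z_coords
    # nearest contour plane per voxel plane, then the band test
    nearest = uniq_z[np.argmin(np.abs(zc[:, None] - uniq_z[None, :]), axis=1)]
    covered = np.abs(zc - nearest) <= band + 1e-9

    xx, yy = np.meshgrid(grid.x_coords, grid.y_coords, indexing="xy")
    pts2d = np.column_stack([xx.ravel(), yy.ravel()])

    plane_cache: dict[float, np.ndarray] = {}
    for iz in np.nonzero(covered)[0]:
        z = nearest[iz]
        if z not in plane_cache:
            inside = np.zeros(len(pts2d), dtype=bool)
            for c in slices:
                if c.z == z:
                    inside |= points_in_polygon(pts2d, c.points)
            plane_cache[z] = inside.reshape(grid.shape[1], grid.shape[2])
        mask[iz] = plane_cache[z]
    return mask


def tandem_tube(tandem, grid: GridSpec, diameter: float = TANDEM_DIAMETER_MM) -> np.ndarray:
    """Voxels whose centers lie within ``diameter / 2`` of the tandem polyline."""
    line = validate_polyline(tandem, require_monotone_z=False)
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    radius = diameter / 2.0
    # restrict to a bounding box around the polyline for speed
    lo = line.min(axis=0) - radius - 1e-9  # (x, y, z)
    hi = line.max(axis=0) + radius + 1e-9
    zi = np.nonzero((grid.z_coords >= lo[2]) & (grid.z_coords <= hi[2]))[0]
    yi = np.nonzero((grid.y_coords >= lo[1]) & (grid.y_coords <= hi[1]))[0]
    xi = np.nonzero((grid.x_coords >= lo[0]) & (grid.x_coords <= hi[0]))[0]
    mask = np.zeros(grid.shape, dtype=bool)
    if len(zi) == 0 or len(yi) == 0 or len(xi) == 0:
        return mask
    zz, yy, xx = np.meshgrid(
        grid.z_coords[zi], grid.y_coords[yi], grid.x_coords[xi], indexing="ij"
    )
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dist = point_to_polyline_distance(pts, line)
    sub = (dist <= radius + 1e-12).reshape(len(zi), len(yi), len(xi))
    mask[np.ix_(zi, yi, xi)] = sub
    return mask


def compose_label_volume(
    ctv_masks, tandem_mask: np.ndarray, oar_masks, grid: GridSpec
) -> LabelVolume:
    """Combine structure masks into the coded label volume.

    ``ctv_masks`` is an iterable of CTV masks (HR-CTV and, when present,
    IR-CTV) that are unioned; precedence at overlaps is tandem(2) > CTV(1)
    > OAR(3) > background.
    """
    ctv_masks = list(ctv_masks)
    if not ctv_masks:
        raise MissingTarget("no CTV mask supplied")
    ctv = np.zeros(grid.shape, dtype=bool)
    for m in ctv_masks:
        if m.shape != tuple(grid.shape):
            raise ValueError("all masks must share the grid")
        ctv |= m
    if not ctv.any():
        raise MissingTarget("CTV union is empty")
    values = np.zeros(grid.shape, dtype=np.uint8)
    for m in oar_masks:
        if m.shape != tuple(grid.shape):
            raise ValueError("all masks must share the grid")
        values[m] = LABEL_OAR
    values[ctv] = LABEL_CTV
    if tandem_mask is not None:
        if tandem_mask.shape != tuple(grid.shape):
            raise ValueError("all masks must share the grid")
        values[tandem_mask] = LABEL_TANDEM
    return LabelVolume(grid, values)


def resample_and_crop(masks: dict, native: GridSpec, target: GridSpec) -> dict:
    """Nearest-neighbor resample boolean masks from one grid onto another.

    Labels are categorical, so nearest-neighbor lookup at each target voxel
    center is used.  Target voxels mapping outside the native array are
    background.  When a structure loses voxels (it extends beyond the target
    window) a warning reports the count.
    """
    # nearest native index along each target axis
    idx = []
    valid = []
    for axis in range(3):
        coords = target.axis_coords(axis)
        i = np.rint((coords - native.origin[axis]) / native.spacing[axis]).astype(int)
        ok = (i >= 0) & (i < native.shape[axis])
        idx.append(np.clip(i, 0, native.shape[axis] - 1))
        valid.append(ok)
    inside = (
        valid[0][:, None, None] & valid[1][None, :, None] & valid[2][None, None, :]
    )
    out = {}
    for name, mask in masks.items():
        if mask.shape != tuple(native.shape):
            raise ValueError("mask shape does not match native grid")
        res = mask[np.ix_(idx[0], idx[1], idx[2])] & inside
        # voxel loss check in world space: native voxels outside the window
        lost = _voxels_outside_window(mask, native, target)
        if lost:
            warnings.warn(
                f"structure {name!r}: {lost} native voxels fall outside the "
                f"target window and were truncated",
                stacklevel=2,
            )
        out[name] = res
    return out


def _voxels_outside_window(mask: np.ndarray, native: GridSpec, target: GridSpec) -> int:
    if not mask.any():
        return 0
    idx = np.argwhere(mask)
    count = 0
    for axis in range(3):
        coords = native.origin[axis] + idx[:, axis] * native.spacing[axis]
        lo = target.origin[axis] - target.spacing[axis] / 2.0
        hi = (
            target.origin[axis]
            + (target.shape[axis] - 1 + 0.5) * target.spacing[axis]
        )
        outside = (coords < lo) | (coords > hi)
        idx = idx[~outside]
        count += int(outside.sum())
    return count


def tandem_centroid(tandem) -> np.ndarray:
    """Mean of the tandem polyline vertices, (x, y, z) mm."""
    return np.asarray(tandem, dtype=float).mean(axis=0)


def grid_for_structure_set(
    ss: StructureSet, spacing=None, shape=None
) -> GridSpec:
    """The input grid: the default window centered on the tandem centroid."""
    from .grid import DEFAULT_SHAPE, DEFAULT_SPACING

    return GridSpec.centered_on(
        tandem_centroid(ss.tandem),
        spacing=spacing or DEFAULT_SPACING,
        shape=shape or DEFAULT_SHAPE,
    )


def label_volume_from_structure_set(
    ss: StructureSet,
    grid: GridSpec | None = None,
    tandem_diameter: float = TANDEM_DIAMETER_MM,
) -> LabelVolume:
    """End-to-end: rasterize every structure and compose the label volume.

    The grid defaults to the standard window centered on the tandem
    centroid, which registers every insertion the same way.
    """
    ss.validate()
    if grid is None:
        grid = grid_for_structure_set(ss)
    ctv_masks = [rasterize_structure(ss.slices_for(StructureRole.HR_CTV), grid)]
    ir = ss.slices_for(StructureRole.IR_CTV)
    if ir:
        ctv_masks.append(rasterize_structure(ir, grid))
    oar_masks = []
    for role in OAR_ROLES:
        slices = ss.slices_for(role)
        if slices:
            oar_masks.append(rasterize_structure(slices, grid))
    tube = tandem_tube(ss.tandem, grid, diameter=tandem_diameter)
    return compose_label_volume(ctv_masks, tube, oar_masks, grid)
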