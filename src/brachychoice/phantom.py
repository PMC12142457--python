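"""Synthetic pelvic anatomies with a known geometric applicator label.

Institutional brachytherapy contour data cannot be shared, so this module
generates parametric stand-ins: a near-vertical, slightly bowed central
tandem; a CTV built from one to three ellipsoids of controllable volume
(roughly 20-120 cc), lateral extent and left-right asymmetry; and OAR
bodies placed anatomically (bladder anterior, rectum posterior, sigmoid
superior, bowel lateral/superior) at controllable gaps from the CTV.

The ground-truth applicator label is a deterministic geometric rule on the
*generating parameters* (never the rasterization): an insertion calls for
the interstitial Syed applicator when the analytic maximal lateral
extension exceeds ``l_max``, the maximal per-slice center-of-mass offset
exceeds ``delta``, or the CTV volume exceeds ``v_max`` — the same
size/extent/asymmetry considerations that drive the clinical choice (e.g.
the guideline that intracavitary applicators suit tumors smaller than
about 4 x 3 x 3 cm).  Labels are therefore noiseless, which makes
label-recovery by the downstream pipeline a clean end-to-end check; an
optional label-flip rate can emulate physician variability.

Scene coordinates: the tandem base sits at the origin with z superior,
y posterior, x patient-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from shapely.ops import unary_union

from .errors import PhantomError
from .features import _axis_points_at
from .structures import (
    SYED,
    TANDO,
    ContourSlice,
    Structure,
    StructureRole,
    StructureSet,
)

_ANALYTIC_DZ = 0.5  # mm, z step of the analytic slice integration
_ELLIPSE_PTS = 96


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (x, y, z) mm, semi-axes (ax, ay, az) mm."""

    center: tuple
    semi_axes: tuple

    def cross_section(self, z: float):
        """Shapely ellipse of the z cross-section, or None when z misses it."""
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        t = (z - cz) / az
        if abs(t) >= 1.0:
            return None
        s = np.sqrt(1.0 - t * t)
        theta = np.linspace(0.0, 2 * np.pi, _ELLIPSE_PTS, endpoint=False)
        pts = np.column_stack(
            [cx + s * ax * np.cos(theta), cy + s * ay * np.sin(theta)]
        )
        return sgeom.Polygon(pts)

    @property
    def volume_mm3(self) -> float:
        ax, ay, az = self.semi_axes
        return 4.0 / 3.0 * np.pi * ax * ay * az

    @property
    def z_range(self) -> tuple:
        return self.center[2] - self.semi_axes[2], self.center[2] + self.semi_axes[2]


@dataclass(frozen=True)
class RuleThresholds:
    """Syed iff lateral extension > l_max OR asymmetry > delta OR volume > v_max."""

    l_max_mm: float = 30.0
    delta_mm: float = 8.0
    v_max_cc: float = 60.0

    def __post_init__(self):
        if min(self.l_max_mm, self.delta_mm, self.v_max_cc) <= 0:
            raise ValueError("rule thresholds must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one synthetic insertion."""

    ctv_components: tuple  # tuple[Ellipsoid, ...], 1-3 entries
    oars: dict = field(default_factory=dict)  # StructureRole -> Ellipsoid
    tandem_length_mm: float = 60.0
    tandem_bow_mm: float = 2.0
    rule: RuleThresholds = RuleThresholds()
    noise_mm: float = 1.0
    slice_spacing_mm: float = 2.5
    label_flip_rate: float = 0.0

    def __post_init__(self):
        if not 1 <= len(self.ctv_components) <= 3:
            raise ValueError("CTV is a union of 1-3 ellipsoids")
        if self.tandem_length_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("dimensions must be positive")
        if self.noise_mm < 0 or not 0 <= self.label_flip_rate <= 1:
            raise ValueError("invalid noise settings")


def _tandem_polyline(spec: PhantomSpec, n_points: int = 9) -> np.ndarray:
    """Near-vertical tandem with a quadratic lateral bow, base at the origin."""
    z = np.linspace(0.0, spec.tandem_length_mm, n_points)
    u = z / spec.tandem_length_mm
    x = spec.tandem_bow_mm * 4.0 * u * (1.0 - u)
    return np.column_stack([x, np.zeros_like(z), z])


# ---------------------------------------------------------------------------
# analytic rule quantities
# ---------------------------------------------------------------------------


def _union_cross_section(components, z: float):
    polys = [p for p in (c.cross_section(z) for c in components) if p is not None]
    if not polys:
        return None
    return unary_union(polys)


def analytic_ctv_measures(spec: PhantomSpec) -> dict:
    """Volume, maximal lateral extension and maximal COM offset of the CTV.

    Computed by dense (0.5 mm) slice integration of the exact parametric
    cross-sections — independent of any rasterization.
    """
    tandem = _tandem_polyline(spec)
    z_lo = min(c.z_range[0] for c in spec.ctv_components)
    z_hi = max(c.z_range[1] for c in spec.ctv_components)
    zs = np.arange(z_lo + _ANALYTIC_DZ / 2, z_hi, _ANALYTIC_DZ)
    axis_xy = _axis_points_at(tandem, zs)
    volume = 0.0
    lat_max = 0.0
    com_max = 0.0
    for z, axy in zip(zs, axis_xy):
        poly = _union_cross_section(spec.ctv_components, z)
        if poly is None or poly.is_empty:
            continue
        volume += poly.area * _ANALYTIC_DZ
        geoms = getattr(poly, "geoms", [poly])
        verts = np.vstack([np.asarray(g.exterior.coords) for g in geoms])
        lat_max = max(lat_max, float(np.sqrt(((verts - axy) ** 2).sum(axis=1)).max()))
        c = poly.centroid
        com_max = max(com_max, float(np.hypot(c.x - axy[0], c.y - axy[1])))
    return {
        "volume_cc": volume / 1000.0,
        "lat_ext_max_mm": lat_max,
        "com_offset_max_mm": com_max,
    }


def rule_label(measures: dict, rule: RuleThresholds) -> int:
    syed = (
        measures["lat_ext_max_mm"] > rule.l_max_mm
        or measures["com_offset_max_mm"] > rule.delta_mm
        or measures["volume_cc"] > rule.v_max_cc
    )
    return SYED if syed else TANDO


# ---------------------------------------------------------------------------
# contour sampling
# ---------------------------------------------------------------------------


def _jitter_polygon(verts: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth radial perturbation of a closed polygon (low-order Fourier)."""
    if amplitude <= 0:
        return verts
    center = verts.mean(axis=0)
    rel = verts - center
    r = np.sqrt((rel**2).sum(axis=1))
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    bump = np.zeros(len(verts))
    for order in (2, 3, 4):
        a, b = rng.normal(size=2)
        bump += a * np.cos(order * theta) + b * np.sin(order * theta)
    bump *= amplitude / max(np.abs(bump).max(), 1e-12)
    scale = np.maximum((r + bump) / np.maximum(r, 1e-9), 0.05)
    return center + rel * scale[:, None]


def _contours_of(components, spec: PhantomSpec, rng) -> list:
    z_lo = min(c.z_range[0] for c in components)
    z_hi = max(c.z_range[1] for c in components)
    dz = spec.slice_spacing_mm
    # planes aligned to the slice grid, first plane at least half a slice in
    z0 = (np.floor(z_lo / dz) + 1) * dz
    slices = []
    for z in np.arange(z0, z_hi, dz):
        poly = _union_cross_section(components, z)
        if poly is None or poly.is_empty:
            continue
        for g in getattr(poly, "geoms", [poly]):
            verts = np.asarray(g.exterior.coords)[:-1]
            if len(verts) < 3:
                continue
            verts = _jitter_polygon(verts, spec.noise_mm, rng)
            slices.append(ContourSlice(float(z), verts))
    return slices


def _check_feasible(spec: PhantomSpec) -> None:
    tandem = _tandem_polyline(spec)
    for role, e in spec.oars.items():
        z_lo, z_hi = e.z_range
        if z_hi < 0.0 or z_lo > spec.tandem_length_mm:
            continue  # clear of the physical tandem altogether
        z = float(np.clip(e.center[2], max(z_lo, 0.0), min(z_hi, spec.tandem_length_mm)))
        axy = _axis_points_at(tandem, np.array([z]))[0]
        # the tandem itself must not pierce the OAR
        dx = (axy[0] - e.center[0]) / e.semi_axes[0]
        dy = (axy[1] - e.center[1]) / e.semi_axes[1]
        if dx * dx + dy * dy < 1.0:
            raise PhantomError(f"OAR {role} overlaps the tandem axis")


# ---------------------------------------------------------------------------
# single phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomResult:
    structure_set: StructureSet
    analytics: dict
    spec: PhantomSpec

    @property
    def true_label(self) -> int:
        return self.structure_set.true_label


def generate_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    patient_id: str = "phantom",
    insertion_id: str = "1",
) -> PhantomResult:
    """Sample one structure set from a phantom spec.

    The true label comes from the analytic rule on the generating
    parameters; the contours carry the surface jitter.
    """
    rng = rng or np.random.default_rng(0)
    _check_feasible(spec)
    tandem = _tandem_polyline(spec)
    structures = [
        Structure("HR-CTV", StructureRole.HR_CTV, _contours_of(spec.ctv_components, spec, rng))
    ]
    for role, ellipsoid in spec.oars.items():
        role = StructureRole(role)
        structures.append(
            Structure(role.value.title(), role, _contours_of((ellipsoid,), spec, rng))
        )
    measures = analytic_ctv_measures(spec)
    label = rule_label(measures, spec.rule)
    if spec.label_flip_rate > 0 and rng.random() < spec.label_flip_rate:
        label = 1 - label
    ss = StructureSet(
        patient_id=patient_id,
        insertion_id=insertion_id,
        structures=structures,
        tandem=tandem,
        true_label=label,
    ).validate()
    return PhantomResult(ss, measures, spec)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_OAR_SIZES = {
    StructureRole.BLADDER: (32.0, 22.0, 24.0),
    StructureRole.RECTUM: (14.0, 12.0, 32.0),
    StructureRole.SIGMOID: (17.0, 14.0, 18.0),
    StructureRole.SMALL_BOWEL: (24.0, 18.0, 16.0),
    StructureRole.LARGE_BOWEL: (16.0, 14.0, 22.0),
}


def _semi_axes_for_volume(volume_cc: float, r_y: float, r_x: float) -> tuple:
    """Semi-axes (ax, ay, az) of an ellipsoid of given volume and aspect."""
    az = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi * r_y * r_x)) ** (1.0 / 3.0)
    return (r_x * az, r_y * az, az)


def _sample_ctv(regime: int, rng: np.random.Generator) -> tuple:
    """CTV components for one patient; regime 1 = Syed-like, 0 = T&O-like.

    T&O-like anatomies are small (20-38 cc), nearly coaxial and laterally
    contained; Syed-like anatomies trigger the rule through one of three
    mechanisms — bulk volume, lateral asymmetry, or wide lateral extension —
    each with a margin well beyond the per-insertion jitter so the intended
    class is stable within a patient.
    """
    if regime == TANDO:
        volume = rng.uniform(20.0, 38.0)
        r_y = rng.uniform(0.70, 0.90)
        r_x = rng.uniform(0.70, 0.90)
        ax, ay, az = _semi_axes_for_volume(volume, r_y, r_x)
        # keep extension comfortably under the 30 mm threshold
        cap = 20.0
        if ax > cap:
            f = cap / ax
            ay *= f**0.5
            az /= f**1.5  # preserve the volume
            ax = cap
        offset = (rng.uniform(-2.5, 2.5), rng.uniform(-2.0, 2.0))
    else:
        mechanism = rng.integers(3)
        if mechanism == 0:  # bulk volume
            volume = rng.uniform(75.0, 110.0)
            ax, ay, az = _semi_axes_for_volume(volume, rng.uniform(0.75, 0.9), rng.uniform(0.75, 0.9))
            offset = (rng.uniform(-4.0, 4.0), rng.uniform(-2.0, 2.0))
        elif mechanism == 1:  # lateral asymmetry
            volume = rng.uniform(25.0, 45.0)
            ax, ay, az = _semi_axes_for_volume(volume, rng.uniform(0.7, 0.9), rng.uniform(0.7, 0.9))
            side = 1 if rng.random() < 0.5 else -1
            offset = (side * rng.uniform(14.0, 18.0), rng.uniform(-2.0, 2.0))
        else:  # wide lateral extension
            ax = rng.uniform(36.0, 44.0)
            ay = rng.uniform(12.0, 16.0)
            az = rng.uniform(16.0, 22.0)
            offset = (rng.uniform(-3.0, 3.0), rng.uniform(-2.0, 2.0))
    cz = rng.uniform(30.0, 38.0)
    main = Ellipsoid((offset[0], offset[1], cz), (ax, ay, az))
    components = [main]
    if rng.random() < 0.3:  # a contained satellite lobe
        sat_axes = tuple(a * rng.uniform(0.25, 0.4) for a in main.semi_axes)
        sat_center = tuple(
            c + rng.uniform(-0.4, 0.4) * a
            for c, a in zip(main.center, main.semi_axes)
        )
        components.append(Ellipsoid(sat_center, sat_axes))
    return tuple(components)


def _place_oars(ctv_main: Ellipsoid, rng: np.random.Generator) -> dict:
    cx, cy, cz = ctv_main.center
    ax, ay, az = ctv_main.semi_axes
    oars = {}

    def ellip(role, center):
        return Ellipsoid(center, _OAR_SIZES[role])

    gap = lambda lo, hi: rng.uniform(lo, hi)  # noqa: E731
    b = _OAR_SIZES[StructureRole.BLADDER]
    oars[StructureRole.BLADDER] = ellip(
        StructureRole.BLADDER, (cx * 0.3, cy - ay - gap(5, 12) - b[1], cz + rng.uniform(-5, 5))
    )
    r = _OAR_SIZES[StructureRole.RECTUM]
    oars[StructureRole.RECTUM] = ellip(
        StructureRole.RECTUM, (cx * 0.3, cy + ay + gap(5, 12) + r[1], cz - rng.uniform(0, 10))
    )
    s = _OAR_SIZES[StructureRole.SIGMOID]
    # superior to both the CTV and the tandem tip (the tandem pokes above
    # a small CTV into the uterine fundus region)
    sig_base = max(cz + az, 62.0)
    oars[StructureRole.SIGMOID] = ellip(
        StructureRole.SIGMOID,
        (cx * 0.3, cy + rng.uniform(0, 10), sig_base + gap(8, 16) + s[2]),
    )
    sb = _OAR_SIZES[StructureRole.SMALL_BOWEL]
    side = 1 if rng.random() < 0.5 else -1
    oars[StructureRole.SMALL_BOWEL] = ellip(
        StructureRole.SMALL_BOWEL,
        (cx + side * (ax + gap(8, 16) + sb[0]), cy - rng.uniform(0, 8), cz + rng.uniform(0, 15)),
    )
    lb = _OAR_SIZES[StructureRole.LARGE_BOWEL]
    oars[StructureRole.LARGE_BOWEL] = ellip(
        StructureRole.LARGE_BOWEL,
        (cx - side * (ax + gap(8, 16) + lb[0]), cy + rng.uniform(-5, 5), cz + rng.uniform(5, 15)),
    )
    return oars


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Small per-insertion perturbation of a patient's base anatomy (<= ~3 mm)."""

    def jitter_ellipsoid(e: Ellipsoid) -> Ellipsoid:
        center = tuple(c + rng.uniform(-1.5, 1.5) for c in e.center)
        semi = tuple(max(a * rng.uniform(0.95, 1.05), 2.0) for a in e.semi_axes)
        return Ellipsoid(center, semi)

    return replace(
        spec,
        ctv_components=tuple(jitter_ellipsoid(c) for c in spec.ctv_components),
        oars={role: jitter_ellipsoid(e) for role, e in spec.oars.items()},
    )


@dataclass
class SyntheticCohort:
    """Patients with correlated insertions and rule-derived labels."""

    results: list  # list[list[PhantomResult]] grouped by patient
    seed: int

    @property
    def insertions(self) -> list:
        return [r for patient in self.results for r in patient]

    @property
    def structure_sets(self) -> list:
        return [r.structure_set for r in self.insertions]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([r.true_label for r in self.insertions])

    @property
    def syed_fraction(self) -> float:
        return float(self.labels.mean())

    def manifest(self) -> pd.DataFrame:
        rows = []
        for r in self.insertions:
            ss = r.structure_set
            rows.append(
                {
                    "patient_id": ss.patient_id,
                    "insertion_id": ss.insertion_id,
                    "label": ss.true_label,
                    **{k: round(v, 3) for k, v in r.analytics.items()},
                }
            )
        return pd.DataFrame(rows)


def generate_cohort(
    n_patients: int,
    syed_fraction: float = 0.4,
    insertions_per_patient=2,
    seed: int = 0,
    rule: RuleThresholds = RuleThresholds(),
    noise_mm: float = 1.0,
    slice_spacing_mm: float = 2.5,
    label_flip_rate: float = 0.0,
) -> SyntheticCohort:
    """Reproducible synthetic cohort.

    ``insertions_per_patient`` is an int or an inclusive (low, high) range;
    insertions of one patient are jittered copies of a shared base anatomy
    (surface perturbations of a few mm), so patient-grouped CV leakage is
    meaningful to test.  ``syed_fraction`` steers the class mix through the
    sampling regime; labels themselves always come from the rule.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if not 0 < syed_fraction < 1:
        raise ValueError("syed_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    patients = []
    for pi in range(n_patients):
        regime = SYED if rng.random() < syed_fraction else TANDO
        components = _sample_ctv(regime, rng)
        base = PhantomSpec(
            ctv_components=components,
            oars=_place_oars(components[0], rng),
            tandem_bow_mm=rng.uniform(0.5, 2.0),
            rule=rule,
            noise_mm=noise_mm,
            slice_spacing_mm=slice_spacing_mm,
            label_flip_rate=label_flip_rate,
        )
        if isinstance(insertions_per_patient, int):
            n_ins = insertions_per_patient
        else:
            lo, hi = insertions_per_patient
            n_ins = int(rng.integers(lo, hi + 1))
        records = []
        for ii in range(n_ins):
            spec_i = _jitter_spec(base, rng)
            records.append(
                generate_phantom(
                    spec_i, rng, patient_id=f"P{pi:03d}", insertion_id=f"P{pi:03d}-{ii + 1}"
                )
            )
        patients.append(records)
    return SyntheticCohort(patients, seed)
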