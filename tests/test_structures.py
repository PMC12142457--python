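"""Structure-set reading, rasterization and label-volume composition."""

import numpy as np
import pytest
import shapely.geometry as sgeom

from brachychoice.errors import (
    DegenerateContour,
    MalformedTandem,
    MissingTandem,
    MissingTarget,
)
from brachychoice.grid import GridSpec, points_in_polygon
from brachychoice.structures import (
    LABEL_CTV,
    LABEL_OAR,
    LABEL_TANDEM,
    ContourSlice,
    Structure,
    StructureRole,
    StructureSet,
    compose_label_volume,
    rasterize_structure,
    read_structure_set,
    resample_and_crop,
    tandem_tube,
    write_structure_set,
)

from conftest import circle_contour, random_star_polygon, square_contour


class TestPointInPolygon:
    def test_matches_shapely_on_random_star_polygons(self, rng):
        """Even-odd containment agrees with an independent geometry library."""
        for _ in range(30):
            poly = random_star_polygon(rng, int(rng.integers(3, 13)))
            pts = rng.uniform(-25, 25, size=(200, 2))
            ours = points_in_polygon(pts, poly)
            shp = sgeom.Polygon(poly)
            theirs = np.array([shp.contains(sgeom.Point(p)) for p in pts])
            # points essentially on the boundary are legitimately ambiguous
            dist = np.array([shp.exterior.distance(sgeom.Point(p)) for p in pts])
            interior = dist > 1e-9
            assert (ours[interior] == theirs[interior]).all()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            points_in_polygon(np.zeros((1, 2)), np.array([[0, 0], [1, 1]]))


class TestRasterize:
    def test_square_counts_25_voxels(self):
        """10x10 mm square on a 2 mm grid with centers at odd mm: 5x5 inside."""
        grid = GridSpec(spacing=(2.0, 2.0, 2.0), shape=(1, 10, 10), origin=(0.0, 1.0, 1.0))
        contour = ContourSlice(0.0, np.array([[0, 0], [10, 0], [10, 10], [0, 10.0]]))
        mask = rasterize_structure([contour], grid)
        assert mask.sum() == 25

    def test_circle_area_within_5_percent(self):
        grid = GridSpec(spacing=(2.0, 2.0, 2.0), shape=(1, 40, 40), origin=(0.0, -39.0, -39.0))
        mask = rasterize_structure([circle_contour(0.0, 20.0)], grid)
        area = mask.sum() * 4.0  # mm^2 per in-plane voxel
        assert abs(area - np.pi * 400) / (np.pi * 400) < 0.05

    def test_two_vertex_contour_rejected(self):
        with pytest.raises(DegenerateContour):
            ContourSlice(0.0, np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_matches_even_odd_oracle_at_voxel_centers(self, rng):
        """Voxel membership equals the per-center oracle for random polygons."""
        grid = GridSpec(spacing=(2.0, 2.5, 2.5), shape=(4, 24, 24), origin=(-3.0, -29.0, -29.0))
        for _ in range(20):
            poly = random_star_polygon(rng, int(rng.integers(3, 13)))
            slices = [ContourSlice(z, poly) for z in (-2.0, 0.0, 2.0)]
            mask = rasterize_structure(slices, grid)
            shp = sgeom.Polygon(poly)
            for zi in range(grid.shape[0]):
                plane_covered = abs(grid.z_coords[zi]) <= 3.0  # band = spacing/2 = 1
                for yi in range(0, grid.shape[1], 5):
                    for xi in range(0, grid.shape[2], 5):
                        p = sgeom.Point(grid.x_coords[xi], grid.y_coords[yi])
                        if shp.exterior.distance(p) < 1e-6:
                            continue
                        expected = plane_covered and shp.contains(p)
                        assert mask[zi, yi, xi] == expected

    def test_slice_band_excludes_far_planes(self):
        """Voxels more than half a slice spacing from any contour stay 0."""
        grid = GridSpec(spacing=(2.0, 2.0, 2.0), shape=(10, 12, 12), origin=(-9.0, -11.0, -11.0))
        mask = rasterize_structure([square_contour(0.0, half=8.0)], grid)
        filled_planes = np.nonzero(mask.any(axis=(1, 2)))[0]
        # single slice: band defaults to +/- half the grid z spacing
        assert (np.abs(grid.z_coords[filled_planes]) <= 1.0 + 1e-9).all()


class TestTandemTube:
    def test_straight_tube_is_inplane_disc(self, small_grid, straight_tandem):
        mask = tandem_tube(straight_tandem, small_grid, diameter=5.0)
        yy, xx = np.meshgrid(small_grid.y_coords, small_grid.x_coords, indexing="ij")
        disc = np.sqrt(yy**2 + xx**2) <= 2.5
        zz_in = (small_grid.z_coords >= -20) & (small_grid.z_coords <= 20)
        expected = zz_in[:, None, None] & disc[None]
        assert (mask == expected).all()

    def test_zero_diameter_keeps_only_centers_on_the_line(self, small_grid):
        tandem = np.array([[-1.0, -1.0, -15.0], [-1.0, -1.0, 15.0]])
        mask = tandem_tube(tandem, small_grid, diameter=0.0)
        centers = small_grid.voxel_centers_xyz(mask)
        assert mask.sum() > 0
        assert np.allclose(centers[:, :2], [-1.0, -1.0])

    def test_bent_polyline_matches_bruteforce_membership(self, rng):
        """Tube membership equals exhaustive per-segment distance checks."""
        grid = GridSpec(spacing=(3.0, 3.0, 3.0), shape=(12, 12, 12), origin=(-16.0, -16.0, -16.0))
        for _ in range(10):
            n = int(rng.integers(2, 7))
            z = np.sort(rng.uniform(-15, 15, n))
            z += np.linspace(0, 1e-6, n)
            line = np.column_stack([rng.uniform(-8, 8, n), rng.uniform(-8, 8, n), z])
            radius = rng.uniform(2.0, 6.0)
            mask = tandem_tube(line, grid, diameter=2 * radius)
            centers = grid.voxel_centers_xyz()
            # brute force: explicit per-segment point distance
            expected = np.zeros(len(centers), dtype=bool)
            for p_idx, p in enumerate(centers):
                best = np.inf
                for a, b in zip(line[:-1], line[1:]):
                    d = b - a
                    t = np.clip(np.dot(p - a, d) / np.dot(d, d), 0, 1)
                    best = min(best, np.linalg.norm(p - (a + t * d)))
                expected[p_idx] = best <= radius + 1e-12
            assert (mask.ravel() == expected).all()

    def test_single_point_polyline_rejected(self, small_grid):
        with pytest.raises(MalformedTandem):
            tandem_tube(np.array([[0.0, 0.0, 0.0]]), small_grid)


class TestCompose:
    def _masks(self, grid):
        ctv = np.zeros(grid.shape, dtype=bool)
        ctv[4:10, 4:10, 4:10] = True
        tube = np.zeros(grid.shape, dtype=bool)
        tube[2:12, 7, 7] = True
        oar = np.zeros(grid.shape, dtype=bool)
        oar[6:14, 8:14, 2:8] = True
        return ctv, tube, oar

    def test_precedence_tandem_over_ctv_over_oar(self, small_grid):
        ctv, tube, oar = self._masks(small_grid)
        vol = compose_label_volume([ctv], tube, [oar], small_grid)
        assert (vol.values[tube] == LABEL_TANDEM).all()
        assert (vol.values[ctv & ~tube] == LABEL_CTV).all()
        assert (vol.values[oar & ~ctv & ~tube] == LABEL_OAR).all()

    def test_oar_permutation_invariance(self, small_grid, rng):
        ctv, tube, oar = self._masks(small_grid)
        oar2 = np.roll(oar, 3, axis=0)
        a = compose_label_volume([ctv], tube, [oar, oar2], small_grid)
        b = compose_label_volume([ctv], tube, [oar2, oar], small_grid)
        assert (a.values == b.values).all()

    def test_disjoint_counts_add_up(self, small_grid):
        ctv = np.zeros(small_grid.shape, dtype=bool)
        ctv[1:3, 1:3, 1:3] = True
        tube = np.zeros(small_grid.shape, dtype=bool)
        tube[5:7, 5:7, 5:7] = True
        oar = np.zeros(small_grid.shape, dtype=bool)
        oar[10:14, 10:14, 10:14] = True
        vol = compose_label_volume([ctv], tube, [oar], small_grid)
        assert vol.count(LABEL_CTV) == ctv.sum()
        assert vol.count(LABEL_TANDEM) == tube.sum()
        assert vol.count(LABEL_OAR) == oar.sum()

    def test_empty_ctv_union_rejected(self, small_grid):
        empty = np.zeros(small_grid.shape, dtype=bool)
        tube = empty.copy()
        tube[5, 5, 5] = True
        with pytest.raises(MissingTarget):
            compose_label_volume([empty], tube, [], small_grid)


class TestResample:
    def test_identity_on_matching_grids(self, small_grid, rng):
        mask = rng.random(small_grid.shape) > 0.5
        out = resample_and_crop({"m": mask}, small_grid, small_grid)
        assert (out["m"] == mask).all()

    def test_cuboid_volume_preserved_from_finer_grid(self):
        native = GridSpec(spacing=(1.0, 1.0, 1.0), shape=(40, 40, 40), origin=(-19.5, -19.5, -19.5))
        target = GridSpec(spacing=(2.0, 2.0, 2.0), shape=(20, 20, 20), origin=(-19.0, -19.0, -19.0))
        mask = np.zeros(native.shape, dtype=bool)
        # 20 x 16 x 12 mm cuboid
        mask[10:30, 12:28, 14:26] = True
        out = resample_and_crop({"m": mask}, native, target)["m"]
        vol_native = mask.sum() * native.voxel_volume_mm3
        vol_target = out.sum() * target.voxel_volume_mm3
        # within one voxel shell of the analytic volume
        shell = 2 * (20 * 16 + 16 * 12 + 20 * 12) * 2.0
        assert abs(vol_target - vol_native) <= shell

    def test_structure_outside_window_warns_and_empties(self, small_grid):
        native = small_grid
        target = GridSpec(spacing=(2.0, 2.0, 2.0), shape=(4, 4, 4), origin=(200.0, 200.0, 200.0))
        mask = np.zeros(native.shape, dtype=bool)
        mask[3:5, 3:5, 3:5] = True
        with pytest.warns(UserWarning, match="outside the target window"):
            out = resample_and_crop({"m": mask}, native, target)
        assert not out["m"].any()


class TestReadWrite:
    def test_phantom_json_round_trip(self, simple_structure_set, tmp_path):
        path = tmp_path / "ss.json"
        write_structure_set(simple_structure_set, path)
        back = read_structure_set(path)
        assert back.patient_id == simple_structure_set.patient_id
        assert back.true_label == simple_structure_set.true_label
        assert np.allclose(back.tandem, simple_structure_set.tandem)
        for orig, new in zip(simple_structure_set.structures, back.structures):
            assert new.role == orig.role
            assert len(new.slices) == len(orig.slices)
            for a, b in zip(orig.slices, new.slices):
                assert np.allclose(a.points, b.points)
                assert a.z == b.z

    def test_missing_tandem_raises(self, simple_structure_set, tmp_path):
        import json

        path = tmp_path / "ss.json"
        write_structure_set(simple_structure_set, path)
        doc = json.loads(path.read_text())
        del doc["tandem"]
        path.write_text(json.dumps(doc))
        with pytest.raises(MissingTandem):
            read_structure_set(path)

    def test_nonmonotone_tandem_rejected(self):
        with pytest.raises(MalformedTandem):
            StructureSet(
                "p",
                "i",
                [],
                tandem=np.array([[0, 0, 0], [0, 0, 5], [0, 0, 3.0]]),
            )

    def test_rtstruct_round_trip(self, tmp_path):
        """A pydicom-built RTSTRUCT reads back with roles and tandem."""
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import generate_uid

        rtstruct_class_uid = "1.2.840.10008.5.1.4.1.1.481.3"
        ds = Dataset()
        ds.PatientID = "RT01"
        ds.SOPClassUID = rtstruct_class_uid
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "RTSTRUCT"

        def roi(number, name):
            r = Dataset()
            r.ROINumber = number
            r.ROIName = name
            return r

        ds.StructureSetROISequence = [roi(1, "HR-CTV"), roi(2, "Tandem"), roi(3, "Bladder")]

        def contour(points):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(points)
            c.ContourData = [float(v) for p in points for v in p]
            return c

        def roi_contour(number, contours):
            rc = Dataset()
            rc.ReferencedROINumber = number
            rc.ContourSequence = contours
            return rc

        square = [[-10, -10, 0], [10, -10, 0], [10, 10, 0], [-10, 10, 0]]
        tandem_pts = [[0, 0, -20], [0, 0, 0], [1, 0, 20]]
        ds.ROIContourSequence = [
            roi_contour(1, [contour(square)]),
            roi_contour(2, [contour(tandem_pts)]),
            roi_contour(3, [contour([[p[0], p[1] - 30, p[2]] for p in square])]),
        ]
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = rtstruct_class_uid
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = meta
        path = tmp_path / "rs.dcm"
        ds.save_as(path, enforce_file_format=True)

        ss = read_structure_set(path)
        assert ss.patient_id == "RT01"
        roles = {s.role for s in ss.structures}
        assert roles == {StructureRole.HR_CTV, StructureRole.BLADDER}
        assert len(ss.tandem) == 3
        assert len(ss.slices_for(StructureRole.HR_CTV)) == 1

    def test_unrecognized_structures_skipped(self, simple_structure_set, tmp_path):
        import json

        path = tmp_path / "ss.json"
        write_structure_set(simple_structure_set, path)
        doc = json.loads(path.read_text())
        doc["structures"].append(
            {"name": "Mystery", "role": None, "slices": [{"z": 0.0, "points": [[0, 0], [1, 0], [0, 1]]}]}
        )
        path.write_text(json.dumps(doc))
        back = read_structure_set(path)
        assert len(back.structures) == len(simple_structure_set.structures)
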