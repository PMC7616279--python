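import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from spheroidquant import spheroid3d as s3


def digitized_ball(radius, voxel=1.0, pad=3):
    n = int(2 * (radius / voxel + pad)) + 1
    c = (n - 1) / 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * voxel**2 <= radius**2


class TestMorphometrics:
    def test_ball_closed_forms(self):
        """Digitized ball r=20: volume within 2%, sphericity within 5% of 1."""
        ball = digitized_ball(20)
        m = s3.morphometrics(ball, (1, 1, 1))
        true_v = 4 / 3 * np.pi * 20**3
        assert m.volume_um3 == pytest.approx(true_v, rel=0.02)
        assert m.sphericity == pytest.approx(1.0, rel=0.05)
        assert m.equivalent_radius_um == pytest.approx(20, rel=0.01)
        assert m.ellipticity == pytest.approx(1.0, rel=0.02)

    def test_two_to_one_ellipsoid(self):
        """Ellipticity from covariance eigenvalues recovers the axis ratio."""
        zz, yy, xx = np.mgrid[:85, :45, :45]
        ell = ((zz - 42) / 40.0) ** 2 + ((yy - 22) / 20.0) ** 2 + ((xx - 22) / 20.0) ** 2 <= 1
        m = s3.morphometrics(ell, (1, 1, 1))
        assert m.ellipticity == pytest.approx(2.0, rel=0.05)

    def test_anisotropic_voxels(self):
        """A ball sampled on a 2-um z grid still reports the physical volume."""
        n = 51
        c = 25.0
        zz, yy, xx = np.mgrid[:26, :n, :n]
        ball = ((zz * 2 - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= 20**2
        m = s3.morphometrics(ball, (2, 1, 1))
        assert m.volume_um3 == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            s3.morphometrics(np.zeros((4, 4, 4), bool), (1, 1, 1))

    def test_multiple_components_largest_analysed(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[5:25, 5:25, 5:25] = True
        mask[30:33, 30:33, 30:33] = True
        with pytest.warns(UserWarning, match="largest"):
            m = s3.morphometrics(mask, (1, 1, 1))
        assert m.volume_um3 == pytest.approx(20**3)


class TestLumenTopology:
    def test_phantom_two_lumens(self):
        from spheroidquant import phantom

        spec = phantom.PhantomSpec(seed=4, lumen_radii_um=(6.0, 4.0), n_delaminated=0, n_cells=25)
        _, labels, _ = phantom.make_spheroid_phantom(spec)
        count, stats, cls = s3.lumen_topology(labels.lumen, (1, 1, 1))
        assert count == 2 and cls == "multi"
        assert stats.volume_um3.min() > 30

    def test_empty_mask(self):
        count, stats, cls = s3.lumen_topology(np.zeros((4, 4, 4)), (1, 1, 1))
        assert (count, cls) == (0, "none") and stats.empty

    def test_speck_filtered(self):
        mask = digitized_ball(8).astype(np.uint16)
        mask[0, 0, 0] = 1  # 1-voxel speck, below the 30 um^3 filter
        count, _, cls = s3.lumen_topology(mask, (1, 1, 1))
        assert (count, cls) == (1, "single")


class TestLumenDistances:
    def test_norm_distance_zero_at_centroid(self):
        assert s3.norm_lumen_distance([5, 5, 5], [5, 5, 5], 20.0) == 0.0

    def test_norm_distance_half_radius(self):
        assert s3.norm_lumen_distance([0, 0, 10], [0, 0, 0], 20.0) == pytest.approx(0.5)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        n = rng.uniform(0, 10, 3)
        l = rng.uniform(0, 10, 3)
        base = s3.norm_lumen_distance(n, l, 15.0)
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-50, 50, 3)
        assert s3.norm_lumen_distance(q @ n + t, q @ l + t, 15.0) == pytest.approx(base)

    def test_surface_distance_analytic_sphere(self):
        """Nucleus at radial position d from a radius-r lumen scores d - r."""
        lumen = digitized_ball(10, pad=15)
        c = (lumen.shape[0] - 1) / 2
        d = s3.nearest_lumen_surface_distance([c, c, c + 18], lumen, (1, 1, 1))
        assert d == pytest.approx(8.0, abs=1.0)

    def test_surface_distance_on_boundary(self):
        lumen = digitized_ball(10, pad=5)
        c = (lumen.shape[0] - 1) / 2
        d = s3.nearest_lumen_surface_distance([c, c, c + 10], lumen, (1, 1, 1))
        assert d <= 0.75

    def test_no_lumen_rejected(self):
        with pytest.raises(ValueError, match="no lumen"):
            s3.nearest_lumen_surface_distance([0, 0, 0], np.zeros((3, 3, 3)), (1, 1, 1))


class TestDelamination:
    def test_phantom_calls_match_truth(self, spheroid_phantom):
        spec, img, labels, truth = spheroid_phantom
        df, fraction = s3.classify_delamination(labels.cells, labels.lumen, 1, set(), img.voxel_size)
        t = truth.cells.set_index("cell_id")
        d = df.set_index("cell_id")
        assert all(bool(d.lumen_contact[i]) == bool(t.lumen_contact[i]) for i in d.index)
        assert fraction == pytest.approx(spec.n_delaminated / spec.n_cells)

    def test_face_adjacent_contact_at_zero_and_one_tolerance(self):
        cells = np.zeros((3, 5, 5), np.uint16)
        lumen = np.zeros((3, 5, 5), np.uint16)
        lumen[1, 1, 1] = 1
        cells[1, 1, 2] = 1  # face-adjacent
        for tol in (1,):
            df, _ = s3.classify_delamination(cells, lumen, tol)
            assert bool(df.lumen_contact.iloc[0])
        # tolerance 0 means strict overlap-with-dilated-by-0, i.e. only
        # voxels on the lumen itself; face adjacency needs tolerance >= 1
        df0, _ = s3.classify_delamination(cells, lumen, 0)
        assert not bool(df0.lumen_contact.iloc[0])

    def test_mitotic_shadow_exclusion(self):
        """A non-contacting cell under an apically dividing neighbour is excluded."""
        cells = np.zeros((1, 9, 9), np.uint16)
        lumen = np.zeros((1, 9, 9), np.uint16)
        lumen[0, :, 0:2] = 1
        cells[0, 3:6, 2:5] = 2  # mitotic, touching the lumen side
        cells[0, 3:6, 5:8] = 3  # behind it, no contact
        df, fraction = s3.classify_delamination(cells, lumen, 1, mitotic_ids={2})
        d = df.set_index("cell_id")
        assert bool(d.lumen_contact[2]) and not bool(d.lumen_contact[3])
        assert bool(d.excluded_mitotic_shadow[3])
        # the shadowed cell is excluded from both numerator and denominator
        assert fraction == 0.0

    def test_no_lumen_flags_not_applicable(self):
        cells = np.zeros((2, 4, 4), np.uint16)
        cells[0, :2, :2] = 1
        df, fraction = s3.classify_delamination(cells, np.zeros_like(cells))
        assert fraction is None
        assert df.lumen_contact.isna().all()


class TestGolgiAngle:
    def test_collinear_apical(self):
        angle, cls = s3.golgi_angle((0, 0, 0), (10, 0, 0), (5, 0, 0))
        assert angle == pytest.approx(0.0, abs=1e-9)
        assert cls == "polarized"

    def test_orthogonal(self):
        angle, cls = s3.golgi_angle((0, 0, 0), (10, 0, 0), (10, 5, 0))
        assert angle == pytest.approx(90.0)
        assert cls == "unpolarized"

    def test_boundary_is_polarized(self):
        """Exactly 60 degrees stays polarized (strict inequality)."""
        g = (10 + np.cos(np.radians(60)), np.sin(np.radians(60)), 0.0)
        angle, cls = s3.golgi_angle((0, 0, 0), (10, 0, 0), g)
        assert angle == pytest.approx(60.0, abs=1e-9)
        assert cls == "polarized"

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            s3.golgi_angle((0, 0, 0), (1, 1, 1), (1, 1, 1))

    def test_phantom_golgi_classes_recovered(self, spheroid_phantom):
        spec, img, labels, truth = spheroid_phantom
        t = truth.cells[truth.cells.golgi_class != ""]
        lumen_c = np.array(truth.lumen_centroid)
        for _, row in t.iterrows():
            angle, cls = s3.golgi_angle(
                lumen_c,
                (row.nucleus_z, row.nucleus_y, row.nucleus_x),
                (row.golgi_z, row.golgi_y, row.golgi_x),
            )
            assert cls == row.golgi_class


class TestFractions:
    def test_single_plane_count(self):
        df = pd.DataFrame(
            {
                "plane": [3] * 20 + [4] * 5,
                "marker_class": [True] * 4 + [False] * 16 + [True] * 5,
            }
        )
        out = s3.per_spheroid_fractions(df, plane=3)
        assert out["fraction_positive"] == pytest.approx(0.20)
        assert out["n_cells"] == 20

    def test_all_negative(self):
        df = pd.DataFrame({"marker_class": [False] * 7})
        assert s3.per_spheroid_fractions(df)["fraction_positive"] == 0.0

    def test_empty_plane_rejected(self):
        df = pd.DataFrame({"plane": [1], "marker_class": [True]})
        with pytest.raises(ValueError, match="zero cells"):
            s3.per_spheroid_fractions(df, plane=9)

    def test_mitotic_index(self):
        df = pd.DataFrame({"marker_class": [False] * 10, "mitotic": [True] * 2 + [False] * 8})
        out = s3.per_spheroid_fractions(df, mitotic_col="mitotic")
        assert out["mitotic_index"] == pytest.approx(0.2)


class TestCircularity:
    def test_digitized_disk_near_one(self):
        yy, xx = np.mgrid[:120, :120]
        disk = (yy - 60) ** 2 + (xx - 60) ** 2 <= 50**2
        assert s3.circularity_2d(disk) >= 0.95

    def test_thin_rectangle(self):
        """10x1 rectangle: continuum value 4*pi*10/22^2 ~ 0.26, estimator reads high."""
        m = np.zeros((5, 14), bool)
        m[2, 2:12] = True
        c = s3.circularity_2d(m)
        assert c == pytest.approx(4 * np.pi * 10 / 22**2, abs=0.07)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        blob = ndi.binary_dilation(rng.uniform(size=(40, 40)) > 0.97, iterations=3)
        assert s3.circularity_2d(np.rot90(blob)) == pytest.approx(s3.circularity_2d(blob))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            s3.circularity_2d(np.zeros((4, 4), bool))
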