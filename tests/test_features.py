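import numpy as np
import pytest

from meningrad.features import (
    DEFAULT_PANEL,
    CatalogueError,
    DiscretizedVolume,
    discretize,
    enumerate_catalogue,
    extract_panel,
    first_order,
    glcm_features,
    glrlm_features,
    glszm_features,
    run_length_matrix,
    shape_features,
    size_zone_matrix,
)
from meningrad.filters import get_channel
from meningrad.imaging import SegmentationMask, VolumeImage
from meningrad.reference import glcm_oracle, glrlm_oracle, glszm_oracle
from tests.conftest import digital_ball, random_discretized


def full_mask(shape):
    return SegmentationMask(np.ones(shape, dtype=np.uint8))


def disc_from_levels(levels, ng):
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedVolume(
        levels=levels, ng=ng, bin_edges=np.arange(ng + 1, dtype=float), mask=levels > 0
    )


class TestDiscretize:
    def test_equal_width_split(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0]).reshape(4, 1, 1)
        disc = discretize(VolumeImage(vals), full_mask((4, 1, 1)), n_bins=2)
        np.testing.assert_array_equal(disc.levels.ravel(), [1, 1, 2, 2])

    def test_constant_maps_to_level_one(self):
        disc = discretize(VolumeImage(np.full((3, 3, 3), 9.9)), full_mask((3, 3, 3)), 32)
        assert set(np.unique(disc.levels)) == {1}

    def test_uniform_occupancy_roughly_equal(self, rng):
        vals = rng.random((20, 20, 20))
        disc = discretize(VolumeImage(vals), full_mask((20, 20, 20)), 32)
        counts = np.bincount(disc.levels.ravel(), minlength=33)[1:]
        expected = vals.size / 32
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 80  # 31 dof, generous

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            discretize(VolumeImage(np.zeros((2, 2, 2))), full_mask((2, 2, 2)), 1)

    def test_background_excluded(self, rng):
        vals = rng.random((4, 4, 4))
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[:2] = 1
        disc = discretize(VolumeImage(vals), SegmentationMask(m), 4)
        assert (disc.levels[m == 0] == 0).all()


class TestFirstOrder:
    def test_symmetric_set(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(5, 1, 1)
        f = first_order(VolumeImage(vals), full_mask((5, 1, 1)))
        assert f == {"Median": 3.0, "Mean": 3.0, "Minimum": 1.0, "Skewness": 0.0}

    def test_skewed_set_matches_moment_formula(self):
        fg = np.array([0.0, 0.0, 0.0, 9.0])
        f = first_order(VolumeImage(fg.reshape(4, 1, 1)), full_mask((4, 1, 1)))
        assert f["Mean"] == pytest.approx(2.25)
        assert f["Minimum"] == 0.0
        m = fg.mean()
        expected_skew = np.mean((fg - m) ** 3) / np.mean((fg - m) ** 2) ** 1.5
        assert f["Skewness"] == pytest.approx(expected_skew)


class TestGLCM:
    def test_constant_foreground_closed_form(self):
        disc = disc_from_levels(np.ones((4, 4, 4)), ng=32)
        f = glcm_features(disc)
        assert f["Cluster Prominence"] == pytest.approx(0.0, abs=1e-12)
        assert f["Difference Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["Inv. Diff. Normalized"] == pytest.approx(1.0)

    def test_random_volume_matches_pair_enumeration(self, rng):
        for _ in range(10):
            disc = random_discretized(rng)
            got = glcm_features(disc)
            want = glcm_oracle(disc.levels, disc.ng)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_striped_volume_entropy_positive(self):
        # width-2 stripes mix |i-j| = 0 and 1 pairs within one direction
        z = np.indices((4, 4, 4))[2]
        levels = 1 + (z // 2 % 2)
        disc = disc_from_levels(levels, ng=2)
        got = glcm_features(disc)
        want = glcm_oracle(disc.levels, 2)
        assert got["Difference Entropy"] > 0
        assert got["Difference Entropy"] == pytest.approx(want["Difference Entropy"], abs=1e-10)

    def test_parity_checkerboard_is_per_direction_uniform(self):
        # every direction sees a single |i-j| value, so DE averages to zero
        idx = np.indices((4, 4, 4)).sum(axis=0)
        disc = disc_from_levels(1 + (idx % 2), ng=2)
        got = glcm_features(disc)
        want = glcm_oracle(disc.levels, 2)
        assert got["Difference Entropy"] == pytest.approx(want["Difference Entropy"], abs=1e-12)
        assert got["Difference Entropy"] == pytest.approx(0.0, abs=1e-12)


class TestGLRLM:
    def test_single_run_algebra(self):
        levels = np.ones((1, 1, 4), dtype=np.int32)
        disc = disc_from_levels(levels, ng=4)
        R = run_length_matrix(disc, (0, 0, 1))
        # one run: level 1, length 4
        assert R[0, 3] == 1 and R.sum() == 1
        # RLN = 1^2/1 = 1; SRLGLE = 1/(1*16)/1
        assert (R.sum(axis=0) ** 2).sum() / R.sum() == pytest.approx(1.0)
        i = np.arange(1, 5)[:, None]
        j = np.arange(1, R.shape[1] + 1)[None, :]
        assert float((R / (i**2 * j**2)).sum() / R.sum()) == pytest.approx(1 / 16)

    def test_alternating_runs_match_scan_oracle(self):
        levels = np.array([1, 2, 1, 2], dtype=np.int32).reshape(1, 1, 4)
        disc = disc_from_levels(levels, ng=2)
        got = glrlm_features(disc)
        want = glrlm_oracle(disc.levels, 2)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_random_volume_matches_run_scan(self, rng):
        for _ in range(10):
            disc = random_discretized(rng, max_side=5, max_ng=3)
            got = glrlm_features(disc)
            want = glrlm_oracle(disc.levels, disc.ng)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_run_marginal_conservation(self, rng):
        """Total voxels in runs equals foreground count, per direction."""
        from meningrad.features import DIRECTIONS_3D

        disc = random_discretized(rng)
        n_fg = int(disc.mask.sum())
        for d in DIRECTIONS_3D:
            R = run_length_matrix(disc, d)
            j = np.arange(1, R.shape[1] + 1)
            assert int((R.sum(axis=0) * j).sum()) == n_fg


class TestGLSZM:
    def test_one_zone_algebra(self):
        disc = disc_from_levels(np.ones((4, 4, 4)), ng=32)
        f = glszm_features(disc)
        assert f["High Intensity Large Area Emp."] == pytest.approx(4096.0)
        assert f["Low Intensity Large Area Emp."] == pytest.approx(4096.0)
        assert f["Low Intensity Small Area Emp."] == pytest.approx(1 / 4096.0)

    def test_two_disjoint_blobs(self):
        levels = np.zeros((6, 6, 6), dtype=np.int32)
        levels[:2, :2, :2] = 1  # zone of 8
        levels[5, 5, 5] = 1  # zone of 1
        disc = disc_from_levels(levels, ng=1 + 1)  # ng 2, level 1 only
        S = size_zone_matrix(disc)
        assert S.sum() == 2
        got = glszm_features(disc)
        want = glszm_oracle(disc.levels, disc.ng)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_random_volume_matches_flood_fill(self, rng):
        for _ in range(10):
            disc = random_discretized(rng, max_side=5, max_ng=3)
            got = glszm_features(disc)
            want = glszm_oracle(disc.levels, disc.ng)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_zone_marginal_conservation(self, rng):
        disc = random_discretized(rng)
        S = size_zone_matrix(disc)
        j = np.arange(1, S.shape[1] + 1)
        assert int((S.sum(axis=0) * j).sum()) == int(disc.mask.sum())


class TestShape:
    def test_digital_ball_near_unit_disproportion(self):
        mask = digital_ball(10, spacing=1.0)
        f = shape_features(mask)
        assert 1.0 <= f["Spherical Disproportion"] <= 1.10
        assert f["Volume"] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_elongated_ellipsoid_less_spherical(self):
        n = 41
        c = (n - 1) / 2
        x, y, z = np.ogrid[:n, :n, :n]
        ball = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= 8**2
        ellip = ((x - c) ** 2 / 4 + (y - c) ** 2 + (z - c) ** 2) <= (8 / 2**(2/3)) ** 2
        sd_ball = shape_features(SegmentationMask(ball.astype(np.uint8)))["Spherical Disproportion"]
        sd_ell = shape_features(SegmentationMask(ellip.astype(np.uint8)))["Spherical Disproportion"]
        assert sd_ell > sd_ball

    def test_single_slice_disk_diameter(self):
        n = 15
        c = 7
        x, y = np.ogrid[:n, :n]
        disk = ((x - c) ** 2 + (y - c) ** 2) <= 25
        m = np.zeros((n, n, 3), dtype=np.uint8)
        m[:, :, 1] = disk
        f = shape_features(SegmentationMask(m))
        assert f["Maximum Axial Diameter"] == pytest.approx(10.0, abs=1.0)


class TestPanelAndCatalogue:
    def test_panel_minimum_consistent_with_first_order(self, rng):
        vals = rng.normal(100, 10, size=(10, 10, 10))
        img, mask = VolumeImage(vals), full_mask((10, 10, 10))
        panel = extract_panel(img, mask, panel=("Minimum",))
        assert panel["Minimum"] == first_order(img, mask)["Minimum"]

    def test_panel_hhh_hilae_is_glszm_on_subband(self, rng):
        vals = rng.normal(size=(12, 12, 12))
        img, mask = VolumeImage(vals), full_mask((12, 12, 12))
        panel = extract_panel(img, mask, panel=("HHH High Intensity Large Area Emp.",))
        hhh = get_channel(img, "HHH").image
        direct = glszm_features(discretize(hhh, mask, 32))
        assert panel["HHH High Intensity Large Area Emp."] == pytest.approx(
            direct["High Intensity Large Area Emp."]
        )

    def test_default_panel_finite_in_order(self, rng):
        vals = rng.normal(100, 15, size=(16, 16, 16))
        out = extract_panel(VolumeImage(vals), full_mask((16, 16, 16)))
        assert list(out) == list(DEFAULT_PANEL)
        assert all(np.isfinite(v) for v in out.values())

    def test_unknown_name_rejected(self, rng):
        with pytest.raises(CatalogueError):
            extract_panel(
                VolumeImage(np.zeros((8, 8, 8))), full_mask((8, 8, 8)), panel=("Fractal Dim.",)
            )

    def test_catalogue_count_and_uniqueness(self):
        cat = enumerate_catalogue()
        assert len(cat) == 1055
        assert len(set(cat)) == 1055

    def test_catalogue_original_channel_subset(self):
        cat = enumerate_catalogue(channels=("original",))
        assert len(cat) == 65


class TestInvariances:
    def test_texture_features_shift_invariant(self, rng):
        vals = rng.normal(50, 5, size=(8, 8, 8))
        mask = full_mask((8, 8, 8))
        a = discretize(VolumeImage(vals), mask, 8)
        b = discretize(VolumeImage(vals + 123.4), mask, 8)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_glcm_feature_ranges(self, rng):
        for _ in range(5):
            disc = random_discretized(rng)
            f = glcm_features(disc)
            assert 0 < f["Inv. Diff. Normalized"] <= 1.0 + 1e-12
            assert f["Difference Entropy"] >= 0
            assert f["Cluster Prominence"] >= 0
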