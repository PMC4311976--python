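"""360-ray radii, thickness and second moments of area per section."""

import numpy as np
import pytest

from diamorph import structure
from diamorph.sections import CrossSection
from diamorph.structure import centroid, radial_radii, raw_moments, sma_profile

from conftest import annulus_mask

PX = 0.1


def section_of(mask: np.ndarray) -> CrossSection:
    return CrossSection(mask=mask, fraction_length=25.0, index=1)


def random_blob(seed: int, n: int = 64) -> np.ndarray:
    """Random smoothed-threshold blob mask (non-empty)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.normal(size=(n, n)), 6.0)
    mask = f > np.quantile(f, 0.7)
    assert mask.any()
    return mask


class TestCentroid:
    def test_centered_annulus_at_grid_center(self):
        mask = annulus_mask(121)
        c = centroid(section_of(mask))
        np.testing.assert_allclose(c, [60.5 * PX, 60.5 * PX], atol=1e-9)

    def test_translation_equivariance(self):
        mask = annulus_mask(151)
        c0 = centroid(section_of(mask))
        shifted = np.roll(np.roll(mask, -2, axis=0), 3, axis=1)  # +3 px x, -2 px y
        c1 = centroid(section_of(shifted))
        np.testing.assert_allclose(c1 - c0, [0.3, -0.2], atol=1e-9)

    def test_crescent_equals_pixel_mean(self):
        mask = random_blob(0)
        ys, xs = np.nonzero(mask)
        expected = np.array([(xs.mean() + 0.5) * PX, (ys.mean() + 0.5) * PX])
        np.testing.assert_allclose(centroid(section_of(mask)), expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            centroid(section_of(np.zeros((10, 10), dtype=bool)))


class TestRadialRadii:
    def test_annulus_radii_closed_form(self):
        mask = annulus_mask(121, r_out=50, r_in=30)
        peri, endo = radial_radii(section_of(mask))
        assert peri.shape == endo.shape == (360,)
        np.testing.assert_allclose(peri, 50 * PX, atol=0.5 * PX)
        np.testing.assert_allclose(endo, 30 * PX, atol=0.5 * PX)

    def test_720_measurements_per_section(self):
        peri, endo = radial_radii(section_of(annulus_mask()))
        assert peri.size + endo.size == 720

    def test_ellipse_periosteal_at_zero_is_semimajor(self):
        yy, xx = np.mgrid[0:161, 0:161].astype(float)
        ellipse = ((xx - 80) / 70) ** 2 + ((yy - 80) / 40) ** 2 <= 1.0
        peri, _ = radial_radii(section_of(ellipse))
        assert peri[0] == pytest.approx(70 * PX, abs=PX)
        assert peri[90] == pytest.approx(40 * PX, abs=PX)

    def test_solid_rod_has_zero_endosteal(self):
        yy, xx = np.mgrid[0:81, 0:81].astype(float)
        disk = (xx - 40) ** 2 + (yy - 40) ** 2 <= 30**2
        peri, endo = radial_radii(section_of(disk))
        np.testing.assert_array_equal(endo, 0.0)
        thickness = structure.thickness_profile(peri, endo)
        np.testing.assert_array_equal(thickness, peri)

    def test_eccentric_canal_matches_offset_circle_formula(self):
        """Canal offset by d from the centroid-corrected origin: the inner
        crossing along a ray at angle phi from the *canal-offset* geometry
        follows the analytic offset-circle distance."""
        n, r_out, r_in, dx = 161, 60.0, 25.0, 10.0
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        mask = ((xx - c) ** 2 + (yy - c) ** 2 <= r_out**2) & (
            (xx - c - dx) ** 2 + (yy - c) ** 2 >= r_in**2
        )
        sec = section_of(mask)
        cen = centroid(sec)
        peri, endo = radial_radii(sec, cen)
        # analytic: ray from centroid at angle phi hits the canal circle
        # centred at (c+dx) px; solve |p + t u - q| = r_in for smallest t>0
        cx_px, cy_px = cen / PX - 0.5
        qx, qy = c + dx, c
        ang = np.deg2rad(np.arange(360))
        ux, uy = np.cos(ang), np.sin(ang)
        ox, oy = cx_px - qx, cy_px - qy
        b = ox * ux + oy * uy
        disc = b**2 - (ox**2 + oy**2 - r_in**2)
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t_near, t_far = -b - sq, -b + sq
        t = np.where(t_near > 0, t_near, t_far)  # far root when inside the canal
        expected = np.where(hit & (t > 0), t, 0.0) * PX
        np.testing.assert_allclose(endo, expected, atol=0.6 * PX)
        # periosteal: same ray-circle geometry about the outer circle (c, c)
        ox2, oy2 = cx_px - c, cy_px - c
        b2 = ox2 * ux + oy2 * uy
        t_out = -b2 + np.sqrt(b2**2 - (ox2**2 + oy2**2 - r_out**2))
        np.testing.assert_allclose(peri, t_out * PX, atol=0.6 * PX)


class TestSMA:
    def test_annulus_sma_closed_form(self):
        mask = annulus_mask(121, r_out=50, r_in=30)
        sma, _ = sma_profile(section_of(mask))
        expected = np.pi / 4 * ((50 * PX) ** 4 - (30 * PX) ** 4)
        np.testing.assert_allclose(sma, expected, rtol=0.02)

    def test_180_degree_redundancy_exact(self):
        sma, _ = sma_profile(section_of(random_blob(1)))
        np.testing.assert_array_equal(sma[37], sma[(37 + 180) % 360])
        np.testing.assert_allclose(sma, np.roll(sma, 180), rtol=1e-12)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_rotation_formula_equals_brute_force(self, seed):
        """I(theta) from the moment-rotation formula equals direct pixel
        summation of squared perpendicular distances at every degree."""
        mask = random_blob(seed)
        sec = section_of(mask)
        c = centroid(sec)
        sma, _ = sma_profile(sec, c)
        ys, xs = np.nonzero(mask)
        x = (xs + 0.5) * PX - c[0]
        y = (ys + 0.5) * PX - c[1]
        cell = PX * PX
        self_m = xs.size * PX**4 / 12.0
        theta = np.deg2rad(np.arange(360))
        # distance to axis through centroid along (cos t, sin t): |y cos - x sin|
        d2 = (y[None, :] * np.cos(theta)[:, None] - x[None, :] * np.sin(theta)[:, None]) ** 2
        brute = d2.sum(axis=1) * cell + self_m
        np.testing.assert_allclose(sma, brute, rtol=1e-9)

    def test_sma_conservation_under_axis_rotation(self):
        sma, (ixx, iyy, _) = sma_profile(section_of(random_blob(5)))
        total = sma + np.roll(sma, -90)
        np.testing.assert_allclose(total, ixx + iyy, rtol=1e-9)

    def test_sma_extrema_equal_moment_tensor_eigenvalues(self):
        for seed in (6, 7):
            sma, (ixx, iyy, ixy) = sma_profile(section_of(random_blob(seed)))
            evals = np.linalg.eigvalsh(np.array([[ixx, -ixy], [-ixy, iyy]]))
            # the 1-degree grid samples the sinusoid slightly off its extrema
            assert sma.min() == pytest.approx(evals[0], rel=1e-3)
            assert sma.max() == pytest.approx(evals[1], rel=1e-3)

    def test_mask_rotation_permutes_thickness_profile(self):
        mask = annulus_mask(121, r_out=50, r_in=30)
        mask &= ~(np.mgrid[0:121, 0:121][1] > 95)  # break symmetry: flat cut
        t0 = structure.measure_section(section_of(mask)).thickness
        t90 = structure.measure_section(section_of(np.rot90(mask))).thickness
        np.testing.assert_allclose(np.roll(t0, -90), t90, atol=1e-9)


class TestMeasureSection:
    def test_profile_fields_consistent(self):
        p = structure.measure_section(section_of(annulus_mask()))
        np.testing.assert_allclose(
            p.thickness, p.periosteal_r - p.endosteal_r, atol=1e-12
        )
        assert (p.thickness >= 0).all()
        assert p.sma.shape == (360,)

    def test_profile_matrix_ordering(self):
        secs = [section_of(annulus_mask()) for _ in range(3)]
        profs = []
        for i, s in enumerate(secs):
            s = CrossSection(mask=s.mask, fraction_length=25.0 + 2.5 * i, index=i + 1)
            profs.append(structure.measure_section(s))
        mat = structure.profile_matrix(profs[::-1], "thickness")
        assert mat.shape == (3, 360)
        np.testing.assert_allclose(mat[0], profs[0].thickness)
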