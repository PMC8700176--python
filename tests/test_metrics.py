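"""Image-quality metrics against naive double-loop oracles and identities."""
import math

import numpy as np
import pytest

from prcpet.metrics import (compute_pair_stats, compute_rc, compute_sor,
                            disc_mask, _central_slab)
from prcpet.phantoms import make_rod5_phantom, make_sphere1_phantom
from conftest import make_image

VOX = 1.6
SHAPE = (48, 48, 40)


@pytest.fixture(scope="module")
def rod5():
    return make_rod5_phantom(1.0, voxel_size_mm=VOX, shape=SHAPE)


@pytest.fixture(scope="module")
def sphere1():
    return make_sphere1_phantom(voxel_size_mm=VOX, shape=SHAPE)


def naive_pair_stats(a, b):
    """Triple-loop RMSE/PSNR oracle."""
    s = 0.0
    v = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                s += (float(a[i, j, k]) - float(b[i, j, k])) ** 2
                v += 1
    rmse = math.sqrt(s / v)
    return rmse, 20 * math.log10(float(a.max()) / rmse)


class TestPairStats:
    def test_identical_images(self):
        img = make_image(np.random.default_rng(0).random((8, 8, 8)))
        st = compute_pair_stats(img, img)
        assert st.rmse == 0
        assert st.psnr == math.inf

    def test_constant_offset(self):
        a = make_image(np.full((6, 6, 6), 10.0))
        b = make_image(np.full((6, 6, 6), 7.0))
        st = compute_pair_stats(a, b)
        assert st.rmse == pytest.approx(3.0, abs=1e-12)
        # i_max 10, rmse 3 -> psnr = 20 log10(10/3)
        assert st.psnr == pytest.approx(20 * math.log10(10 / 3), abs=1e-10)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        a = make_image(rng.random((12, 11, 10)) * 50)
        b = make_image(rng.random((12, 11, 10)) * 50)
        st = compute_pair_stats(a, b)
        rmse, psnr = naive_pair_stats(a.data, b.data)
        assert st.rmse == pytest.approx(rmse, abs=1e-10)
        assert st.psnr == pytest.approx(psnr, abs=1e-10)

    def test_scale_invariance_of_psnr(self):
        rng = np.random.default_rng(4)
        a = make_image(rng.random((9, 9, 9)) * 20)
        b = make_image(rng.random((9, 9, 9)) * 20)
        s1 = compute_pair_stats(a, b)
        a2 = make_image(a.data * 7.5)
        b2 = make_image(b.data * 7.5)
        s2 = compute_pair_stats(a2, b2)
        assert s2.rmse == pytest.approx(7.5 * s1.rmse, rel=1e-6)
        assert s2.psnr == pytest.approx(s1.psnr, abs=1e-6)


class TestRC:
    def test_uniform_phantom_gives_rc_one(self, rod5, sphere1):
        # rod activity equals the uniform-cylinder activity -> RC = 1
        img_rod = make_image(rod5.activity.copy(), voxel=VOX)
        img_sph = make_image(sphere1.activity.copy(), voxel=VOX)
        rc = compute_rc(img_rod, rod5, img_sph, sphere1)
        for d in (2, 4, 6, 8, 10):
            assert rc.rc(d) == pytest.approx(1.0, abs=1e-9)
            assert rc.cv_rc(d) == pytest.approx(0.0, abs=1e-9)

    def test_pythagorean_cv(self):
        # SD/AVG of 0.3 and 0.4 must combine to 0.5
        assert math.hypot(0.3, 0.4) == pytest.approx(0.5)

    def test_cv_combines_target_and_uniform_in_quadrature(self, rod5, sphere1):
        rng = np.random.default_rng(5)
        img_rod = make_image(rod5.activity * (1 + 0.1 * rng.random(SHAPE)),
                             voxel=VOX)
        img_sph = make_image(sphere1.activity * (1 + 0.1 * rng.random(SHAPE)),
                             voxel=VOX)
        rc = compute_rc(img_rod, rod5, img_sph, sphere1)
        for d, entry in rc.per_rod.items():
            expect = math.hypot(entry["sd_target"] / entry["avg_target"],
                                rc.sd_uniform / rc.avg_uniform)
            assert entry["cv_rc"] == pytest.approx(expect, rel=1e-12)

    def test_matches_naive_roi_oracle(self, rod5, sphere1):
        """Line-profile and ROI statistics recomputed with explicit loops."""
        rng = np.random.default_rng(6)
        img_rod = make_image(rod5.activity * (1 + 0.2 * rng.random(SHAPE)),
                             voxel=VOX)
        img_sph = make_image(sphere1.activity.copy(), voxel=VOX)
        rc = compute_rc(img_rod, rod5, img_sph, sphere1)

        sl = _central_slab(SHAPE[2], VOX)
        avg = img_rod.data[:, :, sl].mean(axis=2, dtype=np.float64)
        mid = rod5.labels[:, :, SHAPE[2] // 2]
        from scipy.ndimage import binary_dilation
        for rod_id, d in rod5.meta["rod_diameters_mm"].items():
            fp = binary_dilation(mid == rod_id)
            best, best_rc = -np.inf, None
            for r in range(SHAPE[0]):
                for c in range(SHAPE[1]):
                    if fp[r, c] and avg[r, c] > best:
                        best, best_rc = avg[r, c], (r, c)
            prof = img_rod.data[best_rc[0], best_rc[1], sl].astype(float)
            assert rc.per_rod[d]["avg_target"] == pytest.approx(
                prof.mean(), rel=1e-10)
            assert rc.per_rod[d]["sd_target"] == pytest.approx(
                prof.std(), rel=1e-9, abs=1e-12)

    def test_scale_invariance(self, rod5, sphere1):
        rng = np.random.default_rng(7)
        img_rod = make_image(rod5.activity * (1 + 0.1 * rng.random(SHAPE)),
                             voxel=VOX)
        img_sph = make_image(sphere1.activity * (1 + 0.1 * rng.random(SHAPE)),
                             voxel=VOX)
        rc1 = compute_rc(img_rod, rod5, img_sph, sphere1)
        rc2 = compute_rc(make_image(img_rod.data * 3.3, voxel=VOX), rod5,
                         make_image(img_sph.data * 3.3, voxel=VOX), sphere1)
        for d in rc1.per_rod:
            assert rc2.rc(d) == pytest.approx(rc1.rc(d), rel=1e-6)
            assert rc2.cv_rc(d) == pytest.approx(rc1.cv_rc(d), rel=1e-6)


class TestSOR:
    def test_cold_sphere_no_blur_gives_zero(self, sphere1):
        img = make_image(sphere1.activity.copy(), voxel=VOX)
        st = compute_sor(img, sphere1)
        assert st.sor == 0.0
        assert st.degenerate
        assert st.cv_sor is None

    def test_ratio_and_cv(self, sphere1):
        data = sphere1.activity.copy().astype(np.float64)
        data[sphere1.labels == sphere1.meta["sphere_label"]] = \
            0.02 * 1.69e6
        st = compute_sor(make_image(data, voxel=VOX), sphere1)
        assert st.sor == pytest.approx(0.02, rel=1e-9)
        assert st.cv_sor == pytest.approx(0.0, abs=1e-9)

    def test_matches_naive_disc_oracle(self, sphere1):
        rng = np.random.default_rng(8)
        data = sphere1.activity * (1 + 0.3 * rng.random(SHAPE)) + 5.0
        img = make_image(data, voxel=VOX)
        st = compute_sor(img, sphere1)
        # naive: loop every pixel of the sphere-center slice
        sph = np.argwhere(sphere1.labels == sphere1.meta["sphere_label"])
        zc = int(round(sph[:, 2].mean()))
        sl = img.data[:, :, zc]
        h = VOX
        r_vox = 5.0 / h
        cc = (SHAPE[0] - 1) / 2.0, (SHAPE[1] - 1) / 2.0
        cold_c = (cc[0] + (-12.5) / h, cc[1])
        hot_c = (cc[0] + 12.5 / h, cc[1])
        cold_vals, hot_vals = [], []
        for r in range(SHAPE[0]):
            for c in range(SHAPE[1]):
                if (r - cold_c[0]) ** 2 + (c - cold_c[1]) ** 2 < r_vox ** 2:
                    cold_vals.append(float(sl[r, c]))
                if (r - hot_c[0]) ** 2 + (c - hot_c[1]) ** 2 < r_vox ** 2:
                    hot_vals.append(float(sl[r, c]))
        assert st.avg_cold == pytest.approx(np.mean(cold_vals), rel=1e-10)
        assert st.avg_hot == pytest.approx(np.mean(hot_vals), rel=1e-10)
        assert st.sor == pytest.approx(np.mean(cold_vals) / np.mean(hot_vals),
                                       rel=1e-10)
        expect_cv = math.hypot(np.std(cold_vals) / np.mean(cold_vals),
                               np.std(hot_vals) / np.mean(hot_vals))
        assert st.cv_sor == pytest.approx(expect_cv, rel=1e-10)


class TestDiscMask:
    def test_membership_by_pixel_center(self):
        m = disc_mask((11, 11), (5.0, 5.0), 2.5)
        # 2.5-pixel radius disc: 21 pixels whose centers fall inside
        assert m[5, 5] and m[5, 7] and not m[5, 8]
        assert int(m.sum()) == 21
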