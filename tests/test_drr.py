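"""DRR engine: Beer-Lambert closed forms, Siddon exactness, database."""

import math

import numpy as np
import pytest

from spinereg.drr import (CTVolume, Radiograph, build_drr_database, hu_to_mu,
                          load_drr_database, ray_path_integrals, raycast_drr,
                          resample_image, resample_volume, save_drr_database)
from spinereg.geometry import CArmIntrinsics, CArmPose, GeometryError


# --------------------------------------------------------------------------
# HU -> mu
# --------------------------------------------------------------------------

@pytest.mark.parametrize("hu,mu_water,expected", [
    (0.0, 0.02, 0.02),        # water maps to mu_water by definition
    (-1000.0, 0.02, 0.0),     # air
    (1000.0, 0.02, 0.04),     # linear scaling
    (-1024.0, 0.02, 0.0),     # clamped below zero
])
def test_hu_to_mu_values(hu, mu_water, expected):
    vol = CTVolume(np.full((2, 2, 2), hu), (1, 1, 1))
    assert hu_to_mu(vol, mu_water).voxels[0, 0, 0] == pytest.approx(expected)


def test_hu_to_mu_rejects_bad_input():
    with pytest.raises(ValueError):
        hu_to_mu(CTVolume(np.full((2, 2, 2), np.nan), (1, 1, 1)))
    with pytest.raises(ValueError):
        hu_to_mu(CTVolume(np.zeros((2, 2, 2)), (1, 1, 1)), mu_water=0.0)


# --------------------------------------------------------------------------
# raycasting
# --------------------------------------------------------------------------

def _cube_volume(mu_val, n=20, voxel=2.0):
    vol = CTVolume(np.full((n, n, n), float(mu_val)), (voxel,) * 3)
    origin = -(np.asarray(vol.shape) - 1) * voxel / 2.0
    return CTVolume(vol.voxels, vol.spacing, tuple(origin))


def test_zero_attenuation_gives_i0_everywhere():
    intr = CArmIntrinsics(1000.0, (1.0, 1.0), (64, 64))
    drr = raycast_drr(_cube_volume(0.0), intr, CArmPose(), out_pixel_mm=4.0,
                      i0=2.5)
    np.testing.assert_array_equal(drr.pixels, 2.5)


def test_beer_lambert_central_ray():
    """Homogeneous cube, exactly central ray: I = I0 exp(-mu L)."""
    mu, voxel, n = 0.013, 2.0, 20
    intr = CArmIntrinsics(1000.0, (1.0, 1.0), (11, 11))  # odd: COP on a pixel
    drr = raycast_drr(_cube_volume(mu, n, voxel), intr, CArmPose(),
                      out_pixel_mm=1.0)
    center = drr.pixels[5, 5]
    assert center == pytest.approx(math.exp(-mu * n * voxel), rel=1e-9)


def test_siddon_chord_lengths_match_ray_box_oracle():
    """Total path length through a mu=1 volume equals the analytic chord of
    the ray with the bounding box, for 100 random rays."""
    rng = np.random.default_rng(3)
    vol = CTVolume(np.ones((7, 9, 8)), (1.7, 0.9, 1.3),
                   tuple(rng.uniform(-5, 5, 3)))
    h = np.asarray(vol.spacing)
    bmin = np.asarray(vol.origin) - h / 2
    bmax = bmin + np.asarray(vol.shape) * h
    src = np.array([-40.0, 1.0, -2.0])
    pix = np.column_stack([np.full(100, 40.0),
                           rng.uniform(-15, 15, 100), rng.uniform(-15, 15, 100)])
    got = ray_path_integrals(vol, src, pix)

    # independent slab-method chord oracle
    d = pix - src
    t1 = (bmin - src) / d
    t2 = (bmax - src) / d
    tmin = np.clip(np.minimum(t1, t2).max(axis=1), 0, None)
    tmax = np.clip(np.maximum(t1, t2).min(axis=1), None, 1)
    chord = np.clip(tmax - tmin, 0, None) * np.linalg.norm(d, axis=1)
    np.testing.assert_allclose(got, chord, atol=1e-6)


def test_siddon_matches_dense_sampling_oracle():
    """Random 5x5x5 mu: Siddon integrals agree with dense fixed-step
    midpoint sampling within 0.1% (plus a small absolute slack for grazing
    rays, whose boundary-crossing quantization dominates)."""
    rng = np.random.default_rng(12)
    vol = CTVolume(rng.uniform(0.0, 0.08, (5, 5, 5)), (1.1, 1.4, 0.9))
    src = np.array([-9.0, 0.7, -0.4])
    pix = np.column_stack([np.full(25, 9.0),
                           rng.uniform(-3, 3, 25), rng.uniform(-3, 3, 25)])
    got = ray_path_integrals(vol, src, pix)

    h = np.asarray(vol.spacing)
    bmin = np.asarray(vol.origin) - h / 2
    step = 0.002
    expected = []
    for p in pix:
        d = p - src
        length = np.linalg.norm(d)
        n = int(length / step)
        ts = (np.arange(n) + 0.5) / n
        pts = src + ts[:, None] * d
        idx = np.floor((pts - bmin) / h).astype(int)
        inside = np.all((idx >= 0) & (idx < vol.shape), axis=1)
        mu = np.zeros(n)
        mu[inside] = vol.voxels[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        expected.append(mu.sum() * length / n)
    np.testing.assert_allclose(got, expected, rtol=1e-3, atol=2e-4)


def test_numba_and_numpy_backends_agree():
    rng = np.random.default_rng(9)
    vol = CTVolume(rng.uniform(0, 0.1, (6, 7, 5)), (1.0, 1.3, 0.8))
    src = np.array([-20.0, 3.0, -1.0])
    pix = rng.uniform([-8, -8, -8], [20, 8, 8], size=(300, 3))
    pix[:, 0] = 20.0
    a = ray_path_integrals(vol, src, pix, backend="numba")
    b = ray_path_integrals(vol, src, pix, backend="numpy")
    np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)


def test_monotonicity_in_attenuation():
    """Raising one voxel's mu never brightens any pixel."""
    rng = np.random.default_rng(4)
    vol = _cube_volume(0.01, n=10, voxel=3.0)
    intr = CArmIntrinsics(600.0, (2.0, 2.0), (32, 32))
    base = raycast_drr(vol, intr, CArmPose(), out_pixel_mm=2.0).pixels
    bumped = vol.voxels.copy()
    bumped[4, 6, 3] += 0.5
    vol2 = CTVolume(bumped, vol.spacing, vol.origin)
    after = raycast_drr(vol2, intr, CArmPose(), out_pixel_mm=2.0).pixels
    assert np.all(after <= base + 1e-15)
    assert after.min() < base.min()  # the bump is actually seen


def test_rig_translation_equals_volume_translation():
    """Cone-beam translation equivariance in its exact form: moving the rig
    by d equals moving the volume content by -d (whole voxels, zero-padded
    interior content)."""
    rng = np.random.default_rng(6)
    inner = rng.uniform(0, 0.05, (8, 8, 8))
    arr = np.zeros((16, 16, 16))
    arr[4:12, 4:12, 4:12] = inner
    voxel = 2.0
    vol = CTVolume(arr, (voxel,) * 3)
    intr = CArmIntrinsics(800.0, (1.0, 1.0), (128, 128))
    shift_vox = (0, 2, -1)
    d = np.asarray(shift_vox) * voxel
    moved_rig = raycast_drr(vol, intr, CArmPose(translation=tuple(d)),
                            out_pixel_mm=2.0)
    rolled = np.roll(arr, shift=[-s for s in shift_vox], axis=(0, 1, 2))
    moved_vol = raycast_drr(CTVolume(rolled, vol.spacing, vol.origin), intr,
                            CArmPose(), out_pixel_mm=2.0)
    np.testing.assert_allclose(moved_rig.pixels, moved_vol.pixels,
                               rtol=1e-10, atol=1e-12)


def test_source_inside_volume_rejected():
    vol = _cube_volume(0.01, n=10, voxel=3.0)
    big = CTVolume(vol.voxels, (120.0, 120.0, 120.0), (-540.0, -540.0, -540.0))
    intr = CArmIntrinsics(1000.0, (1.0, 1.0), (64, 64))
    with pytest.raises(GeometryError):
        raycast_drr(big, intr, CArmPose(), out_pixel_mm=8.0)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def test_resample_identity_and_constant():
    img = Radiograph(np.arange(64.0).reshape(8, 8), (2.0, 2.0))
    same = resample_image(img, 2.0)
    np.testing.assert_array_equal(same.pixels, img.pixels)
    const = Radiograph(np.full((8, 8), 3.3), (1.0, 1.0))
    np.testing.assert_allclose(resample_image(const, 4.0).pixels, 3.3)


def test_resample_block_mean():
    img = Radiograph(np.array([[0.0, 0.0], [100.0, 100.0]]), (1.0, 1.0))
    out = resample_image(img, 2.0)
    assert out.pixels.shape == (1, 1)
    assert out.pixels[0, 0] == pytest.approx(50.0)


def test_resample_conserves_mean_on_downsampling():
    rng = np.random.default_rng(2)
    img = Radiograph(rng.uniform(0, 1, (96, 96)), (1.0, 1.0))
    out = resample_image(img, 4.0)
    assert out.pixels.mean() == pytest.approx(img.pixels.mean(), rel=1e-12)
    with pytest.raises(ValueError):
        resample_image(img, -1.0)


def test_resample_volume_preserves_center():
    rng = np.random.default_rng(8)
    vol = CTVolume(rng.uniform(0, 1, (8, 12, 16)), (2.0, 2.0, 2.0),
                   (-7.0, -11.0, -15.0))
    out = resample_volume(vol, 4.0)
    assert out.shape == (4, 6, 8)
    np.testing.assert_allclose(out.center, vol.center)
    assert out.voxels.mean() == pytest.approx(vol.voxels.mean(), rel=1e-12)


# --------------------------------------------------------------------------
# database
# --------------------------------------------------------------------------

@pytest.fixture
def tiny_db_setup():
    vol = _cube_volume(0.0, n=12, voxel=3.0)
    arr = vol.voxels.copy()
    arr[3:9, 4:8, 2:10] = 0.03
    return CTVolume(arr, vol.spacing, vol.origin), \
        CArmIntrinsics(800.0, (2.0, 2.0), (64, 64))


def test_database_cardinality(tiny_db_setup):
    vol, intr = tiny_db_setup
    db = build_drr_database(vol, intr, range_mm=4.0, step_mm=2.0,
                            coarse_pixel_mm=8.0)
    assert len(db) == 25  # (2*4/2 + 1)^2
    db1 = build_drr_database(vol, intr, range_mm=0.0, step_mm=2.0,
                             coarse_pixel_mm=8.0)
    assert len(db1) == 1 and db1.poses[0].is_nominal
    with pytest.raises(ValueError, match="divisible"):
        build_drr_database(vol, intr, range_mm=5.0, step_mm=2.0)


def test_database_rebuild_is_bit_identical(tiny_db_setup):
    vol, intr = tiny_db_setup
    kw = dict(range_mm=4.0, step_mm=4.0, coarse_pixel_mm=8.0)
    a = build_drr_database(vol, intr, **kw)
    b = build_drr_database(vol, intr, **kw)
    for ia, ib in zip(a.images, b.images):
        np.testing.assert_array_equal(ia, ib)


def test_database_save_load_roundtrip(tiny_db_setup, tmp_path):
    vol, intr = tiny_db_setup
    db = build_drr_database(vol, intr, range_mm=4.0, step_mm=4.0,
                            coarse_pixel_mm=8.0, cache_dir=tmp_path / "db")
    loaded = load_drr_database(tmp_path / "db")
    assert loaded.content_hash == db.content_hash
    assert [p.translation for p in loaded.poses] == [p.translation for p in db.poses]
    for ia, ib in zip(db.images, loaded.images):
        np.testing.assert_array_equal(ia, ib)
    # cache hit: same inputs reload instead of re-rendering
    again = build_drr_database(vol, intr, range_mm=4.0, step_mm=4.0,
                               coarse_pixel_mm=8.0, cache_dir=tmp_path / "db")
    assert again.content_hash == db.content_hash


def test_database_cache_guard(tiny_db_setup, tmp_path):
    vol, intr = tiny_db_setup
    build_drr_database(vol, intr, range_mm=4.0, step_mm=4.0,
                       coarse_pixel_mm=8.0, cache_dir=tmp_path / "db")
    other = CTVolume(vol.voxels + 0.001, vol.spacing, vol.origin)
    with pytest.raises(FileExistsError):
        build_drr_database(other, intr, range_mm=4.0, step_mm=4.0,
                           coarse_pixel_mm=8.0, cache_dir=tmp_path / "db")
    db = build_drr_database(other, intr, range_mm=4.0, step_mm=4.0,
                            coarse_pixel_mm=8.0, cache_dir=tmp_path / "db",
                            overwrite=True)
    assert len(db) == 9
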