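import itertools

import numpy as np
import pytest

from sbhbm.roi_extraction import (
    ExtractionError,
    VolumeImage,
    extract_cohort,
    extract_region_means,
    gaussian_smooth,
    sphere_mask,
    zscore_columns,
)
from sbhbm.synthetic_data import SimulationConfig, generate_cohort, generate_volume_images


def lattice_sphere_count(radius_vox):
    """Brute-force oracle: integer offsets with squared norm <= radius^2."""
    r = int(np.ceil(radius_vox))
    return sum(
        1
        for dx, dy, dz in itertools.product(range(-r, r + 1), repeat=3)
        if dx * dx + dy * dy + dz * dz <= radius_vox**2
    )


@pytest.fixture
def unit_grid():
    return VolumeImage(np.zeros((21, 21, 21)), np.eye(4))


@pytest.mark.parametrize("diameter", [0.5, 2.5, 5.0, 7.5])
def test_sphere_mask_matches_lattice_oracle(unit_grid, diameter):
    m = sphere_mask((10, 10, 10), diameter, unit_grid)
    assert m.sum() == lattice_sphere_count(diameter / 2.0)


def test_sphere_mask_81_voxels_at_default_geometry(unit_grid):
    # 5 mm diameter on a 1 mm grid, center on a voxel center
    assert sphere_mask((10, 10, 10), 5.0, unit_grid).sum() == 81


def test_sphere_mask_single_voxel(unit_grid):
    m = sphere_mask((10, 10, 10), 0.5, unit_grid)
    assert m.sum() == 1 and m[10, 10, 10]


def test_sphere_mask_outside_grid(unit_grid):
    with pytest.raises(ExtractionError, match="outside"):
        sphere_mask((1000.0, 0.0, 0.0), 5.0, unit_grid)


def test_sphere_mask_clipped_guard():
    img = VolumeImage(np.zeros((11, 11, 11)), np.eye(4))
    with pytest.raises(ExtractionError, match="clipped"):
        sphere_mask((0, 5, 5), 5.0, img)
    m = sphere_mask((0, 5, 5), 5.0, img, allow_clipped=True)
    assert 0 < m.sum() < 81


def test_smooth_constant_image_unchanged_in_interior():
    img = VolumeImage(np.full((31, 31, 31), 3.0), np.eye(4))
    s = gaussian_smooth(img, 5.0)
    assert abs(s.data[15, 15, 15] - 3.0) < 1e-6


def test_smooth_conserves_impulse_mass():
    data = np.zeros((41, 41, 41))
    data[20, 20, 20] = 1.0
    s = gaussian_smooth(VolumeImage(data, np.eye(4)), 5.0)
    assert abs(s.data.sum() - 1.0) < 1e-6


def test_smooth_impulse_peak_matches_dense_convolution_oracle():
    """Peak of a smoothed impulse equals direct convolution with the sampled kernel."""
    sigma = 5.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = 13  # 6 sigma ~ 12.7 voxels on a 1 mm grid
    ax = np.arange(-half, half + 1, dtype=float)
    k1 = np.exp(-0.5 * (ax / sigma) ** 2)
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    kernel /= kernel.sum()
    data = np.zeros((41, 41, 41))
    data[20, 20, 20] = 1.0
    s = gaussian_smooth(VolumeImage(data, np.eye(4)), 5.0)
    assert s.data[20, 20, 20] == pytest.approx(kernel[half, half, half], abs=1e-9)


def test_smooth_respects_voxel_size():
    """On a 2 mm grid the kernel sigma in voxel units is half that of a 1 mm grid."""
    sigma_mm = 5.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    data = np.zeros((31, 31, 31))
    data[15, 15, 15] = 1.0
    s = gaussian_smooth(VolumeImage(data, np.diag([2.0, 2.0, 2.0, 1.0])), 5.0)
    sigma_vox = sigma_mm / 2.0
    half = int(np.ceil(6 * sigma_vox))
    ax = np.arange(-half, half + 1, dtype=float)
    k1 = np.exp(-0.5 * (ax / sigma_vox) ** 2)
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    kernel /= kernel.sum()
    assert s.data[15, 15, 15] == pytest.approx(kernel[half, half, half], abs=1e-9)


def test_nonpositive_fwhm_rejected(unit_grid):
    with pytest.raises(ExtractionError):
        gaussian_smooth(unit_grid, 0.0)


def test_nonfinite_image_rejected():
    data = np.zeros((5, 5, 5))
    data[2, 2, 2] = np.nan
    with pytest.raises(ExtractionError, match="non-finite"):
        VolumeImage(data, np.eye(4))


def test_zscore_examples():
    out = zscore_columns(np.array([[1.0], [3.0]]))
    assert np.allclose(out[:, 0], [-1.0, 1.0])
    with pytest.raises(ExtractionError, match="zero-variance"):
        zscore_columns(np.array([[5.0], [5.0], [5.0]]))
    with pytest.raises(ExtractionError):
        zscore_columns(np.array([[1.0]]))


def test_zscore_population_convention():
    rng = np.random.default_rng(4)
    m = rng.normal(3.0, 2.5, size=(101, 4))
    z = zscore_columns(m)
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.var(axis=0), 1.0, atol=1e-12)  # ddof=0


def test_extract_constant_image(default_atlas):
    # 2 mm grid covering the whole atlas
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-90.0, -110.0, -70.0]
    img = VolumeImage(np.full((91, 109, 91), 2.5), affine)
    means = extract_region_means(img, default_atlas, 5.0, None)
    assert np.allclose(means, 2.5)


@pytest.fixture(scope="module")
def painted(small_atlas):
    cohort = generate_cohort(SimulationConfig(n=16, seed=5), small_atlas)
    images = generate_volume_images(cohort, small_atlas, voxel_size_mm=1.0)
    return cohort, images


def test_round_trip_exact_without_smoothing(small_atlas, painted):
    cohort, images = painted
    for img in images[:4]:
        truth = cohort.volumes.values.loc[img.participant_id].to_numpy()
        means = extract_region_means(img, small_atlas, 5.0, None)
        assert np.allclose(means, truth, rtol=0, atol=1e-12)


def test_round_trip_within_one_percent_with_smoothing(small_atlas, painted):
    cohort, images = painted
    for img in images[:4]:
        truth = cohort.volumes.values.loc[img.participant_id].to_numpy()
        means = extract_region_means(img, small_atlas, 5.0, 5.0)
        assert np.all(np.abs(means - truth) / np.abs(truth) < 0.01)


def test_cross_diameter_extractions_agree(small_atlas, painted):
    """Sphere diameters 2.5/5/7.5 mm give near-identical region profiles."""
    cohort, images = painted
    res = {
        d: np.array([extract_region_means(img, small_atlas, d, 5.0) for img in images])
        for d in (2.5, 5.0, 7.5)
    }
    for j in range(len(small_atlas)):
        for a, b in [(2.5, 5.0), (5.0, 7.5), (2.5, 7.5)]:
            r = np.corrcoef(res[a][:, j], res[b][:, j])[0, 1]
            assert r >= 0.95


def test_translation_equivariance(small_atlas, tmp_path, painted):
    cohort, images = painted
    img = images[0]
    shift = np.array([3, -2, 4])  # integer voxels on a 1 mm grid
    rolled = VolumeImage(np.roll(img.data, shift, axis=(0, 1, 2)), img.affine)
    frame = small_atlas.to_frame()
    frame[["x", "y", "z"]] += shift
    shifted_csv = tmp_path / "shifted.csv"
    frame.to_csv(shifted_csv, index=False)
    from sbhbm.atlas import load_atlas

    shifted_atlas = load_atlas(shifted_csv, strict=False)
    m1 = extract_region_means(img, small_atlas, 5.0, None)
    m2 = extract_region_means(rolled, shifted_atlas, 5.0, None)
    assert np.allclose(m1, m2, atol=1e-12)


def test_extract_cohort_batch(small_atlas, painted, tmp_path):
    cohort, images = painted
    paths = []
    for img in images[:2]:
        p = tmp_path / f"{img.participant_id}.nii.gz"
        img.to_nifti(p)
        paths.append(p)
    # duplicate the first file: identical rows out
    paths.append(paths[0])
    raw, z = extract_cohort(paths, small_atlas, 5.0, None)
    assert raw.values.shape == (3, len(small_atlas))
    assert np.allclose(raw.values.iloc[0].to_numpy(), raw.values.iloc[2].to_numpy())
    zm = z.values.to_numpy()
    assert np.allclose(zm.mean(axis=0), 0, atol=1e-8) and np.allclose(zm.var(axis=0), 1, atol=1e-8)


def test_extract_cohort_collects_failures(small_atlas, tmp_path, painted):
    cohort, images = painted
    good = tmp_path / "good.nii.gz"
    images[0].to_nifti(good)
    with pytest.raises(ExtractionError, match="missing.nii"):
        extract_cohort([good, tmp_path / "missing.nii.gz"], small_atlas)
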