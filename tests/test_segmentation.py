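"""3D segmentation: thresholding rules, size filters, connectivity and
end-to-end distribution-shape preservation on synthetic stacks."""

import numpy as np
import pytest

from condkin import stats
from condkin.segmentation import (
    MODE_PRESETS,
    ImageStack,
    SegmentationParams,
    compute_threshold,
    per_cell_distribution,
    segment,
)
from condkin.synthetic import PopulationSpec, RenderSpec, render_stack, sample_population


def _noise_stack(shape=(8, 64, 64), mean=100.0, sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return ImageStack(voxels=np.clip(rng.normal(mean, sd, shape), 0, None))


def test_uniform_image_threshold_equals_value_and_flags():
    stack = ImageStack(voxels=np.full((4, 16, 16), 10.0))
    with pytest.warns(UserWarning, match="zero-variance"):
        thr = compute_threshold(stack, MODE_PRESETS["speckle"])
    assert thr == 10.0
    assert len(segment(stack, thr, MODE_PRESETS["speckle"])) == 0


def test_threshold_is_mean_plus_k_sd_of_max_projection():
    stack = _noise_stack()
    ref = stack.max_projection()
    thr = compute_threshold(stack, SegmentationParams(k_sd=2.0, min_voxels=1))
    assert thr == pytest.approx(ref.mean() + 2.0 * ref.std())


def test_brightest_plane_reference_for_cytoplasmic_mode():
    vox = np.full((5, 16, 16), 100.0)
    vox[3] += 50.0  # brightest plane
    stack = ImageStack(voxels=vox)
    thr = compute_threshold(stack, MODE_PRESETS["polyq"])
    assert thr == pytest.approx(150.0)  # mean of plane 3, zero variance


def test_min_voxel_filter_discards_small_regions():
    vox = np.zeros((6, 32, 32))
    vox[1, 2:7, 2:4] = 100.0  # 10 voxels
    vox[3, 10:15, 10:15] = 100.0  # 25 voxels
    stack = ImageStack(voxels=vox)
    params = SegmentationParams(k_sd=2.0, min_voxels=20)
    table = segment(stack, 50.0, params)
    assert len(table) == 1
    assert table.voxels.iloc[0] == 25


def test_volume_additivity_without_filtering():
    stack = _noise_stack(seed=3)
    stack.voxels[2, 10:20, 10:20] = 300.0
    stack.voxels[5, 30:35, 30:40] = 300.0
    params = SegmentationParams(k_sd=2.0, min_voxels=1)
    thr = compute_threshold(stack, params)
    table = segment(stack, thr, params)
    fg = int((stack.voxels > thr).sum())
    assert table.voxels.sum() == fg
    assert table.volume.sum() == pytest.approx(fg * stack.voxel_volume)


def test_raising_threshold_never_grows_regions():
    stack = _noise_stack(seed=4)
    stack.voxels[3, 8:24, 8:24] = 200.0
    lo = segment(stack, 120.0, SegmentationParams(min_voxels=1))
    hi = segment(stack, 160.0, SegmentationParams(min_voxels=1))
    assert len(hi) <= len(lo)
    assert hi.voxels.sum() <= lo.voxels.sum()


def test_26_connectivity_joins_diagonal_voxels():
    vox = np.zeros((4, 8, 8))
    vox[1, 1, 1] = vox[2, 2, 2] = 100.0  # corner neighbours
    table = segment(ImageStack(voxels=vox), 50.0, SegmentationParams(min_voxels=1))
    assert len(table) == 1


def test_corelet_2d_mode_sphericity_volume():
    """2D mode converts projected area A to V = (4/3)*pi*(A/pi)^1.5."""
    vox = np.zeros((3, 64, 64))
    vox[1, 20:30, 20:30] = 100.0  # 100-pixel square
    stack = ImageStack(voxels=vox, voxel_size=(0.3, 0.1, 0.1))
    table = segment(stack, 50.0, MODE_PRESETS["corelet"])
    area = 100 * 0.1 * 0.1
    assert table.volume.iloc[0] == pytest.approx((4 / 3) * np.pi * (area / np.pi) ** 1.5)


def test_anisotropic_voxels_use_full_volume_product():
    vox = np.zeros((4, 8, 8))
    vox[1, 2:4, 2:4] = 100.0
    stack = ImageStack(voxels=vox, voxel_size=(0.3, 0.1, 0.1))
    table = segment(stack, 50.0, SegmentationParams(min_voxels=1))
    assert table.volume.iloc[0] == pytest.approx(4 * 0.3 * 0.1 * 0.1)


@pytest.mark.parametrize(
    "law, expect_exponential",
    [(("exponential", 1.5), True), (("powerlaw", -1.5, 0.4, 60.0), False)],
)
def test_pipeline_preserves_generator_law(law, expect_exponential):
    """Rendered stacks from a known law, segmented and averaged across
    cells, keep the law's CCDF shape (SNR 10)."""
    spec = PopulationSpec(law=law, n_per_cell=18, n_cells=12, seed=11, detection_floor=0.3)
    cells = sample_population(spec)
    render = RenderSpec(shape=(36, 150, 150), background_sd=10.0)
    params = MODE_PRESETS["speckle"]
    tables = []
    for i, cell in enumerate(cells):
        stack, _ = render_stack(cell.volumes, render, seed=100 + i, cell_id=i)
        tables.append(segment(stack, compute_threshold(stack, params), params))
    samples = [s for s in per_cell_distribution(tables) if s.n >= 5]
    grid, mean, _, _ = stats.rescale_and_average(samples)
    good = mean > 0
    exp_fit = stats.fit_exponential((grid[good], mean[good]), quantiles=(0.05, 0.9))
    pl_fit = stats.fit_powerlaw((grid[good], mean[good]), quantiles=(0.05, 0.9))
    if expect_exponential:
        assert exp_fit.r_squared > pl_fit.r_squared
    else:
        assert pl_fit.r_squared > exp_fit.r_squared


def test_segmented_mean_matches_generator_truth():
    spec = PopulationSpec(law=("exponential", 2.0), n_per_cell=15, n_cells=8, seed=21,
                          detection_floor=0.5)
    cells = sample_population(spec)
    render = RenderSpec(shape=(36, 150, 150), background_sd=5.0)
    params = MODE_PRESETS["speckle"]
    est, true = [], []
    for i, cell in enumerate(cells):
        stack, _ = render_stack(cell.volumes, render, seed=200 + i, cell_id=i)
        table = segment(stack, compute_threshold(stack, params), params)
        est.append(table.volume.mean())
        true.append(cell.mean)
    assert np.mean(est) == pytest.approx(np.mean(true), rel=0.15)


def test_per_cell_distribution_shapes():
    import pandas as pd

    t1 = pd.DataFrame({"label": [1], "voxels": [30], "volume": [1.2], "cell_id": ["a"]})
    (s,) = per_cell_distribution([t1])
    assert s.n == 1 and s.cell_id == "a"
    with pytest.raises(ValueError):
        per_cell_distribution([])
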