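"""Preprocessing chain: crop/resize, slice selection, rescaling, channels."""

import numpy as np
import pytest

from phandose.dvh import compute_dvh, dose_at_volume
from phandose.preprocess import (
    CHANNEL_ORDER,
    PreprocessConfig,
    assemble_channels,
    crop_and_resize,
    normalize_global,
    denormalize,
    preprocess_sample,
    rescale_to_coverage,
    select_slices,
)
from phandose.volumes import DoseGrid, ImageVolume, PlanSample, ROI_NAMES, StructureMask


def _toy_sample(nz=12, ny=40, nx=40, spacing=(2.5, 0.98, 0.98), ptv_slices=(4, 8)):
    """Small synthetic plan with simple geometric masks."""
    shape = (nz, ny, nx)
    img = np.full(shape, 40.0)
    masks = {}
    body = np.zeros(shape, dtype=np.uint8)
    body[:, 4:-4, 4:-4] = 1
    zz, yy, xx = np.mgrid[:nz, :ny, :nx]
    zall = slice(0, nz)
    geoms = {
        "PTV": (slice(ptv_slices[0], ptv_slices[1] + 1), slice(16, 25), slice(16, 25)),
        "rectum": (zall, slice(26, 33), slice(17, 24)),
        "bladder": (zall, slice(8, 15), slice(16, 25)),
        "femoral_head_L": (zall, slice(16, 24), slice(28, 35)),
        "femoral_head_R": (zall, slice(16, 24), slice(5, 12)),
    }
    for roi, sl in geoms.items():
        m = np.zeros(shape, dtype=np.uint8)
        m[sl] = 1
        masks[roi] = StructureMask(roi_name=roi, values=m, spacing=spacing)
    masks["body"] = StructureMask(roi_name="body", values=body, spacing=spacing)
    dose_vals = np.where(masks["PTV"].as_bool(), 70.0, 20.0) * body
    return PlanSample(
        id="toy",
        image=ImageVolume(values=img, spacing=spacing),
        masks=masks,
        dose=DoseGrid(values=dose_vals, prescription=74.8, n_fractions=34, spacing=spacing),
    )


class TestCropAndResize:
    def test_constant_image_stays_constant(self):
        s = _toy_sample()
        out = crop_and_resize(s, PreprocessConfig(crop_size=32, target_size=16))
        assert np.allclose(out.image.values, 40.0)

    def test_clinical_spacing_arithmetic(self):
        # 0.98 mm at a 400 -> 128 reduction gives 3.06 mm in-plane
        s = _toy_sample(nz=2, ny=400, nx=400, ptv_slices=(0, 1))
        out = crop_and_resize(s, PreprocessConfig(crop_size=400, target_size=128))
        assert out.image.spacing[1] == pytest.approx(0.98 * 400 / 128)
        assert round(out.image.spacing[1], 2) == 3.06
        assert out.image.spacing[0] == 2.5  # slice thickness untouched

    def test_mask_area_preserved_by_nearest_neighbour(self):
        # 20-voxel-radius disk halved in resolution: voxel count within 15%
        # of the area-scaled oracle
        shape = (1, 128, 128)
        yy, xx = np.mgrid[:128, :128]
        disk = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2).astype(np.uint8)[None]
        masks = {}
        for roi in ROI_NAMES:
            masks[roi] = StructureMask(roi_name=roi, values=disk, spacing=(2.5, 1, 1))
        body = np.ones(shape, dtype=np.uint8)
        masks["body"] = StructureMask(roi_name="body", values=body, spacing=(2.5, 1, 1))
        s = PlanSample(
            id="disk",
            image=ImageVolume(values=np.zeros(shape), spacing=(2.5, 1, 1)),
            masks=masks,
            dose=DoseGrid(values=np.full(shape, 10.0), prescription=74.8,
                          n_fractions=34, spacing=(2.5, 1, 1)),
        )
        out = crop_and_resize(s, PreprocessConfig(crop_size=128, target_size=64))
        scaled = out.masks["PTV"].voxel_count
        oracle = disk.sum() / 4  # area scales with the square of the factor
        assert scaled == pytest.approx(oracle, rel=0.15)

    def test_masks_stay_binary(self):
        s = _toy_sample()
        out = crop_and_resize(s, PreprocessConfig(crop_size=32, target_size=16))
        for m in out.masks.values():
            assert set(np.unique(m.values)) <= {0, 1}

    def test_crop_window_exceeding_grid_rejected(self):
        s = _toy_sample(ny=30, nx=30)
        with pytest.raises(ValueError, match="crop window"):
            crop_and_resize(s, PreprocessConfig(crop_size=64, target_size=32))


class TestSelectSlices:
    def test_margin_hand_computed(self):
        # PTV on slices 4..8, 1 cm margin at 2.5 mm thickness -> 4 slices each side
        s = _toy_sample(ptv_slices=(4, 8))
        assert select_slices(s, PreprocessConfig(margin_mm=10.0)) == (0, 12 - 1)
        s2 = _toy_sample(nz=30, ptv_slices=(10, 20))
        assert select_slices(s2, PreprocessConfig(margin_mm=10.0)) == (6, 24)

    def test_zero_margin_is_exact_slab(self):
        s = _toy_sample(nz=30, ptv_slices=(10, 20))
        assert select_slices(s, PreprocessConfig(margin_mm=0.0)) == (10, 20)

    def test_cap_with_centred_truncation(self):
        s = _toy_sample(nz=30, ptv_slices=(0, 29))
        lo, hi = select_slices(s, PreprocessConfig(max_slices=11))
        assert hi - lo + 1 == 11
        centroid = 14  # PTV spans the whole grid
        assert lo <= centroid <= hi

    def test_full_grid_capped_at_80(self):
        s = _toy_sample(nz=100, ptv_slices=(0, 99))
        lo, hi = select_slices(s, PreprocessConfig(max_slices=80))
        assert hi - lo + 1 == 80


class TestRescaleToCoverage:
    def test_uniform_dose_hand_arithmetic(self):
        s = _toy_sample()
        scaled, factor = rescale_to_coverage(s.dose, s.masks["PTV"])
        # uniform 70 Gy in the PTV: factor = 0.95 * 74.8 / 70
        assert factor == pytest.approx(71.06 / 70.0, abs=2e-3)
        curve = compute_dvh(scaled, s.masks["PTV"])
        assert dose_at_volume(curve, 95.0) == pytest.approx(71.06, abs=0.1)

    def test_fixed_point(self):
        s = _toy_sample()
        dose = s.dose.with_values(np.where(s.masks["PTV"].as_bool(), 71.06, 20.0))
        _, factor = rescale_to_coverage(dose, s.masks["PTV"])
        assert factor == pytest.approx(1.0, abs=2e-3)

    def test_idempotent(self, phantom_sample):
        sample, _ = phantom_sample
        once, _ = rescale_to_coverage(sample.dose, sample.masks["PTV"])
        _, second_factor = rescale_to_coverage(once, sample.masks["PTV"])
        assert second_factor == pytest.approx(1.0, abs=2e-3)

    def test_zero_dose_rejected(self):
        s = _toy_sample()
        zero = s.dose.with_values(np.zeros_like(s.dose.values))
        with pytest.raises(ValueError):
            rescale_to_coverage(zero, s.masks["PTV"])


class TestNormalizeGlobal:
    def test_definition_and_inverse(self, rng):
        doses = [
            DoseGrid(values=rng.random((3, 4, 4)) * m, prescription=74.8,
                     n_fractions=34, spacing=(3, 3, 3))
            for m in (60.0, 82.3, 40.0)
        ]
        normed, const = normalize_global(doses)
        assert const == pytest.approx(max(d.values.max() for d in doses))
        assert all(a.max() <= 1.0 for a in normed)
        assert max(a.max() for a in normed) == pytest.approx(1.0)
        for a, d in zip(normed, doses):
            assert np.abs(denormalize(a, const) - d.values).max() < 1e-6 * const

    def test_single_sample_cohort(self, rng):
        d = DoseGrid(values=rng.random((2, 3, 3)) * 70, prescription=74.8,
                     n_fractions=34, spacing=(3, 3, 3))
        _, const = normalize_global([d])
        assert const == pytest.approx(d.values.max())

    def test_empty_and_zero_cohorts_rejected(self):
        with pytest.raises(ValueError):
            normalize_global([])
        zero = DoseGrid(values=np.zeros((2, 2, 2)), prescription=74.8,
                        n_fractions=34, spacing=(3, 3, 3))
        with pytest.raises(ValueError):
            normalize_global([zero])


class TestAssembleChannels:
    def test_channel_count_and_order(self, phantom_sample, pp_cfg):
        sample, _ = phantom_sample
        stack, index_map = assemble_channels(sample, pp_cfg)
        assert stack.shape[1] == len(CHANNEL_ORDER) == 7
        assert stack.shape[2:] == sample.shape[1:]
        assert len(index_map) == stack.shape[0]
        # mask channels binary, CT windowed into [0, 1]
        assert np.all((stack >= 0) & (stack <= 1))
        for k, name in enumerate(CHANNEL_ORDER):
            if name != "CT":
                assert set(np.unique(stack[:, k])) <= {0.0, 1.0}

    def test_body_contains_organ_channels(self, phantom_sample, pp_cfg):
        sample, _ = phantom_sample
        stack, _ = assemble_channels(sample, pp_cfg)
        body = stack[:, CHANNEL_ORDER.index("body")]
        for name in ("rectum", "bladder", "PTV"):
            organ = stack[:, CHANNEL_ORDER.index(name)]
            assert np.all(body[organ > 0] == 1.0)

    def test_deterministic(self, phantom_sample, pp_cfg):
        sample, _ = phantom_sample
        a, _ = assemble_channels(sample, pp_cfg)
        b, _ = assemble_channels(sample, pp_cfg)
        assert np.array_equal(a, b)


def test_preprocess_sample_end_to_end(phantom_sample, pp_cfg):
    sample, _ = phantom_sample
    prepped, stack, index_map = preprocess_sample(sample, pp_cfg)
    curve = compute_dvh(prepped.dose, prepped.masks["PTV"])
    assert dose_at_volume(curve, 95.0) == pytest.approx(0.95 * 74.8, abs=0.1)
    assert stack.shape[0] == len(index_map)
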