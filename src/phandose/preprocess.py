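"""Preprocessing: crop/resize, slice selection, coverage rescaling, channels.

The chain from a raw plan sample to model-ready tensors:

1. crop the in-plane field of view around the body centroid and resample to
   the network's input size (bilinear for image/dose, nearest for masks);
2. select up to ``max_slices`` consecutive slices covering the PTV plus a
   craniocaudal margin;
3. rescale the dose so that 95% of the PTV receives 95% of the prescription
   (applied to planned and predicted doses alike, so target coverage is a
   fixed point of the comparison);
4. normalise doses by the global maximum over the training cohort;
5. stack the seven input channels (CT, rectum, bladder, femoral L/R, PTV,
   body) per slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from . import dvh as _dvh
from .volumes import DoseGrid, ImageVolume, PlanSample, StructureMask

#: Fixed channel order of the model input.
CHANNEL_ORDER = ("CT", "rectum", "bladder", "femoral_head_L", "femoral_head_R", "PTV", "body")

#: CT display window (HU) used to scale intensities into [0, 1].
CT_WINDOW = (-200.0, 800.0)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``crop_size``/``target_size`` are in-plane pixel counts; ``None`` for
    ``crop_size`` keeps the full field of view (the phantom default, whose
    grids are already small).  ``coverage_fraction`` x prescription is the
    dose that ``coverage_volume_pct`` percent of the PTV must receive after
    rescaling.
    """

    crop_size: int | None = None
    target_size: int = 64
    max_slices: int = 80
    margin_mm: float = 10.0
    coverage_fraction: float = 0.95
    coverage_volume_pct: float = 95.0
    bin_width: float = _dvh.DEFAULT_BIN_WIDTH_GY

    def __post_init__(self) -> None:
        if self.crop_size is not None and self.target_size > self.crop_size:
            raise ValueError("target size must not exceed crop size")
        if self.margin_mm < 0 or self.max_slices < 1:
            raise ValueError("margin must be >= 0 and max_slices >= 1")
        if not (0 < self.coverage_fraction <= 1 and 0 < self.coverage_volume_pct <= 100):
            raise ValueError("coverage parameters out of range")


def _crop_window(center: float, size: int, full: int) -> slice:
    lo = int(round(center)) - size // 2
    if lo < 0 or lo + size > full:
        raise ValueError(f"crop window [{lo}, {lo + size}) exceeds grid of size {full}")
    return slice(lo, lo + size)


def crop_and_resize(sample: PlanSample, cfg: PreprocessConfig) -> PlanSample:
    """Crop in-plane around the body centroid and resample to target size.

    Image and dose are resampled bilinearly slice by slice; masks with
    nearest neighbour so they stay binary.  In-plane spacing is scaled by
    ``crop_size / target_size`` (e.g. 0.98 mm at a 400 -> 128 reduction
    becomes 3.06 mm).
    """
    nz, ny, nx = sample.shape
    crop = cfg.crop_size if cfg.crop_size is not None else min(ny, nx)
    com = np.argwhere(sample.masks["body"].as_bool())
    cy, cx = com[:, 1].mean(), com[:, 2].mean()
    ys, xs = _crop_window(cy, crop, ny), _crop_window(cx, crop, nx)

    factor = cfg.target_size / crop
    new_spacing = (
        sample.image.spacing[0],
        sample.image.spacing[1] / factor,
        sample.image.spacing[2] / factor,
    )

    def _resample(arr: np.ndarray, order: int) -> np.ndarray:
        sub = arr[:, ys, xs]
        if factor == 1.0:
            return sub.copy()
        out = zoom(sub.astype(np.float64), (1.0, factor, factor), order=order,
                   mode="nearest", grid_mode=True)
        return out

    image = ImageVolume(values=_resample(sample.image.values, 1), spacing=new_spacing)
    dose = DoseGrid(
        values=np.maximum(_resample(sample.dose.values, 1), 0.0),
        prescription=sample.dose.prescription,
        n_fractions=sample.dose.n_fractions,
        spacing=new_spacing,
    )
    masks = {
        roi: StructureMask(
            roi_name=roi,
            values=(_resample(m.values, 0) > 0.5).astype(np.uint8),
            spacing=new_spacing,
        )
        for roi, m in sample.masks.items()
    }
    return PlanSample(id=sample.id, image=image, masks=masks, dose=dose)


def select_slices(sample: PlanSample, cfg: PreprocessConfig) -> tuple[int, int]:
    """Consecutive slice range ``[lo, hi]`` covering the PTV plus margin.

    The margin is ``ceil(margin_mm / slice thickness)`` slices on each side,
    clipped to the grid.  If the covered extent exceeds ``max_slices`` the
    range is truncated symmetrically about the PTV centroid slice.
    """
    ptv = sample.masks["PTV"].as_bool()
    zidx = np.nonzero(ptv.any(axis=(1, 2)))[0]
    if zidx.size == 0:
        raise ValueError("empty PTV: cannot select slices")
    margin = int(np.ceil(cfg.margin_mm / sample.image.spacing[0])) if cfg.margin_mm > 0 else 0
    lo = max(0, int(zidx[0]) - margin)
    hi = min(sample.shape[0] - 1, int(zidx[-1]) + margin)
    if hi - lo + 1 > cfg.max_slices:
        centroid = int(round(np.argwhere(ptv)[:, 0].mean()))
        half = cfg.max_slices // 2
        lo = max(lo, centroid - half)
        hi = min(hi, lo + cfg.max_slices - 1)
        lo = max(0, hi - cfg.max_slices + 1)
    return lo, hi


def rescale_to_coverage(
    dose: DoseGrid, ptv: StructureMask, cfg: PreprocessConfig | None = None
) -> tuple[DoseGrid, float]:
    """Scale the dose so the PTV coverage goal holds exactly.

    The grid is multiplied by ``coverage_fraction * prescription / D95%``
    (with the default 95%/95% goal), after which the PTV D95% equals 0.95 x
    prescription to within DVH interpolation tolerance.  Returns the scaled
    dose and the factor.  Idempotent: a second application has factor ~1.
    """
    cfg = cfg or PreprocessConfig()
    if not np.any(dose.values[ptv.as_bool()] > 0):
        raise ValueError("dose is zero on the PTV; coverage rescale undefined")
    curve = _dvh.compute_dvh(dose, ptv, bin_width=cfg.bin_width)
    d_cov = _dvh.dose_at_volume(curve, cfg.coverage_volume_pct)
    if d_cov <= 0:
        raise ValueError("PTV coverage dose is zero; cannot rescale")
    factor = cfg.coverage_fraction * dose.prescription / d_cov
    return dose.with_values(dose.values * factor), factor


def normalize_global(doses: list[DoseGrid]) -> tuple[list[np.ndarray], float]:
    """Divide all dose grids by the cohort-wide maximum dose.

    Returns the normalised arrays (values in [0, 1]) and the constant, which
    must be stored to denormalise model predictions at test time.
    """
    if not doses:
        raise ValueError("empty cohort")
    constant = max(float(d.values.max()) for d in doses)
    if constant <= 0:
        raise ValueError("cohort-wide maximum dose is zero")
    return [d.values / constant for d in doses], constant


def denormalize(values: np.ndarray, constant: float) -> np.ndarray:
    return values * constant


def _window_ct(values: np.ndarray) -> np.ndarray:
    lo, hi = CT_WINDOW
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def assemble_channels(sample: PlanSample, cfg: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice 7-channel input stack for the selected slice range.

    Returns ``(stack, slice_index_map)`` where ``stack`` has shape
    ``(n_slices, 7, H, W)`` in the fixed :data:`CHANNEL_ORDER` and the index
    map records each slice's position in the source grid.
    """
    lo, hi = select_slices(sample, cfg)
    sl = slice(lo, hi + 1)
    channels = []
    for name in CHANNEL_ORDER:
        if name == "CT":
            channels.append(_window_ct(sample.image.values[sl]))
        else:
            channels.append(sample.masks[name].values[sl].astype(np.float64))
    stack = np.stack(channels, axis=1).astype(np.float32)
    return stack, np.arange(lo, hi + 1)


def preprocess_sample(
    sample: PlanSample, cfg: PreprocessConfig
) -> tuple[PlanSample, np.ndarray, np.ndarray]:
    """Full per-sample chain: crop/resize, coverage rescale, channel stack.

    Returns the resampled sample (dose coverage-rescaled), the channel
    stack and the slice index map.  Global normalisation is a cohort-level
    step and applied separately.
    """
    resampled = crop_and_resize(sample, cfg)
    dose, _ = rescale_to_coverage(resampled.dose, resampled.masks["PTV"], cfg)
    resampled = PlanSample(id=resampled.id, image=resampled.image,
                           masks=resampled.masks, dose=dose)
    stack, index_map = assemble_channels(resampled, cfg)
    return resampled, stack, index_map
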