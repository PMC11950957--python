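"""Synthetic pelvic phantom cohorts.

Generates patient-equivalent plan samples — CT-like image, the six
structures (PTV, rectum, bladder, two femoral heads, body) and an analytic
VMAT-like dose — so that the whole dose-prediction and NTCP pipeline runs
and is testable without any patient data.

Anatomy model
-------------
Everything lives on a coarse grid (default 64 x 64 in-plane, 32 slices at
3 mm isotropic).  The PTV (prostate plus margin) is an ellipsoid near the
grid centre; the rectum is a curved craniocaudal tube posterior to it,
separated by a sampled PTV-rectum gap — the anatomical driver of rectal
dose and hence of bleeding risk; the bladder sits superior-anterior, the
femoral heads lateral, all inside an elliptical body.  Masks are cropped
craniocaudally to PTV +/- 1 cm, mirroring how structures are contoured in
prostate plans.  Organs are pairwise disjoint by construction.

Dose model
----------
The dose is analytic, not a transport or optimiser simulation: prescription
dose (with a small smooth heterogeneity boost) inside the PTV, exponential
lateral fall-off with distance from the PTV surface, and a directional
multiplicative attenuation that deepens toward the rectum, producing the
concave posterior isodose characteristic of rectum-sparing VMAT plans.
Smooth additive noise emulates plan-to-plan variability; dose is clipped to
110% of prescription (the planning-goal maximum) and to zero outside the
body.  Inter-patient variability in the PTV-rectum gap, fall-off scale and
sparing strength yields a cohort whose grade >= 2 late-rectal-bleeding LKB
NTCP spread is comparable to a clinical VMAT training cohort (roughly
10-15%).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .volumes import DoseGrid, ImageVolume, PlanSample, StructureMask, write_plan_sample

log = logging.getLogger(__name__)

Range = tuple[float, float]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, dose-model and cohort parameters for phantom generation.

    Lengths are mm, doses Gy.  Every ``*_range`` is sampled uniformly per
    sample.  Defaults target a desk-scale 64 x 64 x 32 grid at 3 mm voxels
    on which the full train/predict/evaluate loop runs on one CPU.
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    prescription: float = 74.8
    n_fractions: int = 34

    # anatomy (mm)
    ptv_radius_z_range: Range = (16.0, 21.0)
    ptv_radius_y_range: Range = (13.0, 17.0)
    ptv_radius_x_range: Range = (16.0, 21.0)
    ptv_center_jitter_mm: float = 3.0
    rectum_radius_range: Range = (12.0, 16.0)
    rectum_curvature_mm_range: Range = (4.0, 9.0)
    ptv_rectum_gap_range: Range = (-9.0, -4.0)
    bladder_radius_range: Range = (16.0, 22.0)
    femoral_radius_range: Range = (15.0, 19.0)
    femoral_offset_range: Range = (48.0, 55.0)
    body_semiaxis_x_range: Range = (82.0, 90.0)
    body_semiaxis_y_range: Range = (62.0, 72.0)
    crop_margin_mm: float = 10.0

    # dose model: sigmoid penumbra (50% at `falloff` mm from the PTV surface,
    # width `penumbra_mm`) riding on a slowly decaying low-dose bath
    falloff_mm_range: Range = (9.0, 13.0)
    penumbra_mm: float = 2.0
    bath_fraction: float = 0.32
    bath_scale_mm: float = 45.0
    sparing_strength_range: Range = (0.15, 0.25)
    sparing_scale_mm: float = 9.0
    sparing_onset_mm: float = 4.0
    # in-PTV heterogeneity: smooth boost field spanning [het_lo, het_hi] x
    # prescription, giving slight cold and hot spots (D50% > D95% strictly)
    het_lo: float = -0.03
    het_hi: float = 0.07
    noise_gy: float = 0.6

    cohort_size: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_range"):
                lo, hi = v
                if lo > hi:
                    raise ValueError(f"{f.name} must be an ordered range, got {v}")
                # the PTV-rectum gap may be negative (thin interface); all
                # other geometric/dosimetric ranges must be non-negative
                if f.name != "ptv_rectum_gap_range" and lo < 0:
                    raise ValueError(f"{f.name} must be non-negative, got {v}")
        if min(self.spacing) <= 0 or min(self.shape) <= 0:
            raise ValueError("shape and spacing must be positive")
        if self.prescription <= 0 or self.n_fractions < 1:
            raise ValueError("invalid prescription/fractionation")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("shape", "spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key, val in raw.items():
            if key.endswith("_range"):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _coords_mm(shape, spacing):
    z = np.arange(shape[0])[:, None, None] * spacing[0]
    y = np.arange(shape[1])[None, :, None] * spacing[1]
    x = np.arange(shape[2])[None, None, :] * spacing[2]
    return z, y, x


def _sample_params(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    """Draw all per-sample scalars in one fixed order (determinism contract)."""
    u = rng.uniform
    return {
        "ptv_rz": u(*cfg.ptv_radius_z_range),
        "ptv_ry": u(*cfg.ptv_radius_y_range),
        "ptv_rx": u(*cfg.ptv_radius_x_range),
        "jitter_y": u(-cfg.ptv_center_jitter_mm, cfg.ptv_center_jitter_mm),
        "jitter_x": u(-cfg.ptv_center_jitter_mm, cfg.ptv_center_jitter_mm),
        "rect_r": u(*cfg.rectum_radius_range),
        "rect_curv": u(*cfg.rectum_curvature_mm_range),
        "gap": u(*cfg.ptv_rectum_gap_range),
        "blad_r": u(*cfg.bladder_radius_range),
        "fem_r": u(*cfg.femoral_radius_range),
        "fem_off": u(*cfg.femoral_offset_range),
        "body_bx": u(*cfg.body_semiaxis_x_range),
        "body_by": u(*cfg.body_semiaxis_y_range),
        "falloff": u(*cfg.falloff_mm_range),
        "sparing": u(*cfg.sparing_strength_range),
    }


def generate_anatomy(
    cfg: PhantomConfig, rng: np.random.Generator
) -> tuple[ImageVolume, dict[str, StructureMask], dict]:
    """One phantom anatomy: CT-like image, six masks, sampled parameters.

    The returned parameter dict records the sampled geometry (notably the
    PTV-rectum ``gap`` in mm) for downstream realism checks.
    """
    shape, spacing = cfg.shape, cfg.spacing
    p = _sample_params(cfg, rng)
    z, y, x = _coords_mm(shape, spacing)
    extent = tuple((n - 1) * s for n, s in zip(shape, spacing))
    cz, cy, cx = extent[0] / 2, extent[1] / 2 - 8.0 + p["jitter_y"], extent[2] / 2 + p["jitter_x"]

    ptv = ((z - cz) / p["ptv_rz"]) ** 2 + ((y - cy) / p["ptv_ry"]) ** 2 + (
        (x - cx) / p["ptv_rx"]
    ) ** 2 <= 1.0

    # rectum: tube posterior to the PTV, bowing further posterior toward the
    # cranial/caudal ends; the mid-slice anterior surface sits `gap` mm from
    # the PTV's posterior surface.
    y_rect = cy + p["ptv_ry"] + p["gap"] + p["rect_r"]
    bow = p["rect_curv"] * ((z - cz) / max(extent[0] / 2, 1.0)) ** 2
    rect = ((y - (y_rect + bow)) ** 2 + (x - cx) ** 2) <= p["rect_r"] ** 2
    # a negative sampled gap leaves a thin PTV/anterior-rectal-wall interface
    # (as in real structure sets, where the PTV margin reaches into the
    # rectal wall); all other organ pairs are disjoint by construction

    # bladder: ellipsoid superior-anterior to the PTV
    bz = cz + p["ptv_rz"] + 0.55 * p["blad_r"]
    by = cy - p["ptv_ry"] - 0.3 * p["blad_r"]
    blad = ((z - bz) / p["blad_r"]) ** 2 + ((y - by) / p["blad_r"]) ** 2 + (
        (x - cx) / (1.15 * p["blad_r"])
    ) ** 2 <= 1.0
    blad = blad & ~ptv & ~rect

    fem_l = (z - cz) ** 2 + (y - cy) ** 2 + (x - (cx + p["fem_off"])) ** 2 <= p["fem_r"] ** 2
    fem_r = (z - cz) ** 2 + (y - cy) ** 2 + (x - (cx - p["fem_off"])) ** 2 <= p["fem_r"] ** 2

    body = ((y - extent[1] / 2) / p["body_by"]) ** 2 + (
        (x - extent[2] / 2) / p["body_bx"]
    ) ** 2 <= 1.0
    body = np.broadcast_to(body, shape).copy()

    organs = {"PTV": ptv, "rectum": rect, "bladder": blad,
              "femoral_head_L": fem_l, "femoral_head_R": fem_r}
    for name, m in organs.items():
        if not m.any():
            raise ValueError(f"phantom organ {name!r} is empty; check config ranges")
        if (m & ~body).any():
            raise ValueError(f"phantom organ {name!r} leaves the body outline")

    # craniocaudal crop: structures only exist within PTV +/- crop margin
    zidx = np.nonzero(ptv.any(axis=(1, 2)))[0]
    margin = int(np.ceil(cfg.crop_margin_mm / spacing[0]))
    z0, z1 = max(0, zidx[0] - margin), min(shape[0] - 1, zidx[-1] + margin)
    slab = np.zeros(shape, dtype=bool)
    slab[z0 : z1 + 1] = True
    masks = {
        name: StructureMask(roi_name=name, values=(m & slab).astype(np.uint8), spacing=spacing)
        for name, m in {**organs, "body": body}.items()
    }

    # CT-like image: soft tissue ~40, urine ~15, bone ~700, air -1000,
    # plus smooth texture noise.
    img = np.full(shape, -1000.0)
    img[body] = 40.0
    img[blad] = 15.0
    img[ptv] = 45.0
    img[rect] = 25.0
    img[fem_l | fem_r] = 700.0
    img += gaussian_filter(rng.standard_normal(shape), sigma=1.5) * 30.0 * body
    image = ImageVolume(values=img, spacing=spacing)
    p.update({"z0": int(z0), "z1": int(z1), "ptv_center_mm": (cz, cy, cx)})
    return image, masks, p


def analytic_dose(
    masks: dict[str, StructureMask],
    cfg: PhantomConfig,
    rng: np.random.Generator,
    params: dict,
    include_noise: bool = True,
) -> DoseGrid:
    """VMAT-like analytic dose for one phantom anatomy.

    Prescription (plus a smooth in-target boost) inside the PTV, exponential
    fall-off outside, attenuated toward the rectum; optional smooth noise;
    clipped to [0, 1.1 x prescription] and zeroed outside the body.
    """
    spacing = cfg.spacing
    ptv = masks["PTV"].as_bool()
    rect = masks["rectum"].as_bool()
    body = masks["body"].as_bool()
    pres = cfg.prescription

    d_ptv = distance_transform_edt(~ptv, sampling=spacing)
    d_rect = distance_transform_edt(~rect, sampling=spacing)

    # penumbra: ~100% at the PTV surface, 50% at `falloff` mm, plus a slow
    # low-dose bath carrying intermediate dose out to the bladder and beyond
    penumbra = 1.0 / (1.0 + np.exp((d_ptv - params["falloff"]) / cfg.penumbra_mm))
    bath = np.exp(-d_ptv / cfg.bath_scale_mm)
    base = (1.0 - cfg.bath_fraction) * penumbra + cfg.bath_fraction * bath

    # concave rectal sparing: deepest attenuation at/inside the rectum, no
    # effect inside the PTV itself
    onset = 1.0 - np.exp(-d_ptv / cfg.sparing_onset_mm)
    atten = 1.0 - params["sparing"] * np.exp(-d_rect / cfg.sparing_scale_mm) * onset
    dose = pres * base * atten

    if cfg.het_hi > cfg.het_lo and ptv.any():
        field = gaussian_filter(rng.standard_normal(cfg.shape), sigma=2.5)
        fvals = field[ptv]
        lo, hi = fvals.min(), fvals.max()
        unit = (field - lo) / max(hi - lo, 1e-12)
        # hot spots taper toward the PTV surface, as optimisers push them
        # away from the adjacent rectal wall
        d_inside = distance_transform_edt(ptv, sampling=spacing)
        interior = 1.0 - np.exp(-d_inside / 5.0)
        boost = cfg.het_lo + (cfg.het_hi - cfg.het_lo) * unit * interior
        dose[ptv] = pres * (1.0 + boost[ptv])
    if include_noise and cfg.noise_gy > 0:
        noise = gaussian_filter(rng.standard_normal(cfg.shape), sigma=2.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        dose = dose + cfg.noise_gy * noise
    dose = np.clip(dose, 0.0, 1.10 * pres) * body
    return DoseGrid(
        values=dose, prescription=pres, n_fractions=cfg.n_fractions, spacing=spacing
    )


def generate_plan_sample(cfg: PhantomConfig, sample_id: str, seed_seq) -> tuple[PlanSample, dict]:
    """One phantom plan from a ``numpy.random.SeedSequence``."""
    rng = np.random.default_rng(seed_seq)
    image, masks, params = generate_anatomy(cfg, rng)
    dose = analytic_dose(masks, cfg, rng, params)
    return PlanSample(id=sample_id, image=image, masks=masks, dose=dose), params


def generate_cohort(
    cfg: PhantomConfig, out_dir: str | Path | None = None
) -> tuple[list[PlanSample], list[dict]]:
    """A cohort of ``cfg.cohort_size`` phantoms, optionally written to disk.

    Per-sample seeds are spawned from ``cfg.seed`` so the cohort is a pure
    function of the config.  Returns the samples and their sampled-parameter
    records; when ``out_dir`` is given, NIfTI volumes plus one JSON manifest
    per sample are written there.
    """
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.cohort_size)
    samples, records = [], []
    for i, ss in enumerate(seqs):
        sid = f"phantom_{i:03d}"
        sample, params = generate_plan_sample(cfg, sid, ss)
        samples.append(sample)
        records.append(params)
        if out_dir is not None:
            write_plan_sample(sample, out_dir)
    log.info("generated %d phantom plan(s)", len(samples))
    return samples, records
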