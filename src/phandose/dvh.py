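"""Cumulative dose-volume histograms and plan-quality metrics.

The cumulative DVH of a structure reports, for each dose level ``d``, the
percentage of the structure's volume receiving at least ``d`` Gy.  All
DVH-derived metrics in this package (D_x%, V_xGy, homogeneity index, R50%,
the NTCP models) are computed from one shared curve representation with a
default bin width of 0.1 Gy, fine enough that interpolation error is well
below the 0.01 Gy precision at which plan metrics are usually reported.

Conventions
-----------
* ``D_x%`` — the minimum dose received by the hottest x% of the structure.
  On flat curve segments ties resolve to the *largest* qualifying dose.
* ``V_xGy`` — percentage of the structure receiving at least x Gy, linearly
  interpolated between bin edges.
* Structure volumes are voxel counts times the voxel volume of the
  structure's own grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import DoseGrid, StructureMask

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH sampled at uniform bin edges.

    ``edges[i]`` is a dose in Gy and ``cum_volume_pct[i]`` the percentage of
    the structure receiving at least that dose.  The curve starts at 0 Gy
    with 100% and is non-increasing.
    """

    edges: np.ndarray
    cum_volume_pct: np.ndarray
    voxel_count: int
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.float64)
        c = np.asarray(self.cum_volume_pct, dtype=np.float64)
        if e.ndim != 1 or e.shape != c.shape or e.size < 2:
            raise ValueError("edges and cum_volume_pct must be 1D arrays of equal length >= 2")
        if np.any(np.diff(c) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing in dose")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "cum_volume_pct", c)

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def structure_volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin centers (Gy) and relative volumes ``v_i`` summing to 1.

        The differential histogram underlying the cumulative curve: bin i
        spans ``[edges[i], edges[i+1])`` and holds the fraction of the
        structure whose dose falls in that bin.
        """
        v = -np.diff(self.cum_volume_pct) / 100.0
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return centers, v


def compute_dvh(
    dose: DoseGrid | np.ndarray,
    mask: StructureMask | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
    voxel_volume_mm3: float | None = None,
) -> DVHCurve:
    """Cumulative DVH of ``dose`` over the voxels of ``mask``.

    Raises ``ValueError`` for an empty mask — a structure with no delineated
    voxels has no DVH (plans with a missing structure are excluded upstream).
    """
    if isinstance(dose, DoseGrid):
        dose_values = dose.values
        if voxel_volume_mm3 is None:
            voxel_volume_mm3 = float(np.prod(dose.spacing))
    else:
        dose_values = np.asarray(dose, dtype=np.float64)
        if voxel_volume_mm3 is None:
            voxel_volume_mm3 = 1.0
    mvals = mask.as_bool() if isinstance(mask, StructureMask) else np.asarray(mask, dtype=bool)
    if mvals.shape != dose_values.shape:
        raise ValueError(f"grid mismatch: mask {mvals.shape} vs dose {dose_values.shape}")
    voxels = dose_values[mvals]
    if voxels.size == 0:
        raise ValueError("empty structure mask: DVH undefined")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")

    dmax = float(voxels.max())
    n_bins = int(np.ceil(dmax / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(voxels, bins=edges)
    # Cumulative count of voxels with dose >= each edge.  A voxel falling in
    # bin [e_i, e_{i+1}) counts toward all edges <= e_i.
    cum = np.concatenate([np.cumsum(hist[::-1])[::-1], [0]])
    cum_pct = 100.0 * cum / voxels.size
    return DVHCurve(
        edges=edges,
        cum_volume_pct=cum_pct,
        voxel_count=int(voxels.size),
        voxel_volume_mm3=float(voxel_volume_mm3),
    )


def volume_at_dose(curve: DVHCurve, dose_gy: float) -> float:
    """V_xGy: percent of the structure receiving at least ``dose_gy``."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if dose_gy >= curve.edges[-1]:
        return 0.0
    return float(np.interp(dose_gy, curve.edges, curve.cum_volume_pct))


def dose_at_volume(curve: DVHCurve, volume_pct: float) -> float:
    """D_x%: minimum dose delivered to the hottest ``volume_pct`` percent.

    Inverse interpolation of the cumulative curve.  Where the curve is flat
    at exactly ``volume_pct``, the largest qualifying dose is returned,
    matching the "minimum dose to the hottest x%" reading.
    """
    if not 0 < volume_pct <= 100:
        raise ValueError("volume percentage must be in (0, 100]")
    c = curve.cum_volume_pct
    e = curve.edges
    qualifying = np.nonzero(c >= volume_pct)[0]
    if qualifying.size == 0:
        return 0.0
    i = qualifying[-1]  # largest edge with coverage >= x
    if i == len(e) - 1 or c[i] == volume_pct:
        return float(e[i])
    # interpolate on the falling segment [e_i, e_{i+1}]
    c0, c1 = c[i], c[i + 1]
    if c0 == c1:
        return float(e[i + 1])
    frac = (c0 - volume_pct) / (c0 - c1)
    return float(e[i] + frac * (e[i + 1] - e[i]))


def mean_dose(dose: DoseGrid | np.ndarray, mask: StructureMask | np.ndarray) -> float:
    """D_mean in Gy, computed exactly from voxel doses (no binning)."""
    dv = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose, dtype=np.float64)
    mv = mask.as_bool() if isinstance(mask, StructureMask) else np.asarray(mask, dtype=bool)
    voxels = dv[mv]
    if voxels.size == 0:
        raise ValueError("empty structure mask")
    return float(voxels.mean())


def homogeneity_index(curve: DVHCurve) -> float:
    """HI = 100 * (D2% - D98%) / D50%, in percent, for a PTV curve."""
    d2 = dose_at_volume(curve, 2.0)
    d98 = dose_at_volume(curve, 98.0)
    d50 = dose_at_volume(curve, 50.0)
    if d50 == 0:
        raise ValueError("D50% is zero; homogeneity index undefined")
    return 100.0 * (d2 - d98) / d50


def r50(dose: DoseGrid, ptv: StructureMask, body: StructureMask | None = None) -> float:
    """R50% = 100 * (volume receiving >= half the prescription) / PTV volume.

    The half-prescription isodose is evaluated over the whole grid,
    intersected with the body mask when one is given (dose spilling into air
    is not counted).
    """
    iso = dose.values >= 0.5 * dose.prescription
    if body is not None:
        iso = iso & body.as_bool()
    n_ptv = ptv.voxel_count
    if n_ptv == 0:
        raise ValueError("empty PTV")
    return 100.0 * float(iso.sum()) / n_ptv


# Metric tables ---------------------------------------------------------------

#: (structure, metric) pairs reported for every plan, in report order.
DVH_METRICS: tuple[tuple[str, str], ...] = (
    ("PTV", "D98%"), ("PTV", "D95%"), ("PTV", "D50%"), ("PTV", "D2%"),
    ("PTV", "Dmean"), ("PTV", "HI"), ("PTV", "R50%"),
    ("rectum", "V70Gy"), ("rectum", "V60Gy"), ("rectum", "V50Gy"),
    ("rectum", "V40Gy"), ("rectum", "D2%"), ("rectum", "Dmean"),
    ("bladder", "V70Gy"), ("bladder", "V60Gy"), ("bladder", "V50Gy"),
    ("bladder", "V40Gy"), ("bladder", "D2%"), ("bladder", "Dmean"),
    ("femoral_head_R", "D2%"), ("femoral_head_R", "Dmean"),
    ("femoral_head_L", "D2%"), ("femoral_head_L", "Dmean"),
)

#: Metrics expressed in Gy (the rest are percentages).
GY_METRICS = frozenset({"D98%", "D95%", "D50%", "D2%", "Dmean"})


def metric_suite(
    dose: DoseGrid,
    masks,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> dict[tuple[str, str], float]:
    """All standard DVH metrics for one plan.

    Returns a mapping from (structure, metric) to value: PTV
    D98/D95/D50/D2/Dmean/HI/R50%, rectum and bladder V70/V60/V50/V40/D2/Dmean,
    and femoral-head D2/Dmean — 23 metrics in total.
    """
    curves = {}
    for roi in ("PTV", "rectum", "bladder", "femoral_head_R", "femoral_head_L"):
        curves[roi] = compute_dvh(dose, masks[roi], bin_width=bin_width)

    out: dict[tuple[str, str], float] = {}
    for roi, metric in DVH_METRICS:
        if metric == "HI":
            out[(roi, metric)] = homogeneity_index(curves[roi])
        elif metric == "R50%":
            out[(roi, metric)] = r50(dose, masks["PTV"], masks.get("body"))
        elif metric == "Dmean":
            out[(roi, metric)] = mean_dose(dose, masks[roi])
        elif metric.startswith("D"):
            pct = float(metric[1:-1])
            out[(roi, metric)] = dose_at_volume(curves[roi], pct)
        else:  # VxGy
            gy = float(metric[1:-2])
            out[(roi, metric)] = volume_at_dose(curves[roi], gy)
    return out
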