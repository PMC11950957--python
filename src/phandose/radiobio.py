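"""Radiobiological models: EQD2 conversion and rectal NTCP.

Two normal-tissue complication probability (NTCP) models for late rectal
toxicity are implemented, both evaluated on the cumulative DVH of the rectum
after converting each dose bin to its equivalent dose in 2-Gy fractions
(EQD2) under the linear-quadratic model:

* **Lyman-Kutcher-Burman (LKB)** — the DVH is reduced to a single "effective
  dose" ``Deff = (sum_i v_i * EQD2_i**(1/n))**n`` (a generalised power mean
  over the differential bins), and NTCP is the standard-normal CDF of
  ``t = (Deff - TD50) / (m * TD50)``.  Small ``n`` makes the organ behave
  serially (Deff tracks the hottest subvolume).

* **Relative seriality (RS)** — each subvolume responds by the Poisson model
  ``P(D) = 2**(-exp(e**gamma * (1 - D/D50)))`` and responses combine as
  ``NTCP = (1 - prod_i (1 - P(D_i)**s)**v_i)**(1/s)`` with seriality ``s``.

Endpoint parameters (seven LKB endpoints for late rectal bleeding, stool
frequency, bowel pain, sphincter control and stricture/ulcer, plus an RS
grade-2 bleeding endpoint) ship in a versioned YAML registry with
``alpha/beta = 3.0 Gy`` throughout.  Public NTCP outputs are percentages;
internal math uses fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Mapping

import numpy as np
import yaml
from scipy.special import ndtr

from .dvh import DEFAULT_BIN_WIDTH_GY, DVHCurve, compute_dvh
from .volumes import DoseGrid, StructureMask


@dataclass(frozen=True)
class LKBParams:
    """Lyman-Kutcher-Burman endpoint parameters."""

    n: float
    m: float
    td50: float
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.m > 0 and self.td50 > 0 and self.alpha_beta > 0):
            raise ValueError("all LKB parameters must be positive")


@dataclass(frozen=True)
class RSParams:
    """Relative-seriality endpoint parameters."""

    d50: float
    gamma: float
    s: float
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if not (self.d50 > 0 and self.gamma > 0 and self.s > 0 and self.alpha_beta > 0):
            raise ValueError("all RS parameters must be positive")


def load_registry() -> Mapping[str, Mapping[str, LKBParams | RSParams]]:
    """The packaged endpoint-parameter registry, read-only.

    Returns ``{"lkb": {endpoint: LKBParams}, "rs": {endpoint: RSParams}}``.
    """
    text = resources.files("phandose.data").joinpath("endpoints.yaml").read_text()
    raw = yaml.safe_load(text)
    lkb = {
        name: LKBParams(n=e["n"], m=e["m"], td50=e["td50"], alpha_beta=e["alpha_beta"])
        for name, e in raw["lkb"].items()
    }
    rs = {
        name: RSParams(d50=e["d50"], gamma=e["gamma"], s=e["s"], alpha_beta=e["alpha_beta"])
        for name, e in raw["rs"].items()
    }
    return MappingProxyType({"lkb": MappingProxyType(lkb), "rs": MappingProxyType(rs)})


REGISTRY = load_registry()

#: Endpoint columns of the NTCP suite, in report order.
NTCP_ENDPOINTS: tuple[str, ...] = (
    "G1-LRB-LKB-NTCP",
    "G2-LRB-LKB-NTCP",
    "G2-LRB-RS-NTCP",
    "G1-stool-frequency",
    "G2-stool-frequency",
    "G1-bowel-pain",
    "G1-sphincter-control",
    "G1-stricture-ulcer",
)


def eqd2(total_dose_gy, n_fractions: int, alpha_beta: float = 3.0):
    """Equivalent dose in 2-Gy fractions under the linear-quadratic model.

    ``EQD2 = D * (d + a/b) / (2 + a/b)`` where ``d = D / N`` is the local
    dose per fraction: a voxel (or DVH bin) receiving total dose D over N
    fractions receives D/N per fraction.  Total doses delivered at exactly
    2 Gy/fraction are fixed points.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    d = np.asarray(total_dose_gy, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = d * (d / n_fractions + alpha_beta) / (2.0 + alpha_beta)
    return float(out) if np.isscalar(total_dose_gy) else out


def _differential_eqd2(curve: DVHCurve, n_fractions: int, alpha_beta: float):
    """Bin-centre EQD2 values and relative volumes from a physical-dose DVH."""
    centers, v = curve.differential()
    keep = v > 0
    return eqd2(centers[keep], n_fractions, alpha_beta), v[keep]


def effective_dose(eqd2_gy: np.ndarray, v: np.ndarray, p: LKBParams) -> float:
    """Generalised-mean effective dose ``(sum v_i * D_i**(1/n))**n`` in Gy.

    ``v`` must sum to 1 over the structure's differential bins.  ``n = 1``
    reduces to the mean dose; ``n -> 0`` approaches the maximum bin dose.
    """
    eqd2_gy = np.asarray(eqd2_gy, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if eqd2_gy.size == 0:
        raise ValueError("empty DVH")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"relative volumes must sum to 1, got {v.sum():.6f}")
    # Evaluate in log space: D_i**(1/n) overflows double for serial organs
    # (1/n > 5) at clinical doses only near float limits, but log-sum-exp is
    # safe for any n > 0.
    with np.errstate(divide="ignore"):
        logd = np.log(eqd2_gy, out=np.full_like(eqd2_gy, -np.inf), where=eqd2_gy > 0)
    a = logd / p.n + np.log(np.maximum(v, 1e-300))
    amax = a.max()
    if np.isinf(amax):
        return 0.0
    return float(np.exp(p.n * (amax + np.log(np.sum(np.exp(a - amax))))))


def lkb_ntcp_from_bins(eqd2_gy: np.ndarray, v: np.ndarray, p: LKBParams) -> float:
    """LKB NTCP (fraction in [0, 1]) from differential EQD2 bins."""
    deff = effective_dose(eqd2_gy, v, p)
    t = (deff - p.td50) / (p.m * p.td50)
    return float(ndtr(t))


def lkb_ntcp(curve: DVHCurve, p: LKBParams, n_fractions: int) -> float:
    """LKB NTCP (fraction) from a physical-dose DVH; EQD2 applied per bin."""
    e, v = _differential_eqd2(curve, n_fractions, p.alpha_beta)
    return lkb_ntcp_from_bins(e, v / v.sum(), p)


def rs_response(eqd2_gy, p: RSParams):
    """Poisson dose-response ``P(D) = 2**(-exp(e**gamma * (1 - D/D50)))``.

    Strictly increasing in D with range (0, 1); P(D50) = 1/2.
    """
    d = np.asarray(eqd2_gy, dtype=np.float64)
    out = np.exp2(-np.exp(np.exp(p.gamma) * (1.0 - d / p.d50)))
    return float(out) if np.isscalar(eqd2_gy) else out


def rs_ntcp_from_bins(eqd2_gy: np.ndarray, v: np.ndarray, p: RSParams) -> float:
    """Relative-seriality NTCP (fraction) from differential EQD2 bins."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty DVH")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"relative volumes must sum to 1, got {v.sum():.6f}")
    resp = rs_response(np.asarray(eqd2_gy, dtype=np.float64), p)
    # log of prod_i (1 - P_i**s)**v_i, guarded against log(0) when a bin is
    # essentially certain to respond.
    inner = np.clip(1.0 - resp**p.s, 1e-300, 1.0)
    log_prod = float(np.sum(v * np.log(inner)))
    return float((1.0 - np.exp(log_prod)) ** (1.0 / p.s))


def rs_ntcp(curve: DVHCurve, p: RSParams, n_fractions: int) -> float:
    """Relative-seriality NTCP (fraction) from a physical-dose DVH."""
    e, v = _differential_eqd2(curve, n_fractions, p.alpha_beta)
    return rs_ntcp_from_bins(e, v / v.sum(), p)


def ntcp_suite(
    dose: DoseGrid,
    rectum: StructureMask,
    registry=REGISTRY,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> dict[str, float]:
    """All rectal NTCP endpoints for one plan, in percent.

    The rectum DVH is computed once at ``bin_width``; each bin is converted
    to EQD2 with the plan's fraction count and the endpoint's alpha/beta
    before model evaluation.  Returns the seven LKB endpoints plus the RS
    grade-2 late-rectal-bleeding endpoint.
    """
    curve = compute_dvh(dose, rectum, bin_width=bin_width)
    out: dict[str, float] = {}
    for name, p in registry["lkb"].items():
        key = f"{name}-LKB-NTCP" if name.endswith("LRB") else name
        out[key] = 100.0 * lkb_ntcp(curve, p, dose.n_fractions)
    for name, p in registry["rs"].items():
        out[f"{name}-RS-NTCP"] = 100.0 * rs_ntcp(curve, p, dose.n_fractions)
    return {k: out[k] for k in NTCP_ENDPOINTS}
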