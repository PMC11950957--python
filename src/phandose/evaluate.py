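"""Plan-similarity and statistical evaluation.

Provides the comparison layer between planned and model-predicted dose
distributions: isodose-volume Dice similarity (iDSC) across dose levels,
percent mean absolute error (%MAE) of DVH/NTCP metrics, ordinary
least-squares goodness-of-fit with a Wald slope test, power analysis for a
target coefficient of determination, and a cohort-level report table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dvh as _dvh
from . import radiobio as _radiobio
from .volumes import DoseGrid, StructureMask


@dataclass(frozen=True)
class RegressionResult:
    """OLS of predicted on planned values: slope, intercept, R^2, Wald p."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def idsc(
    planned: DoseGrid,
    predicted: DoseGrid,
    level_gy: float,
    body: StructureMask | None = None,
) -> float:
    """Dice similarity of the two iso-dose volumes at ``level_gy``.

    ``2|A n B| / (|A| + |B|)`` where A, B are the voxel sets with dose >=
    ``level_gy`` (restricted to the body mask when given, so agreement in
    air is not credited).  When both volumes are empty — levels above both
    maxima — the coefficient is defined as 1: the plans agree the isodose is
    absent.
    """
    if planned.shape != predicted.shape:
        raise ValueError(f"grid mismatch: {planned.shape} vs {predicted.shape}")
    a = planned.values >= level_gy
    b = predicted.values >= level_gy
    if body is not None:
        bb = body.as_bool()
        a, b = a & bb, b & bb
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def mean_idsc(
    planned: DoseGrid,
    predicted: DoseGrid,
    d_min: float = 0.0,
    step: float = 1.0,
    body: StructureMask | None = None,
) -> float:
    """Mean iDSC over dose levels ``d_min, d_min+step, ...`` up to prescription.

    The two published variants use ``d_min = 0`` (overall agreement) and
    ``d_min = 50`` Gy (high-dose region).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if d_min > planned.prescription:
        raise ValueError("d_min exceeds the prescription dose")
    n_levels = int(np.floor((planned.prescription - d_min) / step)) + 1
    levels = d_min + step * np.arange(n_levels)
    return float(np.mean([idsc(planned, predicted, d, body) for d in levels]))


def pmae(
    planned: np.ndarray, predicted: np.ndarray, kind: str, prescription: float | None = None
) -> float:
    """Percent mean absolute error between paired metric values.

    ``kind='gy'``: mean of 100*|pred - plan| / prescription (prescription
    required).  ``kind='percent'``: mean absolute difference in percentage
    points (V_xGy, NTCP).
    """
    planned = np.asarray(planned, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if planned.shape != predicted.shape:
        raise ValueError("planned/predicted length mismatch")
    err = np.abs(predicted - planned)
    if kind == "gy":
        if not prescription or prescription <= 0:
            raise ValueError("prescription required for Gy-kind %MAE")
        return float(np.mean(100.0 * err / prescription))
    if kind == "percent":
        return float(np.mean(err))
    raise ValueError(f"unknown metric kind {kind!r}")


def regress(planned: np.ndarray, predicted: np.ndarray) -> RegressionResult:
    """OLS of predicted on planned with a two-sided Wald t-test on the slope."""
    planned = np.asarray(planned, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if planned.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(planned) == 0:
        raise ValueError("zero variance in planned values")
    res = stats.linregress(planned, predicted)
    if np.isnan(res.rvalue):  # constant predictions: no association
        return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                                r2=0.0, p=1.0, n=int(planned.size))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=int(planned.size),
    )


def power_r2(n: int, r2: float, alpha: float = 0.05, method: str = "normal") -> float:
    """Power of the two-sided slope test to detect a target R^2 at size n.

    Effect size ``f^2 = r2 / (1 - r2)``.  ``method='normal'`` uses the
    large-sample approximation ``Phi(sqrt(n f^2) - z_{1-alpha/2})``;
    ``method='ncf'`` uses the exact noncentral-F distribution of the
    simple-regression F statistic (df 1 and n-2, noncentrality ``n f^2``).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0 < r2 < 1 and 0 < alpha < 1):
        raise ValueError("r2 and alpha must lie in (0, 1)")
    f2 = r2 / (1.0 - r2)
    lam = n * f2
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return float(stats.norm.cdf(np.sqrt(lam) - z))
    if method == "ncf":
        fcrit = stats.f.ppf(1.0 - alpha, 1, n - 2)
        return float(stats.ncf.sf(fcrit, 1, n - 2, lam))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

def _metric_rows(sample) -> dict:
    """All DVH + NTCP metrics for one plan, keyed (structure, metric)."""
    rows = dict(_dvh.metric_suite(sample.dose, sample.masks))
    ntcp = _radiobio.ntcp_suite(sample.dose, sample.masks["rectum"])
    rows.update({("rectum", k): v for k, v in ntcp.items()})
    return rows


#: Report rows in published-table order: PTV DVH, rectum NTCP, rectum DVH,
#: bladder DVH, femoral-head DVH — 23 DVH + 8 NTCP = 31 rows.
REPORT_ROWS: tuple[tuple[str, str], ...] = (
    tuple((s, m) for s, m in _dvh.DVH_METRICS if s == "PTV")
    + tuple(("rectum", e) for e in _radiobio.NTCP_ENDPOINTS)
    + tuple((s, m) for s, m in _dvh.DVH_METRICS if s != "PTV")
)


def cohort_report(
    planned_samples,
    predicted_samples,
    mean_idsc_step: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort evaluation in the standard published layout.

    ``planned_samples`` and ``predicted_samples`` are matched lists of
    PlanSamples sharing anatomy but carrying planned vs predicted doses.
    Returns ``(metrics, per_sample)``:

    * ``metrics`` — one row per (structure, metric): planned mean/SD,
      predicted mean/SD, %MAE mean/SD, R^2 and Wald p over the cohort;
    * ``per_sample`` — mean iDSC over all dose levels and over levels
      >= 50 Gy for each sample.
    """
    if len(planned_samples) != len(predicted_samples) or len(planned_samples) < 3:
        raise ValueError("need >= 3 matched planned/predicted samples")
    plan_vals: dict[tuple[str, str], list[float]] = {k: [] for k in REPORT_ROWS}
    pred_vals: dict[tuple[str, str], list[float]] = {k: [] for k in REPORT_ROWS}
    idsc_rows = []
    for ps, qs in zip(planned_samples, predicted_samples):
        pm, qm = _metric_rows(ps), _metric_rows(qs)
        for k in REPORT_ROWS:
            plan_vals[k].append(pm[k])
            pred_vals[k].append(qm[k])
        body = ps.masks["body"]
        idsc_rows.append(
            {
                "id": ps.id,
                "mean_idsc_0gy": mean_idsc(ps.dose, qs.dose, 0.0, mean_idsc_step, body),
                "mean_idsc_50gy": mean_idsc(ps.dose, qs.dose, 50.0, mean_idsc_step, body),
            }
        )

    records = []
    for (structure, metric) in REPORT_ROWS:
        plan = np.array(plan_vals[(structure, metric)])
        pred = np.array(pred_vals[(structure, metric)])
        kind = "gy" if metric in _dvh.GY_METRICS else "percent"
        prescription = planned_samples[0].dose.prescription
        abs_err = (
            100.0 * np.abs(pred - plan) / prescription if kind == "gy" else np.abs(pred - plan)
        )
        try:
            reg = regress(plan, pred)
            r2, p = reg.r2, reg.p
        except ValueError:
            r2, p = np.nan, np.nan
        records.append(
            {
                "structure": structure,
                "metric": metric,
                "planned_mean": plan.mean(),
                "planned_sd": plan.std(ddof=1),
                "predicted_mean": pred.mean(),
                "predicted_sd": pred.std(ddof=1),
                "pmae_mean": abs_err.mean(),
                "pmae_sd": abs_err.std(ddof=1),
                "r2": r2,
                "p": p,
            }
        )
    return pd.DataFrame.from_records(records), pd.DataFrame.from_records(idsc_rows)
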