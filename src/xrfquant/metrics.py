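"""Method-performance statistics.

Calibration quality is summarized by R² and the standard error of
calibration (SEC) over per-standard mean predictions; detection and
quantification limits follow the Eurachem replicate-standard-deviation
approach

    LOD = 3·s₀/√n        LOQ = k_Q·s₀/√n        bias = x̄ − x_actual

with s₀ the sample SD of replicate predictions, n the number of
observations averaged when reporting a result, and k_Q the IUPAC default
factor of 10 (corresponding to a 10 % RSD requirement).  Validation
agreement uses the regulatory ±20 % rule, falling back to absolute error
where the actual concentration sits below the applicable LOQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from xrfquant.errors import DomainError, ValidationError


@dataclass(frozen=True)
class CalMetrics:
    """Calibration summary for one element (concentrations in µg kg⁻¹)."""

    element: str
    r2: float
    sec: float
    relative_sec: float          # % of the working concentration range
    slope: float                 # predicted-vs-actual OLS line
    intercept: float


@dataclass(frozen=True)
class LimitEstimate:
    """Detection/quantification limits for one element and scenario."""

    element: str
    actual: float
    mean_pred: float
    s0: float
    n: int
    kQ: float
    lod: float
    loq: float
    bias_abs: float
    bias_pct: float


@dataclass(frozen=True)
class IcpLoqInput:
    """Blank SD and calibration slope of the reference (ICP-MS) method."""

    blank_sd: float
    slope: float

    def __post_init__(self) -> None:
        if self.blank_sd < 0:
            raise ValidationError("blank_sd must be >= 0")
        if self.slope == 0:
            raise ValidationError("slope must be nonzero")


@dataclass(frozen=True)
class AgreementRecord:
    """Predicted-vs-actual comparison for one validation sample/element.

    ``agrees`` is only defined when the actual concentration is
    quantifiable (>= the applicable LOQ); below the LOQ only the absolute
    error is meaningful.
    """

    sample: str
    element: str
    predicted: float
    actual: float
    error_abs: float
    error_pct: float | None
    quantifiable: bool
    agrees: bool | None
    category: str = ""


# ---------------------------------------------------------------------------

def calibration_metrics(predicted: Sequence[float], actual: Sequence[float],
                        working_range: float,
                        element: str = "") -> CalMetrics:
    """R², SEC and the predicted-vs-actual regression line.

    R² = 1 − SS_res/SS_tot of predictions against actuals;
    SEC = sqrt(Σ(pred−actual)²/(N−1)) over per-standard mean predictions
    (the N−1 divisor is the common chemometrics convention);
    slope/intercept by ordinary least squares of predicted on actual.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1 or p.size < 3:
        raise ValidationError("need >= 3 paired standards")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("actual concentrations have zero variance")
    if working_range <= 0:
        raise ValidationError("working_range must be positive")
    resid = p - a
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    sec = float(np.sqrt(np.sum(resid ** 2) / (p.size - 1)))
    slope, intercept = np.polyfit(a, p, 1)
    return CalMetrics(element=element, r2=r2, sec=sec,
                      relative_sec=100.0 * sec / working_range,
                      slope=float(slope), intercept=float(intercept))


def limits_from_summary(s0: float, n: int, actual: float, mean_pred: float,
                        kQ: float = 10.0, element: str = "") -> LimitEstimate:
    """Limits and bias from an already-summarized prediction set."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if s0 < 0:
        raise DomainError("s0 must be >= 0")
    root_n = np.sqrt(n)
    bias_abs = mean_pred - actual
    bias_pct = 100.0 * bias_abs / actual if actual > 0 else float("nan")
    return LimitEstimate(
        element=element, actual=actual, mean_pred=mean_pred, s0=s0, n=int(n),
        kQ=kQ, lod=3.0 * s0 / root_n, loq=kQ * s0 / root_n,
        bias_abs=bias_abs, bias_pct=bias_pct)


def detection_limits(replicate_preds: Sequence[float], n: int, actual: float,
                     kQ: float = 10.0, element: str = "") -> LimitEstimate:
    """Limits from the per-standard mean predictions of a scenario set.

    ``replicate_preds`` are the (typically 10) per-standard prediction
    means; s₀ is their sample SD (divisor N−1).  ``n`` is the number of
    observations averaged when a result is reported — 3 pellets by
    default study design — and is an explicit argument because it is a
    reporting convention, not a property of the data.
    """
    preds = np.asarray(replicate_preds, dtype=float)
    if preds.size < 2:
        raise ValidationError("need >= 2 replicate predictions")
    s0 = float(preds.std(ddof=1))
    return limits_from_summary(s0=s0, n=n, actual=actual,
                               mean_pred=float(preds.mean()), kQ=kQ,
                               element=element)


def icp_loq(x: IcpLoqInput) -> float:
    """Blank-based reference-method LOQ: 10·σ_S/b."""
    if x.slope <= 0:
        raise DomainError("slope must be positive")
    return 10.0 * x.blank_sd / x.slope


def assess_agreement(pred: float, actual: float, threshold_pct: float = 20.0,
                     loq: float = 0.0, sample: str = "", element: str = "",
                     category: str = "") -> AgreementRecord:
    """±threshold % agreement check, LOQ-gated.

    When ``actual`` is below ``loq`` (or zero), the percent error is not
    quantitatively meaningful: the record carries the absolute error only
    and ``agrees`` is None.
    """
    if actual < 0:
        raise ValidationError("actual must be >= 0")
    error_abs = pred - actual
    quantifiable = actual >= loq and actual > 0
    if quantifiable:
        error_pct = 100.0 * error_abs / actual
        agrees = abs(error_pct) <= threshold_pct
    else:
        error_pct = 100.0 * error_abs / actual if actual > 0 else None
        agrees = None
    return AgreementRecord(sample=sample, element=element, predicted=pred,
                           actual=actual, error_abs=error_abs,
                           error_pct=error_pct, quantifiable=quantifiable,
                           agrees=agrees, category=category)


def category_summary(records: Sequence[AgreementRecord]
                     ) -> dict[tuple[str, str], dict[str, float | str | int]]:
    """Mean and median absolute error per (category, element).

    Quantifiable records contribute absolute percent errors; categories
    whose records are all below the LOQ are summarized on absolute
    µg kg⁻¹ errors instead.  The median of an even-count set is the mean
    of the two central values.
    """
    if not records:
        raise ValidationError("no records")
    out: dict[tuple[str, str], dict[str, float | str | int]] = {}
    keys = list(dict.fromkeys((r.category, r.element) for r in records))
    for key in keys:
        grp = [r for r in records if (r.category, r.element) == key]
        quant = [r for r in grp if r.quantifiable]
        if quant:
            errors = np.abs([r.error_pct for r in quant])
            unit = "%"
        else:
            errors = np.abs([r.error_abs for r in grp])
            unit = "ug_kg"
        out[key] = {"mean": float(np.mean(errors)),
                    "median": float(np.median(errors)),
                    "unit": unit, "n": len(grp)}
    return out
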