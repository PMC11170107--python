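"""Tolerance-interval calibration of the per-parameter effect zones.

The no-effect zone is the vehicle tolerance interval (TI) on well-level dd%
values; the mild zone runs from the vehicle TI bound to the corresponding
positive-control TI bound, and the strong zone lies beyond it.  Directions
are handled separately; when only one positive-control direction is
observed, its strong boundary is mirrored around the vehicle center.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


class CalibrationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ToleranceInterval:
    lower: float
    upper: float
    coverage_p: float
    confidence_gamma: float
    n: int
    k_factor: float
    method: str = "normal"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("tolerance interval requires n >= 2")
        if self.lower > self.upper:
            raise ValidationError("TI lower bound exceeds upper bound")


def howe_k_factor(n: int, coverage_p: float, confidence_gamma: float) -> float:
    """Howe's two-sided tolerance-interval factor.

    k = z_{(1+p)/2} * sqrt(nu * (1 + 1/n) / chi2_{1-gamma, nu}), nu = n - 1.
    Tends to the standard-normal quantile z_{(1+p)/2} as n grows.
    """
    if n < 2:
        raise ValidationError("k factor requires n >= 2")
    nu = n - 1
    z = stats.norm.ppf((1.0 + coverage_p) / 2.0)
    chi2 = stats.chi2.ppf(1.0 - confidence_gamma, nu)
    return float(z * math.sqrt(nu * (1.0 + 1.0 / n) / chi2))


def normal_tolerance_interval(
    samples, coverage_p: float = 0.95, confidence_gamma: float = 0.95
) -> ToleranceInterval:
    """Two-sided normal-theory TI: mean +/- k*sd with Howe's k factor."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValidationError(
            f"tolerance interval requires n >= 2 finite samples, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    k = howe_k_factor(x.size, coverage_p, confidence_gamma)
    if sd == 0:
        warnings.warn(
            "zero-variance sample: degenerate tolerance interval",
            CalibrationWarning,
            stacklevel=2,
        )
        return ToleranceInterval(mean, mean, coverage_p, confidence_gamma, x.size, k)
    return ToleranceInterval(
        mean - k * sd, mean + k * sd, coverage_p, confidence_gamma, x.size, k
    )


def nonparametric_tolerance_interval(
    samples, coverage_p: float = 0.95, confidence_gamma: float = 0.95
) -> ToleranceInterval:
    """Order-statistic (distribution-free) two-sided TI.

    Uses the symmetric pair of order statistics [x_(r), x_(n+1-r)] with the
    largest r such that P(coverage >= p) = BinomCDF(n - 2r; n, p) >= gamma;
    falls back to the sample range (r = 1) when n is too small, with a
    warning.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValidationError("tolerance interval requires n >= 2")
    r_best = 0
    for r in range(1, n // 2 + 1):
        if stats.binom.cdf(n - 2 * r, n, coverage_p) >= confidence_gamma:
            r_best = r
        else:
            break
    if r_best == 0:
        warnings.warn(
            f"n={n} too small for a distribution-free {coverage_p}/{confidence_gamma} "
            "TI; using the sample range",
            CalibrationWarning,
            stacklevel=2,
        )
        r_best = 1
    lo, hi = float(x[r_best - 1]), float(x[n - r_best])
    return ToleranceInterval(
        lo, hi, coverage_p, confidence_gamma, n,
        k_factor=howe_k_factor(n, coverage_p, confidence_gamma),
        method="nonparametric",
    )


def tolerance_interval(
    samples,
    coverage_p: float = 0.95,
    confidence_gamma: float = 0.95,
    method: str = "auto",
    normality_alpha: float = 0.01,
) -> ToleranceInterval:
    """Normal-theory TI, with a distribution-free fallback.

    ``auto`` applies the normal TI unless a Shapiro-Wilk test rejects
    normality at ``normality_alpha``.
    """
    if method == "normal":
        return normal_tolerance_interval(samples, coverage_p, confidence_gamma)
    if method == "nonparametric":
        return nonparametric_tolerance_interval(
            samples, coverage_p, confidence_gamma
        )
    if method != "auto":
        raise ValidationError(f"unknown TI method {method!r}")
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if 3 <= x.size <= 5000 and np.ptp(x) > 0:
        p = stats.shapiro(x).pvalue
        if p < normality_alpha:
            logger.info(
                "normality rejected (p=%.3g); using distribution-free TI", p
            )
            return nonparametric_tolerance_interval(
                x, coverage_p, confidence_gamma
            )
    return normal_tolerance_interval(x, coverage_p, confidence_gamma)


# ---------------------------------------------------------------------------
# zone cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZoneCutoffs:
    """Partition of the dd% axis into effect zones for one parameter.

    Zones (most negative to most positive):
      strong_down (-inf, strong_down_edge] | mild_down (.., mild_down_edge]
      | no_effect (mild_down_edge, mild_up_edge) | mild_up [mild_up_edge, ..)
      | strong_up [strong_up_edge, +inf).
    Boundary values are assigned to the more severe zone.
    """

    parameter: str
    mild_down_edge: float  # vehicle TI lower bound
    mild_up_edge: float  # vehicle TI upper bound
    strong_down_edge: float
    strong_up_edge: float

    def __post_init__(self) -> None:
        if not (
            self.strong_down_edge
            <= self.mild_down_edge
            < self.mild_up_edge
            <= self.strong_up_edge
        ):
            raise ValidationError(
                f"{self.parameter}: zone boundaries not monotone: "
                f"{self.strong_down_edge}, {self.mild_down_edge}, "
                f"{self.mild_up_edge}, {self.strong_up_edge}"
            )

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "mild_down_edge": self.mild_down_edge,
            "mild_up_edge": self.mild_up_edge,
            "strong_down_edge": self.strong_down_edge,
            "strong_up_edge": self.strong_up_edge,
        }

    @classmethod
    def from_dict(cls, d) -> "ZoneCutoffs":
        return cls(
            parameter=d["parameter"],
            mild_down_edge=float(d["mild_down_edge"]),
            mild_up_edge=float(d["mild_up_edge"]),
            strong_down_edge=float(d["strong_down_edge"]),
            strong_up_edge=float(d["strong_up_edge"]),
        )


def derive_cutoffs_for_parameter(
    parameter: str,
    vehicle_dd,
    positive_dd,
    coverage_p: float = 0.95,
    confidence_gamma: float = 0.95,
    ti_method: str = "auto",
    normality_alpha: float = 0.01,
) -> ZoneCutoffs:
    """Zone boundaries for one parameter from vehicle and positive-control dd%.

    The vehicle TI is the no-effect zone.  The positive-control TI bound
    nearer the vehicle center starts the strong zone on the positive
    control's side of the axis; the opposite side is mirrored around the
    vehicle center.  When the positive-control bound does not clear the
    vehicle TI, the mild zone collapses to zero width (warning).
    """
    veh_ti = tolerance_interval(
        vehicle_dd, coverage_p, confidence_gamma, ti_method, normality_alpha
    )
    pos = np.asarray(positive_dd, dtype=float)
    pos = pos[~np.isnan(pos)]
    pos_ti = tolerance_interval(
        pos, coverage_p, confidence_gamma, ti_method, normality_alpha
    )
    center = 0.5 * (veh_ti.lower + veh_ti.upper)

    if np.mean(pos) >= center:
        up_edge = pos_ti.lower
        down_edge = center - (up_edge - center)  # mirror
    else:
        down_edge = pos_ti.upper
        up_edge = center + (center - down_edge)

    if up_edge <= veh_ti.upper:
        warnings.warn(
            f"{parameter}: positive-control TI overlaps the vehicle TI; "
            "mild zones collapse to zero width",
            CalibrationWarning,
            stacklevel=2,
        )
        up_edge = veh_ti.upper
        down_edge = veh_ti.lower
    return ZoneCutoffs(
        parameter=parameter,
        mild_down_edge=veh_ti.lower,
        mild_up_edge=veh_ti.upper,
        strong_down_edge=min(down_edge, veh_ti.lower),
        strong_up_edge=max(up_edge, veh_ti.upper),
    )


def derive_cutoffs(
    vehicle_dd_by_param: dict[str, np.ndarray],
    positive_dd_by_param: dict[str, np.ndarray],
    cfg,
) -> dict[str, ZoneCutoffs]:
    """Per-parameter cutoffs from pooled vehicle / positive-control dd%."""
    cutoffs = {}
    for param, veh in vehicle_dd_by_param.items():
        if param not in positive_dd_by_param:
            continue
        veh_arr = np.asarray(veh, dtype=float)
        pos_arr = np.asarray(positive_dd_by_param[param], dtype=float)
        veh_arr = veh_arr[~np.isnan(veh_arr)]
        pos_arr = pos_arr[~np.isnan(pos_arr)]
        if veh_arr.size < 2 or pos_arr.size < 2:
            logger.warning("%s: insufficient data for calibration, skipped", param)
            continue
        cutoffs[param] = derive_cutoffs_for_parameter(
            param,
            veh_arr,
            pos_arr,
            coverage_p=cfg.ti_coverage,
            confidence_gamma=cfg.ti_confidence,
            ti_method=cfg.ti_method,
            normality_alpha=cfg.normality_alpha,
        )
    return cutoffs


def cutoffs_to_dict(cutoffs: dict[str, ZoneCutoffs]) -> dict:
    return {p: c.to_dict() for p, c in cutoffs.items()}


def cutoffs_from_dict(d: dict) -> dict[str, ZoneCutoffs]:
    return {p: ZoneCutoffs.from_dict(c) for p, c in d.items()}
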