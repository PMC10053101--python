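"""Eadie–Hofstee thermal-inhibition kinetics.

Thermostability of an enzyme preparation is summarized by regressing residual
activity J (after a 30-min treatment at temperature I, °C) on the ratio J/I —
an Eadie–Hofstee-style linearization repurposed for thermal inhibition:

    J = I_MIN + slope · (J/I),      TC50 = |slope|

with the companion identity  I_MAX = I_C − I_MIN,  where

* ``TC50`` — temperature (°C) at half of the maximal inhibited activity;
* ``I_MIN`` — minimal inhibited activity (the regression intercept);
* ``I_MAX`` — maximal inhibited activity;
* ``I_C`` — mean activity of the unheated (22 °C) control group.

A preparation whose activity has no linear J-vs-J/I relation (slope p > 0.05)
yields no interpretable thermal-inhibition parameters: the result is gated NS
and only the control mean is reported.  An intercept that does not differ from
zero (p > 0.05) is reported as "0" with the raw estimate preserved in the
diagnostics; I_MAX always uses the raw intercept.

All quantities may be on the absolute activity scale (nmol·mg⁻¹·min⁻¹) or the
percent-of-control scale; TC50 is invariant to that choice because rescaling J
rescales J/I identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import (
    NS,
    AnalysisResult,
    DomainError,
    ThermalSeries,
    UnderDeterminedError,
    digest,
)
from .kinetic_models import _ols

SLOPE_ALPHA = 0.05  # NS gate on the linear-term slope


@dataclass(frozen=True)
class ThermostabilityResult:
    """Eadie–Hofstee thermal-inhibition parameter set.

    When ``ns_flag`` is set the numeric fields for TC50/I_MIN/I_MAX are None
    and the accessors report the NS marker instead; ``i_c`` is always numeric.
    """

    tc50: float | None
    se_tc50: float | None
    i_min: float | None          # raw intercept estimate
    se_i_min: float | None
    i_min_reported: object       # raw value, or "0" when intercept_p > 0.05
    i_max: float | None
    i_c: float
    slope: float | None          # signed regression slope (diagnostic)
    slope_p: float
    intercept_p: float
    r_squared: float
    ns_flag: bool
    n: int
    is_relative: bool = False

    def __post_init__(self):
        if self.i_c <= 0:
            raise DomainError(f"control activity I_C must be > 0, got {self.i_c}")

    def reported(self, name: str):
        """Table-style value for a parameter: a number or the NS marker."""
        if self.ns_flag and name in ("tc50", "i_min", "i_max"):
            return NS
        if name == "i_min":
            return self.i_min_reported
        return getattr(self, name)


def eadie_hofstee_transform(series: ThermalSeries):
    """Map each (I, J) measurement to the pair (x=J/I, y=J), order preserved.

    Every point, the control included, enters the transform; temperatures of
    0 °C cannot be transformed and raise with the offending row index.
    """
    t, j = series.t, series.j
    zero = np.flatnonzero(t == 0.0)
    if len(zero):
        raise DomainError(
            f"temperature 0 °C at row(s) {zero.tolist()}: J/I undefined"
        )
    return j / t, j.copy()


def relative_residual(series: ThermalSeries, control_activity: float) -> ThermalSeries:
    """Rescale a thermal series to percent of the control activity."""
    if control_activity <= 0:
        raise DomainError("control activity must be > 0")
    return ThermalSeries(
        series.temperature,
        tuple(100.0 * (j / control_activity) for j in series.residual_activity),
        is_relative=True,
    )


def estimate_thermal_params(
    series: ThermalSeries, control_activity: float
) -> ThermostabilityResult:
    """Estimate (TC50, I_MIN, I_MAX, I_C) from a thermal series.

    OLS of J on J/I; the intercept is I_MIN, the slope magnitude is TC50 and
    I_MAX = I_C − I_MIN with the raw intercept.  ``control_activity`` is the
    unheated control-group mean I_C, on the same scale as the series.
    """
    if control_activity <= 0:
        raise DomainError("control activity I_C must be > 0")
    x, y = eadie_hofstee_transform(series)
    if len(x) < 4:
        raise UnderDeterminedError("need >= 4 points for the Eadie–Hofstee fit")
    X = np.column_stack([np.ones_like(x), x])
    beta, se, r2, dof = _ols(X, y)
    intercept, slope = float(beta[0]), float(beta[1])
    se_int, se_slope = float(se[0]), float(se[1])

    def two_sided_p(est, se_):
        if se_ == 0.0:
            return 0.0 if est != 0.0 else 1.0
        return float(2.0 * stats.t.sf(abs(est) / se_, dof))

    slope_p = two_sided_p(slope, se_slope)
    intercept_p = two_sided_p(intercept, se_int)
    ns = slope_p > SLOPE_ALPHA

    if ns:
        return ThermostabilityResult(
            tc50=None, se_tc50=None, i_min=None, se_i_min=None,
            i_min_reported=NS, i_max=None, i_c=control_activity,
            slope=slope, slope_p=slope_p, intercept_p=intercept_p,
            r_squared=r2, ns_flag=True, n=len(x),
            is_relative=series.is_relative,
        )
    return ThermostabilityResult(
        tc50=abs(slope), se_tc50=se_slope,
        i_min=intercept, se_i_min=se_int,
        i_min_reported=("0" if intercept_p > SLOPE_ALPHA else intercept),
        i_max=control_activity - intercept,
        i_c=control_activity,
        slope=slope, slope_p=slope_p, intercept_p=intercept_p,
        r_squared=r2, ns_flag=False, n=len(x),
        is_relative=series.is_relative,
    )


def thermostability_result(
    res: ThermostabilityResult, series: ThermalSeries, seed=None
) -> AnalysisResult:
    """Package a ThermostabilityResult for serialization, spelling NS markers."""
    params = {
        "TC50": (res.reported("tc50"), res.se_tc50 if not res.ns_flag else None),
        "I_MIN": (res.reported("i_min"), res.se_i_min if not res.ns_flag else None),
        "I_MAX": (res.reported("i_max"), None),
        "I_C": (res.i_c, None),
    }
    return AnalysisResult(
        stage="thermostability",
        parameters=params,
        diagnostics={
            "slope": res.slope, "slope_p": res.slope_p,
            "intercept_p": res.intercept_p, "r_squared": res.r_squared,
            "n": res.n, "ns_flag": res.ns_flag,
            "is_relative": res.is_relative,
            "raw_i_min": res.i_min,
        },
        provenance={"input_digest": digest(series.t, series.j), "seed": seed},
    )
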