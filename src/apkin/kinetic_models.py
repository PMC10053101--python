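"""Model evaluation and nonlinear least-squares fitting.

Four response models recur in alkaline-phosphatase (AP) assay work and are
implemented here with a common fitting discipline:

* Michaelis–Menten, ``v = Vmax·S/(Km + S)`` — substrate-gradient kinetics;
* a four-parameter logistic on a *linear* dose axis,
  ``Y = Bo + (To − Bo)/(1 + 10^((ED50 − x)·h))`` — deglycosylation
  dose-response, where ``Bo``/``To`` are the bottom/top plateaus, ``ED50`` the
  half-effective dose (U/mg protein) and ``h`` the Hill slope;
* a simple exponential ``Y = J0·e^(b·x)`` and a quadratic in temperature —
  thermal-response curves.

All nonlinear fits use unweighted least squares (scipy ``curve_fit``) with
data-driven initial values, bounded jittered restarts, standard errors from
the estimator covariance and R² = 1 − SSres/SStot about the response mean.
The assay layer converts plate absorbances and time courses into specific
activities (nmol p-nitrophenol · mg protein⁻¹ · min⁻¹; 1 U = 1 nmol/min).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_io import (
    DegenerateDataError,
    DomainError,
    DoseResponseTable,
    FitFailureError,
    KineticDataset,
    ThermalSeries,
    UnderDeterminedError,
    digest,
)

# convergence policy shared by every nonlinear fit (recorded in provenance)
FIT_TOL = 1e-10
MAX_ITER = 200
MAX_RESTARTS = 5
_FIT_POLICY = {"tol": FIT_TOL, "max_iter": MAX_ITER, "max_restarts": MAX_RESTARTS}


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten estimates: Km in µM, Vmax in nmol·mg⁻¹·min⁻¹."""

    Km: float
    Vmax: float
    se_Km: float = 0.0
    se_Vmax: float = 0.0
    r_squared: float = float("nan")
    converged: bool = True
    n: int = 0

    def __post_init__(self):
        if self.converged and (self.Km <= 0 or self.Vmax <= 0):
            raise DomainError(
                f"converged fit requires Km > 0 and Vmax > 0, got "
                f"Km={self.Km}, Vmax={self.Vmax}"
            )
        if self.se_Km < 0 or self.se_Vmax < 0:
            raise DomainError("standard errors must be non-negative")


@dataclass(frozen=True)
class SigmoidParams:
    """Four-parameter logistic estimates on the linear dose axis."""

    Bo: float
    To: float
    ED50: float
    hill_slope: float
    se_Bo: float = 0.0
    se_To: float = 0.0
    se_ED50: float = 0.0
    se_hill: float = 0.0
    r_squared: float = float("nan")
    n: int = 0
    ed50_in_range: bool = True

    def caption_rescaled(self, scale: float = 500.0) -> dict:
        """Re-express the fit with the dose axis divided by ``scale`` and the
        Hill slope absorbed, the parametrization some reports print
        (exponent ``x/scale − c`` instead of ``(ED50 − x)·h``).

        Solving ``(ED50 − x)·h = x/scale − c`` requires ``h = −1/scale`` and
        gives ``c = ED50/scale``; the returned dict carries both plus the span.
        """
        return {
            "scale": scale,
            "offset": self.ED50 / scale,
            "implied_hill": -1.0 / scale,
            "bottom": self.Bo,
            "span": self.To - self.Bo,
        }


@dataclass(frozen=True)
class ExpParams:
    """Exponential thermal-response estimates Y = J0·e^(b·x)."""

    J0: float
    b: float
    se_J0: float = 0.0
    se_b: float = 0.0
    r_squared: float = float("nan")
    n: int = 0

    def __post_init__(self):
        if self.J0 <= 0:
            raise DomainError(f"J0 must be > 0, got {self.J0}")


@dataclass(frozen=True)
class QuadParams:
    """Quadratic thermal-response coefficients Y = c0 + c1·x + c2·x²."""

    c0: float
    c1: float
    c2: float
    se_c0: float = 0.0
    se_c1: float = 0.0
    se_c2: float = 0.0
    r_squared: float = float("nan")
    n: int = 0


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope with standard error and r² (time-course activities)."""

    slope: float
    se: float
    intercept: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def michaelis_menten(S, Km: float, Vmax: float):
    """Vectorized Michaelis–Menten velocity; no domain checks."""
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def eval_michaelis_menten(S: float, params: MMParams) -> float:
    """Velocity at substrate concentration ``S`` (µM); errors on S < 0."""
    if np.any(np.asarray(S) < 0):
        raise DomainError("substrate concentration must be >= 0")
    return float(michaelis_menten(S, params.Km, params.Vmax))


def sigmoid_dose_response(x, Bo: float, To: float, ED50: float, hill: float):
    """Four-parameter logistic on a linear dose axis (base-10).

    The exponent is clipped to ±300 so extreme initial values cannot overflow
    during optimization; the clipped region is flat, which the restart logic
    escapes via jitter.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip((ED50 - x) * hill, -300.0, 300.0)
    return Bo + (To - Bo) / (1.0 + 10.0 ** z)


def exponential_response(x, J0: float, b: float):
    x = np.asarray(x, dtype=float)
    return J0 * np.exp(b * x)


def quadratic_response(x, c0: float, c1: float, c2: float):
    x = np.asarray(x, dtype=float)
    return c0 + c1 * x + c2 * x * x


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------


def r_squared_of(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _nls(model, x, y, p0, seed: int = 0):
    """curve_fit with bounded jittered restarts; returns (popt, perr)."""
    rng = np.random.default_rng(seed)
    p0 = np.asarray(p0, dtype=float)
    last_err, last_iterate = None, p0
    for attempt in range(MAX_RESTARTS + 1):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 2.0, size=p0.shape)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, x, y, p0=start,
                    maxfev=MAX_ITER * (len(p0) + 1) * 20,
                    ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
                )
            perr = np.sqrt(np.abs(np.diag(pcov)))
            if np.all(np.isfinite(popt)):
                return popt, perr
            last_iterate = popt
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
    raise FitFailureError(
        f"nonlinear fit failed after {MAX_RESTARTS} restarts: {last_err}",
        last_iterate=last_iterate,
    )


def _ols(X: np.ndarray, y: np.ndarray):
    """Plain OLS via normal equations with coefficient SEs; returns
    (beta, se, r2, resid_df)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise UnderDeterminedError(f"{n} points cannot identify {p} coefficients")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise DegenerateDataError("singular design matrix")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    return beta, se, r_squared_of(y, X @ beta), dof


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


def fit_michaelis_menten(data: KineticDataset, on_means: bool = False) -> MMParams:
    """Nonlinear least-squares Michaelis–Menten fit.

    Requires >= 4 distinct substrate levels.  ``on_means`` collapses replicate
    velocities to per-level means first (both entry modes occur in assay
    reporting; the choice is recorded by the caller in provenance).

    Initialization: Vmax0 = max observed velocity; Km0 = substrate at the
    first point whose velocity exceeds Vmax0/2.
    """
    if on_means:
        data = data.level_means()
    if data.n_levels < 4:
        raise UnderDeterminedError(
            f"need >= 4 distinct substrate levels, got {data.n_levels}"
        )
    s, v = data.substrate, data.velocity
    if np.all(v <= 0):
        raise DegenerateDataError("all velocities are <= 0; nothing to fit")
    vmax0 = float(np.max(v))
    above = s[v > vmax0 / 2.0]
    km0 = float(np.min(above[above > 0])) if np.any(above > 0) else float(np.median(s[s > 0]))
    popt, perr = _nls(michaelis_menten, s, v, [km0, vmax0])
    km, vmax = popt
    if km <= 0 or vmax <= 0:
        raise FitFailureError(
            f"fit converged to non-physical parameters Km={km:.4g}, Vmax={vmax:.4g}",
            last_iterate=popt,
        )
    r2 = r_squared_of(v, michaelis_menten(s, km, vmax))
    return MMParams(float(km), float(vmax), float(perr[0]), float(perr[1]),
                    r2, True, len(s))


def fit_sigmoid_dose_response(data: DoseResponseTable) -> SigmoidParams:
    """Fit the four-parameter logistic to a dose-response table.

    Requires >= 5 distinct doses (one more than the parameter count).  The
    bottom/top plateaus initialize at the extreme observed responses, ED50 at
    the dose nearest the mid-response, and the Hill slope at
    ±4/(ln10·dose span) — the magnitude that places the logistic transition
    across the observed dose window — signed by the response direction.
    """
    x, y = data.x, data.y
    if data.n_doses < 5:
        raise UnderDeterminedError(
            f"need >= 5 distinct doses for a 4-parameter fit, got {data.n_doses}"
        )
    span = float(np.max(y) - np.min(y))
    if span == 0.0 or span < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise DegenerateDataError("constant response: span indistinguishable from 0")
    lo, hi = float(np.min(y)), float(np.max(y))
    mid = (lo + hi) / 2.0
    ed50_0 = float(x[np.argmin(np.abs(y - mid))])
    xspan = float(np.max(x) - np.min(x)) or 1.0
    # decreasing response over dose => negative Hill slope in this parametrization
    direction = 1.0 if y[np.argmax(x)] >= y[np.argmin(x)] else -1.0
    hill0 = direction * 4.0 / (math.log(10.0) * xspan)
    popt, perr = _nls(sigmoid_dose_response, x, y, [lo, hi, ed50_0, hill0])
    bo, to, ed50, hill = (float(p) for p in popt)
    in_range = float(np.min(x)) <= ed50 <= float(np.max(x))
    if not in_range:
        warnings.warn(
            f"ED50 {ed50:.4g} lies outside the observed dose range "
            f"[{np.min(x):.4g}, {np.max(x):.4g}]",
            stacklevel=2,
        )
    r2 = r_squared_of(y, sigmoid_dose_response(x, *popt))
    return SigmoidParams(bo, to, ed50, hill, *(float(e) for e in perr),
                         r_squared=r2, n=len(x), ed50_in_range=in_range)


def fit_exponential(data: ThermalSeries) -> ExpParams:
    """Fit Y = J0·e^(b·x); the sign of b is unconstrained (rising thermal
    responses occur for thermotolerant bacterial AP, falling ones for the
    porcine isoform).

    With all-positive responses the start values come from OLS in log space;
    otherwise the fit falls back to direct NLS from crude moments.
    """
    x, y = data.t, data.j
    if len(x) < 3:
        raise UnderDeterminedError("need >= 3 points for the exponential fit")
    if np.all(y > 0):
        beta, _, _, _ = _ols(np.column_stack([np.ones_like(x), x]), np.log(y))
        p0 = [math.exp(beta[0]), beta[1]]
    else:
        p0 = [max(float(np.mean(np.abs(y))), 1e-6), 0.0]
    popt, perr = _nls(exponential_response, x, y, p0)
    j0, b = float(popt[0]), float(popt[1])
    if j0 <= 0:
        raise FitFailureError(f"fit converged to non-positive J0={j0:.4g}",
                              last_iterate=popt)
    r2 = r_squared_of(y, exponential_response(x, j0, b))
    return ExpParams(j0, b, float(perr[0]), float(perr[1]), r2, len(x))


def fit_quadratic(data: ThermalSeries) -> QuadParams:
    """OLS fit of Y on [1, x, x²] with coefficient SEs and R²."""
    x, y = data.t, data.j
    if len(x) < 4:
        raise UnderDeterminedError("need >= 4 points for the quadratic fit")
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, se, r2, _ = _ols(X, y)
    return QuadParams(*(float(b) for b in beta), *(float(s) for s in se),
                      r_squared=r2, n=len(x))


def timecourse_slope(times, product) -> SlopeFit:
    """OLS slope of product (nmol per mg protein) on time (min).

    This is how activities at sub-saturating substrate are derived from
    time-course incubations: the slope is the specific activity in
    nmol·mg⁻¹·min⁻¹.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(product, dtype=float)
    if len(t) < 3:
        raise UnderDeterminedError("need >= 3 time points")
    if 0.0 not in t:
        raise DomainError("time course must include t=0")
    if len(set(t.tolist())) < 2:
        raise DegenerateDataError("all time points identical: singular design")
    X = np.column_stack([np.ones_like(t), t])
    beta, se, r2, _ = _ols(X, p)
    return SlopeFit(float(beta[1]), float(se[1]), float(beta[0]), r2, len(t))


def specific_activity(
    delta_absorbance: float,
    calibration_slope: float,
    protein_mg: float,
    minutes: float,
    calibration_intercept: float = 0.0,
) -> float:
    """Specific activity from an endpoint absorbance change.

    nmol pNP = (ΔA − intercept)/slope with the calibration in AU per nmol;
    activity = nmol/(protein·minutes), i.e. U per mg protein.
    """
    if calibration_slope <= 0:
        raise DomainError("calibration slope must be > 0")
    if protein_mg <= 0 or minutes <= 0:
        raise DomainError("protein mass and incubation time must be > 0")
    nmol = (delta_absorbance - calibration_intercept) / calibration_slope
    return nmol / (protein_mg * minutes)


# ---------------------------------------------------------------------------
# AnalysisResult adapters
# ---------------------------------------------------------------------------


def mm_result(params: MMParams, data: KineticDataset, seed=None,
              on_means: bool = False):
    from .core_io import AnalysisResult

    return AnalysisResult(
        stage="fit_michaelis_menten",
        parameters={"Km": (params.Km, params.se_Km),
                    "Vmax": (params.Vmax, params.se_Vmax)},
        diagnostics={"r_squared": params.r_squared, "n": params.n,
                     "converged": params.converged},
        provenance={"input_digest": digest(data.substrate, data.velocity),
                    "seed": seed, "entry_mode": "means" if on_means else "replicates",
                    **_FIT_POLICY},
    )
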