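"""Device-performance and growth metrics from plate-reader curves.

Induction response is summarized by steady-state OD-normalized fluorescence
(Fss, averaged over a late-growth window, default 6-12 h) as a function of
inducer concentration and fit with the Hill function

    Fss(x) = beta * x**n / (K**n + x**n) + C

where ``beta`` is the maximum output above baseline (RFU), ``K`` the
activation coefficient (inducer units: mM arabinose or nM aTc), ``n`` the
Hill coefficient, and ``C`` the empirical baseline at zero inducer (fixed
to the mean Fss of the zero-inducer wells, never fitted).  The dynamic
range DR = beta / C is the largest fold-change the reporter can produce.

Growth is summarized by the maximum specific rate mu (1/h) from a rolling
log-linear regression and by the Zwietering modified Gompertz model with
an explicit lag parameter,

    y(t) = y0 + A * exp(-exp((mu*e/A) * (lambda - t) + 1)),

whose maximum slope is exactly ``mu`` at the inflection point.  For the
two mu estimates to agree, the Gompertz model must be fit on the same
scale the rolling regression differentiates, i.e. log abundance; pass
``log_input=True`` to fit ln(OD600) (then ``A`` is the log-scale span
ln(N_max/N_0) and ``mu`` the maximum specific growth rate in 1/h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "GompertzFit",
    "RollingRateResult",
    "hill",
    "gompertz_lag",
    "steady_state_fss",
    "fit_hill",
    "dynamic_range",
    "rolling_max_rate",
    "fit_gompertz_lag",
    "delta_mu",
    "specific_dynamic_range",
]


# ---------------------------------------------------------------------------
# model functions


def hill(x, beta, K, n, C):
    """Hill activation curve; x in inducer units, output in RFU."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = np.where(x > 0, x, 1.0) ** n
        resp = np.where(x > 0, beta * xn / (K**n + xn), 0.0)
    return resp + C


def gompertz_lag(t, A, mu, lam, y0=0.0):
    """Zwietering modified Gompertz with lag; max slope is mu at inflection."""
    t = np.asarray(t, dtype=float)
    return y0 + A * np.exp(-np.exp((mu * np.e / A) * (lam - t) + 1.0))


# ---------------------------------------------------------------------------
# result containers


@dataclass
class HillFit:
    beta: float
    K: float
    n: float
    C: float
    dr: float = np.nan
    ss_res: float = np.nan
    converged: bool = False
    dr_defined: bool = True

    def predict(self, x):
        return hill(x, self.beta, self.K, self.n, self.C)


@dataclass
class GompertzFit:
    A: float
    mu: float
    lam: float
    y0: float
    ss_res: float = np.nan
    converged: bool = False
    log_input: bool = False

    def predict(self, t):
        y = gompertz_lag(t, self.A, self.mu, self.lam, self.y0)
        return np.exp(y) if self.log_input else y


@dataclass
class RollingRateResult:
    mu: float
    r2: float = np.nan
    t_start: float = np.nan
    ok: bool = False
    slopes: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


# ---------------------------------------------------------------------------
# operations


def steady_state_fss(time, value, window=(6.0, 12.0)):
    """Mean signal over the late-growth steady-state window (hours)."""
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    t0, t1 = window
    mask = (time >= t0) & (time <= t1)
    if mask.sum() < 2:
        raise ValueError(
            f"steady-state window [{t0}, {t1}] h contains "
            f"{int(mask.sum())} samples (need >= 2)"
        )
    return float(value[mask].mean())


def fit_hill(concentrations, responses, baseline=None) -> HillFit:
    """Fit the Hill function to Fss-vs-concentration data.

    ``concentrations`` and ``responses`` are flat, parallel arrays;
    replicate wells appear as repeated concentrations and are averaged
    before fitting.  The baseline ``C`` is the empirical mean response at
    zero inducer (or ``baseline`` if given) and is held fixed; ``beta``,
    ``K`` and ``n`` are estimated by bounded nonlinear least squares with
    multiple starts for the Hill coefficient.  Non-convergence never
    raises: the returned fit carries ``converged=False``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concentrations and responses must align")
    if (x < 0).any():
        raise ValueError("inducer concentrations must be non-negative")
    # replicate means per unique concentration
    xs = np.unique(x)
    ym = np.array([y[x == xi].mean() for xi in xs])
    if baseline is None:
        if 0.0 not in xs:
            raise ValueError("zero-inducer wells required to fix the baseline C")
        baseline = float(ym[xs == 0.0][0])
    C = float(baseline)
    if len(xs) < 4:
        raise ValueError("need >= 4 distinct concentrations")

    pos = xs > 0
    k0 = float(np.exp(np.median(np.log(xs[pos]))))  # geometric median conc
    beta0 = max(float(ym.max() - C), 1e-6)

    def model(x, beta, K, n):
        return hill(x, beta, K, n, C)

    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        try:
            popt, _ = curve_fit(
                model,
                xs,
                ym,
                p0=[beta0, k0, n0],
                bounds=([0.0, 1e-12, 1e-3], [np.inf, np.inf, 50.0]),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
        except RuntimeError:
            continue
        ss = float(np.sum((model(xs, *popt) - ym) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, C, converged=False)
    ss, (beta, K, n) = best
    fit = HillFit(float(beta), float(K), float(n), C, ss_res=ss, converged=True)
    fit.dr, fit.dr_defined = _dr(fit.beta, fit.C)
    return fit


def _dr(beta, C):
    if C > 0:
        return beta / C, True
    warnings.warn("baseline C <= 0: dynamic range undefined", stacklevel=3)
    return np.nan, False


def dynamic_range(fit: HillFit) -> float:
    """DR = beta / C, the device's maximal fold-change output."""
    dr, _ = _dr(fit.beta, fit.C)
    return dr


def _rolling_slopes(time, y, h):
    """OLS slope and R^2 of y vs time for every window of h points."""
    tw = sliding_window_view(time, h)
    yw = sliding_window_view(y, h)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    stt = ((tw - tm) ** 2).sum(axis=1)
    sty = ((tw - tm) * (yw - ym)).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    slope = sty / stt
    ss_res = syy - sty**2 / stt
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, 1.0 - ss_res / syy, 1.0)
    # numerically perfect fits can give tiny negative ss_res
    r2 = np.clip(r2, 0.0, 1.0)
    return slope, r2


def rolling_max_rate(time, value, h=5, r2_min=0.95) -> RollingRateResult:
    """Maximum specific rate via rolling log-linear regression.

    For every window of ``h`` consecutive points an OLS line is fit to
    ln(value) vs time; the maximum slope among windows with R^2 >=
    ``r2_min`` is returned (1/h units).  Windows containing non-positive
    values are skipped; a perfectly flat window counts as R^2 = 1 with
    slope 0.  If no window passes the filter the result is flagged
    (``ok=False``) instead of raising.
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    if len(time) < h:
        raise ValueError(f"need at least h={h} points")
    valid = sliding_window_view(value > 0, h).all(axis=1)
    if not valid.any():
        return RollingRateResult(np.nan, ok=False)
    logv = np.where(value > 0, np.log(np.where(value > 0, value, 1.0)), np.nan)
    slope, r2 = _rolling_slopes(time, logv, h)
    passing = valid & (r2 >= r2_min)
    if not passing.any():
        return RollingRateResult(np.nan, ok=False, slopes=slope)
    idx = np.flatnonzero(passing)[np.nanargmax(slope[passing])]
    return RollingRateResult(
        float(slope[idx]), r2=float(r2[idx]), t_start=float(time[idx]),
        ok=True, slopes=slope,
    )


def fit_gompertz_lag(time, value, log_input=False, h=5) -> GompertzFit:
    """Fit the Zwietering Gompertz-with-lag model by least squares.

    With ``log_input=True`` the model is fit to ln(value) so that ``mu``
    is the maximum *specific* rate (1/h), directly comparable to
    :func:`rolling_max_rate`, and ``A`` the log-scale span.  Multi-start
    initialization uses the rolling maximum slope and the data extremes.
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    if log_input:
        if (value <= 0).any():
            raise ValueError("log_input requires strictly positive values")
        y = np.log(value)
    else:
        y = value
    if y.max() <= y.min():
        raise ValueError("curve has no dynamic span to fit")

    y0_0 = float(y.min())
    A0 = float(y.max() - y.min())
    slope, _ = _rolling_slopes(time, y, min(h, len(y)))
    mu0 = max(float(np.nanmax(slope)), 1e-3)
    # first time the curve clears 10% of its span, minus the rise time
    above = time[y > y0_0 + 0.1 * A0]
    lam0 = max(float(above[0]) - 0.1 * A0 / mu0, 0.0) if len(above) else 0.0
    span = float(time.max() - time.min())

    best = None
    for lam_start in {0.0, lam0, 0.25 * span}:
        for mu_start in (mu0, 0.5 * mu0, 2.0 * mu0):
            try:
                popt, _ = curve_fit(
                    gompertz_lag,
                    time,
                    y,
                    p0=[A0, mu_start, lam_start, y0_0],
                    bounds=(
                        [1e-9, 1e-9, 0.0, -np.inf],
                        [np.inf, np.inf, max(span, 1e-9), np.inf],
                    ),
                    maxfev=20000,
                    xtol=1e-14,
                    ftol=1e-14,
                )
            except RuntimeError:
                continue
            ss = float(np.sum((gompertz_lag(time, *popt) - y) ** 2))
            if best is None or ss < best[0]:
                best = (ss, popt)
    if best is None:
        return GompertzFit(
            np.nan, np.nan, np.nan, np.nan, converged=False, log_input=log_input
        )
    ss, (A, mu, lam, y0) = best
    return GompertzFit(
        float(A), float(mu), float(lam), float(y0),
        ss_res=ss, converged=True, log_input=log_input,
    )


def delta_mu(mu_1, mu_2) -> float:
    """Relative percentage change in max specific growth rate.

    Delta-mu = ((mu_1 - mu_2) / mu_1) * 100; positive values mean the
    second condition grows slower (a growth burden), negative values a
    growth increase.
    """
    if mu_1 <= 0:
        raise ValueError("reference growth rate mu_1 must be positive")
    return (mu_1 - mu_2) / mu_1 * 100.0


def specific_dynamic_range(fss_induced, fss_baseline) -> float:
    """DR_S: induced-state Fss over the same host/channel's NI-state Fss.

    Values below 1 mean the induced output dropped under the non-induced
    baseline.  A non-positive baseline makes the ratio undefined (NaN,
    with a warning) rather than raising.
    """
    if fss_baseline <= 0:
        warnings.warn("non-positive baseline Fss: DR_S undefined", stacklevel=2)
        return np.nan
    return float(fss_induced) / float(fss_baseline)
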