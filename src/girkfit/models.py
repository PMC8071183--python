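"""Curve-fit estimators in the scikit-learn idiom.

Three small regressors cover every fit the analysis pipeline performs:

* :class:`MonoExponential` -- Levenberg-Marquardt fit of a single
  exponential relaxation to a trace segment (activation or deactivation).
* :class:`ConcentrationResponse` -- the fixed-slope, zero-bottom logistic
  ``Y = Top / (1 + 10**(logEC50 - X))`` on log10-concentration data.
* :class:`KobsLinear` -- ordinary least squares of the observed activation
  rate against concentration, restricted to the concentration prefix over
  which the relation is statistically linear (``k_obs = [A]*k_on + k_off``).

Each follows the fit/predict contract with ``get_params``/``set_params``
inherited from :class:`sklearn.base.BaseEstimator` and fitted attributes
carrying a trailing underscore, so they compose with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
import lmfit
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError(f"X must have a single column, got shape {X.shape}")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError(f"X must be 1-D or a single column, got shape {X.shape}")
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError(f"X and y lengths differ: {X.shape} vs {y.shape}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    return X, y


class MonoExponential(BaseEstimator, RegressorMixin):
    """Single-exponential relaxation ``y = offset + amplitude * exp(-(t-t0)/tau)``.

    A positive fitted amplitude describes a decay, a negative one a rise
    toward ``offset``.  Initial guesses are scale-free: amplitude = first
    minus last sample, offset = last sample, tau = window/3; tau is bounded
    to [sample interval, 10 x window].

    Parameters
    ----------
    t0 : float, optional
        Time origin of the exponential; defaults to the first sample.
    fix_offset : bool
        Anchor the offset at ``offset_value`` instead of fitting it.
    offset_value : float
        Offset used when ``fix_offset`` is true.

    Attributes
    ----------
    tau_, amplitude_, offset_ : float
        Fitted parameters (tau in the units of the time axis).
    tau_stderr_ : float or nan
        Standard error of tau from the fit covariance.
    rmse_ : float
        Root-mean-square residual.
    converged_ : bool
    reasons_ : list of str
        Diagnostics when the fit did not converge cleanly (including tau
        pinned at a bound).
    """

    def __init__(self, t0: float | None = None, fix_offset: bool = False,
                 offset_value: float = 0.0):
        self.t0 = t0
        self.fix_offset = fix_offset
        self.offset_value = offset_value

    def fit(self, X, y):
        t, y = _as_xy(X, y)
        if len(t) < 4:
            raise ValueError("need at least 4 samples for an exponential fit")
        order = np.argsort(t)
        t, y = t[order], y[order]
        t0 = float(t[0] if self.t0 is None else self.t0)
        window = float(t[-1] - t0)
        if window <= 0:
            raise ValueError("time window has non-positive length")
        dt = float(np.min(np.diff(t)))
        tau_min, tau_max = max(dt, 1e-12), 10.0 * window

        pars = lmfit.Parameters()
        pars.add("amplitude", value=float(y[0] - y[-1]) or 1e-12)
        pars.add("tau", value=np.clip(window / 3.0, tau_min, tau_max),
                 min=tau_min, max=tau_max)
        pars.add("offset", value=(self.offset_value if self.fix_offset
                                  else float(y[-1])),
                 vary=not self.fix_offset)

        def residual(p):
            return (p["offset"] + p["amplitude"]
                    * np.exp(-(t - t0) / p["tau"])) - y

        res = lmfit.minimize(residual, pars, method="leastsq",
                             xtol=1e-10, ftol=1e-10)
        self.tau_ = float(res.params["tau"].value)
        self.amplitude_ = float(res.params["amplitude"].value)
        self.offset_ = float(res.params["offset"].value)
        stderr = res.params["tau"].stderr
        self.tau_stderr_ = float(stderr) if stderr is not None else float("nan")
        self.rmse_ = float(np.sqrt(np.mean(res.residual ** 2)))
        self.window_ = (t0, float(t[-1]))
        self.reasons_ = []
        if not res.success:
            self.reasons_.append(f"solver did not converge: {res.message}")
        rel = (self.tau_ - tau_min) / (tau_max - tau_min)
        if rel < 1e-6 or rel > 1 - 1e-6:
            self.reasons_.append(
                f"tau={self.tau_:.4g}s pinned at bound [{tau_min:.4g}, {tau_max:.4g}]")
        self.converged_ = not self.reasons_
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        t0 = self.window_[0]
        return self.offset_ + self.amplitude_ * np.exp(-(t - t0) / self.tau_)


class ConcentrationResponse(BaseEstimator, RegressorMixin):
    """Fixed-slope logistic concentration-response curve.

    Fits ``Y = Top / (1 + 10**(logEC50 - X))`` where ``X`` is
    log10(agonist concentration in M) and ``Y`` the reference-normalized
    response.  Bottom is fixed at 0 and the Hill slope at 1 (the model has
    neither as a free parameter), so only potency (pEC50 = -logEC50) and
    maximal response (Top, the relative efficacy) are estimated.

    Attributes
    ----------
    pec50_, top_ : float
    pec50_sem_, top_sem_ : float
        Standard errors from the fit covariance (nan if unavailable).
    n_points_ : int
    converged_ : bool
    reasons_ : list of str
    """

    def fit(self, X, y):
        x, y = _as_xy(X, y)
        if len(np.unique(x)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        self.reasons_ = []
        if np.ptp(y) == 0.0:
            # A flat response carries no potency information.
            self.pec50_ = float("nan")
            self.top_ = float(y[0])
            self.pec50_sem_ = self.top_sem_ = float("nan")
            self.n_points_ = len(x)
            self.reasons_.append("all responses equal: curve not identifiable")
            self.converged_ = False
            return self

        top0 = float(np.max(y))
        half = 0.5 * top0
        logec50_0 = float(x[np.argmin(np.abs(y - half))])
        pars = lmfit.Parameters()
        pars.add("top", value=top0 or 1.0)
        pars.add("logec50", value=logec50_0)

        def residual(p):
            return p["top"] / (1.0 + 10.0 ** (p["logec50"] - x)) - y

        res = lmfit.minimize(residual, pars, method="leastsq",
                             xtol=1e-10, ftol=1e-10)
        self.top_ = float(res.params["top"].value)
        self.pec50_ = -float(res.params["logec50"].value)
        t_err = res.params["top"].stderr
        e_err = res.params["logec50"].stderr
        self.top_sem_ = float(t_err) if t_err is not None else float("nan")
        self.pec50_sem_ = float(e_err) if e_err is not None else float("nan")
        self.n_points_ = len(x)
        if not res.success:
            self.reasons_.append(f"solver did not converge: {res.message}")
        if not self.top_ > 0:
            self.reasons_.append(f"fitted Top is non-positive ({self.top_:.3g})")
        self.converged_ = not self.reasons_
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.top_ / (1.0 + 10.0 ** (-self.pec50_ - x))


class KobsLinear(BaseEstimator, RegressorMixin):
    """Linear-range fit of observed activation rate vs concentration.

    Sorts the points by concentration and selects the largest
    low-concentration prefix (>= 3 points) on which (a) adding a quadratic
    term does not significantly improve the straight-line fit (partial
    F-test at level ``alpha``) and (b) the highest included point deviates
    from the line by less than ``max_relative_deviation``.  Ordinary least
    squares on that prefix yields the slope (the k_on estimate) and
    intercept (retained only as a diagnostic against the washout k_off).

    Attributes
    ----------
    slope_, intercept_ : float
    slope_sem_, intercept_sem_ : float
    r_squared_ : float
    included_, excluded_ : ndarray
        Concentrations inside/outside the selected linear range.
    n_included_ : int
    """

    def __init__(self, alpha: float = 0.05, max_relative_deviation: float = 0.15):
        self.alpha = alpha
        self.max_relative_deviation = max_relative_deviation

    def fit(self, X, y):
        c, k = _as_xy(X, y)
        if len(c) < 3:
            raise ValueError("need at least 3 (concentration, k_obs) points")
        if len(np.unique(c)) != len(c):
            raise ValueError("concentrations must be distinct")
        order = np.argsort(c)
        c, k = c[order], k[order]

        chosen = None
        for m in range(len(c), 2, -1):
            if self._prefix_is_linear(c[:m], k[:m]):
                chosen = m
                break
        if chosen is None:
            raise ValueError(
                "no admissible linear prefix of >= 3 concentrations; "
                "collect data at lower concentrations")

        cm, km = c[:chosen], k[:chosen]
        slope, intercept, sl_se, ic_se, r2 = _ols_line(cm, km)
        self.slope_ = slope
        self.intercept_ = intercept
        self.slope_sem_ = sl_se
        self.intercept_sem_ = ic_se
        self.r_squared_ = r2
        self.included_ = cm.copy()
        self.excluded_ = c[chosen:].copy()
        self.n_included_ = chosen
        return self

    def _prefix_is_linear(self, c, k) -> bool:
        slope, intercept, *_ = _ols_line(c, k)
        pred = intercept + slope * c
        if pred[-1] != 0:
            dev = abs(k[-1] - pred[-1]) / abs(pred[-1])
            if dev >= self.max_relative_deviation:
                return False
        n = len(c)
        if n <= 3:
            # The quadratic saturates 3 points; linearity cannot be rejected.
            return True
        sse_lin = float(np.sum((k - pred) ** 2))
        # Standardize the regressor so the quadratic column is not lost to
        # conditioning at molar concentration scales.
        z = (c - c.mean()) / c.std()
        design = np.column_stack([np.ones(n), z, z ** 2])
        beta, *_ = np.linalg.lstsq(design, k, rcond=None)
        sse_quad = float(np.sum((k - design @ beta) ** 2))
        if sse_quad <= 0:
            return sse_lin <= 1e-25
        f = (sse_lin - sse_quad) / (sse_quad / (n - 3))
        p = stats.f.sf(f, 1, n - 3)
        return p > self.alpha

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * c


def _ols_line(x, y):
    """Straight-line OLS returning slope, intercept, their SEs and R^2."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if n > 2:
        s2 = sse / (n - 2)
        slope_se = float(np.sqrt(s2 / sxx))
        intercept_se = float(np.sqrt(s2 * (1.0 / n + xm ** 2 / sxx)))
    else:
        slope_se = intercept_se = float("nan")
    return slope, intercept, slope_se, intercept_se, r2
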