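"""Standardised major axis (SMA) regression and the two headline scaling tests.

SMA estimates the underlying bivariate line rather than predicting y from x:
slope = sign(r) * sd(y)/sd(x), intercept through the means. The hypothesis
test for a target slope ``b0`` checks the Pearson correlation between the
residual axis ``y - b0*x`` and the fitted axis ``y + b0*x`` (zero exactly when
``b0`` equals the fitted SMA slope), with df = n - 2 and a two-sided t-tail.
Confidence intervals come from a seeded case-resampling bootstrap.

The two headline tests on log-log axes:

* ``proportionality_test`` — temperature-corrected community rate against
  mass-corrected biomass, target slope 1 (direct proportionality).
* ``compensation_test`` — total abundance against per-capita rate, target
  slope −1 (zero-sum metabolic compensation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import t as t_dist

from .core import (
    Community,
    average_individual_rate,
    mass_corrected_biomass,
    temperature_correct,
)
from .errors import DataError

__all__ = [
    "SMAResult",
    "sma_fit",
    "sma_slope_test",
    "bootstrap_sma",
    "ols_slope",
    "proportionality_test",
    "compensation_test",
]


@dataclass
class SMAResult:
    slope: float
    intercept: float
    r2: float
    n: int
    boot_ci_slope: Optional[tuple[float, float]] = None
    boot_ci_intercept: Optional[tuple[float, float]] = None
    slope_test: Optional[dict] = None
    ols_slope: Optional[float] = None
    n_boot: int = 0
    n_degenerate_resamples: int = 0
    x: np.ndarray = field(default=None, repr=False, compare=False)
    y: np.ndarray = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n": self.n,
            "boot_ci_slope": self.boot_ci_slope,
            "boot_ci_intercept": self.boot_ci_intercept,
            "slope_test": self.slope_test,
            "ols_slope": self.ols_slope,
            "n_boot": self.n_boot,
        }


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise DataError(f"need at least 3 points, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance on one axis; SMA undefined")
    return x, y


def sma_fit(x, y) -> SMAResult:
    """Standardised major axis line on already-log-transformed data."""
    x, y = _validate_xy(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * float(np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAResult(slope=slope, intercept=intercept, r2=r * r, n=x.size, x=x, y=y)


def sma_slope_test(x, y, b0: float) -> dict:
    """Two-sided test of the SMA slope against ``b0``.

    Correlates the residual scores ``y - b0*x`` with the fitted scores
    ``y + b0*x``; under a true slope of ``b0`` the two axes are uncorrelated.
    """
    x, y = _validate_xy(x, y)
    resid = y - b0 * x
    fitted = y + b0 * x
    if np.std(resid) == 0 or np.std(fitted) == 0:
        raise DataError("degenerate residual/fitted axis in slope test")
    r = float(np.corrcoef(resid, fitted)[0, 1])
    df = x.size - 2
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t_stat = r * np.sqrt(df / denom)
    p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return {"b0": b0, "r": r, "df": df, "p": p}


def bootstrap_sma(
    x, y, n_boot: int = 1000, seed: Optional[int] = 0
) -> tuple[tuple[float, float], tuple[float, float], int]:
    """Percentile bootstrap CIs for the SMA slope and intercept.

    Case resampling; a degenerate resample (zero variance on either axis) is
    redrawn and counted. Returns (slope CI, intercept CI, n redrawn).
    """
    x, y = _validate_xy(x, y)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    n_degenerate = 0
    for b in range(n_boot):
        for _ in range(100):
            take = rng.integers(0, x.size, size=x.size)
            xb, yb = x[take], y[take]
            if np.std(xb) > 0 and np.std(yb) > 0:
                break
            n_degenerate += 1
        else:  # pragma: no cover - pathological input
            raise DataError("could not draw a non-degenerate bootstrap resample")
        fit = sma_fit(xb, yb)
        slopes[b], intercepts[b] = fit.slope, fit.intercept
    slope_ci = tuple(float(q) for q in np.quantile(slopes, [0.025, 0.975]))
    int_ci = tuple(float(q) for q in np.quantile(intercepts, [0.025, 0.975]))
    return slope_ci, int_ci, n_degenerate


def ols_slope(x, y) -> float:
    """Ordinary least-squares slope, reported alongside SMA for comparison."""
    x, y = _validate_xy(x, y)
    return float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))


def _finish(result: SMAResult, b0: float, n_boot: int, seed) -> SMAResult:
    result.slope_test = sma_slope_test(result.x, result.y, b0)
    result.ols_slope = ols_slope(result.x, result.y)
    if n_boot > 0:
        slope_ci, int_ci, n_deg = bootstrap_sma(result.x, result.y, n_boot, seed)
        result.boot_ci_slope = slope_ci
        result.boot_ci_intercept = int_ci
        result.n_boot = n_boot
        result.n_degenerate_resamples = n_deg
    return result


def _refit_bootstrap(communities, fit, flux, kind, n_boot, seed, result: SMAResult) -> SMAResult:
    """Bootstrap over communities, refitting the scaling model per replicate.

    Resampling the data *and* the model propagates parameter-estimation
    uncertainty into the slope/intercept intervals, which a point-level case
    resample cannot see. Works on the vectorised likelihood arrays so each
    replicate costs one bounded 1-D re-optimisation of alpha.
    """
    from scipy.optimize import minimize, minimize_scalar

    from .errors import IdentifiabilityError
    from .inference import _Prepared, _rss_given_alpha

    prep = _Prepared(communities, flux, fit.t_ref)
    spec = fit.model_spec
    X, names = prep.design(spec)
    b_cols = np.array([i for i, nm in enumerate(names) if nm.startswith("ln_b")])
    e_cols = np.array([i for i, nm in enumerate(names) if nm.startswith("E")])
    ln_n = np.log(np.array([c.n_tot for c in communities]))
    split_alpha = "alpha" in spec.split
    alpha_hat = (
        np.array([fit.params[f"alpha[{lv}]"] for lv in prep.levels])
        if split_alpha
        else np.array([fit.params["alpha"]])
    )

    class _View:
        """Row-resampled view sharing the full per-mass arrays."""

        def __init__(self, take):
            self.take = take
            self.y = prep.y[take]
            self.n = take.size
            self.levels = prep.levels

        def ln_S(self, alpha_by_group):
            return prep.ln_S(alpha_by_group)[self.take]

    rng = np.random.default_rng(seed)
    slopes, intercepts = [], []
    n = prep.n
    n_deg = 0
    while len(slopes) < n_boot:
        take = rng.integers(0, n, size=n)
        view = _View(take)
        Xb = X[take]

        def rss_of(alpha_vec):
            return _rss_given_alpha(view, spec, alpha_vec, Xb)

        try:
            if split_alpha:
                res = minimize(
                    lambda th: rss_of(np.asarray(th))[0], alpha_hat,
                    method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12},
                )
                alpha = np.asarray(res.x)
            else:
                res = minimize_scalar(
                    lambda a: rss_of(np.full(max(len(prep.levels), 1), a))[0],
                    bounds=(-1.0, 3.0), method="bounded",
                    options={"xatol": 1e-8},
                )
                alpha = np.full(max(len(prep.levels), 1), res.x)
            _, beta = rss_of(alpha)
            ln_s = view.ln_S(alpha if split_alpha else np.full(max(len(prep.levels), 1), alpha[0]))
            b_part = Xb[:, b_cols] @ beta[b_cols]
            e_part = Xb[:, e_cols] @ beta[e_cols]
            if kind == "proportionality":
                xb = b_part + ln_s
                yb = view.y - e_part
            else:  # compensation
                xb = b_part + ln_s + e_part - ln_n[take]
                yb = ln_n[take]
            bfit = sma_fit(xb, yb)
        except (DataError, IdentifiabilityError):
            n_deg += 1
            if n_deg > 10 * n_boot:  # pragma: no cover - pathological input
                raise DataError("could not draw non-degenerate bootstrap resamples")
            continue
        slopes.append(bfit.slope)
        intercepts.append(bfit.intercept)
    result.boot_ci_slope = tuple(float(q) for q in np.quantile(slopes, [0.025, 0.975]))
    result.boot_ci_intercept = tuple(
        float(q) for q in np.quantile(intercepts, [0.025, 0.975])
    )
    result.n_boot = n_boot
    result.n_degenerate_resamples = n_deg
    return result


def _proportionality_xy(communities, fit, flux):
    xs, ys = [], []
    for comm in communities:
        p = fit.params_for(comm.mesocosm_treatment)
        xs.append(
            np.log(
                mass_corrected_biomass(comm.masses, p.alpha, p.ln_b_tc, comm.scale_to_litre)
            )
        )
        ys.append(
            np.log(
                temperature_correct(
                    comm.observed_rate(flux), p.activation_energy, comm.incubator_t, p.t_ref
                )
            )
        )
    return np.array(xs), np.array(ys)


def _compensation_xy(communities, fit, flux):
    xs, ys = [], []
    for comm in communities:
        p = fit.params_for(comm.mesocosm_treatment)
        if comm.n_tot <= 0:
            raise DataError(f"{comm.id}: zero abundance")
        xs.append(np.log(average_individual_rate(comm, p)))
        ys.append(np.log(comm.n_tot))
    return np.array(xs), np.array(ys)


def _headline_test(communities, fit, flux, b0, n_boot, seed, bootstrap, xy_of):
    x, y = xy_of(communities, fit, flux)
    result = sma_fit(x, y)
    result.slope_test = sma_slope_test(x, y, b0)
    result.ols_slope = ols_slope(x, y)
    if n_boot <= 0:
        return result
    if bootstrap == "refit":
        kind = "proportionality" if b0 > 0 else "compensation"
        return _refit_bootstrap(communities, fit, flux, kind, n_boot, seed, result)
    if bootstrap == "cases":
        return _finish(result, b0=b0, n_boot=n_boot, seed=seed)
    raise DataError(f"bootstrap must be 'refit' or 'cases', got {bootstrap!r}")


def proportionality_test(
    communities: Sequence[Community],
    fit,
    flux: str = "gpp",
    n_boot: int = 1000,
    seed: Optional[int] = 0,
    bootstrap: str = "refit",
) -> SMAResult:
    """Test direct proportionality of corrected rate to mass-corrected biomass.

    x = ln mass-corrected biomass, y = ln temperature-corrected observed
    rate, both computed from the fitted parameters; SMA with slope test
    against 1. Noise-free model data fall exactly on the y = x line.

    The default bootstrap resamples communities and refits the scaling model
    per replicate ("data and model"); ``bootstrap="cases"`` resamples the
    (x, y) points with the parameters held fixed.
    """
    return _headline_test(
        communities, fit, flux, 1.0, n_boot, seed, bootstrap, _proportionality_xy
    )


def compensation_test(
    communities: Sequence[Community],
    fit,
    flux: str = "gpp",
    n_boot: int = 1000,
    seed: Optional[int] = 0,
    bootstrap: str = "refit",
) -> SMAResult:
    """Test the zero-sum abundance / per-capita-rate trade-off (target −1).

    x = ln average individual rate under the fitted parameters, y = ln total
    abundance; SMA with slope test against −1. Bootstrap modes as in
    :func:`proportionality_test`.
    """
    return _headline_test(
        communities, fit, flux, -1.0, n_boot, seed, bootstrap, _compensation_xy
    )
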