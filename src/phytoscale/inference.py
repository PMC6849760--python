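"""Maximum-likelihood estimation of the community metabolic-scaling model.

The observation model is Gaussian on the natural-log rate::

    ln B_j ~ Normal( ln_b_tc + ln(sum_i m_ij**alpha * scale_j) + E * x_j, sigma**2 )

with ``x_j = 1/(k*Tc) - 1/(k*T_j)``. Conditional on the size-scaling
exponent(s) ``alpha`` the predictor is linear in ``ln_b_tc`` and ``E``, so
those coefficients and ``sigma`` have closed-form conditional MLEs; the
seeded multistart optimisation therefore runs over ``alpha`` alone, which is
the same maximum as a joint 4-parameter search with far better conditioning.

Any of ``ln_b_tc``, ``E`` and ``alpha`` can be split by the long-term
treatment; nested variants are compared with likelihood-ratio tests.
Confidence intervals are profile-likelihood intervals at the chi-square(1)
95% deviance cutoff, falling back to a quadratic approximation (flagged)
when the profile runs into the search bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, norm

from .core import BOLTZMANN_EV, T_REF, Community, MSTParams, community_rate
from .errors import ConvergenceError, DataError, IdentifiabilityError

__all__ = [
    "ModelSpec",
    "MSTFitResult",
    "LRTResult",
    "ProfileCI",
    "log_likelihood",
    "fit_mst",
    "profile_ci",
    "compare_treatment_models",
]

SPLITTABLE = ("ln_b_tc", "E", "alpha")
_SIGMA_FLOOR = 1e-300


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters get a separate value per long-term treatment."""

    split: frozenset = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.split) - set(SPLITTABLE)
        if bad:
            raise DataError(f"unknown split parameters: {sorted(bad)}")

    @classmethod
    def shared(cls) -> "ModelSpec":
        return cls(frozenset())

    @classmethod
    def splitting(cls, *names: str) -> "ModelSpec":
        return cls(frozenset(names))

    def label(self) -> str:
        return "shared" if not self.split else "split:" + "+".join(sorted(self.split))


@dataclass(frozen=True)
class ProfileCI:
    lower: float
    upper: float
    level: float = 0.95
    method: str = "profile"  # or "wald_fallback", "bracket"
    note: str = ""


@dataclass
class MSTFitResult:
    """Result of one maximum-likelihood fit for one flux."""

    flux: str
    model_spec: ModelSpec
    params: dict
    sigma: float
    loglik: float
    aic: float
    rss: float
    n_obs: int
    n_params: int
    converged: bool
    t_ref: float = T_REF
    ci: dict = field(default_factory=dict)
    _prepared: object = field(default=None, repr=False, compare=False)

    def params_for(self, treatment: Optional[str] = None) -> MSTParams:
        """Materialise an :class:`MSTParams` for one treatment (or the pooled fit)."""

        def pick(name):
            if name in self.params:
                return self.params[name]
            if treatment is None:
                raise DataError(f"{name} is treatment-split; pass a treatment")
            return self.params[f"{name}[{treatment}]"]

        return MSTParams(
            ln_b_tc=pick("ln_b_tc"),
            alpha=pick("alpha"),
            activation_energy=pick("E"),
            sigma=self.sigma,
            t_ref=self.t_ref,
        )

    def summary_dict(self) -> dict:
        out = {
            "flux": self.flux,
            "model": self.model_spec.label(),
            "estimates": dict(self.params),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "ci": {
                k: {"lower": v.lower, "upper": v.upper, "method": v.method}
                for k, v in self.ci.items()
            },
        }
        return out


@dataclass(frozen=True)
class LRTResult:
    parameter: str
    statistic: Optional[float]
    df: int
    p_value: Optional[float]
    preferred: str
    aic_shared: Optional[float]
    aic_split: Optional[float]
    converged: bool
    note: str = ""


def log_likelihood(
    params, communities: Sequence[Community], flux: str, t_ref: float = T_REF
) -> float:
    """Direct (unconcentrated) log-likelihood of observed rates.

    ``params`` is either a single :class:`MSTParams` or a mapping from
    long-term treatment to :class:`MSTParams`. This is the independent route
    against which the concentrated fit is validated.
    """
    total = 0.0
    for comm in communities:
        p = params[comm.mesocosm_treatment] if isinstance(params, dict) else params
        if p.t_ref != t_ref:
            p = replace(p, t_ref=t_ref)
        obs = comm.observed_rate(flux)
        if obs <= 0:
            raise DataError(f"{comm.id}: observed {flux} rate must be > 0")
        if comm.masses.size == 0:
            raise DataError(f"{comm.id}: empty mass vector")
        pred = np.log(community_rate(p, comm))
        sigma = max(p.sigma, np.sqrt(_SIGMA_FLOOR))
        total += norm.logpdf(np.log(obs), loc=pred, scale=sigma)
    return float(total)


class _Prepared:
    """Vectorised view of the dataset used by the concentrated likelihood."""

    def __init__(self, communities: Sequence[Community], flux: str, t_ref: float):
        if len(communities) == 0:
            raise DataError("no communities supplied")
        y, x, log_scale, groups, treatments = [], [], [], [], []
        log_masses, idx = [], []
        for j, comm in enumerate(communities):
            obs = comm.observed_rate(flux)
            if obs <= 0:
                raise DataError(f"{comm.id}: observed {flux} rate must be > 0")
            if comm.masses.size == 0:
                raise DataError(f"{comm.id}: empty mass vector")
            y.append(np.log(obs))
            x.append(1.0 / (BOLTZMANN_EV * t_ref) - 1.0 / (BOLTZMANN_EV * comm.incubator_t))
            log_scale.append(np.log(comm.scale_to_litre))
            treatments.append(comm.mesocosm_treatment)
            log_masses.append(np.log(comm.masses))
            idx.append(np.full(comm.masses.size, j))
        self.y = np.array(y)
        self.x = np.array(x)
        self.log_scale = np.array(log_scale)
        self.n = len(communities)
        self.levels = sorted(set(treatments))
        level_index = {t: i for i, t in enumerate(self.levels)}
        self.group = np.array([level_index[t] for t in treatments])
        self.log_m = np.concatenate(log_masses)
        self.idx = np.concatenate(idx).astype(np.intp)

    def ln_S(self, alpha_by_group: np.ndarray) -> np.ndarray:
        """log( sum_i m_i**alpha * scale ) per community, exact at each alpha."""
        alpha_per_mass = alpha_by_group[self.group[self.idx]]
        terms = alpha_per_mass * self.log_m
        # stabilised per-community log-sum-exp via a per-community max shift
        shift = np.full(self.n, -np.inf)
        np.maximum.at(shift, self.idx, terms)
        sums = np.bincount(self.idx, weights=np.exp(terms - shift[self.idx]), minlength=self.n)
        return shift + np.log(sums) + self.log_scale

    def design(self, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
        cols, names = [], []
        if "ln_b_tc" in spec.split:
            for g, level in enumerate(self.levels):
                cols.append((self.group == g).astype(float))
                names.append(f"ln_b_tc[{level}]")
        else:
            cols.append(np.ones(self.n))
            names.append("ln_b_tc")
        if "E" in spec.split:
            for g, level in enumerate(self.levels):
                cols.append(self.x * (self.group == g))
                names.append(f"E[{level}]")
        else:
            cols.append(self.x)
            names.append("E")
        return np.column_stack(cols), names


def _check_identifiable(prep: _Prepared, spec: ModelSpec) -> None:
    if np.ptp(prep.x) < 1e-12:
        raise IdentifiabilityError(
            "E is not identifiable: all communities share a single assay temperature"
        )
    if spec.split and len(prep.levels) < 2:
        raise IdentifiabilityError(
            f"treatment split requested but only one treatment present: {prep.levels}"
        )
    if "E" in spec.split:
        for g, level in enumerate(prep.levels):
            if np.ptp(prep.x[prep.group == g]) < 1e-12:
                raise IdentifiabilityError(
                    f"E[{level}] is not identifiable: single assay temperature in group"
                )


def _rss_given_alpha(
    prep: _Prepared,
    spec: ModelSpec,
    alpha_by_group: np.ndarray,
    X: np.ndarray,
    fixed_col: Optional[int] = None,
    fixed_value: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Exact inner OLS; optionally one linear coefficient is held fixed."""
    r = prep.y - prep.ln_S(alpha_by_group)
    if fixed_col is not None:
        r = r - fixed_value * X[:, fixed_col]
        X = np.delete(X, fixed_col, axis=1)
    if X.shape[1] == 0:
        resid = r
        beta = np.empty(0)
    else:
        beta, _, rank, _ = np.linalg.lstsq(X, r, rcond=None)
        if rank < X.shape[1]:
            raise IdentifiabilityError(
                "design matrix is rank deficient (collinear temperature/treatment structure)"
            )
        resid = r - X @ beta
    return float(resid @ resid), beta


def _alpha_vector(spec: ModelSpec, prep: _Prepared, theta: np.ndarray) -> np.ndarray:
    if "alpha" in spec.split:
        return np.asarray(theta, dtype=float)
    return np.full(len(prep.levels) or 1, float(theta[0]))


def _optimise_alpha(
    prep: _Prepared,
    spec: ModelSpec,
    X: np.ndarray,
    n_starts: int,
    seed: Optional[int],
    alpha_bounds: tuple[float, float],
    fixed_col: Optional[int] = None,
    fixed_value: float = 0.0,
    fixed_alpha: Optional[dict] = None,
    x0_hint: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Multistart Nelder-Mead over the free alpha coordinates (RSS objective).

    ``x0_hint`` (e.g. the unconstrained MLE when profiling) is used as the
    first start; the remaining ``n_starts - 1`` starts are seeded uniform
    draws within ``alpha_bounds``.
    """
    n_alpha = len(prep.levels) if "alpha" in spec.split else 1
    free = [i for i in range(n_alpha) if not (fixed_alpha and i in fixed_alpha)]

    def full_alpha(theta_free):
        th = np.empty(n_alpha)
        for i, v in (fixed_alpha or {}).items():
            th[i] = v
        th[free] = theta_free
        return _alpha_vector(spec, prep, th) if "alpha" in spec.split else np.full(
            max(len(prep.levels), 1), th[0]
        )

    def objective(theta_free):
        try:
            rss, _ = _rss_given_alpha(
                prep, spec, full_alpha(theta_free), X, fixed_col, fixed_value
            )
        except IdentifiabilityError:
            raise
        return rss

    if not free:
        alpha = full_alpha(np.empty(0))
        rss, beta = _rss_given_alpha(prep, spec, alpha, X, fixed_col, fixed_value)
        return alpha, rss, beta, True

    rng = np.random.default_rng(seed)
    lo, hi = alpha_bounds
    starts = []
    if x0_hint is not None:
        starts.append(np.asarray(x0_hint, dtype=float)[: len(free)])
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(lo, hi, size=len(free)))
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise ConvergenceError("alpha optimisation failed from every start")
    alpha = full_alpha(best.x)
    rss, beta = _rss_given_alpha(prep, spec, alpha, X, fixed_col, fixed_value)
    return alpha, rss, beta, any_success


def _loglik_from_rss(rss: float, n: int) -> float:
    sigma2 = max(rss / n, _SIGMA_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_mst(
    communities: Sequence[Community],
    flux: str = "gpp",
    model_spec: Optional[ModelSpec] = None,
    n_starts: int = 50,
    seed: Optional[int] = 0,
    alpha_bounds: tuple[float, float] = (-1.0, 3.0),
    t_ref: float = T_REF,
    compute_ci: bool = True,
    ci_level: float = 0.95,
    _x0_hint: Optional[np.ndarray] = None,
) -> MSTFitResult:
    """Fit the metabolic-scaling model to observed community rates by ML.

    Requires at least two distinct assay temperatures (E identifiability) and
    mass variation between communities (alpha identifiability); deterministic
    under a fixed ``seed``.
    """
    spec = model_spec or ModelSpec.shared()
    prep = _Prepared(communities, flux, t_ref)
    _check_identifiable(prep, spec)
    X, names = prep.design(spec)
    min_params = X.shape[1] + (len(prep.levels) if "alpha" in spec.split else 1) + 1
    if prep.n < min_params:
        raise DataError(f"need at least {min_params} communities, got {prep.n}")

    alpha, rss, beta, converged = _optimise_alpha(
        prep, spec, X, n_starts, seed, alpha_bounds, x0_hint=_x0_hint
    )
    params = dict(zip(names, (float(b) for b in beta)))
    if "alpha" in spec.split:
        for g, level in enumerate(prep.levels):
            params[f"alpha[{level}]"] = float(alpha[g])
    else:
        params["alpha"] = float(alpha[0])
    n_params = len(params) + 1  # + sigma
    sigma = float(np.sqrt(max(rss / prep.n, 0.0)))
    loglik = _loglik_from_rss(rss, prep.n)
    fit = MSTFitResult(
        flux=flux,
        model_spec=spec,
        params=params,
        sigma=sigma,
        loglik=loglik,
        aic=2.0 * n_params - 2.0 * loglik,
        rss=rss,
        n_obs=prep.n,
        n_params=n_params,
        converged=converged,
        t_ref=t_ref,
        _prepared=prep,
    )
    if compute_ci:
        for name in params:
            fit.ci[name] = profile_ci(fit, name, level=ci_level, seed=seed)
    return fit


def _profile_rss(fit: MSTFitResult, parameter: str, value: float, seed) -> float:
    """Lowest RSS with ``parameter`` pinned at ``value``."""
    prep: _Prepared = fit._prepared
    spec = fit.model_spec
    X, names = prep.design(spec)
    if "alpha" in spec.split:
        alpha_hat = np.array([fit.params[f"alpha[{lv}]"] for lv in prep.levels])
    else:
        alpha_hat = np.array([fit.params["alpha"]])
    if parameter in names:
        col = names.index(parameter)
        _, rss, _, _ = _optimise_alpha(
            prep, spec, X, n_starts=2, seed=seed, alpha_bounds=(-1.0, 3.0),
            fixed_col=col, fixed_value=value, x0_hint=alpha_hat,
        )
        return rss
    if parameter == "alpha" and "alpha" not in spec.split:
        alpha = np.full(max(len(prep.levels), 1), value)
        rss, _ = _rss_given_alpha(prep, spec, alpha, X)
        return rss
    if parameter.startswith("alpha[") and "alpha" in spec.split:
        level = parameter[len("alpha["):-1]
        g = prep.levels.index(level)
        free_hat = np.array([alpha_hat[i] for i in range(len(alpha_hat)) if i != g])
        _, rss, _, _ = _optimise_alpha(
            prep, spec, X, n_starts=2, seed=seed, alpha_bounds=(-1.0, 3.0),
            fixed_alpha={g: value}, x0_hint=free_hat,
        )
        return rss
    raise DataError(f"unknown parameter {parameter!r}")


def profile_ci(
    fit: MSTFitResult,
    parameter: str,
    level: float = 0.95,
    seed: Optional[int] = 0,
    max_expand: int = 60,
) -> ProfileCI:
    """Profile-likelihood interval at the chi-square(1) deviance cutoff.

    Falls back to a quadratic (Wald-style) interval, flagged in ``method``,
    when the profile fails to cross the cutoff within the search range.
    """
    if fit._prepared is None:
        raise DataError("fit carries no data; refit with the same inputs first")
    if parameter not in fit.params:
        raise DataError(f"unknown parameter {parameter!r}; have {sorted(fit.params)}")
    crit = chi2.ppf(level, df=1)
    n = fit.n_obs
    rss_hat = max(fit.rss, _SIGMA_FLOOR)
    mle = fit.params[parameter]

    def deviance(value):
        rss = max(_profile_rss(fit, parameter, value, seed), _SIGMA_FLOOR)
        return n * (np.log(rss) - np.log(rss_hat))

    # curvature-based step scale from a small symmetric perturbation
    h = max(abs(mle) * 1e-3, 1e-4)
    d2 = deviance(mle + h) + deviance(mle - h)
    scale = h / np.sqrt(max(d2 / 2.0, 1e-12)) * np.sqrt(crit)
    scale = min(max(scale, 1e-6), 1e3)

    def bound(direction: int) -> tuple[float, str]:
        lo_v, lo_d = mle, 0.0
        step = scale * 0.5
        for _ in range(max_expand):
            cand = mle + direction * step
            d = deviance(cand)
            if d >= crit:
                a, b = (lo_v, cand) if direction > 0 else (cand, lo_v)
                root = brentq(lambda v: deviance(v) - crit, a, b, xtol=1e-8)
                return float(root), "profile"
            lo_v, lo_d = cand, d
            step *= 1.6
        # profile never crossed: quadratic fallback from the curvature estimate
        se = scale / np.sqrt(crit)
        return float(mle + direction * np.sqrt(crit) * se), "wald_fallback"

    upper, m_up = bound(+1)
    lower, m_lo = bound(-1)
    method = "profile" if (m_up == m_lo == "profile") else "wald_fallback"
    note = "" if method == "profile" else "profile did not cross the cutoff; quadratic approximation"
    return ProfileCI(lower=lower, upper=upper, level=level, method=method, note=note)


def compare_treatment_models(
    communities: Sequence[Community],
    flux: str = "gpp",
    n_starts: int = 50,
    seed: Optional[int] = 0,
    t_ref: float = T_REF,
) -> tuple[list[LRTResult], dict]:
    """Shared model vs each one-parameter treatment split, by LRT and AIC.

    Returns the per-parameter LRT rows and a dict of the underlying fits
    (keys: "shared" and the split parameter names). An unconverged sub-model
    produces a flagged row with the comparison withheld.
    """
    prep_check = {c.mesocosm_treatment for c in communities}
    if len(prep_check) < 2:
        raise DataError(f"both treatments required, found {sorted(prep_check)}")
    shared = fit_mst(
        communities, flux, ModelSpec.shared(), n_starts=n_starts, seed=seed,
        t_ref=t_ref, compute_ci=False,
    )
    fits = {"shared": shared}
    rows: list[LRTResult] = []
    for param in SPLITTABLE:
        try:
            split_fit = fit_mst(
                communities, flux, ModelSpec.splitting(param), n_starts=n_starts,
                seed=seed, t_ref=t_ref, compute_ci=False,
            )
        except (ConvergenceError, DataError) as exc:
            rows.append(
                LRTResult(param, None, 1, None, "unresolved", shared.aic, None,
                          converged=False, note=str(exc))
            )
            continue
        fits[param] = split_fit
        stat = 2.0 * (split_fit.loglik - shared.loglik)
        p = float(chi2.sf(stat, df=1))
        preferred = f"split:{param}" if p < 0.05 else "shared"
        rows.append(
            LRTResult(param, float(stat), 1, p, preferred, shared.aic, split_fit.aic,
                      converged=True)
        )
    return rows, fits
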