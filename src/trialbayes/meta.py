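"""Bayesian random-effects meta-analysis by deterministic grid integration.

Model (normal-normal hierarchical model, NNHM):

    y_i     ~ Normal(theta_i, sigma_i^2)        observed study effects
    theta_i ~ Normal(mu, tau^2)                 true study effects
    mu      ~ Normal(0, mu_prior_sd^2)          overall effect
    tau     ~ half-normal(sd) or Jeffreys       between-study heterogeneity

Conditional on tau the mu posterior is conjugate normal, so the only
numerical task is the one-dimensional tau marginal.  It is evaluated on a
dense linear grid expanded until the posterior mass is captured, plus a
geometric tail extension for heavy-tailed (improper) priors whose posterior
decays only polynomially.  Everything downstream — mu and predictive
summaries, shrinkage, Savage-Dickey Bayes factors — mixes the conjugate
conditionals over that grid, so results are bit-reproducible given the grid
specification (stored on the fitted object).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.integrate import cumulative_trapezoid, trapezoid

from .errors import InvalidInputError, NumericalError

_TAIL_FRACTION = 1e-6
_MAX_DOUBLINGS = 40


@dataclass(frozen=True)
class StudyInput:
    """One study: observed effect ``y`` with within-study SE ``sigma``."""

    label: str
    y: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise InvalidInputError(f"{self.label}: sigma must be > 0")


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Prior on the heterogeneity SD tau.

    ``half_normal``: density proportional to exp(-tau^2 / (2 sd^2)), tau >= 0.
    ``jeffreys``: the Fisher-information (scale-invariant-at-infinity) prior
    pi(tau) proportional to tau * sqrt(sum_i (sigma_i^2 + tau^2)^-2); improper,
    normalized numerically on the integration grid.
    """

    family: str
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("half_normal", "jeffreys"):
            raise InvalidInputError(f"unknown heterogeneity prior: {self.family!r}")
        if self.family == "half_normal" and not (self.sd is not None and self.sd > 0):
            raise InvalidInputError("half_normal prior needs sd > 0")

    def log_density(self, tau: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        if self.family == "half_normal":
            return stats.halfnorm.logpdf(tau, scale=self.sd)
        with np.errstate(divide="ignore"):
            inner = ((sigmas[None, :] ** 2 + tau[:, None] ** 2) ** -2).sum(axis=1)
            return np.log(tau) + 0.5 * np.log(inner)


def half_normal_prior(sd: float = 0.5) -> HeterogeneityPrior:
    return HeterogeneityPrior(family="half_normal", sd=sd)


def jeffreys_prior() -> HeterogeneityPrior:
    return HeterogeneityPrior(family="jeffreys")


@dataclass
class MetaPosterior:
    """Gridded joint posterior over (mu, tau) with conjugate conditionals.

    ``tau_grid`` carries the marginal tau posterior density; per node the
    conditional mu posterior is Normal(``cond_mean``, ``cond_var``).
    ``log_marglik`` is log p(y) under the (grid-normalized) priors.
    """

    studies: list[StudyInput]
    mu_prior_sd: float
    tau_prior: HeterogeneityPrior
    tau_grid: np.ndarray
    tau_density: np.ndarray
    cond_mean: np.ndarray
    cond_var: np.ndarray
    log_marglik: float
    log_marglik_mu0: float
    grid_spec: dict
    tau_cdf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.tau_cdf = cumulative_trapezoid(self.tau_density, self.tau_grid, initial=0.0)

    # -- mixture machinery ---------------------------------------------------

    def mu_mixture_cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = stats.norm.cdf(x[:, None], self.cond_mean[None, :], np.sqrt(self.cond_var)[None, :])
        return trapezoid(comp * self.tau_density[None, :], self.tau_grid, axis=1)

    def mu_mixture_pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = stats.norm.pdf(x[:, None], self.cond_mean[None, :], np.sqrt(self.cond_var)[None, :])
        return trapezoid(comp * self.tau_density[None, :], self.tau_grid, axis=1)


def _log_marginal_given_tau(
    y: np.ndarray, sigmas: np.ndarray, tau: np.ndarray, mu_prior_sd: float
):
    """log p(y | tau) with mu integrated out, plus the conjugate moments."""
    var = sigmas[None, :] ** 2 + tau[:, None] ** 2
    prior_prec = 1.0 / mu_prior_sd**2
    prec = (1.0 / var).sum(axis=1) + prior_prec
    mean = (y[None, :] / var).sum(axis=1) / prec
    log_m = (-0.5 * np.log(2.0 * np.pi * var) - 0.5 * y[None, :] ** 2 / var).sum(axis=1)
    log_m += 0.5 * np.log(prior_prec / prec) + 0.5 * mean**2 * prec
    return log_m, mean, 1.0 / prec


def _log_marginal_mu0(y: np.ndarray, sigmas: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """log p(y | tau, mu = 0)."""
    var = sigmas[None, :] ** 2 + tau[:, None] ** 2
    return (-0.5 * np.log(2.0 * np.pi * var) - 0.5 * y[None, :] ** 2 / var).sum(axis=1)


def _build_grid(upper: float, n_core: int) -> np.ndarray:
    return np.linspace(0.0, upper, n_core)


def fit_nnhm(
    studies: Sequence[StudyInput],
    mu_prior_sd: float = 1.0,
    tau_prior: Optional[HeterogeneityPrior] = None,
    n_grid: int = 3200,
) -> MetaPosterior:
    """Fit the NNHM by grid integration over tau.

    The linear core grid (``n_grid`` nodes, >= 1600) starts at a data/prior
    scale and doubles its upper bound until the top half of the range holds
    less than 1e-6 of the posterior mass; heavy-tailed priors then get a
    geometric tail extension under the same criterion.  Failure to capture
    the mass raises :class:`NumericalError`.
    """
    studies = list(studies)
    if not studies:
        raise InvalidInputError("need at least one study")
    if not (mu_prior_sd > 0):
        raise InvalidInputError("mu_prior_sd must be > 0")
    if n_grid < 1600:
        raise InvalidInputError("n_grid must be >= 1600")
    if tau_prior is None:
        tau_prior = half_normal_prior()

    y = np.array([s.y for s in studies], dtype=float)
    sigmas = np.array([s.sigma for s in studies], dtype=float)

    # precision-weighted data/sigma scales: an arbitrarily noisy study must
    # not inflate the grid (it carries no information about tau)
    weights = 1.0 / sigmas**2
    sigma_scale = float(np.sqrt(len(studies) / weights.sum()))
    if len(studies) > 1:
        y_bar = float((weights * y).sum() / weights.sum())
        data_scale = float(np.sqrt((weights * (y - y_bar) ** 2).sum() / weights.sum()))
    else:
        data_scale = 0.0
    prior_scale = tau_prior.sd if tau_prior.family == "half_normal" else sigma_scale
    upper = max(4.0 * (data_scale + sigma_scale), 6.0 * prior_scale, 1e-6)

    def unnorm_log_post(tau: np.ndarray) -> np.ndarray:
        log_m, _, _ = _log_marginal_given_tau(y, sigmas, tau, mu_prior_sd)
        lp = tau_prior.log_density(tau, sigmas) + log_m
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    # expand the linear core until its top half is negligible
    for _ in range(_MAX_DOUBLINGS):
        grid = _build_grid(upper, n_grid)
        lp = unnorm_log_post(grid)
        w = np.exp(lp - lp.max())
        total = trapezoid(w, grid)
        top = trapezoid(np.where(grid >= upper / 2.0, w, 0.0), grid)
        if top / total < 1e-3:
            break
        upper *= 2.0
    else:
        raise NumericalError("tau grid failed to capture posterior mass", {"upper": upper})

    # geometric tail extension until the relative tail contribution is < 1e-6
    tail_start = grid[-1]
    tail_grids = []
    tail_upper = tail_start
    for _ in range(_MAX_DOUBLINGS):
        if top / total < _TAIL_FRACTION:
            break
        seg = np.geomspace(tail_upper, tail_upper * 4.0, 200)[1:]
        seg_lp = unnorm_log_post(seg)
        seg_w = np.exp(seg_lp - lp.max())
        seg_mass = trapezoid(seg_w, seg)
        tail_grids.append(seg)
        tail_upper *= 4.0
        total += seg_mass
        top = seg_mass
    else:
        raise NumericalError(
            "tau posterior tail not captured", {"tail_upper": tail_upper, "frac": top / total}
        )
    if tail_grids:
        grid = np.concatenate([grid] + tail_grids)
        lp = unnorm_log_post(grid)

    shift = lp.max()
    w = np.exp(lp - shift)
    norm = trapezoid(w, grid)
    density = w / norm

    log_m, cond_mean, cond_var = _log_marginal_given_tau(y, sigmas, grid, mu_prior_sd)
    log_prior = tau_prior.log_density(grid, sigmas)
    log_prior[~np.isfinite(log_prior)] = -np.inf

    # normalize the tau prior on the grid (exact for proper priors up to
    # truncation; defines the reference measure for improper ones)
    wp = np.exp(log_prior - np.max(log_prior[np.isfinite(log_prior)]))
    log_prior_norm = math.log(trapezoid(wp, grid)) + float(
        np.max(log_prior[np.isfinite(log_prior)])
    )

    log_marglik = math.log(norm) + shift - log_prior_norm
    # p(y | mu = 0) under the same (grid-normalized) tau prior
    lp0 = log_prior + _log_marginal_mu0(y, sigmas, grid)
    lp0[~np.isfinite(lp0)] = -np.inf
    shift0 = lp0.max()
    log_marglik_mu0 = math.log(trapezoid(np.exp(lp0 - shift0), grid)) + shift0 - log_prior_norm

    return MetaPosterior(
        studies=studies,
        mu_prior_sd=mu_prior_sd,
        tau_prior=tau_prior,
        tau_grid=grid,
        tau_density=density,
        cond_mean=cond_mean,
        cond_var=cond_var,
        log_marglik=log_marglik,
        log_marglik_mu0=log_marglik_mu0,
        grid_spec={
            "n_core": n_grid,
            "core_upper": float(tail_start),
            "total_nodes": int(grid.size),
            "upper": float(grid[-1]),
        },
    )


# ---------------------------------------------------------------------------
# posterior summaries


def _mixture_quantile(p: MetaPosterior, q: float) -> float:
    lo = float(np.min(p.cond_mean) - 12.0 * math.sqrt(np.max(p.cond_var)))
    hi = float(np.max(p.cond_mean) + 12.0 * math.sqrt(np.max(p.cond_var)))
    return float(optimize.brentq(lambda x: p.mu_mixture_cdf(x)[0] - q, lo, hi, xtol=1e-10))


def _tau_quantile(p: MetaPosterior, q: float) -> float:
    return float(np.interp(q, p.tau_cdf, p.tau_grid))


def _tau_shortest_interval(p: MetaPosterior, level: float) -> tuple[float, float]:
    """Shortest interval with the given tau posterior mass (lower may be 0)."""
    cdf, grid = p.tau_cdf, p.tau_grid
    top = cdf[-1]
    # candidate lower bounds: fine grid over the feasible range
    max_lower = float(np.interp(top - level, cdf, grid))
    lowers = np.linspace(0.0, max_lower, 4000)
    cdf_low = np.interp(lowers, grid, cdf)
    uppers = np.interp(cdf_low + level, cdf, grid)
    widths = uppers - lowers
    i = int(np.argmin(widths))
    return float(lowers[i]), float(uppers[i])


def posterior_summary(
    p: MetaPosterior,
    param: str,
    kind: str = "median",
    cri_level: float = 0.95,
    cri_style: Optional[str] = None,
) -> dict:
    """Point estimate and credible interval for mu or tau.

    mu intervals are equal-tailed by default; tau intervals are
    shortest-coverage (the lower bound may touch 0).  ``cri_style`` overrides
    with "equal_tailed" or "shortest".
    """
    if not (0.0 < cri_level < 1.0):
        raise InvalidInputError(f"cri_level must be in (0, 1), got {cri_level}")
    if kind not in ("median", "mean"):
        raise InvalidInputError(f"unknown summary kind: {kind!r}")
    alpha = 1.0 - cri_level
    if param == "mu":
        style = cri_style or "equal_tailed"
        if kind == "median":
            est = _mixture_quantile(p, 0.5)
        else:
            est = float(trapezoid(p.tau_density * p.cond_mean, p.tau_grid))
        if style == "equal_tailed":
            lo = _mixture_quantile(p, alpha / 2.0)
            hi = _mixture_quantile(p, 1.0 - alpha / 2.0)
        elif style == "shortest":
            # mu posterior is unimodal and near-symmetric here; search over
            # the lower tail probability
            def width(a):
                return _mixture_quantile(p, a + cri_level) - _mixture_quantile(p, a)

            res = optimize.minimize_scalar(width, bounds=(1e-6, alpha - 1e-6), method="bounded")
            lo = _mixture_quantile(p, float(res.x))
            hi = lo + float(res.fun)
        else:
            raise InvalidInputError(f"unknown cri_style: {cri_style!r}")
    elif param == "tau":
        style = cri_style or "shortest"
        if kind == "median":
            est = _tau_quantile(p, 0.5)
        else:
            est = float(trapezoid(p.tau_density * p.tau_grid, p.tau_grid))
        if style == "shortest":
            lo, hi = _tau_shortest_interval(p, cri_level)
        elif style == "equal_tailed":
            lo = _tau_quantile(p, alpha / 2.0)
            hi = _tau_quantile(p, 1.0 - alpha / 2.0)
        else:
            raise InvalidInputError(f"unknown cri_style: {cri_style!r}")
    else:
        raise InvalidInputError(f"unknown parameter: {param!r}")
    return {"estimate": est, "cri_lower": lo, "cri_upper": hi, "level": cri_level, "kind": kind}


def shrinkage(p: MetaPosterior, index: int, cri_level: float = 0.95) -> dict:
    """Posterior of one study's true effect theta_i (the shrinkage estimate).

    Conditional on tau, theta_i mixes the direct estimate and the pooled
    mean with weight k = tau^2/(sigma_i^2 + tau^2):

        theta_i | tau, y ~ Normal(k y_i + (1-k) m(tau), k sigma_i^2 + (1-k)^2 v(tau))

    and the marginal mixes these over the tau posterior.
    """
    if not (0 <= index < len(p.studies)):
        raise InvalidInputError(f"study index {index} out of range")
    s = p.studies[index]
    k = p.tau_grid**2 / (s.sigma**2 + p.tau_grid**2)
    means = k * s.y + (1.0 - k) * p.cond_mean
    variances = k * s.sigma**2 + (1.0 - k) ** 2 * p.cond_var
    return _mixture_summary(p, means, variances, cri_level) | {"label": s.label}


def predictive(p: MetaPosterior, cri_level: float = 0.95) -> dict:
    """Posterior predictive for the effect in a new, exchangeable study.

    theta_new | tau, y ~ Normal(m(tau), v(tau) + tau^2), mixed over tau; the
    interval is at least as wide as the mu interval since it adds tau^2.
    """
    means = p.cond_mean
    variances = p.cond_var + p.tau_grid**2
    return _mixture_summary(p, means, variances, cri_level)


def _mixture_summary(p: MetaPosterior, means, variances, cri_level: float) -> dict:
    sds = np.sqrt(variances)

    def cdf(x):
        comp = stats.norm.cdf(x, means, sds)
        return float(trapezoid(comp * p.tau_density, p.tau_grid))

    lo0 = float(np.min(means) - 12.0 * np.max(sds))
    hi0 = float(np.max(means) + 12.0 * np.max(sds))
    alpha = 1.0 - cri_level

    def q(prob):
        return float(optimize.brentq(lambda x: cdf(x) - prob, lo0, hi0, xtol=1e-10))

    return {
        "estimate": q(0.5),
        "cri_lower": q(alpha / 2.0),
        "cri_upper": q(1.0 - alpha / 2.0),
        "level": cri_level,
        "kind": "median",
    }


# ---------------------------------------------------------------------------
# Bayes factors


def bf10_meta(p: MetaPosterior, null: str = "no_effect", method: str = "default") -> dict:
    """Bayes factor for a treatment effect in the fitted meta-analysis.

    null = "no_effect" (default): marginal-likelihood ratio of the
    random-effects model against the global point null mu = 0, tau = 0 — the
    hypothesis that treatment does nothing in any study.

    null = "mu_zero": the nested null mu = 0 with tau free (same prior).
    method "savage_dickey" (default for this null) evaluates the
    posterior/prior density ratio of mu at 0; method "marginal_likelihood"
    computes the same BF from the two marginal likelihoods — the agreement
    of the two routes is a consistency check on the integration.
    """
    prior_density_at_0 = stats.norm.pdf(0.0, 0.0, p.mu_prior_sd)
    if null == "no_effect":
        y = np.array([s.y for s in p.studies])
        sigmas = np.array([s.sigma for s in p.studies])
        log_m_null = float(np.sum(stats.norm.logpdf(y, 0.0, sigmas)))
        log_bf10 = p.log_marglik - log_m_null
    elif null == "mu_zero":
        if method in ("default", "savage_dickey"):
            post0 = float(p.mu_mixture_pdf(0.0)[0])
            log_bf10 = math.log(prior_density_at_0) - math.log(post0)
        elif method == "marginal_likelihood":
            log_bf10 = p.log_marglik - p.log_marglik_mu0
        else:
            raise InvalidInputError(f"unknown method: {method!r}")
    else:
        raise InvalidInputError(f"unknown null: {null!r}")
    bf10 = math.exp(log_bf10)
    return {"bf10": bf10, "bf01": 1.0 / bf10, "log_bf10": log_bf10, "null": null}


# ---------------------------------------------------------------------------
# forest-plot data


def forest_data(p: MetaPosterior, cri_level: float = 0.95) -> "pd.DataFrame":
    """Direct and shrinkage estimates per study plus overall and prediction
    rows — the plot-ready content of a forest plot."""
    import pandas as pd

    z = stats.norm.ppf(0.5 + cri_level / 2.0)
    rows = []
    for i, s in enumerate(p.studies):
        sh = shrinkage(p, i, cri_level)
        rows.append(
            {
                "label": s.label,
                "direct": s.y,
                "direct_lower": s.y - z * s.sigma,
                "direct_upper": s.y + z * s.sigma,
                "shrinkage": sh["estimate"],
                "shrinkage_lower": sh["cri_lower"],
                "shrinkage_upper": sh["cri_upper"],
            }
        )
    mu = posterior_summary(p, "mu", cri_level=cri_level)
    rows.append(
        {
            "label": "overall effect",
            "shrinkage": mu["estimate"],
            "shrinkage_lower": mu["cri_lower"],
            "shrinkage_upper": mu["cri_upper"],
        }
    )
    pred = predictive(p, cri_level)
    rows.append(
        {
            "label": "prediction",
            "shrinkage": pred["estimate"],
            "shrinkage_lower": pred["cri_lower"],
            "shrinkage_upper": pred["cri_upper"],
        }
    )
    return pd.DataFrame(rows)
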