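"""Bayesian local-level state-space model fit by forward-filter
backward-sample (FFBS) Gibbs sampling.

The model, on the transformed scale ``z_t = log(1 + y_t)``:

    z_t      = mu_t + eps_t,      eps_t ~ N(0, sigma2_eps)   (observation)
    mu_{t+1} = mu_t + eta_t,      eta_t ~ N(0, sigma2_eta)   (random-walk level)

with conjugate inverse-gamma priors on both variances.  The Gibbs sampler
alternates (a) an exact joint draw of the level path ``mu_{1..T}`` given the
variances (Kalman forward filter, then backward sampling) and (b) conjugate
inverse-gamma draws of the two variances given the path.  Missing years are
handled by skipping the measurement update, so the time index always
advances.  A known-variance mode skips step (b); in that mode the retained
level draws are i.i.d. from the exact smoothing posterior, which is what the
Kalman-smoother equivalence tests rely on.

The log1p transform keeps the Gaussian observation model away from negative
counts: a Gaussian on raw counts puts mass below zero and makes
"probability of a zero-moth median" ill-defined.  An identity transform is
available for sensitivity checks.

One-step-ahead prediction propagates each retained level draw forward with a
fresh level innovation, adds observation noise, and inverts the transform
(``y* = max(exp(z*) - 1, 0)``).  The probability that the next year's median
rounds to zero is the fraction of predictive draws below 0.5 moths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "McmcConfig",
    "LocalLevelPosterior",
    "InsufficientDataError",
    "fit_local_level",
    "forecast_one_step",
    "prob_zero",
]


class InsufficientDataError(ValueError):
    """Raised when a series has too few observations to calibrate the model."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings and prior hyperparameters.

    Priors are weakly informative and scale-adaptive: inverse-gamma with
    shape 1 and scale proportional to the variance of the *differenced*
    transformed series (factor 0.5 for the observation variance, 0.05 for
    the level-innovation variance, floored to keep them proper on
    degenerate series).  The differenced variance (= 2 s2_eps + s2_eta) is
    used because the marginal variance is inflated by level wander and
    would bias both variance posteriors upward.
    """

    iterations: int = 2000
    burn_in: int = 500
    prior_shape: float = 1.0
    prior_scale_eps: float = 0.5  # times Var(diff z)
    prior_scale_eta: float = 0.05  # times Var(diff z)
    scale_floor: float = 0.01
    transform: str = "log1p"  # or "identity"
    zero_threshold: float = 0.5  # count below which a median "rounds to zero"
    prob_definition: str = "predictive"  # or "latent"
    min_obs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be < iterations")
        if self.zero_threshold <= 0:
            raise ValueError("zero threshold must be > 0")
        if self.transform not in ("log1p", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.prob_definition not in ("predictive", "latent"):
            raise ValueError(f"unknown prob definition {self.prob_definition!r}")


@dataclass
class LocalLevelPosterior:
    """Retained MCMC draws from one local-level fit.

    ``level`` has shape (n_draws, T); the variance arrays and the two
    forecast arrays have length n_draws.  ``level_forecast`` is the level
    propagated one step (transformed scale); ``z_forecast`` adds
    observation noise on top.
    """

    level: np.ndarray
    sigma2_eps: np.ndarray
    sigma2_eta: np.ndarray
    level_forecast: np.ndarray
    z_forecast: np.ndarray
    transform: str
    known_variance: bool


@njit(cache=True)
def _gibbs_core(
    z,
    obs,
    m0,
    C0,
    iters,
    burn,
    b_eps,
    b_eta,
    g_eps,
    g_eta,
    normals,
    fore_normals,
    sig_eps0,
    sig_eta0,
    known_variance,
):
    T = z.shape[0]
    keep = iters - burn
    mu_draws = np.empty((keep, T))
    se_draws = np.empty(keep)
    sn_draws = np.empty(keep)
    lf_draws = np.empty(keep)
    zf_draws = np.empty(keep)
    sig_eps = sig_eps0
    sig_eta = sig_eta0
    m = np.empty(T)
    C = np.empty(T)
    mu = np.empty(T)
    for it in range(iters):
        # forward Kalman filter (skip measurement update on missing years)
        a = m0
        R = C0
        for t in range(T):
            if t > 0:
                a = m[t - 1]
                R = C[t - 1] + sig_eta
            if obs[t]:
                K = R / (R + sig_eps)
                m[t] = a + K * (z[t] - a)
                C[t] = (1.0 - K) * R
            else:
                m[t] = a
                C[t] = R
        # backward sampling of the joint level path
        mu[T - 1] = m[T - 1] + math.sqrt(C[T - 1]) * normals[it, T - 1]
        for t in range(T - 2, -1, -1):
            denom = C[t] + sig_eta
            if denom <= 0.0:
                mu[t] = m[t]
            else:
                B = C[t] / denom
                h = m[t] + B * (mu[t + 1] - m[t])
                H = C[t] * (1.0 - B)
                mu[t] = h + math.sqrt(H) * normals[it, t]
        if not known_variance:
            ss_e = 0.0
            for t in range(T):
                if obs[t]:
                    d = z[t] - mu[t]
                    ss_e += d * d
            ss_n = 0.0
            for t in range(1, T):
                d = mu[t] - mu[t - 1]
                ss_n += d * d
            sig_eps = (b_eps + 0.5 * ss_e) / g_eps[it]
            sig_eta = (b_eta + 0.5 * ss_n) / g_eta[it]
        if it >= burn:
            j = it - burn
            for t in range(T):
                mu_draws[j, t] = mu[t]
            se_draws[j] = sig_eps
            sn_draws[j] = sig_eta
            lf = mu[T - 1] + math.sqrt(sig_eta) * fore_normals[it, 0]
            lf_draws[j] = lf
            zf_draws[j] = lf + math.sqrt(sig_eps) * fore_normals[it, 1]
    return mu_draws, se_draws, sn_draws, lf_draws, zf_draws


def _transform(y: np.ndarray, name: str) -> np.ndarray:
    return np.log1p(y) if name == "log1p" else np.asarray(y, float)


def fit_local_level(
    y: np.ndarray,
    cfg: McmcConfig,
    known_variances: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> LocalLevelPosterior:
    """Fit the local-level model to one observed series.

    Parameters
    ----------
    y : yearly counts (medians) with NaN marking years without traps.
    cfg : sampler configuration (iterations, burn-in, priors, transform,
        seed).
    known_variances : optional ``(sigma2_eps, sigma2_eta)`` to hold the
        variances fixed (no inverse-gamma steps); used by the
        Kalman-equivalence checks.
    rng : optional generator overriding ``cfg.seed`` (the per-quadrat
        scheduler passes streams split from one pipeline seed).
    """
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    if np.any(~np.isfinite(y[obs])):
        raise ValueError("non-finite observations in input series")
    if cfg.transform == "log1p" and np.any(y[obs] < 0):
        raise ValueError("negative counts in input series")
    n_obs = int(obs.sum())
    if n_obs < cfg.min_obs:
        raise InsufficientDataError(
            f"insufficient calibration data: {n_obs} observations "
            f"(need >= {cfg.min_obs})"
        )
    z = np.where(obs, _transform(np.where(obs, y, 0.0), cfg.transform), 0.0)
    z_obs = z[obs]
    var_z = float(np.var(z_obs))
    # prior scales key off the differenced series: Var(diff) = 2*s2_eps +
    # s2_eta regardless of how far the level wanders, whereas the marginal
    # Var(z) is inflated by level variation and would bias the variance
    # posteriors upward
    var_d = float(np.var(np.diff(z_obs))) if len(z_obs) > 2 else var_z
    T = len(y)
    m0 = float(z_obs.mean())
    C0 = max(4.0 * var_z, 1.0)

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    iters = cfg.iterations
    normals = rng.standard_normal((iters, T))
    fore_normals = rng.standard_normal((iters, 2))

    if known_variances is not None:
        s_eps, s_eta = map(float, known_variances)
        if s_eps <= 0:
            raise ValueError("observation variance must be > 0")
        if s_eta < 0:
            raise ValueError("level-innovation variance must be >= 0")
        g_eps = g_eta = np.ones(1)
        b_eps = b_eta = 0.0
        known = True
    else:
        b_eps = max(cfg.prior_scale_eps * var_d, cfg.scale_floor)
        b_eta = max(cfg.prior_scale_eta * var_d, cfg.scale_floor)
        shape_eps = cfg.prior_shape + 0.5 * n_obs
        shape_eta = cfg.prior_shape + 0.5 * (T - 1)
        g_eps = rng.gamma(shape_eps, 1.0, iters)
        g_eta = rng.gamma(shape_eta, 1.0, iters)
        s_eps = max(0.5 * var_d, 2 * cfg.scale_floor)
        s_eta = max(0.1 * var_d, cfg.scale_floor)
        known = False

    mu, se, sn, lf, zf = _gibbs_core(
        z,
        obs,
        m0,
        C0,
        iters,
        cfg.burn_in,
        b_eps,
        b_eta,
        g_eps,
        g_eta,
        normals,
        fore_normals,
        s_eps,
        s_eta,
        known,
    )
    return LocalLevelPosterior(
        level=mu,
        sigma2_eps=se,
        sigma2_eta=sn,
        level_forecast=lf,
        z_forecast=zf,
        transform=cfg.transform,
        known_variance=known,
    )


def forecast_one_step(posterior: LocalLevelPosterior) -> np.ndarray:
    """One-step-ahead predictive draws on the count scale.

    Each retained draw propagates its level with a fresh innovation, adds
    observation noise, and inverts the transform (floored at zero).
    """
    z = posterior.z_forecast
    if posterior.transform == "log1p":
        return np.maximum(np.expm1(z), 0.0)
    return np.maximum(z, 0.0)


def prob_zero(draws: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of predictive draws below ``threshold`` moths.

    With the default threshold 0.5 this is the posterior predictive
    probability that next year's median catch rounds to zero.
    """
    draws = np.asarray(draws, float)
    if draws.size == 0:
        raise ValueError("empty predictive draw set")
    return float(np.mean(draws < threshold))


def prob_zero_latent(
    posterior: LocalLevelPosterior, threshold: float = 0.5
) -> float:
    """Alternative latent-level criterion: P(next-year level below the
    transformed zero threshold), ignoring observation noise."""
    lf = posterior.level_forecast
    if posterior.transform == "log1p":
        cut = math.log1p(threshold * 2)  # latent density for a median of one
    else:
        cut = threshold * 2
    return float(np.mean(lf < cut))
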