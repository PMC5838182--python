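"""Bayesian misclassification model for one sender-receiver province pair.

Generative model, per covariate pattern (stratum) r:

    T_r ~ Poisson(lambda_S_r * n_S_r)        true sender cases
    z_r | T_r ~ Binomial(T_r, theta)          cases registered at the receiver
    y_S_r = T_r - z_r                         observed sender count
    W_r ~ Poisson(lambda_R_r * n_R_r)         true receiver cases
    y_R_r = W_r + z_r                         observed receiver count

theta is the probability that a true sender case is registered in the
receiver's registry; it is shared across the 8 strata, matching the single
percentage reported per pair. Binomial thinning of a Poisson count gives
Poisson marginals for both observed vectors:

    y_S_r ~ Poisson((1 - theta) lambda_S_r n_S_r)
    y_R_r ~ Poisson(lambda_R_r n_R_r + theta lambda_S_r n_S_r)

With a Beta(a, b) prior on theta and Gamma(shape, rate) priors on the
rates, every full conditional is a named standard distribution, so the
posterior is sampled by plain Gibbs:

    z_r | ...      ~ Binomial(y_R_r, theta l_S / (l_R + theta l_S)),
                     l_S = lambda_S_r n_S_r, l_R = lambda_R_r n_R_r
    theta | ...    ~ Beta(a + sum z_r, b + sum y_S_r)
    lambda_S_r|... ~ Gamma(shape + y_S_r + z_r, rate + n_S_r)
    lambda_R_r|... ~ Gamma(shape + y_R_r - z_r, rate + n_R_r)

Under ``shared_rates`` the two provinces share one incidence rate per
stratum (the premise that neighbouring provinces have about the same true
incidence); then lambda_r | ... ~ Gamma(shape + y_S_r + y_R_r,
rate + n_S_r + n_R_r) — z cancels from the conditional because the latent
split moves cases between two registries with a common rate. The shared
variant is the identifiable one: with separate rates the likelihood only
constrains ridges of ((1-theta) lambda_S, lambda_R + theta lambda_S n_S/n_R)
and the theta posterior is prior-dominated.

A brute-force oracle (`oracle_posterior`) integrates the rates analytically
and sums over all latent vectors on a theta grid; it validates the sampler
on small fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from sklearn.base import BaseEstimator

from .priors import BetaPrior, GammaPrior, default_rate_prior
from .strata import STRATA

__all__ = [
    "PairData",
    "ModelConfig",
    "Chain",
    "PosteriorSummary",
    "z_conditional",
    "theta_conditional",
    "lambda_conditionals",
    "gibbs_run",
    "oracle_posterior",
    "summarize",
    "crude_rate_prior",
    "PairMisclassificationModel",
]


@dataclass
class PairData:
    """Observed counts and exposures for a sender-receiver pair.

    Vectors are indexed by the same strata in both provinces; the standard
    registry layout has the 8 sex x age-band cells, but any length works
    (toy fixtures use fewer).
    """

    y_S: np.ndarray
    y_R: np.ndarray
    n_S: np.ndarray
    n_R: np.ndarray
    strata: tuple = ()
    pair_id: str = ""

    def __post_init__(self) -> None:
        self.y_S = np.asarray(self.y_S, dtype=float)
        self.y_R = np.asarray(self.y_R, dtype=float)
        self.n_S = np.asarray(self.n_S, dtype=float)
        self.n_R = np.asarray(self.n_R, dtype=float)
        r = self.y_S.shape[0]
        for name in ("y_R", "n_S", "n_R"):
            if getattr(self, name).shape != (r,):
                raise ValueError("pair vectors must share one stratum axis")
        if np.any(self.y_S < 0) or np.any(self.y_R < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.y_S != np.floor(self.y_S)) or np.any(self.y_R != np.floor(self.y_R)):
            raise ValueError("counts must be integral")
        if np.any(self.n_S <= 0) or np.any(self.n_R <= 0):
            raise ValueError("exposures must be positive")
        if not self.strata:
            self.strata = tuple(STRATA) if r == len(STRATA) else tuple(range(r))

    @property
    def n_strata(self) -> int:
        return self.y_S.shape[0]


@dataclass(frozen=True)
class ModelConfig:
    """Gibbs sampler settings."""

    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    shared_rates: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.thin <= 0:
            raise ValueError("iterations and thin must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.iterations - self.burn_in < 1000:
            warnings.warn(
                "fewer than 1000 post-burn-in iterations; reported summaries "
                "will be noisy",
                stacklevel=2,
            )


@dataclass
class Chain:
    """Post-burn-in, thinned Gibbs draws."""

    theta: np.ndarray            # (n_draws,)
    z: np.ndarray                # (n_draws, r)
    lambda_S: np.ndarray         # (n_draws, r)
    lambda_R: np.ndarray         # (n_draws, r)
    pair: PairData | None = None
    config: ModelConfig | None = None

    def __len__(self) -> int:
        return self.theta.shape[0]

    def to_frame(self):
        import pandas as pd

        r = self.z.shape[1]
        data = {"theta": self.theta}
        for j in range(r):
            data[f"z_{j + 1}"] = self.z[:, j]
        for j in range(r):
            data[f"lambda_S_{j + 1}"] = self.lambda_S[:, j]
        for j in range(r):
            data[f"lambda_R_{j + 1}"] = self.lambda_R[:, j]
        frame = pd.DataFrame(data)
        frame.insert(0, "iteration", np.arange(len(self)))
        return frame


@dataclass
class PosteriorSummary:
    theta_mean: float
    theta_ci: tuple[float, float]
    theta_sd: float
    ess_theta: float
    mcse_theta: float
    z_mean: np.ndarray
    lambda_S_mean: np.ndarray
    lambda_R_mean: np.ndarray
    n_draws: int

    def as_dict(self) -> dict:
        return {
            "theta_mean": self.theta_mean,
            "theta_ci_low": self.theta_ci[0],
            "theta_ci_high": self.theta_ci[1],
            "theta_sd": self.theta_sd,
            "ess_theta": self.ess_theta,
            "mcse_theta": self.mcse_theta,
            "z_mean": list(map(float, self.z_mean)),
            "lambda_S_mean": list(map(float, self.lambda_S_mean)),
            "lambda_R_mean": list(map(float, self.lambda_R_mean)),
            "n_draws": self.n_draws,
        }


# ---------------------------------------------------------------------------
# full conditionals (each a named standard distribution)


def z_conditional(
    y_R_r: float, theta: float, lamS_nS: float, lamR_nR: float
) -> tuple[int, float]:
    """Binomial(trials, p) conditional for the latent misregistered count.

    trials = y_R_r; p = theta*l_S / (l_R + theta*l_S) with l_S, l_R the
    expected sender/receiver caseloads. p = 0 when the numerator vanishes.
    """
    if theta < 0 or theta > 1:
        raise ValueError("theta must lie in [0, 1]")
    if lamS_nS < 0 or lamR_nR < 0 or y_R_r < 0:
        raise ValueError("inputs must be non-negative")
    num = theta * lamS_nS
    den = lamR_nR + num
    if den == 0.0:
        if y_R_r > 0:
            raise ZeroDivisionError(
                "degenerate model: observed receiver cases but zero expected "
                "caseload from either source"
            )
        return int(y_R_r), 0.0
    return int(y_R_r), (num / den if num > 0 else 0.0)


def theta_conditional(z_total: float, yS_total: float, prior: BetaPrior) -> BetaPrior:
    """Beta(a + sum z, b + sum y_S) conditional for theta.

    The Binomial split of each true sender count into misregistered (z) vs
    correctly registered (y_S) cases makes this the standard conjugate
    update.
    """
    if z_total < 0 or yS_total < 0:
        raise ValueError("totals must be non-negative")
    return BetaPrior(prior.a + z_total, prior.b + yS_total)


def lambda_conditionals(
    y_S_r: float,
    z_r: float,
    y_R_r: float,
    n_S_r: float,
    n_R_r: float,
    prior: GammaPrior,
) -> tuple[GammaPrior, GammaPrior]:
    """Gamma conditionals for the sender and receiver incidence rates.

    Sender truth is y_S + z cases over n_S person-years; receiver truth is
    y_R - z over n_R.
    """
    if not 0 <= z_r <= y_R_r:
        raise ValueError(f"latent count z={z_r} outside [0, y_R={y_R_r}]")
    sender = GammaPrior(prior.shape + y_S_r + z_r, prior.rate + n_S_r)
    receiver = GammaPrior(prior.shape + y_R_r - z_r, prior.rate + n_R_r)
    return sender, receiver


# ---------------------------------------------------------------------------
# Gibbs sampler


def crude_rate_prior(pair: PairData, shape: float = 1.0) -> GammaPrior:
    """Default weakly-informative rate prior anchored at the crude pooled rate."""
    total = float(pair.y_S.sum() + pair.y_R.sum())
    exposure = float(pair.n_S.sum() + pair.n_R.sum())
    return default_rate_prior(max(total, 0.5), exposure, shape=shape)


def gibbs_run(
    pair: PairData,
    theta_prior: BetaPrior,
    rate_prior: GammaPrior | None = None,
    config: ModelConfig | None = None,
) -> Chain:
    """Run the Gibbs sampler; deterministic for a fixed seed and inputs.

    Cycles z -> theta -> rates using the conjugate conditionals. z starts
    at 0; rates start at the crude per-stratum rates max(count, 0.5) /
    exposure (the 0.5 floor avoids a zero-rate absorbing start); theta
    starts at its prior mean.
    """
    config = config or ModelConfig()
    rate_prior = rate_prior or crude_rate_prior(pair)
    rng = np.random.default_rng(config.seed)
    r = pair.n_strata
    y_S, y_R = pair.y_S, pair.y_R
    n_S, n_R = pair.n_S, pair.n_R
    yR_int = y_R.astype(np.int64)
    yS_total = float(y_S.sum())
    a0, b0 = theta_prior.a, theta_prior.b
    shape0, rate0 = rate_prior.shape, rate_prior.rate

    z = np.zeros(r)
    lam_S = np.maximum(y_S, 0.5) / n_S
    lam_R = np.maximum(y_R, 0.5) / n_R
    theta = theta_prior.mean

    n_kept = (config.iterations - config.burn_in + config.thin - 1) // config.thin
    theta_out = np.empty(n_kept)
    z_out = np.empty((n_kept, r))
    lam_S_out = np.empty((n_kept, r))
    lam_R_out = np.empty((n_kept, r))

    k = 0
    for it in range(config.iterations):
        # z | theta, rates
        num = theta * lam_S * n_S
        den = lam_R * n_R + num
        p = np.where(num > 0, num / np.where(den > 0, den, 1.0), 0.0)
        z = rng.binomial(yR_int, p).astype(float)
        # theta | z
        theta = rng.beta(a0 + z.sum(), b0 + yS_total)
        # rates | z (shared: one rate per stratum, z cancels)
        if config.shared_rates:
            lam = rng.gamma(shape0 + y_S + y_R, 1.0 / (rate0 + n_S + n_R))
            lam_S = lam_R = lam
        else:
            lam_S = rng.gamma(shape0 + y_S + z, 1.0 / (rate0 + n_S))
            lam_R = rng.gamma(shape0 + y_R - z, 1.0 / (rate0 + n_R))
        if not (np.isfinite(theta) and np.isfinite(lam_S).all() and np.isfinite(lam_R).all()):
            raise FloatingPointError(f"non-finite sampler state at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            theta_out[k] = theta
            z_out[k] = z
            lam_S_out[k] = lam_S
            lam_R_out[k] = lam_R
            k += 1

    return Chain(theta_out[:k], z_out[:k], lam_S_out[:k], lam_R_out[:k], pair, config)


def _ess(x: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0.0:
        return float(x.size)
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[np.newaxis, :]))


def summarize(chain: Chain) -> PosteriorSummary:
    """Posterior means, 95% percentile interval, ESS and Monte-Carlo SE."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    theta = chain.theta
    ess = _ess(theta)
    sd = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
    lo, hi = np.percentile(theta, [2.5, 97.5])
    return PosteriorSummary(
        theta_mean=float(theta.mean()),
        theta_ci=(float(lo), float(hi)),
        theta_sd=sd,
        ess_theta=ess,
        mcse_theta=sd / np.sqrt(ess) if ess > 0 else float("nan"),
        z_mean=chain.z.mean(axis=0),
        lambda_S_mean=chain.lambda_S.mean(axis=0),
        lambda_R_mean=chain.lambda_R.mean(axis=0),
        n_draws=len(chain),
    )


# ---------------------------------------------------------------------------
# brute-force enumeration oracle


@dataclass
class OraclePosterior:
    """Discretized theta posterior with the rates integrated analytically."""

    grid: np.ndarray
    density: np.ndarray          # normalized to sum to 1 on the grid
    theta_mean: float
    z_mean: np.ndarray

    def cdf(self, x: float) -> float:
        return float(self.density[self.grid <= x].sum())


def _log_nb(count: np.ndarray, shape: float, rate: float, exposure: float) -> np.ndarray:
    """log of the Poisson-Gamma (negative-binomial) marginal pmf."""
    return (
        gammaln(shape + count)
        - gammaln(shape)
        - gammaln(count + 1.0)
        + shape * np.log(rate / (rate + exposure))
        + count * np.log(exposure / (rate + exposure))
    )


def oracle_posterior(
    pair: PairData,
    theta_prior: BetaPrior,
    rate_prior: GammaPrior | None = None,
    grid_size: int = 2001,
    shared_rates: bool = False,
    enumeration_guard: int = 1_000_000,
) -> OraclePosterior:
    """Exact (to grid resolution) theta posterior by latent enumeration.

    Integrates the Gamma rates in closed form, leaving per-stratum weights
    over z_r in {0..y_R_r} whose theta-dependence is theta^z (1-theta)^y_S.
    Strata are combined by convolving their weight polynomials in the total
    latent count, so the posterior on a uniform midpoint grid is

        p(theta) ~ Beta(theta; a, b) (1-theta)^{sum y_S} sum_m A_m theta^m.

    Feasible only for small receiver counts (guard on prod(y_R + 1)).
    """
    rate_prior = rate_prior or crude_rate_prior(pair)
    if np.prod(pair.y_R + 1.0) > enumeration_guard:
        raise ValueError("enumeration guard exceeded; oracle infeasible for this pair")
    alpha, beta_r = rate_prior.shape, rate_prior.rate
    r = pair.n_strata

    # per-stratum log-weights over z_r, theta-terms excluded
    stratum_logw: list[np.ndarray] = []
    for j in range(r):
        yS, yR = pair.y_S[j], pair.y_R[j]
        nS, nR = pair.n_S[j], pair.n_R[j]
        z = np.arange(int(yR) + 1, dtype=float)
        T = yS + z
        W = yR - z
        log_choose = gammaln(T + 1.0) - gammaln(z + 1.0) - gammaln(yS + 1.0)
        if shared_rates:
            lw = (
                gammaln(alpha + T + W)
                - gammaln(alpha)
                - gammaln(T + 1.0)
                - gammaln(W + 1.0)
                + alpha * np.log(beta_r)
                + T * np.log(nS)
                + W * np.log(nR)
                - (alpha + T + W) * np.log(beta_r + nS + nR)
            )
        else:
            lw = _log_nb(T, alpha, beta_r, nS) + _log_nb(W, alpha, beta_r, nR)
        stratum_logw.append(lw + log_choose)

    # combine strata: polynomial convolution in the total latent count m
    def _convolve(logws: list[np.ndarray]) -> tuple[np.ndarray, float]:
        offset = 0.0
        poly = np.ones(1)
        for lw in logws:
            m = lw.max()
            poly = np.convolve(poly, np.exp(lw - m))
            offset += m
            s = poly.max()
            poly /= s
            offset += np.log(s)
        return np.log(np.maximum(poly, 1e-300)) + offset, offset

    logA, _ = _convolve(stratum_logw)
    m_grid = np.arange(logA.size, dtype=float)

    grid = (np.arange(grid_size) + 0.5) / grid_size
    log_theta = np.log(grid)
    log_1m = np.log1p(-grid)
    log_prior = (
        (theta_prior.a - 1.0) * log_theta
        + (theta_prior.b - 1.0) * log_1m
        - betaln(theta_prior.a, theta_prior.b)
    )
    yS_total = float(pair.y_S.sum())
    # (grid, m) -> logsumexp over m
    log_post = log_prior + yS_total * log_1m + logsumexp(
        logA[np.newaxis, :] + np.outer(log_theta, m_grid), axis=1
    )
    log_post -= logsumexp(log_post)
    density = np.exp(log_post)
    theta_mean = float(np.sum(grid * density))

    # E[z_j]: reweight stratum j's polynomial by z and integrate over theta
    log_I = logsumexp(
        log_prior[:, np.newaxis] + yS_total * log_1m[:, np.newaxis]
        + np.outer(log_theta, m_grid),
        axis=0,
    )  # log integral of theta^m terms, per total m
    norm = logsumexp(logA + log_I)
    z_mean = np.empty(r)
    for j in range(r):
        if stratum_logw[j].size == 1:  # y_R_j = 0 forces z_j = 0
            z_mean[j] = 0.0
            continue
        zj = np.arange(stratum_logw[j].size, dtype=float)
        # drop the z_j = 0 term (zero weight in the expectation)
        lw_j = stratum_logw[j][1:] + np.log(zj[1:])
        others = [stratum_logw[i] for i in range(r) if i != j] + [lw_j]
        logB, _ = _convolve(others)
        # logB index m' corresponds to total latent count m = m' + 1
        z_mean[j] = np.exp(logsumexp(logB + log_I[1 : logB.size + 1]) - norm)
    return OraclePosterior(grid, density, theta_mean, z_mean)


# ---------------------------------------------------------------------------
# estimator facade


class PairMisclassificationModel(BaseEstimator):
    """Scikit-learn-style estimator for the pair misclassification model.

    Parameters
    ----------
    prior_a, prior_b : float
        Beta prior shapes for theta (elicit from coverage via
        :func:`regmis.priors.beta_from_coverage`). Default flat Beta(1, 1).
    rate_shape : float
        Gamma shape of the rate hyperprior; its rate parameter is anchored
        at the crude pooled rate of the fitted pair unless ``rate_rate`` is
        given explicitly.
    rate_rate : float or None
        Explicit Gamma rate (per person-year) for the rate hyperprior.
    iterations, burn_in, thin : int
        Gibbs sampler schedule.
    shared_rates : bool
        Share one incidence rate per stratum between the two provinces
        (identifiable variant).
    random_state : int
        Sampler seed; fits are bitwise reproducible.

    Attributes (after ``fit``)
    --------------------------
    chain_ : Chain of posterior draws.
    summary_ : PosteriorSummary.
    theta_mean_, theta_ci_, z_mean_, ess_theta_ : convenience views.
    """

    def __init__(
        self,
        prior_a: float = 1.0,
        prior_b: float = 1.0,
        rate_shape: float = 1.0,
        rate_rate: float | None = None,
        iterations: int = 10_000,
        burn_in: int = 2_000,
        thin: int = 1,
        shared_rates: bool = False,
        random_state: int = 0,
    ):
        self.prior_a = prior_a
        self.prior_b = prior_b
        self.rate_shape = rate_shape
        self.rate_rate = rate_rate
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.shared_rates = shared_rates
        self.random_state = random_state

    def _priors(self, pair: PairData) -> tuple[BetaPrior, GammaPrior]:
        theta_prior = BetaPrior(self.prior_a, self.prior_b)
        if self.rate_rate is not None:
            rate_prior = GammaPrior(self.rate_shape, self.rate_rate)
        else:
            rate_prior = crude_rate_prior(pair, shape=self.rate_shape)
        return theta_prior, rate_prior

    def fit(self, X: PairData, y=None) -> "PairMisclassificationModel":
        if not isinstance(X, PairData):
            raise TypeError("X must be a PairData")
        theta_prior, rate_prior = self._priors(X)
        config = ModelConfig(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            shared_rates=self.shared_rates,
        )
        self.pair_ = X
        self.chain_ = gibbs_run(X, theta_prior, rate_prior, config)
        self.summary_ = summarize(self.chain_)
        self.theta_mean_ = self.summary_.theta_mean
        self.theta_ci_ = self.summary_.theta_ci
        self.z_mean_ = self.summary_.z_mean
        self.ess_theta_ = self.summary_.ess_theta
        return self

    def oracle(self, X: PairData | None = None, grid_size: int = 2001) -> OraclePosterior:
        """Enumeration-oracle posterior under this estimator's priors."""
        pair = X if X is not None else self.pair_
        theta_prior, rate_prior = self._priors(pair)
        return oracle_posterior(
            pair, theta_prior, rate_prior, grid_size=grid_size,
            shared_rates=self.shared_rates,
        )
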