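"""Local robit regression for efficacy.

Efficacy cannot be handled the way toxicity is: the partial-ordering
assumption need not hold for response, and enumerating all response
orderings of even a 5-dose neighbourhood is combinatorially hopeless.
Instead the response rate over the 9-dose neighbourhood B is modelled
with a robit (Student-t link) regression on standardized doses,

    F_v^{-1}(q_jk) = alpha + beta1*dA + beta2*dB + gamma1*dA^2 + gamma2*dB^2,

where F_v is the t CDF with v degrees of freedom.  The t link covers
logistic-like (v ~ 7) through probit (v -> infinity) behaviour, and the
quadratic terms let the fitted surface bend, which matters for
plateauing or umbrella-shaped dose-response.

Priors: alpha ~ N(mu_a, s2_a), beta1, beta2 ~ N(mu_b, s2_b),
gamma1, gamma2 ~ N(mu_g, s2_g), v ~ half-t(0, 1, df) (the stated
t(0,1,df) prior truncated to v > 0, the only positivity-respecting
reading), df ~ Uniform(a_df, b_df).  Posterior sampling is an adaptive
random-walk Metropolis on (theta, log v, df); the posterior is a smooth
7-dimensional surface over at most 9 binomial cells, so a tuned RW
chain mixes quickly and keeps the simulator dependency-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, stdtr

__all__ = [
    "EffCounts", "EffPriors", "MCMCConfig", "EffPosterior",
    "robit_prob", "eff_posterior", "futility_eliminate",
]


@dataclass(frozen=True)
class EffCounts:
    """Per-dose patient and responder counts, J x K arrays indexed [j-1, k-1]."""

    n: np.ndarray
    yE: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n, dtype=int)
        yE = np.asarray(self.yE, dtype=int)
        if n.shape != yE.shape or n.ndim != 2:
            raise ValueError("n and yE must be matching J x K matrices")
        if (yE < 0).any() or (yE > n).any():
            raise ValueError("need 0 <= yE <= n elementwise")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "yE", yE)

    def at(self, dose):
        j, k = dose
        return int(self.n[j - 1, k - 1]), int(self.yE[j - 1, k - 1])


@dataclass(frozen=True)
class EffPriors:
    """Hyperparameters of the robit efficacy model (variances, not SDs)."""

    mu_alpha: float = 0.0
    sd2_alpha: float = 1.3
    mu_beta: float = 0.8
    sd2_beta: float = 1.3
    mu_gamma: float = 0.0
    sd2_gamma: float = 1.3
    a_df: float = 2.0
    b_df: float = 10.0


@dataclass(frozen=True)
class MCMCConfig:
    iters: int = 3000     # post-burn-in draws kept
    burnin: int = 1000
    target_accept: float = 0.3


@dataclass(frozen=True)
class EffPosterior:
    """Posterior sample of the robit model over a set of doses."""

    doses: tuple                      # (j,k) pairs modelled
    q_draws: np.ndarray               # (draws, len(doses)) efficacy probabilities
    theta_draws: np.ndarray           # (draws, 5) alpha, beta1, beta2, gamma1, gamma2
    v_draws: np.ndarray               # (draws,) degrees of freedom of the link
    accept_rate: float
    qbar: dict = field(init=False)    # dose -> posterior-mean efficacy

    def __post_init__(self):
        means = self.q_draws.mean(axis=0)
        object.__setattr__(
            self, "qbar", {d: float(m) for d, m in zip(self.doses, means)})

    def prob_below(self, threshold: float) -> dict:
        """Per-dose posterior probability Pr(q < threshold)."""
        frac = (self.q_draws < threshold).mean(axis=0)
        return {d: float(f) for d, f in zip(self.doses, frac)}


def robit_prob(theta, v: float, dA: float, dB: float) -> float:
    """Efficacy probability under the robit model at standardized doses."""
    if v <= 0:
        raise ValueError("degrees of freedom v must be positive")
    a, b1, b2, g1, g2 = theta
    eta = a + b1 * dA + b2 * dB + g1 * dA * dA + g2 * dB * dB
    return float(stdtr(v, eta))


def _half_t_logpdf(v: float, df: float) -> float:
    # half-t(0, 1, df) on v > 0
    return (math.log(2.0) + gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * math.log(df * math.pi)
            - (df + 1) / 2 * math.log1p(v * v / df))


def eff_posterior(counts: EffCounts, doses, grid, priors: EffPriors = EffPriors(),
                  mcmc: MCMCConfig = MCMCConfig(), rng=None) -> EffPosterior:
    """Posterior sample of the robit model fitted to the given doses.

    Parameters
    ----------
    counts : EffCounts
        Full-grid counts; only the cells listed in ``doses`` enter the
        likelihood (cells with n = 0 contribute nothing).
    doses : iterable of (j, k)
        The doses modelled, typically the local set B or, at final
        selection, all tried doses.
    grid : DoseGrid
        Supplies the standardized dose values.
    rng : numpy Generator or int, optional
        Source of randomness; fixing it makes the draw sequence
        reproducible bit for bit.
    """
    rng = np.random.default_rng(rng)
    doses = tuple(sorted(tuple(d) for d in doses))
    X = np.array([[1.0, dA, dB, dA * dA, dB * dB]
                  for dA, dB in (grid.std_dose(d) for d in doses)])
    n = np.array([counts.at(d)[0] for d in doses], dtype=float)
    y = np.array([counts.at(d)[1] for d in doses], dtype=float)
    has_data = n > 0
    Xd, nd, yd = X[has_data], n[has_data], y[has_data]

    p = priors
    prior_mu = np.array([p.mu_alpha, p.mu_beta, p.mu_beta, p.mu_gamma, p.mu_gamma])
    prior_s2 = np.array([p.sd2_alpha, p.sd2_beta, p.sd2_beta, p.sd2_gamma, p.sd2_gamma])

    def log_post(theta, logv, df):
        """Log posterior plus the per-dose efficacy probabilities."""
        if not (p.a_df < df < p.b_df):
            return -np.inf, None
        v = math.exp(logv)
        lp = -0.5 * float(((theta - prior_mu) ** 2 / prior_s2).sum())
        lp += _half_t_logpdf(v, df) + logv  # Jacobian of v = exp(logv)
        q = stdtr(v, X @ theta)
        qd = np.clip(q[has_data], 1e-12, 1 - 1e-12)
        lp += float(yd @ np.log(qd) + (nd - yd) @ np.log1p(-qd))
        return lp, q

    # state: theta (5), log v, df
    theta = prior_mu.copy()
    logv, df = math.log(7.0), 0.5 * (p.a_df + p.b_df)
    lp, q_cur = log_post(theta, logv, df)
    scales = np.array([0.3, 0.3, 0.3, 0.3, 0.3, 0.5, 1.0])
    log_s = 0.0  # global log step-size multiplier, adapted in burn-in

    total = mcmc.burnin + mcmc.iters
    q_draws = np.empty((mcmc.iters, len(doses)))
    theta_draws = np.empty((mcmc.iters, 5))
    v_draws = np.empty(mcmc.iters)
    steps = rng.standard_normal((total, 7))
    unif = np.log(rng.random(total))
    accepted = 0
    acc_window = 0
    for t in range(total):
        prop = steps[t] * scales * math.exp(log_s)
        th_p = theta + prop[:5]
        lv_p = logv + prop[5]
        df_p = df + prop[6]
        lp_p, q_p = log_post(th_p, lv_p, df_p)
        if lp_p - lp > unif[t]:
            theta, logv, df, lp, q_cur = th_p, lv_p, df_p, lp_p, q_p
            accepted += 1
            acc_window += 1
        if t < mcmc.burnin and (t + 1) % 50 == 0:
            rate = acc_window / 50.0
            log_s += 0.5 * (rate - mcmc.target_accept)
            acc_window = 0
        if t >= mcmc.burnin:
            i = t - mcmc.burnin
            q_draws[i] = q_cur
            theta_draws[i] = theta
            v_draws[i] = math.exp(logv)
    rate = accepted / total
    if not (0.05 <= rate <= 0.8):
        warnings.warn(f"robit sampler acceptance rate {rate:.3f} outside [0.05, 0.8]",
                      RuntimeWarning, stacklevel=2)
    return EffPosterior(doses=doses, q_draws=q_draws, theta_draws=theta_draws,
                        v_draws=v_draws, accept_rate=rate)


def futility_eliminate(post: EffPosterior, phiE: float, cE: float,
                       min_n: int, counts: EffCounts) -> set:
    """Doses whose posterior puts more than cE probability below phiE.

    Only doses with at least ``min_n`` patients can be flagged; flagged
    doses are treated as permanently removed by the calling design.
    """
    below = post.prob_below(phiE)
    return {d for d in post.doses
            if counts.at(d)[0] >= min_n and below[d] > cE}
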