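"""Local empiric-CRM toxicity model with Bayesian model averaging.

Each complete toxicity ordering O_i of the local set A defines a
one-parameter empiric CRM model p_jk = pi(r_i(j,k))^exp(a_i) with
a_i ~ N(0, sigma_a^2).  The per-ordering posterior involves only a 1-D
integral over a_i, evaluated here by a fixed high-order Gauss-Legendre
rule; posterior toxicity estimates are then averaged over orderings
with weights proportional to the marginal likelihoods (equal prior
model probabilities 1/I).

Overdose elimination is a separate, model-free rule: a dose (and every
higher combination) is dropped when its own Beta(1+y, 1+n-y) posterior
puts more than c_T probability above the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

from .orderings import LocalSet, Ordering, enumerate_orderings
from .skeleton import Skeleton, generate_skeleton, prior_mtd_position

__all__ = [
    "ToxCounts", "ToxPosterior", "tox_prob", "ordering_posterior",
    "bma_estimates", "safety_eliminate",
]

# Gauss-Legendre nodes on a in [-10, 10]: > 7 prior SDs for sigma_a^2 <= 2,
# and plenty of nodes for the smooth, unimodal integrands that arise from
# <= 51 binomial observations.
_A_LO, _A_HI = -10.0, 10.0
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(301)
_A_GRID = 0.5 * (_A_HI - _A_LO) * _GL_NODES + 0.5 * (_A_HI + _A_LO)
_A_W = 0.5 * (_A_HI - _A_LO) * _GL_WEIGHTS
_EXP_A = np.exp(_A_GRID)


@dataclass(frozen=True)
class ToxCounts:
    """Per-dose patient and DLT counts, as J x K arrays indexed [j-1, k-1]."""

    n: np.ndarray
    yT: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n, dtype=int)
        yT = np.asarray(self.yT, dtype=int)
        if n.shape != yT.shape or n.ndim != 2:
            raise ValueError("n and yT must be matching J x K matrices")
        if (yT < 0).any() or (yT > n).any():
            raise ValueError("need 0 <= yT <= n elementwise")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "yT", yT)

    def at(self, dose):
        j, k = dose
        return int(self.n[j - 1, k - 1]), int(self.yT[j - 1, k - 1])


@dataclass(frozen=True)
class ToxPosterior:
    """BMA summary over the orderings of a local set."""

    local: LocalSet
    orderings: tuple          # the Ordering objects averaged over
    weights: np.ndarray       # Pr(O_i | D), sums to 1
    per_ordering: tuple       # dict dose -> posterior mean, one per ordering
    pbar: dict                # dose -> BMA toxicity estimate
    prior_sd2: float


def tox_prob(skeleton: Skeleton, ordering: Ordering, dose, a: float) -> float:
    """Empiric-model toxicity probability pi(rank)^exp(a) at one dose."""
    return skeleton[ordering.rank(dose)] ** math.exp(a)


def _log_prior(a_grid: np.ndarray, prior_sd2: float, prior: str) -> np.ndarray:
    if prior == "normal":
        return -0.5 * a_grid**2 / prior_sd2 - 0.5 * math.log(2 * math.pi * prior_sd2)
    if prior == "exponential":
        # exp(a) ~ Exp(1)  =>  density of a is exp(a - exp(a))
        return a_grid - np.exp(a_grid)
    raise ValueError(f"unknown prior {prior!r}")


def _ordering_log_posterior(counts, ls, skeleton, ordering, prior_sd2, prior):
    """Log marginal likelihood and posterior-mean toxicities for one ordering."""
    pi = np.array([skeleton[ordering.rank(d)] for d in ls.A])  # (|A|,)
    # probs[d, g] = pi_d ^ exp(a_g)
    probs = pi[:, None] ** _EXP_A[None, :]
    log_lik = np.zeros_like(_A_GRID)
    with np.errstate(divide="ignore"):
        for i, d in enumerate(ls.A):
            n, y = counts.at(d)
            # guard the zero-count factors: pi^exp(a) underflows to 0 (or
            # rounds to 1) at extreme a, where the likelihood is honestly 0
            if y > 0:
                log_lik += y * np.log(probs[i])
            if n - y > 0:
                log_lik += (n - y) * np.log1p(-probs[i])
    log_int = log_lik + _log_prior(_A_GRID, prior_sd2, prior)
    shift = log_int.max()
    dens = np.exp(log_int - shift) * _A_W
    z = dens.sum()
    if not np.isfinite(z) or z <= 0:
        raise FloatingPointError("toxicity posterior integration failed")
    log_marginal = math.log(z) + shift
    post_means = {d: float((probs[i] * dens).sum() / z) for i, d in enumerate(ls.A)}
    return log_marginal, post_means


def ordering_posterior(counts: ToxCounts, ls: LocalSet, skeleton: Skeleton,
                       ordering: Ordering, prior_sd2: float = 2.0,
                       prior: str = "normal"):
    """Marginal likelihood and posterior-mean toxicities for one ordering.

    Returns ``(marginal_likelihood, post_means)`` where ``post_means``
    maps each dose in A to E[pi(r)^exp(a) | data].  The binomial
    coefficients are omitted from the likelihood; they cancel both in
    the ordering weights and in the posterior means.
    """
    log_m, post_means = _ordering_log_posterior(counts, ls, skeleton, ordering,
                                                prior_sd2, prior)
    return math.exp(log_m), post_means


def bma_estimates(counts: ToxCounts, ls: LocalSet, prior_sd2: float = 2.0,
                  halfwidth: float = 0.05, target: float = 0.3,
                  prior: str = "normal",
                  prior_mtd_rule: str = "n_minus_1") -> ToxPosterior:
    """Model-averaged toxicity estimates pbar over the local set A.

    Orderings receive equal prior probabilities 1/I; posterior weights
    are proportional to the per-ordering marginal likelihoods.
    """
    orderings = enumerate_orderings(ls)
    nu = prior_mtd_position(len(ls.A), prior_mtd_rule,
                            current_rank=orderings[0].rank(ls.current))
    skel = generate_skeleton(target, len(ls.A), nu, halfwidth)
    log_marginals = np.empty(len(orderings))
    per_ordering = []
    for i, o in enumerate(orderings):
        lm, means = _ordering_log_posterior(counts, ls, skel, o, prior_sd2, prior)
        log_marginals[i] = lm
        per_ordering.append(means)
    # equal prior model probabilities cancel in the softmax
    w = np.exp(log_marginals - log_marginals.max())
    weights = w / w.sum()
    pbar = {d: float(sum(w * means[d] for w, means in zip(weights, per_ordering)))
            for d in ls.A}
    return ToxPosterior(local=ls, orderings=tuple(orderings), weights=weights,
                        per_ordering=tuple(per_ordering), pbar=pbar,
                        prior_sd2=prior_sd2)


def safety_eliminate(counts: ToxCounts, target: float, cutoff: float,
                     min_n: int = 3) -> set:
    """Doses flagged as overly toxic by the beta-binomial rule, upward-closed.

    A dose with at least ``min_n`` patients is flagged when
    Pr(p > target) > cutoff under p ~ Beta(1 + y, 1 + n - y); every
    combination with both dose levels at least as high is then flagged
    with it.
    """
    J, K = counts.n.shape
    flagged = set()
    for j in range(1, J + 1):
        for k in range(1, K + 1):
            n, y = counts.at((j, k))
            if n < min_n:
                continue
            tail = 1.0 - betainc(1 + y, 1 + n - y, target)
            if tail > cutoff:
                for jj in range(j, J + 1):
                    for kk in range(k, K + 1):
                        flagged.add((jj, kk))
    return flagged
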