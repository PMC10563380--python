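"""CRM skeletons by the indifference-interval (Lee–Cheung) algorithm.

The empiric CRM working model writes the toxicity probability of the
dose with rank l as pi(l)^exp(a).  The skeleton pi(1) < ... < pi(L) of
prior guesses is generated so that dose ``prior_mtd`` carries the target
rate exactly and each adjacent pair of skeleton values is separated by
an indifference interval of halfwidth delta: at the parameter value a
where the model switches its recommendation between positions l and
l+1, position l sits at target - delta and position l+1 at
target + delta.  Under the empiric model this gives the closed-form
recursion (moving up from position nu, with t = target)

    log pi(l+1) = log(t + delta) * log pi(l) / log(t - delta)

and its mirror image moving down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

__all__ = ["Skeleton", "generate_skeleton"]


@dataclass(frozen=True)
class Skeleton:
    probs: tuple  # pi(1) < ... < pi(L), each in (0,1)
    target: float
    prior_mtd: int  # 1-based position nu with probs[nu-1] == target
    halfwidth: float

    def __len__(self) -> int:
        return len(self.probs)

    def __getitem__(self, rank: int) -> float:
        """Skeleton value at 1-based rank."""
        return self.probs[rank - 1]


@lru_cache(maxsize=None)
def generate_skeleton(target: float, n_doses: int, prior_mtd: int,
                      halfwidth: float) -> Skeleton:
    """Indifference-interval skeleton for the empiric model.

    Parameters
    ----------
    target : float
        Target toxicity probability phi_T, in (0, 1).
    n_doses : int
        Number of skeleton positions L (= |A| for a local CRM).
    prior_mtd : int
        1-based position nu whose prior guess equals the target.
    halfwidth : float
        Indifference-interval halfwidth delta, 0 < delta < target.
    """
    if not (1 <= prior_mtd <= n_doses):
        raise ValueError("prior_mtd out of range")
    if not (0.0 < halfwidth < target < 1.0):
        raise ValueError("need 0 < halfwidth < target < 1")
    if target + halfwidth >= 1.0:
        raise ValueError("target + halfwidth must stay below 1")

    lo = math.log(target - halfwidth)
    hi = math.log(target + halfwidth)
    probs = [0.0] * n_doses
    probs[prior_mtd - 1] = target
    for l in range(prior_mtd, n_doses):          # upward: values increase
        probs[l] = math.exp(hi * math.log(probs[l - 1]) / lo)
    for l in range(prior_mtd - 2, -1, -1):       # downward: values decrease
        probs[l] = math.exp(lo * math.log(probs[l + 1]) / hi)

    if any(not (0.0 < p < 1.0) for p in probs):
        raise ValueError(
            f"skeleton recursion left (0,1): target={target}, "
            f"n_doses={n_doses}, prior_mtd={prior_mtd}, halfwidth={halfwidth}"
        )
    if any(b <= a for a, b in zip(probs, probs[1:])):
        raise ValueError("skeleton is not strictly increasing")
    return Skeleton(probs=tuple(probs), target=target,
                    prior_mtd=prior_mtd, halfwidth=halfwidth)


def prior_mtd_position(n_doses: int, rule: str = "n_minus_1",
                       current_rank: int | None = None) -> int:
    """Map local-set size to the prior-MTD skeleton position.

    The default pairs |A| = 3, 4, 5 with nu = 2, 3, 4.  The alternative
    ``"current_rank"`` rule places the prior MTD at the current dose's
    rank within its local set.
    """
    if rule == "n_minus_1":
        return max(1, n_doses - 1)
    if rule == "current_rank":
        if current_rank is None:
            raise ValueError("current_rank required for rule 'current_rank'")
        return current_rank
    raise ValueError(f"unknown prior_mtd rule {rule!r}")
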