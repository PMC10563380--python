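"""Local dose sets and enumeration of toxicity orderings.

Under the partial-ordering assumption (toxicity increases in either
drug's dose while the other is held fixed) most dose pairs in a
combination grid cannot be ranked against each other.  Within the local
neighbourhood of the current dose, however, the number of complete
toxicity orderings consistent with partial ordering is small and can be
enumerated exhaustively: up to four for an interior dose, two at the
(1,1) and (J,K) corners and a single certain ordering at (J,1) / (1,K).

The local set ``A`` holds the current dose and its one-step axis
neighbours (at most 5 pairs); ``B`` adds the in-grid diagonal
neighbours (at most 9 pairs) and is the support of the efficacy model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import DoseGrid

__all__ = ["LocalSet", "Ordering", "local_set", "enumerate_orderings"]


@dataclass(frozen=True)
class LocalSet:
    """Neighbourhood of the current dose, in canonical (j, k) order."""

    current: tuple
    A: tuple  # axis neighbours incl. current, |A| in {3,4,5}
    B: tuple  # A plus diagonal neighbours, |B| <= 9


@dataclass(frozen=True)
class Ordering:
    """One complete toxicity ordering of a local set A.

    ``ranks`` maps each dose pair in A to its toxicity rank 1..|A|
    (smallest to largest); it is a bijection consistent with
    componentwise dominance.
    """

    ranks: dict

    def __post_init__(self):
        object.__setattr__(self, "ranks", dict(self.ranks))

    def rank(self, dose) -> int:
        return self.ranks[tuple(dose)]

    def __len__(self) -> int:
        return len(self.ranks)


def local_set(grid: DoseGrid, current) -> LocalSet:
    """Build the local sets A (axis) and B (axis + diagonal) around ``current``.

    Both sets are clipped to the grid and stored row-major by (j, k) so
    downstream enumeration and tie-breaking are reproducible.
    """
    j, k = current
    if not grid.contains((j, k)):
        raise ValueError(f"current dose {current!r} outside {grid.J}x{grid.K} grid")
    axis = [(j - 1, k), (j, k - 1), (j, k), (j + 1, k), (j, k + 1)]
    diag = [(j - 1, k - 1), (j - 1, k + 1), (j + 1, k - 1), (j + 1, k + 1)]
    A = tuple(sorted(d for d in axis if grid.contains(d)))
    B = tuple(sorted(d for d in axis + diag if grid.contains(d)))
    return LocalSet(current=(j, k), A=A, B=B)


def _dominates(a, b) -> bool:
    """True when a is componentwise >= b and a != b (strictly more toxic)."""
    return a != b and a[0] >= b[0] and a[1] >= b[1]


def enumerate_orderings(ls: LocalSet):
    """All linear extensions of the dominance partial order on A.

    Generic backtracking over the local poset; for an interior dose this
    yields exactly the four classical orderings, and the edge/corner
    cases (2 or 1 orderings) fall out automatically.  The current dose's
    rank is identical across all returned orderings.
    """
    doses = list(ls.A)
    below = {d: {e for e in doses if _dominates(d, e)} for d in doses}
    out: list[Ordering] = []
    chosen: list = []

    def extend(remaining: set):
        if not remaining:
            out.append(Ordering({d: r + 1 for r, d in enumerate(chosen)}))
            return
        # next element must have all its dominated predecessors placed
        for d in sorted(remaining):
            if below[d] <= set(chosen):
                chosen.append(d)
                extend(remaining - {d})
                chosen.pop()

    extend(set(doses))
    return out
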