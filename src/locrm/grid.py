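"""Dose-combination grids and dose standardization.

A drug-combination trial explores a J x K matrix of dose pairs (j, k),
j indexing the J levels of drug A and k the K levels of drug B.  Indices
are 1-based throughout, matching the usual presentation of combination
dose-finding designs.  Regression-style efficacy models work on
standardized (mean 0, unit sample SD) dose values rather than raw doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "standardize_doses"]


def standardize_doses(raw) -> np.ndarray:
    """Center and scale raw dose values to mean 0 and unit sample SD.

    Uses the n-1 denominator, so e.g. (0.08, 0.16, 0.24) maps to
    (-1, 0, 1).  Full precision is kept; round only for display.

    Raises
    ------
    ValueError
        If fewer than two doses are given or all doses are equal.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("need at least two dose values to standardize")
    sd = raw.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(raw.mean())):
        raise ValueError("dose values are constant; cannot standardize")
    return (raw - raw.mean()) / sd


@dataclass(frozen=True)
class DoseGrid:
    """The J x K combination space with raw and standardized doses.

    Attributes
    ----------
    rawA, rawB : tuple of float
        Raw dose values of drug A (length J) and drug B (length K),
        strictly increasing.
    stdA, stdB : tuple of float
        Standardized doses (mean 0, unit sample SD); equal to the raw
        doses when a drug has a single level.
    """

    rawA: tuple
    rawB: tuple
    stdA: tuple = field(init=False)
    stdB: tuple = field(init=False)

    def __post_init__(self):
        rawA = tuple(float(x) for x in self.rawA)
        rawB = tuple(float(x) for x in self.rawB)
        if len(rawA) < 1 or len(rawB) < 1:
            raise ValueError("each drug needs at least one dose level")
        for raw, name in ((rawA, "rawA"), (rawB, "rawB")):
            if any(b <= a for a, b in zip(raw, raw[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        object.__setattr__(self, "rawA", rawA)
        object.__setattr__(self, "rawB", rawB)
        stdA = tuple(standardize_doses(rawA)) if len(rawA) >= 2 else rawA
        stdB = tuple(standardize_doses(rawB)) if len(rawB) >= 2 else rawB
        object.__setattr__(self, "stdA", stdA)
        object.__setattr__(self, "stdB", stdB)

    @property
    def J(self) -> int:
        return len(self.rawA)

    @property
    def K(self) -> int:
        return len(self.rawB)

    def contains(self, dose) -> bool:
        j, k = dose
        return 1 <= j <= self.J and 1 <= k <= self.K

    def doses(self):
        """All (j, k) pairs in row-major order (j fastest-varying last)."""
        return [(j, k) for j in range(1, self.J + 1) for k in range(1, self.K + 1)]

    def std_dose(self, dose):
        """Standardized (d_j^A, d_k^B) for a 1-based pair."""
        j, k = dose
        return self.stdA[j - 1], self.stdB[k - 1]
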