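"""Weighted bivariate isotonic regression on a dose grid.

The final dose selection smooths the observed toxicity-rate matrix by
projecting it, in weighted least squares, onto the cone of matrices
non-decreasing along both axes.  The doubly-monotone cone is the
intersection of the row-monotone and column-monotone cones, so the
projection is computed by Dykstra's alternating-projection scheme, with
each 1-D projection done by weighted pool-adjacent-violators
(scipy's isotonic_regression).  Plain cyclic row/column PAVA without
Dykstra's correction terms is not an exact projection onto the
intersection; with them, the iterates converge to the true projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

__all__ = ["IsotonicFit", "biviso"]


@dataclass(frozen=True)
class IsotonicFit:
    fitted: np.ndarray   # J x K, non-decreasing along both axes
    weights: np.ndarray
    iterations: int


def _project_axis(x: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    out = np.empty_like(x)
    if axis == 0:
        for k in range(x.shape[1]):
            out[:, k] = isotonic_regression(x[:, k], weights=w[:, k]).x
    else:
        for j in range(x.shape[0]):
            out[j, :] = isotonic_regression(x[j, :], weights=w[j, :]).x
    return out


def biviso(rates, weights=None, tol: float = 1e-10,
           max_iter: int = 10_000) -> IsotonicFit:
    """Weighted L2 projection onto the doubly-monotone cone.

    Parameters
    ----------
    rates : (J, K) array
        Values to smooth, e.g. observed toxicity rates indexed [j-1, k-1].
    weights : (J, K) array, optional
        Non-negative weights, typically patient counts; defaults to all
        ones.  Cells may carry (near-)zero weight, but not all of them.
    tol : float
        Convergence threshold on the max absolute change per sweep.
    """
    x = np.asarray(rates, dtype=float)
    if x.ndim != 2:
        raise ValueError("rates must be a 2-D matrix")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match rates in shape")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if not (w > 0).any():
        raise ValueError("all weights are zero")
    # PAVA needs strictly positive weights; nudge exact zeros
    w = np.maximum(w, 1e-12)

    y = x.copy()
    p = np.zeros_like(x)  # Dykstra increments for each cone
    q = np.zeros_like(x)
    for it in range(1, max_iter + 1):
        r = _project_axis(y + p, w, axis=0)
        p = y + p - r
        y_new = _project_axis(r + q, w, axis=1)
        q = r + q - y_new
        delta = np.abs(y_new - y).max()
        y = y_new
        if delta < tol:
            break
    return IsotonicFit(fitted=y, weights=w, iterations=it)
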