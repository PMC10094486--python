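"""Tricube-weighted local polynomial regression (loess).

Supports arbitrary polynomial degree and returns the analytic first
derivative of the local fit, which is what a Marey map needs: the smoothed
genetic position cM(x) and its slope d cM/dx evaluated at arbitrary points.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["loess_fit"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x0: np.ndarray,
    span: float = 0.2,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit y ~ local polynomial in x, evaluated at points ``x0``.

    Parameters
    ----------
    x, y
        Observed predictor/response, need not be sorted.
    x0
        Evaluation points.
    span
        Fraction of observations in each local neighbourhood.
    degree
        Local polynomial degree (0, 1 or 2 are the usual choices).

    Returns
    -------
    (values, slopes)
        Fitted value and analytic first derivative of the local polynomial
        at each evaluation point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    min_pts = degree + 2
    if n < min_pts:
        raise ValueError(f"need at least {min_pts} points for degree {degree}")
    q = max(int(np.ceil(span * n)), min_pts)
    q = min(q, n)

    values = np.empty(x0.size)
    slopes = np.empty(x0.size)
    for i, xi in enumerate(x0):
        d = np.abs(x - xi)
        h = np.partition(d, q - 1)[q - 1]
        values[i], slopes[i] = _local_poly(x, y, xi, d, h, degree)
    return values, slopes


def _local_poly(x, y, xi, d, h, degree):
    # widen a degenerate bandwidth (duplicate abscissae) until the weighted
    # design has enough support
    for _ in range(60):
        if h <= 0:
            h = max(np.max(d) * 1e-6, 1e-12)
        w = _tricube(d / h)
        active = w > 0
        if np.count_nonzero(active) >= degree + 1 and np.unique(x[active]).size >= degree + 1:
            z = (x[active] - xi) / h
            design = np.vander(z, degree + 1, increasing=True)
            sw = np.sqrt(w[active])
            beta, *_ = np.linalg.lstsq(design * sw[:, None], y[active] * sw, rcond=None)
            value = beta[0]
            slope = beta[1] / h if degree >= 1 else 0.0
            return value, slope
        h *= 2.0
    warnings.warn("loess: local fit degenerate after widening; returning nearest value")
    j = int(np.argmin(d))
    return y[j], 0.0
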