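"""Shared quadrature helpers.

All solvers in this package discretize Volterra convolution integrals with the
composite trapezoidal rule on one uniform grid, so that cross-model
comparisons are grid-aligned and share the same O(dt^2) quadrature error.
"""
from __future__ import annotations

import numpy as np


def trap_convolve(f_vals: np.ndarray, g_vals: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal discretization of ``c(t_k) = int_0^{t_k} f(tau) g(t_k - tau) dtau``.

    Parameters
    ----------
    f_vals, g_vals
        Values of f and g on the uniform grid ``0, dt, ..., K*dt``
        (equal length).
    dt
        Grid spacing.

    Returns
    -------
    Array of the same length; entry k holds the trapezoid approximation of
    the convolution up to ``t_k`` (entry 0 is exactly 0).
    """
    f = np.asarray(f_vals, dtype=float)
    g = np.asarray(g_vals, dtype=float)
    if f.shape != g.shape or f.ndim != 1:
        raise ValueError("f_vals and g_vals must be 1-d arrays of equal length")
    n = f.size
    full = np.convolve(f, g)[:n]
    # remove half of both endpoint contributions (trapezoid weights 1/2)
    full -= 0.5 * f[0] * g
    full -= 0.5 * f * g[0]
    out = dt * full
    out[0] = 0.0
    return out


def trap_cumulative(values: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative trapezoid integral of sampled values, starting at 0."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    out[0] = 0.0
    np.cumsum(0.5 * dt * (v[1:] + v[:-1]), out=out[1:])
    return out
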