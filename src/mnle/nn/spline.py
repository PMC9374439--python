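"""Monotonic rational-quadratic spline transforms.

The spline maps ``[-bound, bound]`` onto itself through ``K`` monotone
rational-quadratic segments whose knot widths, heights and interior
derivatives are free parameters (here produced by a conditioning network);
outside the interval the map is the identity with unit derivative, so the
boundary derivatives are fixed to 1.  This is the standard building block
of neural spline flows.

``rq_spline_forward`` runs on autodiff tensors (for maximum-likelihood
training through the log-determinant); ``rq_spline_inverse`` is a plain
NumPy root-solve used only for sampling.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gather, softmax, softplus, where

__all__ = ["make_spline_params", "rq_spline_forward", "rq_spline_inverse"]

MIN_BIN = 1e-3
MIN_DERIV = 1e-3


def make_spline_params(raw: Tensor, n_bins: int, bound: float):
    """Map unconstrained network outputs to knot positions and derivatives.

    ``raw`` has shape (n, 3K-1): K raw widths, K raw heights, K-1 raw
    interior derivatives.  Returns tensors ``x_knots, y_knots`` of shape
    (n, K+1) and ``derivs`` of shape (n, K+1) with boundary derivatives 1.
    """
    n = raw.shape[0]
    K = n_bins
    raw_w = raw[:, :K]
    raw_h = raw[:, K:2 * K]
    raw_d = raw[:, 2 * K:]

    widths = softmax(raw_w, axis=-1) * (1 - MIN_BIN * K) + MIN_BIN
    heights = softmax(raw_h, axis=-1) * (1 - MIN_BIN * K) + MIN_BIN
    widths = widths * (2 * bound)
    heights = heights * (2 * bound)

    zeros = Tensor(np.zeros((n, 1)))
    x_knots = concat([zeros, widths.cumsum(axis=-1)], axis=-1) + (-bound)
    y_knots = concat([zeros, heights.cumsum(axis=-1)], axis=-1) + (-bound)

    ones = Tensor(np.ones((n, 1)))
    d_interior = softplus(raw_d) + MIN_DERIV
    derivs = concat([ones, d_interior, ones], axis=-1)
    return x_knots, y_knots, derivs


def _bin_index(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Per-row bin index of x within its own knot vector (constant wrt grads)."""
    n, Kp1 = knots.shape
    idx = np.empty((n, 1), dtype=np.intp)
    # vectorized row-wise searchsorted via comparison count
    idx[:, 0] = np.sum(knots[:, 1:-1] <= x[:, None], axis=1)
    return np.clip(idx, 0, Kp1 - 2)


def rq_spline_forward(y, x_knots: Tensor, y_knots: Tensor, derivs: Tensor,
                      bound: float):
    """Apply the spline to ``y`` (Tensor or array); returns (z, log|dz/dy|).

    Values outside ``[-bound, bound]`` pass through the identity tails.
    """
    y_t = y if isinstance(y, Tensor) else Tensor(y)
    y_data = y_t.data
    inside = (np.abs(y_data) < bound)[:, None]
    yc = y_t.clip(-bound + 1e-9, bound - 1e-9) if isinstance(y, Tensor) else \
        Tensor(np.clip(y_data, -bound + 1e-9, bound - 1e-9))

    idx = _bin_index(yc.data, x_knots.data)
    xk = gather(x_knots, idx)
    xk1 = gather(x_knots, idx + 1)
    yk = gather(y_knots, idx)
    yk1 = gather(y_knots, idx + 1)
    dk = gather(derivs, idx)
    dk1 = gather(derivs, idx + 1)

    wk = xk1 - xk
    hk = yk1 - yk
    sk = hk / wk
    yc2 = yc.reshape(-1, 1)
    xi = (yc2 - xk) / wk
    xi1m = 1.0 - xi
    xixi1m = xi * xi1m
    denom = sk + (dk1 + dk - sk * 2.0) * xixi1m
    z_in = yk + hk * (sk * xi * xi + dk * xixi1m) / denom
    num_ld = sk * sk * (dk1 * xi * xi + sk * xixi1m * 2.0 + dk * xi1m * xi1m)
    ld_in = num_ld.log() - denom.log() * 2.0

    z = where(inside, z_in, y_t.reshape(-1, 1))
    ld = where(inside, ld_in, Tensor(np.zeros_like(y_data[:, None])))
    return z.reshape(-1), ld.reshape(-1)


def rq_spline_inverse(z: np.ndarray, x_knots: np.ndarray, y_knots: np.ndarray,
                      derivs: np.ndarray, bound: float) -> np.ndarray:
    """Invert the spline for sampling (pure NumPy, quadratic root solve)."""
    z = np.asarray(z, dtype=float)
    inside = np.abs(z) < bound
    zc = np.clip(z, -bound + 1e-9, bound - 1e-9)
    i0 = _bin_index(zc, y_knots)[:, 0]
    r = np.arange(z.shape[0])
    xk, xk1 = x_knots[r, i0], x_knots[r, i0 + 1]
    yk, yk1 = y_knots[r, i0], y_knots[r, i0 + 1]
    dk, dk1 = derivs[r, i0], derivs[r, i0 + 1]
    wk = xk1 - xk
    hk = yk1 - yk
    sk = hk / wk
    dz = zc - yk
    term = dz * (dk1 + dk - 2.0 * sk)
    a_ = hk * (sk - dk) + term
    b_ = hk * dk - term
    c_ = -sk * dz
    disc = np.maximum(b_ * b_ - 4.0 * a_ * c_, 0.0)
    xi = 2.0 * c_ / (-b_ - np.sqrt(disc))
    y = xi * wk + xk
    return np.where(inside, y, z)


# ---------------------------------------------------------------------------
# Gradient-free NumPy fast path (evaluation / sampling only)
# ---------------------------------------------------------------------------

def spline_params_numpy(raw: np.ndarray, n_bins: int, bound: float):
    """NumPy twin of :func:`make_spline_params` for evaluation."""
    n, K = raw.shape[0], n_bins
    raw_w, raw_h, raw_d = raw[:, :K], raw[:, K:2 * K], raw[:, 2 * K:]

    def _softmax(x):
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    widths = (_softmax(raw_w) * (1 - MIN_BIN * K) + MIN_BIN) * (2 * bound)
    heights = (_softmax(raw_h) * (1 - MIN_BIN * K) + MIN_BIN) * (2 * bound)
    zeros = np.zeros((n, 1))
    x_knots = np.concatenate([zeros, widths.cumsum(axis=-1)], axis=-1) - bound
    y_knots = np.concatenate([zeros, heights.cumsum(axis=-1)], axis=-1) - bound
    d_int = np.logaddexp(0.0, raw_d) + MIN_DERIV
    derivs = np.concatenate([np.ones((n, 1)), d_int, np.ones((n, 1))], axis=-1)
    return x_knots, y_knots, derivs


def rq_spline_forward_numpy(y: np.ndarray, x_knots: np.ndarray,
                            y_knots: np.ndarray, derivs: np.ndarray,
                            bound: float):
    """NumPy twin of :func:`rq_spline_forward`; returns (z, logdet) arrays."""
    y = np.asarray(y, float)
    inside = np.abs(y) < bound
    yc = np.clip(y, -bound + 1e-9, bound - 1e-9)
    i0 = _bin_index(yc, x_knots)[:, 0]
    r = np.arange(y.shape[0])
    xk, xk1 = x_knots[r, i0], x_knots[r, i0 + 1]
    yk, yk1 = y_knots[r, i0], y_knots[r, i0 + 1]
    dk, dk1 = derivs[r, i0], derivs[r, i0 + 1]
    wk, hk = xk1 - xk, yk1 - yk
    sk = hk / wk
    xi = (yc - xk) / wk
    xi1m = 1.0 - xi
    xx = xi * xi1m
    denom = sk + (dk1 + dk - 2.0 * sk) * xx
    z = yk + hk * (sk * xi**2 + dk * xx) / denom
    ld = (np.log(sk**2 * (dk1 * xi**2 + 2.0 * sk * xx + dk * xi1m**2))
          - 2.0 * np.log(denom))
    return np.where(inside, z, y), np.where(inside, ld, 0.0)
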