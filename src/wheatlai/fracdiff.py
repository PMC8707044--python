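"""Grünwald-Letnikov fractional-order differentiation of reflectance spectra.

The fractional derivative of order ``alpha`` at band ``lambda`` (unit 1 nm
spacing) is the weighted history sum

    d^a f / dl^a  =  sum_{k>=0} c_k(alpha) * f(lambda - k),
    c_0 = 1,  c_k = c_{k-1} * (k - 1 - alpha) / k  =  (-1)^k * binom(alpha, k),

which interpolates between the raw spectrum (alpha = 0), the first
difference (alpha = 1) and the second difference (alpha = 2).  Orders
0-2 in steps of 0.1 (21 slabs) are the analysis default.

Bands whose history is shorter than the operator requires are flagged
invalid rather than zero-filled, and excluded from downstream screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .spectra import SpectraSet

#: Default order ladder: 0.0, 0.1, ..., 2.0.
DEFAULT_ORDERS = tuple(np.round(np.arange(0.0, 2.01, 0.1), 1))


def gl_coefficients(alpha: float, m: int) -> np.ndarray:
    """First ``m + 1`` Grünwald-Letnikov weights c_0..c_m for order ``alpha``.

    Computed by the stable ratio recursion; equal to (-1)^k * binom(alpha, k)
    = Gamma(k - alpha) / (Gamma(-alpha) * k!).  Integer orders terminate
    exactly (binomial rows with alternating signs).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    c = np.empty(m + 1)
    c[0] = 1.0
    for k in range(1, m + 1):
        c[k] = c[k - 1] * (k - 1 - alpha) / k
    return c


def _invalid_leading_bands(alpha: float, window_m: int) -> int:
    """Number of leading bands where truncated history changes the operator.

    Integer orders need exactly ``alpha`` left neighbours (weights beyond
    are exactly zero); fractional orders under a fixed window need the full
    window, while full-history mode flags the ceil(alpha) bands carrying
    the heaviest truncated weights.
    """
    if alpha == 0:
        return 0
    if float(alpha).is_integer():
        return min(int(alpha), window_m)
    return window_m


def fractional_derivative(
    spectra: SpectraSet | np.ndarray,
    alpha: float,
    window_m: int | None = None,
    max_order: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional derivative of each spectrum along the band axis.

    Parameters
    ----------
    spectra : SpectraSet or (n_samples, n_bands) array on a unit (1 nm) grid.
    alpha : differentiation order in [0, max_order].
    window_m : history length per band; ``None`` uses the full available
        history (the formula's own upper limit).

    Returns
    -------
    (values, valid) : the (n_samples, n_bands) differential spectra and a
        (n_bands,) boolean mask; leading bands with insufficient history
        are flagged invalid (their values are still the truncated sums).
    """
    if not 0.0 <= alpha <= max_order:
        raise ValueError(f"alpha={alpha} outside [0, {max_order}]")
    x = spectra.reflectance if isinstance(spectra, SpectraSet) else np.atleast_2d(np.asarray(spectra, dtype=float))
    n_bands = x.shape[1]
    if window_m is None:
        m = n_bands - 1
        invalid = 0 if alpha == 0 else min(math.ceil(alpha), m)
    else:
        if window_m < 1 and alpha > 0:
            raise ValueError("window_m must be >= 1 for alpha > 0")
        m = min(int(window_m), n_bands - 1)
        invalid = _invalid_leading_bands(alpha, m)
    c = gl_coefficients(alpha, m)
    kernel = np.zeros(n_bands)
    kernel[: m + 1] = c
    # Lower-triangular Toeplitz: out[:, i] = sum_k c_k * x[:, i - k]
    op = toeplitz(kernel, np.zeros(n_bands))
    values = x @ op.T
    valid = np.ones(n_bands, dtype=bool)
    valid[:invalid] = False
    return values, valid


@dataclass
class DerivativeStack:
    """Order-indexed stack of differential spectra.

    ``data`` has shape (n_orders, n_samples, n_bands); ``valid`` flags per
    order the bands computable without history truncation.
    """

    orders: np.ndarray
    data: np.ndarray
    valid: np.ndarray
    wavelengths: np.ndarray
    window_m: int | None = None

    def slab(self, alpha: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.orders - alpha)))
        if abs(self.orders[idx] - alpha) > 1e-9:
            raise KeyError(f"order {alpha} not in stack")
        return self.data[idx]


def derivative_stack(
    s: SpectraSet,
    orders=DEFAULT_ORDERS,
    window_m: int | None = None,
) -> DerivativeStack:
    """Apply the fractional derivative at every order (default 0-2 step 0.1)."""
    orders = np.asarray(orders, dtype=float)
    if orders.size == 0:
        raise ValueError("orders must be nonempty")
    data = np.empty((orders.size, s.n_samples, s.n_bands))
    valid = np.empty((orders.size, s.n_bands), dtype=bool)
    for i, a in enumerate(orders):
        data[i], valid[i] = fractional_derivative(s, a, window_m=window_m)
    return DerivativeStack(orders, data, valid, s.wavelengths, window_m)
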