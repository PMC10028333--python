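"""Mittag--Leffler family and the fractional-relaxation building blocks.

The closed-form channel solutions are assembled from three primitives:

* the (two-parameter) Mittag--Leffler function
  ``E_{a,b}(z) = sum_k z^k / Gamma(a k + b)``,
* the Robotnov--Hartley function
  ``F_a(-r, tau) = L^{-1}[1/(q^a + r)] = tau^{a-1} E_{a,a}(-r tau^a)``,
* its convolutions with 1 and with the singular power kernel
  ``h(t) = t^{-a}/Gamma(1-a) = L^{-1}[q^{a-1}]``, which collapse to

      (1 * F_a(-r, .))(tau) = (1 - E_a(-r tau^a)) / r,
      (h * F_a(-r, .))(tau) = E_a(-r tau^a).

Arguments arising in the channel model are real and bounded
(|z| <= r2 tau^a with r2 = a/(1-a)), so a power series with
cancellation monitoring suffices; when alternating-series cancellation
would spoil float64, the sum is redone in mpmath at raised precision.
"""

from __future__ import annotations

import math

import mpmath
import numpy as np
from scipy.special import gammaln, rgamma

__all__ = [
    "ConvergenceError",
    "mittag_leffler",
    "robotnov_hartley",
    "convolve_with_one",
    "convolve_with_h",
]

_MAX_TERMS = 10_000


class ConvergenceError(RuntimeError):
    """Series or quadrature failed to meet tolerance.

    Carries the partial-sum tail estimate in ``tail``.
    """

    def __init__(self, message: str, tail: float | None = None):
        super().__init__(message)
        self.tail = tail


def _ml_series_float(a: float, b: float, z: float,
                     tol: float, n_terms: int) -> tuple[float, float]:
    """Float64 series; returns (sum, largest |term|)."""
    total = 0.0
    biggest = 0.0
    peak = abs(z) ** (1.0 / a) / a   # index where terms start decaying
    term = 1.0 / math.gamma(b)
    for k in range(n_terms):
        total += term
        at = abs(term)
        biggest = max(biggest, at)
        # terms decay monotonically once k is past the peak index
        if at < tol * max(abs(total), 1e-300) and k > peak:
            return total, biggest
        # term_{k+1} = term_k * z * Gamma(ak+b)/Gamma(a(k+1)+b)
        term *= z * math.exp(gammaln(a * k + b) - gammaln(a * (k + 1) + b))
    raise ConvergenceError(
        f"Mittag-Leffler series did not converge in {n_terms} terms",
        tail=abs(term))


def _ml_mpmath(a: float, b: float, z: float, tol: float,
               n_terms: int) -> float:
    # precision sized to the cancellation of the alternating series
    mag = abs(z) ** (1.0 / a) if z != 0 else 0.0   # cancellation scale
    peak = mag / a                                  # term-decay index
    extra = int(mag / math.log(10)) + 10
    with mpmath.workdps(20 + extra):
        za = mpmath.mpf(z)
        am = mpmath.mpf(a)
        bm = mpmath.mpf(b)
        total = mpmath.mpf(0)
        for k in range(n_terms):
            # gamma argument formed at working precision: with 10^16-fold
            # cancellation each term needs accuracy far below float64
            term = za ** k / mpmath.gamma(am * k + bm)
            total += term
            if abs(term) < tol * max(abs(total), mpmath.mpf("1e-300")) and k > peak:
                return float(total)
        raise ConvergenceError(
            f"Mittag-Leffler series did not converge in {n_terms} terms",
            tail=float(abs(term)))


def _ml_asymptotic(a: float, b: float, z: float,
                   tol: float) -> tuple[float, bool]:
    """Large-|z| expansion for z < 0:  sum_k -(z^-k)/Gamma(b - a k).

    The reciprocal gamma handles the poles (terms vanish there).  The
    series is divergent; it is truncated at the smallest term and
    accepted only if that term meets the tolerance.
    """
    total = 0.0
    prev = math.inf
    for k in range(1, 80):
        term = -z ** (-k) * float(rgamma(b - a * k))
        at = abs(term)
        if at == 0.0:
            continue                     # Gamma pole: term vanishes exactly
        if at > prev:
            return total, prev < tol * max(abs(total), 1e-300)
        total += term
        if at < tol * max(abs(total), 1e-300):
            return total, True
        prev = at
    return total, False


def _ml_scalar(a: float, b: float, z: float, tol: float,
               n_terms: int) -> float:
    if a == 1.0 and b == 1.0:
        return math.exp(z)
    if z == 0.0:
        return 1.0 / math.gamma(b)
    # cancellation estimate: largest term ~ exp(|z|^(1/a)) for z < 0
    peak = abs(z) ** (1.0 / a)
    if z < 0 and peak > 9.0:          # float64 would lose > ~4 digits
        value, ok = _ml_asymptotic(a, b, z, tol)
        if ok:
            return value
        return _ml_mpmath(a, b, z, tol, n_terms)
    value, biggest = _ml_series_float(a, b, z, tol, n_terms)
    if biggest * 1e-16 > tol * max(abs(value), 1e-300):
        return _ml_mpmath(a, b, z, tol, n_terms)
    return value


def mittag_leffler(order: float, z, order2: float = 1.0, *,
                   tol: float = 1e-12, n_terms: int = _MAX_TERMS):
    """Two-parameter Mittag--Leffler function E_{order, order2}(z).

    Parameters
    ----------
    order : float
        First parameter, in (0, 1].
    z : float or array_like
        Real argument (negative arguments are the model's use case).
    order2 : float, optional
        Second parameter (default 1 gives the classical function).
    tol : float
        Absolute/relative tail tolerance of the series.
    n_terms : int
        Series truncation cap; exceeding it raises
        :class:`ConvergenceError` with the tail estimate attached.
    """
    if not 0.0 < order <= 1.0:
        raise ValueError(f"order={order} outside (0, 1]")
    if order2 <= 0.0:
        raise ValueError("order2 must be positive")
    zarr = np.asarray(z, dtype=float)
    if zarr.ndim == 0:
        return _ml_scalar(order, order2, float(zarr), tol, n_terms)
    return _ml_array(order, order2, zarr, tol, n_terms)


def _ml_array(a: float, b: float, z: np.ndarray, tol: float,
              n_terms: int) -> np.ndarray:
    """Vectorised series with a term-ratio recurrence (overflow-free)."""
    if a == 1.0 and b == 1.0:
        return np.exp(z)
    flat = z.ravel().copy()
    # heavy-cancellation elements go through the scalar asymptotic /
    # high-precision route; the float recurrence would overflow
    heavy = np.abs(flat) ** (1.0 / a) > 9.0
    heavy_vals = {i: _ml_scalar(a, b, float(flat[i]), tol, n_terms)
                  for i in np.nonzero(heavy)[0]}
    flat[heavy] = 0.0
    total = np.zeros_like(flat)
    biggest = np.zeros_like(flat)
    term = np.full_like(flat, 1.0 / math.gamma(b))
    peak_max = (float(np.max(np.abs(flat))) ** (1.0 / a) / a
                if flat.size else 0.0)
    converged = False
    for k in range(n_terms):
        total += term
        at = np.abs(term)
        np.maximum(biggest, at, out=biggest)
        if k > peak_max and np.all(at < tol * np.maximum(np.abs(total), 1e-300)):
            converged = True
            break
        term *= flat * math.exp(gammaln(a * k + b) - gammaln(a * (k + 1) + b))
    if not converged and np.any(np.abs(term) >= tol * np.maximum(np.abs(total), 1e-300)):
        raise ConvergenceError(
            f"Mittag-Leffler series did not converge in {n_terms} terms",
            tail=float(np.max(np.abs(term))))
    # redo cancellation-spoiled elements at higher precision
    bad = biggest * 1e-16 > tol * np.maximum(np.abs(total), 1e-300)
    for i in np.nonzero(bad)[0]:
        total[i] = _ml_mpmath(a, b, float(flat[i]), tol, n_terms)
    for i, v in heavy_vals.items():
        total[i] = v
    return total.reshape(z.shape)


def robotnov_hartley(order: float, rate: float, tau, *,
                     tol: float = 1e-12, method: str = "ml"):
    """Robotnov--Hartley function F_order(-rate, tau).

    ``F_a(-r, tau) = sum_{n>=0} (-r)^n tau^{(n+1)a - 1} / Gamma((n+1)a)``
    which equals ``tau^{a-1} E_{a,a}(-r tau^a)``.  The kernel is
    singular at tau = 0 for a < 1.

    method : 'ml' (two-parameter Mittag--Leffler route, default) or
             'series' (direct series; retained as the independent dual
             route).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    tarr = np.asarray(tau, dtype=float)
    if np.any(tarr <= 0):
        raise ValueError("tau must be positive (kernel singular at 0)")
    if method == "ml":
        val = tarr ** (order - 1.0) * mittag_leffler(
            order, -rate * tarr ** order, order, tol=tol)
    elif method == "series":
        # sum_{n>=0} (-r)^n tau^{(n+1)a-1}/Gamma((n+1)a)
        def one(t: float) -> float:
            x = -rate * t ** order
            mag = abs(x) ** (1.0 / order) if x != 0 else 0.0
            peak = mag / order
            dps = 20 + int(mag / math.log(10)) + 10
            with mpmath.workdps(dps):
                tm = mpmath.mpf(t)
                om = mpmath.mpf(order)
                rm = mpmath.mpf(rate)
                total = mpmath.mpf(0)
                for n in range(_MAX_TERMS):
                    term = ((-rm) ** n * tm ** ((n + 1) * om - 1)
                            / mpmath.gamma((n + 1) * om))
                    total += term
                    if abs(term) < tol * max(abs(total), mpmath.mpf("1e-300")) and n > peak:
                        return float(total)
                raise ConvergenceError("Robotnov-Hartley series did not "
                                       "converge", tail=float(abs(term)))
        val = (np.vectorize(one)(tarr) if tarr.ndim else one(float(tarr)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return val if np.ndim(tau) else float(val)


def convolve_with_one(order: float, rate: float, tau, *,
                      tol: float = 1e-12):
    """(1 * F_order(-rate, .))(tau) = int_0^tau F_order(-rate, s) ds.

    Closed forms: ``(1 - E_order(-rate tau^order))/rate`` for rate > 0
    and ``tau^order / Gamma(order + 1)`` for rate = 0.
    """
    tarr = np.asarray(tau, dtype=float)
    if np.any(tarr <= 0):
        raise ValueError("tau must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0.0:
        val = tarr ** order / math.gamma(order + 1.0)
    else:
        val = (1.0 - mittag_leffler(order, -rate * tarr ** order, tol=tol)) / rate
    return val if np.ndim(tau) else float(val)


def convolve_with_h(order: float, rate: float, tau, *,
                    tol: float = 1e-12):
    """(h * F_order(-rate, .))(tau) with h(t) = t^{-order}/Gamma(1-order).

    In the Laplace domain this is q^{order-1}/(q^order + rate), whose
    inverse is ``E_order(-rate tau^order)``.  At order = 1 the kernel h
    degenerates to a delta and the value is exp(-rate tau).
    """
    tarr = np.asarray(tau, dtype=float)
    if np.any(tarr <= 0):
        raise ValueError("tau must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if order == 1.0:
        val = np.exp(-rate * tarr)
    else:
        val = mittag_leffler(order, -rate * tarr ** order, tol=tol)
    return val if np.ndim(tau) else float(val)
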