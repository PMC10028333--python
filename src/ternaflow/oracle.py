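"""Independent numerical cross-check of the closed-form solutions.

The per-mode Laplace-domain images of temperature and velocity are
simple rational functions of ``q^alpha``:

    theta_F(n, q) = r5 (q^a + r2) / (q (q^a + r4))
    w_F(n, q)     = [S_n/(r7 sigma_n)] (q^a + r2) / (q (q^a + r8))
                  + [B2 r5 / r7] (q^a + r2)^2 / (q (q^a + r4)(q^a + r8))

with ``S_n = G(1 - (-1)^n) + sigma_n^2 + lam sigma_n^4``.  This module
inverts those images *numerically* (fixed-Talbot contour, with a
de Hoog-class method as a second, fully independent route) and
reassembles the field by the inverse finite sine transform.  Nothing
here reuses the closed-form partial fractions or Mittag--Leffler
evaluations, which makes the comparison an end-to-end check of the
analytic series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import mpmath
import numpy as np

from .solution import FieldProfile, ModeCoefficients, steady_velocity
from .thermophysics import ModelParameters

__all__ = [
    "LaplaceImage",
    "temperature_image",
    "velocity_image",
    "evaluate_image",
    "invert_numerically",
    "invert_talbot",
    "reconstruct_field",
    "convolve_quadrature",
]


@dataclass(frozen=True)
class LaplaceImage:
    """Rational description of a per-mode image over q^alpha."""

    n: int
    alpha: float
    kind: str                       # 'temperature' or 'velocity'
    coeffs: tuple                   # kind-specific coefficient tuple

    def __call__(self, q: complex) -> complex:
        return evaluate_image(self, q)


def temperature_image(mode: ModeCoefficients, alpha: float) -> LaplaceImage:
    return LaplaceImage(mode.n, alpha, "temperature",
                        (mode.r2, mode.r4, mode.r5))


def velocity_image(mode: ModeCoefficients, params: ModelParameters) -> LaplaceImage:
    s = mode.sigma
    stuff = (params.G * (1.0 - (-1.0) ** mode.n)
             + s * s + params.lam * s ** 4)
    return LaplaceImage(mode.n, params.alpha, "velocity",
                        (mode.r2, mode.r4, mode.r5, mode.r7, mode.r8,
                         stuff, s, params.B2))


def evaluate_image(image: LaplaceImage, q: complex) -> complex:
    """Evaluate the printed rational image at Laplace variable q.

    ``q^alpha`` uses the principal branch; points on the negative real
    axis (the branch cut) are rejected.
    """
    q = complex(q)
    if q.real < 0 and q.imag == 0:
        raise ValueError("q on the negative real axis (branch cut)")
    if q == 0:
        raise ValueError("q must be nonzero")
    qa = q ** image.alpha
    if image.kind == "temperature":
        r2, r4, r5 = image.coeffs
        return r5 * (qa + r2) / (q * (qa + r4))
    r2, r4, r5, r7, r8, stuff, s, B2 = image.coeffs
    term1 = (stuff / (r7 * s)) * (qa + r2) / (q * (qa + r8))
    term2 = (B2 * r5 / r7) * (qa + r2) ** 2 / (q * (qa + r4) * (qa + r8))
    return term1 + term2


def _talbot_nodes(tau: float, M: int):
    """Fixed-Talbot contour nodes and weights (Abate--Valko)."""
    r = 2.0 * M / (5.0 * tau)
    theta = np.arange(1, M) * math.pi / M
    cot = 1.0 / np.tan(theta)
    q = r * theta * (cot + 1j)               # contour points, k = 1..M-1
    sigma = theta + (theta * cot - 1.0) * cot
    weight = np.exp(tau * q) * (1.0 + 1j * sigma)
    return r, q, weight


def invert_talbot(fun: Callable[[complex], complex], tau: float,
                  M: int = 32) -> float:
    """Fixed-Talbot numerical inverse Laplace transform at time tau.

    The deformed contour wraps the negative real axis, which keeps the
    branch cut of q^alpha outside; accuracy on smooth images is well
    below 1e-6 relative at the default M.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    r, q, weight = _talbot_nodes(tau, M)
    total = 0.5 * math.exp(r * tau) * complex(fun(complex(r, 0.0))).real
    vals = np.array([complex(fun(complex(qk))) for qk in q])
    total += float(np.sum((weight * vals).real))
    out = total * r / M
    if not math.isfinite(out):
        raise ArithmeticError("Talbot contour overflowed or produced "
                              "non-finite values")
    return out


def invert_numerically(image: Callable[[complex], complex], tau: float,
                       method: str = "talbot", M: int = 32) -> float:
    """Invert a Laplace image at tau by a contour method.

    method : 'talbot' (own fixed-Talbot contour) or 'dehoog'
             (mpmath's de Hoog-class algorithm; slower, used as the
             independent second route).
    """
    if method == "talbot":
        return invert_talbot(image, tau, M=M)
    if method == "dehoog":
        with mpmath.workdps(30):
            val = mpmath.invertlaplace(lambda p: image(complex(p)), tau,
                                       method="dehoog")
        return float(val)
    raise ValueError(f"unknown inversion method {method!r}")


def _batched_talbot_modes(params: ModelParameters, n_modes: int,
                          tau: float, kind: str, M: int) -> np.ndarray:
    """Talbot inversion of all mode images at once (vectorised)."""
    a = params.alpha
    n = np.arange(1, n_modes + 1)
    s = n * math.pi / params.h
    s2, s4 = s * s, s ** 4
    r1 = params.B3 / (1.0 - a)
    r2 = a / (1.0 - a)
    r4 = r2 * s2 / (r1 + s2)
    r5 = s / (r1 + s2)
    r6 = params.B0 / (1.0 - a)
    r7 = r6 + s2 + params.lam * s4
    r8 = (r2 * s2 + params.lam * r2 * s4) / r7

    r, q, weight = _talbot_nodes(tau, M)
    qs = np.concatenate(([complex(r, 0.0)], q))       # (M,)
    w = np.concatenate(([0.5 * math.exp(r * tau)], weight))
    qa = qs ** a                                       # principal branch

    qa_ = qa[None, :]
    q_ = qs[None, :]
    if kind == "temperature":
        F = r5[:, None] * (qa_ + r2) / (q_ * (qa_ + r4[:, None]))
    elif kind == "velocity":
        stuff = params.G * (1.0 - (-1.0) ** n) + s2 + params.lam * s4
        F = ((stuff / (r7 * s))[:, None] * (qa_ + r2)
             / (q_ * (qa_ + r8[:, None]))
             + (params.B2 * r5 / r7)[:, None] * (qa_ + r2) ** 2
             / (q_ * (qa_ + r4[:, None]) * (qa_ + r8[:, None])))
    else:
        raise ValueError(f"unknown field kind {kind!r}")
    vals = (w[None, :] * F).real.sum(axis=1) * r / M
    if not np.all(np.isfinite(vals)):
        raise ArithmeticError("Talbot contour produced non-finite mode values")
    return vals


def reconstruct_field(params: ModelParameters, tau: float, xi_grid,
                      n_modes: int = 300, field_kind: str = "temperature",
                      M: int = 32) -> FieldProfile:
    """Numerically inverted solution on a xi grid.

    The slowly-converging boundary-lifting component (mode value
    ``1/sigma_n`` for both fields, plus the pressure/couple-stress
    permanent modes for velocity) is replaced by its closed form; every
    remaining mode value comes from the numerical inversion, so the
    reconstruction shares no inversion code with the analytic series.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = np.asarray(xi_grid, dtype=float)
    inv = _batched_talbot_modes(params, n_modes, tau, field_kind, M)
    n = np.arange(1, n_modes + 1)
    s = n * math.pi / params.h
    if field_kind == "temperature":
        steady = 1.0 - x / params.h
        lift = 1.0 / s
    else:
        steady = steady_velocity(params, x)
        s2, s4 = s * s, s ** 4
        stuff = params.G * (1.0 - (-1.0) ** n) + s2 + params.lam * s4
        lift = stuff / (s * (s2 + params.lam * s4))
    resid = inv - lift
    series = (2.0 / params.h) * (resid[:, None]
                                 * np.sin(np.outer(n, x) * math.pi / params.h)
                                 ).sum(axis=0)
    return FieldProfile(x, steady + series, tau, field_kind, n_modes)


def convolve_quadrature(order: float, rate: float, tau: float,
                        kernel: str = "one", tol: float = 1e-11) -> float:
    """Direct (singular) quadrature of the convolution integrals.

    Test oracle for the closed forms in :mod:`ternaflow.special`:
    computes ``int_0^tau k(tau - s) F_order(-rate, s) ds`` with k = 1 or
    k = h(t) = t^{-order}/Gamma(1-order), using tanh-sinh quadrature
    which absorbs the algebraic endpoint singularities.  The
    Robotnov--Hartley factor is summed termwise in mpmath, independent
    of the production Mittag--Leffler path.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if kernel not in ("one", "h"):
        raise ValueError("kernel must be 'one' or 'h'")
    with mpmath.workdps(30):
        b = mpmath.mpf(order)
        t = mpmath.mpf(tau)

        def F(sv):
            # direct series for F_order(-rate, s)
            total = mpmath.mpf(0)
            for k in range(500):
                term = ((-rate) ** k * sv ** ((k + 1) * b - 1)
                        / mpmath.gamma((k + 1) * b))
                total += term
                if abs(term) < mpmath.mpf(10) ** -35 and k > 5:
                    break
            return total

        if kernel == "one":
            integrand = F
        else:
            def integrand(sv):
                return (t - sv) ** (-b) / mpmath.gamma(1 - b) * F(sv)

        val = mpmath.quad(integrand, [0, t / 2, t])
        err = abs(mpmath.quad(integrand, [0, t / 3, 2 * t / 3, t]) - val)
        if err > tol * max(1.0, abs(val)):
            raise ArithmeticError(f"quadrature tolerance not met ({err})")
        return float(val)
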