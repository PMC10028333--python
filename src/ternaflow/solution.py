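"""Closed-form fractional temperature and velocity fields.

The dimensionless model on the unit channel xi in [0, 1] is

    B0 D_tau^alpha w = G + w_xixi - lam w_xixixixi + B2 theta,
    B3 D_tau^alpha theta = theta_xixi,

with a unit-step moving hot wall at xi = 0 (w = theta = 1), a resting
ambient wall at xi = 1 (w = theta = 0), couple-stress wall conditions
w_xixi = 0 at both walls, and D_tau^alpha the Atangana--Baleanu
derivative (Mittag--Leffler kernel, normalisation taken as 1).

A finite sine-Fourier transform diagonalises the Dirichlet problem into
modes sigma_n = n pi / h; the Laplace transform then yields per-mode
rational images in q^alpha whose inverses are Mittag--Leffler /
Robotnov--Hartley terms.  This module evaluates those series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .special import ConvergenceError, mittag_leffler
from .thermophysics import ModelParameters

__all__ = [
    "ModeCoefficients",
    "SolutionConfig",
    "FieldProfile",
    "mode_coefficients",
    "steady_velocity",
    "temperature_profile",
    "velocity_profile",
    "classical_limit_profile",
]

logger = logging.getLogger(__name__)

# The energy equation's diffusion term is a second xi-derivative of the
# temperature; a stray field symbol in some statements of the model is
# read that way.  Logged once per process so runs are traceable.
_model_note_emitted = False


def _emit_model_note() -> None:
    global _model_note_emitted
    if not _model_note_emitted:
        logger.info("energy equation read with diffusion term d2(theta)/dxi2; "
                    "wall motion applied as a unit step (w(0, tau)=1 for tau>0)")
        _model_note_emitted = True


@dataclass(frozen=True)
class ModeCoefficients:
    """Per-mode rational coefficients of the Laplace-domain solution.

    With s = sigma_n = n pi / h and alpha < 1:

        r1 = B3/(1-alpha)        r2 = alpha/(1-alpha)
        r3 = r1 + s^2            r4 = r2 s^2 / r3
        r5 = s / r3
        r6 = B0/(1-alpha)        r7 = r6 + s^2 + lam s^4
        r8 = r2 (s^2 + lam s^4) / r7

    A1..A4 are the velocity-series amplitudes.
    """

    n: int
    sigma: float
    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r6: float
    r7: float
    r8: float
    A1: float
    A2: float
    A3: float
    A4: float


def mode_coefficients(params: ModelParameters, n: int) -> ModeCoefficients:
    """Coefficients of Fourier mode ``n`` (alpha < 1 branch).

    At alpha = 1 the (1-alpha) denominators degenerate; use
    :func:`classical_limit_profile` instead.
    """
    if n < 1:
        raise ValueError("mode index n must be >= 1")
    a = params.alpha
    if a >= 1.0:
        raise ValueError("mode coefficients are defined for alpha < 1; "
                         "use the classical-limit path at alpha = 1")
    s = n * math.pi / params.h
    s2 = s * s
    s4 = s2 * s2
    r1 = params.B3 / (1.0 - a)
    r2 = a / (1.0 - a)
    r3 = r1 + s2
    r4 = r2 * s2 / r3
    r5 = s / r3
    r6 = params.B0 / (1.0 - a)
    r7 = r6 + s2 + params.lam * s4
    r8 = (r2 * s2 + params.lam * r2 * s4) / r7
    stuff = params.G * (1.0 - (-1.0) ** n) + s2 + params.lam * s4
    A1 = (stuff / s) * (r8 - r2) / (r7 * r8)
    A2 = params.B2 * r5 / r7
    dr = r4 - r8
    if dr != 0.0:
        A3 = A2 * (r2 - r4) ** 2 / dr
        A4 = A2 * (r2 - r8) ** 2 / dr
    else:                      # resonant mode: amplitudes handled as a limit
        A3 = math.inf
        A4 = math.inf
    return ModeCoefficients(n, s, r1, r2, r3, r4, r5, r6, r7, r8,
                            A1, A2, A3, A4)


@dataclass(frozen=True)
class SolutionConfig:
    """Truncation control for the mode series.

    The series stops once the newest mode's largest possible
    contribution falls below ``series_tol`` and at least ``min_modes``
    modes are summed; ``n_modes`` caps the truncation.
    """

    n_modes: int = 500
    series_tol: float = 1e-9
    h: float = 1.0
    min_modes: int = 20

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.series_tol <= 0:
            raise ValueError("series_tol must be positive")


@dataclass
class FieldProfile:
    """Field samples over an ascending grid xi in [0, 1] at one time."""

    xi_grid: np.ndarray
    values: np.ndarray
    tau: float
    field_kind: str           # 'temperature' or 'velocity'
    n_modes_used: int = 0

    def __post_init__(self) -> None:
        self.xi_grid = np.asarray(self.xi_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.xi_grid.min() < 0 or self.xi_grid.max() > 1:
            raise ValueError("xi grid must lie within [0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "xi": self.xi_grid,
            "value": self.values,
            "tau": np.full_like(self.xi_grid, self.tau),
            "field_kind": [self.field_kind] * len(self.xi_grid),
        })
        df.to_csv(path, index=False, float_format="%.12e")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FieldProfile":
        df = pd.read_csv(path)
        return cls(df["xi"].to_numpy(), df["value"].to_numpy(),
                   float(df["tau"].iloc[0]), str(df["field_kind"].iloc[0]))


def _default_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 41)


def steady_velocity(params: ModelParameters, xi) -> np.ndarray:
    """Steady (permanent) part of the velocity field.

    Solves ``0 = G + w'' - lam w''''`` with w(0)=1, w(1)=0 and
    w''(0)=w''(1)=0 on the unit channel:

        w_p = 1 - xi + G [ xi(1 - xi)/2
              + lam (cosh((xi - 1/2)/sqrt(lam))/cosh(1/(2 sqrt(lam))) - 1) ]

    (for lam = 0 the bracket is the plane-Poiseuille parabola).  The
    buoyancy contribution to the permanent state is carried by the mode
    series, not by this closed form.
    """
    x = np.asarray(xi, dtype=float)
    G = params.G
    lam = params.lam
    base = 1.0 - x
    if G == 0.0:
        return base
    para = x * (1.0 - x) / 2.0
    if lam == 0.0:
        return base + G * para
    sl = math.sqrt(lam)
    cosh_term = np.cosh((x - 0.5) / sl) / math.cosh(0.5 / sl)
    return base + G * (para + lam * (cosh_term - 1.0))


def _sum_modes(coeff_fn: Callable[[np.ndarray], np.ndarray],
               xi: np.ndarray, config: SolutionConfig) -> tuple[np.ndarray, int]:
    """Sum (2/h) sum_n c_n sin(n pi xi / h) with adaptive truncation.

    ``coeff_fn`` maps an array of mode indices to coefficients c_n.
    """
    h = config.h
    total = np.zeros_like(xi)
    block = 25
    n_done = 0
    last_max = math.inf
    while n_done < config.n_modes:
        n = np.arange(n_done + 1, min(n_done + block, config.n_modes) + 1)
        c = coeff_fn(n)
        total = total + (2.0 / h) * (c[:, None] *
                                     np.sin(np.outer(n, xi) * math.pi / h)).sum(axis=0)
        n_done = int(n[-1])
        last_max = 2.0 / h * float(np.max(np.abs(c[-min(5, len(c)):])))
        if last_max < config.series_tol and n_done >= config.min_modes:
            return total, n_done
    if last_max >= config.series_tol:
        raise ConvergenceError(
            f"mode series not converged after {n_done} modes",
            tail=last_max)
    return total, n_done


def _mode_arrays(params: ModelParameters, n: np.ndarray):
    """Vectorised r coefficients for an array of mode indices."""
    a = params.alpha
    s = n * math.pi / params.h
    s2 = s * s
    s4 = s2 * s2
    r1 = params.B3 / (1.0 - a)
    r2 = a / (1.0 - a)
    r3 = r1 + s2
    r4 = r2 * s2 / r3
    r5 = s / r3
    r6 = params.B0 / (1.0 - a)
    r7 = r6 + s2 + params.lam * s4
    r8 = (r2 * s2 + params.lam * r2 * s4) / r7
    return s, s2, s4, r1, r2, r3, r4, r5, r6, r7, r8


def temperature_profile(params: ModelParameters, tau: float,
                        xi=None, config: SolutionConfig | None = None,
                        ) -> FieldProfile:
    """Temperature field theta(xi, tau).

    theta = (1 - xi) + (2/h) sum_n [r5 (r4 - r2)/r4] E_alpha(-r4 tau^alpha)
            sin(sigma_n xi)

    The boundary values theta(0) = 1 and theta(1) = 0 are exact (the
    sine series vanishes at the walls).
    """
    _emit_model_note()
    if tau <= 0:
        raise ValueError("tau must be positive")
    config = config or SolutionConfig()
    x = _default_grid() if xi is None else np.asarray(xi, dtype=float)
    if params.alpha == 1.0:
        return classical_limit_profile(params, tau, x, config,
                                       field_kind="temperature")

    a = params.alpha
    r1s = params.B3 / (1.0 - a)
    r2s = a / (1.0 - a)
    e_inf = mittag_leffler(a, -r2s * tau ** a)

    def coeffs(n: np.ndarray) -> np.ndarray:
        s, _, _, r1, r2, r3, r4, r5, *_ = _mode_arrays(params, n)
        ml = mittag_leffler(a, -r4 * tau ** a)
        # large-n asymptote -r1 E_alpha(-r2 tau^alpha)/sigma_n^3 is
        # summed in closed form below; only the 1/n^5 residue remains
        return r5 * (r4 - r2) / r4 * ml + (r1 / s ** 3) * e_inf

    series, used = _sum_modes(coeffs, x, config)
    values = (1.0 - x / params.h) + series \
        - 2.0 * e_inf * r1s * _sine_cubed_sum(x) / math.pi ** 3
    return FieldProfile(x, values, tau, "temperature", used)


def _sine_cubed_sum(x: np.ndarray) -> np.ndarray:
    """sum_n sin(n pi x)/n^3 = pi^2 y/6 - pi y^2/4 + y^3/12, y = pi x."""
    y = math.pi * x
    return math.pi ** 2 * y / 6.0 - math.pi * y * y / 4.0 + y ** 3 / 12.0


def _transient_velocity_coeffs(params: ModelParameters, n: np.ndarray,
                               tau: float) -> np.ndarray:
    """Per-mode transient + buoyancy coefficient of the velocity series."""
    a = params.alpha
    s, s2, s4, r1, r2, r3, r4, r5, r6, r7, r8 = _mode_arrays(params, n)
    ta = tau ** a
    ml8 = mittag_leffler(a, -r8 * ta)
    stuff = params.G * (1.0 - (-1.0) ** n) + s2 + params.lam * s4
    A1 = (stuff / s) * (r8 - r2) / (r7 * r8)
    A2 = params.B2 * r5 / r7
    # bracket = 1 - [(r2-r4)^2 g(r4) - (r2-r8)^2 g(r8)] / (r4 - r8),
    # g(r) = (1 - E_alpha(-r tau^alpha)) / r; finite limit when r4 -> r8
    g4 = (1.0 - mittag_leffler(a, -r4 * ta)) / r4
    g8 = (1.0 - ml8) / r8
    dr = r4 - r8
    near = np.abs(dr) < 1e-9 * np.maximum(r4, r8)
    bracket = np.empty_like(r4)
    safe = ~near
    bracket[safe] = 1.0 - ((r2 - r4[safe]) ** 2 * g4[safe]
                           - (r2 - r8[safe]) ** 2 * g8[safe]) / dr[safe]
    if np.any(near):
        # derivative of f(r) = (r2 - r)^2 g(r) at r4 via central difference
        for i in np.nonzero(near)[0]:
            r = r4[i]
            eps = max(1e-6 * r, 1e-9)
            def f(rr: float) -> float:
                return ((r2 - rr) ** 2
                        * (1.0 - mittag_leffler(a, -rr * ta)) / rr)
            bracket[i] = 1.0 - (f(r + eps) - f(r - eps)) / (2.0 * eps)
    return A1 * ml8 + A2 * bracket


def velocity_profile(params: ModelParameters, tau: float,
                     xi=None, config: SolutionConfig | None = None,
                     ) -> FieldProfile:
    """Velocity field w(xi, tau) = steady part + transient mode series.

    Each mode combines a wall/pressure relaxation
    ``A1 (h * F_alpha(-r8, .))`` with the buoyancy response
    ``A2 - A3 (1 * F_alpha(-r4, .)) + A4 (1 * F_alpha(-r8, .))``.
    Boundary values w(0) = 1 and w(1) = 0 are exact.
    """
    _emit_model_note()
    if tau <= 0:
        raise ValueError("tau must be positive")
    config = config or SolutionConfig()
    x = _default_grid() if xi is None else np.asarray(xi, dtype=float)
    if params.alpha == 1.0:
        return classical_limit_profile(params, tau, x, config,
                                       field_kind="velocity")

    # without couple stress the transient coefficients decay only like
    # (B2 - r6 E_alpha(-r2 tau^alpha))/sigma_n^3; sum that asymptote in
    # closed form so the residual series converges at 1/n^5
    cinf = 0.0
    if params.lam == 0.0:
        a = params.alpha
        r2s = a / (1.0 - a)
        r6s = params.B0 / (1.0 - a)
        cinf = params.B2 - r6s * float(
            mittag_leffler(a, -r2s * tau ** a))

    def coeffs(n: np.ndarray) -> np.ndarray:
        c = _transient_velocity_coeffs(params, n, tau)
        if cinf:
            c = c - cinf / (n * math.pi / params.h) ** 3
        return c

    series, used = _sum_modes(coeffs, x, config)
    values = steady_velocity(params, x) + series \
        + 2.0 * cinf * _sine_cubed_sum(x) / math.pi ** 3
    return FieldProfile(x, values, tau, "velocity", used)


def classical_limit_profile(params: ModelParameters, tau: float,
                            xi=None, config: SolutionConfig | None = None,
                            *, field_kind: str = "temperature",
                            ) -> FieldProfile:
    """Integer-order (alpha = 1) solution, evaluated on its own path.

    The alpha -> 1 limits replace the Mittag--Leffler relaxations with
    exponentials: per-mode decay rates are sigma_n^2/B3 (temperature)
    and (sigma_n^2 + lam sigma_n^4)/B0 (velocity).
    """
    _emit_model_note()
    if tau <= 0:
        raise ValueError("tau must be positive")
    config = config or SolutionConfig()
    x = _default_grid() if xi is None else np.asarray(xi, dtype=float)
    h = params.h

    if field_kind == "temperature":
        def coeffs(n: np.ndarray) -> np.ndarray:
            s = n * math.pi / h
            return -np.exp(-(s * s) * tau / params.B3) / s

        series, used = _sum_modes(coeffs, x, config)
        return FieldProfile(x, (1.0 - x / h) + series, tau,
                            "temperature", used)

    if field_kind != "velocity":
        raise ValueError(f"unknown field kind {field_kind!r}")

    lam = params.lam
    # lam = 0: buoyancy modes decay like B2/sigma_n^3 with no exponential
    # damping; sum the asymptote in closed form (cf. velocity_profile)
    cinf = params.B2 if lam == 0.0 else 0.0

    def coeffs(n: np.ndarray) -> np.ndarray:
        s = n * math.pi / h
        s2 = s * s
        s4 = s2 * s2
        stuff = params.G * (1.0 - (-1.0) ** n) + s2 + lam * s4
        rt4 = s2 / params.B3
        rt8 = (s2 + lam * s4) / params.B0
        A1 = -stuff / (s * (s2 + lam * s4))
        wall = A1 * np.exp(-rt8 * tau)
        drt = rt4 - rt8
        C = params.B2 * s / (params.B3 * params.B0)
        cone4 = (1.0 - np.exp(-rt4 * tau)) / rt4
        cone8 = (1.0 - np.exp(-rt8 * tau)) / rt8
        with np.errstate(divide="ignore", invalid="ignore"):
            buoy = C * (cone8 - cone4) / drt
        near = np.abs(drt) < 1e-12 * np.maximum(rt4, rt8)
        if np.any(near):
            # limit of (cone(r) - cone(r'))/(r' - r) as r' -> r
            r = rt4[near]
            buoy[near] = C[near] * ((1.0 - np.exp(-r * tau)) / r ** 2
                                    - tau * np.exp(-r * tau) / r)
        return wall + buoy - cinf / s ** 3

    series, used = _sum_modes(coeffs, x, config)
    values = (steady_velocity(params, x) + series
              + 2.0 * cinf * _sine_cubed_sum(x) / math.pi ** 3)
    return FieldProfile(x, values, tau, "velocity", used)
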