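"""Thermophysical mixture correlations for ternary hybrid nanofluids.

A ternary (tri-hybrid) nanofluid is a base fluid carrying three
nanoparticle species at volume fractions ``phi1, phi2, phi3``.  Bulk
properties (density, heat capacitance, thermal expansion) follow linear
mixture rules; effective viscosity and thermal conductivity are
shape-dependent: each species contributes through an empirical
polynomial viscosity correlation and a Hamilton--Crosser-type
conductivity ratio, and the suspension value is the volume-fraction
weighted mean of the per-species ratios.

All mixture quantities are expressed as dimensionless ratios against
the base-fluid property (the ``chi`` coefficients); the momentum and
energy equations only ever see these ratios, folded into the derived
groups ``B0..B3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Shape",
    "MaterialProperties",
    "MixtureState",
    "ModelParameters",
    "BLOOD",
    "FE3O4",
    "ZN",
    "AU",
    "DEFAULT_MATERIALS",
    "mixture_ratio_density",
    "mixture_ratio_heat_capacity",
    "mixture_ratio_expansion",
    "shape_viscosity_ratio",
    "shape_conductivity_ratio",
    "maxwell_conductivity_ratio",
    "assemble_mixture",
    "dimensionless_groups",
    "load_materials_csv",
    "save_materials_csv",
]


class Shape:
    """Correlation-set labels for suspended particles.

    The label selects the viscosity polynomial and the
    Hamilton--Crosser coefficient used for a species; it is a modelling
    choice carried by each material record.
    """

    SPHERICAL = "spherical"
    CYLINDRICAL = "cylindrical"
    PLATELET = "platelet"
    BASE_FLUID = "base_fluid"

    ALL = (SPHERICAL, CYLINDRICAL, PLATELET, BASE_FLUID)


# viscosity polynomial (a, b) in 1 + a*phi + b*phi**2, and
# Hamilton-Crosser coefficient c in (kp + c*kbf + c*phi*(kp-kbf)) /
#                                   (kp + c*kbf -   phi*(kp-kbf))
_VISCOSITY_POLY = {
    Shape.SPHERICAL: (2.5, 6.2),
    Shape.CYLINDRICAL: (13.5, 904.4),
    Shape.PLATELET: (37.1, 612.6),
}
_CONDUCTIVITY_COEFF = {
    Shape.SPHERICAL: 2.0,
    Shape.CYLINDRICAL: 3.9,
    Shape.PLATELET: 4.7,
}


@dataclass(frozen=True)
class MaterialProperties:
    """Density / conductivity / heat-capacity / expansion record.

    Parameters
    ----------
    name : str
        Species label.
    rho : float
        Density, kg/m^3.
    k : float
        Thermal conductivity, W/(m K).
    cp : float
        Specific heat, J/(kg K).
    beta_T : float
        Thermal expansion coefficient, 1/K (any common scale; only
        ratios against the base fluid enter the model).
    shape : str
        One of :class:`Shape` -- selects the correlation set.
    """

    name: str
    rho: float
    k: float
    cp: float
    beta_T: float
    shape: str = Shape.SPHERICAL

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.k <= 0 or self.cp <= 0 or self.beta_T <= 0:
            raise ValueError(
                f"material {self.name!r}: rho, k, cp, beta_T must be positive"
            )
        if self.shape not in Shape.ALL:
            raise ValueError(
                f"material {self.name!r}: unknown shape {self.shape!r}; "
                f"expected one of {Shape.ALL}"
            )

    @property
    def rho_cp(self) -> float:
        return self.rho * self.cp

    @property
    def rho_beta(self) -> float:
        return self.rho * self.beta_T


# Built-in fixture: blood base fluid and the three default species.
# The correlation-set assignment pairs Fe3O4 with the spherical set,
# Zn with the cylindrical set and Au with the platelet set; this is the
# pairing the model's chi-coefficients define and the one its reference
# heat-transfer tabulations are built on.  Assignments are configurable
# through user-supplied material records.
BLOOD = MaterialProperties("blood", rho=1053.0, k=0.492, cp=3594.0, beta_T=0.8,
                           shape=Shape.BASE_FLUID)
FE3O4 = MaterialProperties("Fe3O4", rho=5200.0, k=6.0, cp=670.0, beta_T=1.3,
                           shape=Shape.SPHERICAL)
ZN = MaterialProperties("Zn", rho=7140.0, k=116.0, cp=389.0, beta_T=3.5,
                        shape=Shape.CYLINDRICAL)
AU = MaterialProperties("Au", rho=19300.0, k=318.0, cp=129.0, beta_T=1.41,
                        shape=Shape.PLATELET)

DEFAULT_MATERIALS = (BLOOD, FE3O4, ZN, AU)


def _validate_fractions(phi: Sequence[float]) -> float:
    for p in phi:
        if p < 0:
            raise ValueError(f"negative volume fraction {p}")
    total = float(sum(phi))
    if total >= 1.0:
        raise ValueError(f"total volume fraction {total} must be < 1")
    return total


def mixture_ratio_density(phi1: float, phi2: float, phi3: float,
                          materials: Sequence[MaterialProperties] = DEFAULT_MATERIALS,
                          ) -> float:
    """chi1: mixture density over base-fluid density (linear rule)."""
    _validate_fractions((phi1, phi2, phi3))
    bf, s1, s2, s3 = materials
    return ((1.0 - phi1 - phi2 - phi3)
            + phi1 * s1.rho / bf.rho
            + phi2 * s2.rho / bf.rho
            + phi3 * s3.rho / bf.rho)


def mixture_ratio_heat_capacity(phi1: float, phi2: float, phi3: float,
                                materials: Sequence[MaterialProperties] = DEFAULT_MATERIALS,
                                ) -> float:
    """chi7: mixture (rho*Cp) over base-fluid (rho*Cp)."""
    _validate_fractions((phi1, phi2, phi3))
    bf, s1, s2, s3 = materials
    return ((1.0 - phi1 - phi2 - phi3)
            + phi1 * s1.rho_cp / bf.rho_cp
            + phi2 * s2.rho_cp / bf.rho_cp
            + phi3 * s3.rho_cp / bf.rho_cp)


def mixture_ratio_expansion(phi1: float, phi2: float, phi3: float,
                            materials: Sequence[MaterialProperties] = DEFAULT_MATERIALS,
                            ) -> float:
    """chi6: mixture (rho*beta_T) over base-fluid (rho*beta_T)."""
    _validate_fractions((phi1, phi2, phi3))
    bf, s1, s2, s3 = materials
    return ((1.0 - phi1 - phi2 - phi3)
            + phi1 * s1.rho_beta / bf.rho_beta
            + phi2 * s2.rho_beta / bf.rho_beta
            + phi3 * s3.rho_beta / bf.rho_beta)


def shape_viscosity_ratio(shape: str, phi: float) -> float:
    """Effective-viscosity ratio mu_nf/mu_bf for one correlation set.

    spherical:   1 + 2.5 phi + 6.2 phi^2
    cylindrical: 1 + 13.5 phi + 904.4 phi^2
    platelet:    1 + 37.1 phi + 612.6 phi^2
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"volume fraction {phi} outside [0, 1)")
    try:
        a, b = _VISCOSITY_POLY[shape]
    except KeyError:
        raise ValueError(f"unknown particle shape {shape!r}") from None
    return 1.0 + a * phi + b * phi * phi


def shape_conductivity_ratio(shape: str, phi: float,
                             k_particle: float, k_bf: float) -> float:
    """Hamilton--Crosser-type conductivity ratio k_nf/k_bf.

    The coefficient c is 2 (spherical), 3.9 (cylindrical) or 4.7
    (platelet):

        (kp + c kbf + c phi (kp - kbf)) / (kp + c kbf - phi (kp - kbf))
    """
    if k_particle <= 0 or k_bf <= 0:
        raise ValueError("conductivities must be positive")
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"volume fraction {phi} outside [0, 1)")
    try:
        c = _CONDUCTIVITY_COEFF[shape]
    except KeyError:
        raise ValueError(f"unknown particle shape {shape!r}") from None
    dk = k_particle - k_bf
    den = k_particle + c * k_bf - phi * dk
    if den <= 0:
        raise ValueError("conductivity-ratio denominator non-positive")
    return (k_particle + c * k_bf + c * phi * dk) / den


def maxwell_conductivity_ratio(phi: float, k_particle: float, k_bf: float,
                               n: float = 3.0) -> float:
    """General Maxwell / Hamilton--Crosser ratio with shape factor n.

    ``n = 3/psi`` where psi is sphericity (n = 3 recovers spheres).
    Provided as a helper; the pipeline uses the shape-specific
    correlations of :func:`shape_conductivity_ratio`.
    """
    if k_particle <= 0 or k_bf <= 0:
        raise ValueError("conductivities must be positive")
    dk = k_particle - k_bf
    den = k_particle + (n - 1.0) * k_bf - phi * dk
    if den <= 0:
        raise ValueError("conductivity-ratio denominator non-positive")
    return (k_particle + (n - 1.0) * k_bf + (n - 1.0) * phi * dk) / den


@dataclass(frozen=True)
class MixtureState:
    """Volume fractions plus the derived chi ratios of the suspension.

    chi1  : density ratio
    chi2-4: per-species viscosity ratios (evaluated at phi_hnf)
    chi5  : suspension viscosity ratio (phi-weighted mean of chi2..chi4)
    chi6  : thermal-expansion (rho*beta) ratio
    chi7  : heat-capacitance (rho*Cp) ratio
    chi8-10: per-species conductivity ratios (at phi_hnf)
    chi11 : suspension conductivity ratio (weighted mean of chi8..chi10)
    """

    phi1: float
    phi2: float
    phi3: float
    chi1: float
    chi2: float
    chi3: float
    chi4: float
    chi5: float
    chi6: float
    chi7: float
    chi8: float
    chi9: float
    chi10: float
    chi11: float
    materials: tuple = DEFAULT_MATERIALS

    @property
    def phi_hnf(self) -> float:
        return self.phi1 + self.phi2 + self.phi3


def assemble_mixture(phi1: float, phi2: float, phi3: float,
                     materials: Sequence[MaterialProperties] = DEFAULT_MATERIALS,
                     ) -> MixtureState:
    """Compute every chi ratio for a ternary suspension.

    The per-species viscosity and conductivity polynomials are evaluated
    at the *total* fraction ``phi_hnf``; the suspension ratios chi5 and
    chi11 are the fraction-weighted means, defined as 1 in the pure
    base-fluid limit (continuous at phi_hnf = 0).
    """
    phi_hnf = _validate_fractions((phi1, phi2, phi3))
    bf, s1, s2, s3 = materials

    chi1 = mixture_ratio_density(phi1, phi2, phi3, materials)
    chi6 = mixture_ratio_expansion(phi1, phi2, phi3, materials)
    chi7 = mixture_ratio_heat_capacity(phi1, phi2, phi3, materials)

    chi2 = shape_viscosity_ratio(s1.shape, phi_hnf)
    chi3 = shape_viscosity_ratio(s2.shape, phi_hnf)
    chi4 = shape_viscosity_ratio(s3.shape, phi_hnf)
    chi8 = shape_conductivity_ratio(s1.shape, phi_hnf, s1.k, bf.k)
    chi9 = shape_conductivity_ratio(s2.shape, phi_hnf, s2.k, bf.k)
    chi10 = shape_conductivity_ratio(s3.shape, phi_hnf, s3.k, bf.k)

    if phi_hnf == 0.0:
        chi5 = 1.0
        chi11 = 1.0
    else:
        chi5 = (chi2 * phi1 + chi3 * phi2 + chi4 * phi3) / phi_hnf
        chi11 = (chi8 * phi1 + chi9 * phi2 + chi10 * phi3) / phi_hnf

    return MixtureState(phi1, phi2, phi3, chi1, chi2, chi3, chi4, chi5,
                        chi6, chi7, chi8, chi9, chi10, chi11,
                        tuple(materials))


@dataclass(frozen=True)
class ModelParameters:
    """Dimensionless parameters of the channel-flow model.

    alpha        : fractional order of the time derivative, in (0, 1]
    beta_casson  : Casson parameter (> 0); momentum diffusivity carries
                   a (1 + 1/beta) factor absorbed into B0
    lam          : couple-stress parameter (>= 0), coefficient of the
                   fourth-order velocity derivative
    G            : dimensionless axial pressure gradient
    Gr, Pr, Re   : Grashof, Prandtl and Reynolds numbers
    h            : dimensionless channel height (fixed 1; the walls map
                   to xi = 0 and xi = 1)
    B0..B3       : derived coefficients,
                   B0 = Re chi1 / (beta chi5), B1 = chi6/chi5,
                   B2 = B1 Gr / beta,          B3 = Pr chi7 Re / chi11
    """

    alpha: float
    beta_casson: float
    lam: float
    G: float
    Gr: float
    Pr: float
    Re: float
    h: float
    B0: float
    B1: float
    B2: float
    B3: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"fractional order alpha={self.alpha} outside (0, 1]")
        if self.B0 <= 0 or self.B3 <= 0:
            raise ValueError("B0 and B3 must be positive")
        if self.lam < 0:
            raise ValueError("couple-stress parameter lam must be >= 0")
        if self.h != 1.0:
            raise ValueError("only the unit dimensionless channel height "
                             "h = 1 is supported")


def dimensionless_groups(mixture: MixtureState, *, alpha: float,
                         beta_casson: float, lam: float, G: float,
                         Gr: float, Pr: float, Re: float,
                         h: float = 1.0) -> ModelParameters:
    """Fold mixture ratios and flow groups into the B coefficients.

    Gr has no independently assigned velocity/length scales in this
    model and is therefore always a direct input.
    """
    if beta_casson <= 0:
        raise ValueError("Casson parameter beta must be positive")
    if mixture.chi5 <= 0 or mixture.chi11 <= 0:
        raise ValueError("mixture ratios chi5, chi11 must be positive")
    B0 = Re * mixture.chi1 / (beta_casson * mixture.chi5)
    B1 = mixture.chi6 / mixture.chi5
    B2 = B1 * Gr / beta_casson
    B3 = Pr * mixture.chi7 * Re / mixture.chi11
    return ModelParameters(alpha=alpha, beta_casson=beta_casson, lam=lam,
                           G=G, Gr=Gr, Pr=Pr, Re=Re, h=h,
                           B0=B0, B1=B1, B2=B2, B3=B3)


_CSV_COLUMNS = ["name", "rho", "k", "cp", "beta_T", "shape"]


def save_materials_csv(path: str | Path,
                       materials: Iterable[MaterialProperties]) -> None:
    """Write material records as CSV (columns name,rho,k,cp,beta_T,shape)."""
    rows = [{"name": m.name, "rho": m.rho, "k": m.k, "cp": m.cp,
             "beta_T": m.beta_T, "shape": m.shape} for m in materials]
    # pandas' default shortest-repr float formatting round-trips bit-exactly
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def load_materials_csv(path: str | Path) -> tuple[MaterialProperties, ...]:
    """Read material records written by :func:`save_materials_csv`."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"material table missing columns {sorted(missing)}")
    return tuple(
        MaterialProperties(str(r["name"]), float(r["rho"]), float(r["k"]),
                           float(r["cp"]), float(r["beta_T"]), str(r["shape"]))
        for _, r in df.iterrows()
    )
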