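"""Closed-form / quadrature terms of the staged-restraint binding cycle.

In the free state the dimer partners tumble independently, so the cost of
imposing the orientational restraint u_o(Θ, Φ, Ψ) is an analytic average over
an isotropic orientation distribution,

    exp(−β ΔG_o^free) = (1/8π²) ∫₀^π sinΘ dΘ ∫₀^{2π} dΦ ∫₀^{2π} dΨ e^{−β u_o},

and the axial-angle restraints u_a(θ, ϕ) enter through the effective angular
surface available to the separated partner at radius r*,

    S* = r*² ∫₀^π sinθ e^{−β kθ(θ−θ0)²/2} dθ · ∫₀^{2π} e^{−β kϕ(ϕ−ϕ0)²/2} dϕ.

Both integrands are separable, so each is evaluated as a product of 1-D
Gauss–Legendre quadratures (401 nodes per factor by default): dense enough
for the stiff k ≈ 1000 kcal/mol/rad² Gaussians while reproducing the exact
k = 0 normalization.  Dihedral factors integrate over the stated [0, 2π]
domain with the integrand evaluated through the minimum-image wrap, so
centers quoted on (−π, π] (e.g. Ψ₀ = −2.38) are covered.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import wrap_angle
from .thermo import ThermoContext, standard_volume

__all__ = [
    "dg_o_free",
    "dg_o_free_stiff",
    "s_star",
    "standard_volume",
    "r_star_shift",
    "QUAD_NODES",
]

#: Default number of Gauss–Legendre nodes per 1-D factor.
QUAD_NODES = 401


def _gauss_legendre(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (b - a)
    return a + half * (x + 1.0), half * w


def _gaussian_factor(
    k: float, center: float, beta: float, lo: float, hi: float,
    jacobian_sin: bool, wrap: bool, nodes: int,
) -> float:
    """∫ [sin x] exp(−β k Δ²/2) dx over [lo, hi], Δ wrapped for dihedrals."""
    x, w = _gauss_legendre(lo, hi, nodes)
    delta = wrap_angle(x - center) if wrap else (x - center)
    integrand = np.exp(-beta * 0.5 * k * np.square(delta))
    if jacobian_sin:
        integrand = integrand * np.sin(x)
    return float(np.dot(w, integrand))


def dg_o_free(
    k_Theta: float, k_Phi: float, k_Psi: float,
    Theta0: float, Phi0: float, Psi0: float,
    thermo: ThermoContext | None = None,
    nodes: int = QUAD_NODES,
) -> float:
    """Free-state orientational restraint free energy (kcal/mol).

    Parameters are the three harmonic spring constants (kcal/mol/rad²) and
    centers (rad) of u_o(Θ, Φ, Ψ).  All-zero spring constants give exactly 0
    (the integral reduces to the 8π² normalization).
    """
    thermo = thermo or ThermoContext()
    beta = thermo.beta
    i_theta = _gaussian_factor(k_Theta, Theta0, beta, 0.0, math.pi, True, False, nodes)
    i_phi = _gaussian_factor(k_Phi, Phi0, beta, 0.0, 2.0 * math.pi, False, True, nodes)
    i_psi = _gaussian_factor(k_Psi, Psi0, beta, 0.0, 2.0 * math.pi, False, True, nodes)
    integral = i_theta * i_phi * i_psi / (8.0 * math.pi**2)
    return -thermo.kT * math.log(integral)


def dg_o_free_stiff(
    k_Theta: float, k_Phi: float, k_Psi: float,
    Theta0: float, Phi0: float, Psi0: float,
    thermo: ThermoContext | None = None,
) -> float:
    """Stiff-spring (Gaussian) closed form of :func:`dg_o_free`.

    Valid when each k ≫ kT: the sinΘ Jacobian is frozen at Θ₀ and each
    Gaussian integrates to √(2πkT/k) over the full line,

        ΔG ≈ −kT ln[ sinΘ₀ (2πkT)^{3/2} / (8π² √(kΘ kΦ kΨ)) ].
    """
    thermo = thermo or ThermoContext()
    kT = thermo.kT
    num = math.sin(Theta0) * (2.0 * math.pi * kT) ** 1.5
    den = 8.0 * math.pi**2 * math.sqrt(k_Theta * k_Phi * k_Psi)
    return -kT * math.log(num / den)


def s_star(
    r_star: float,
    k_theta: float, k_phi: float,
    theta0: float, phi0: float,
    thermo: ThermoContext | None = None,
    nodes: int = QUAD_NODES,
) -> float:
    """Effective angular surface S* (Å²) at separation radius r*.

    In the limit k_theta = k_phi = 0 this is the full sphere 4π r*².
    """
    if r_star < 0:
        raise ValueError("r_star must be non-negative")
    thermo = thermo or ThermoContext()
    beta = thermo.beta
    i_theta = _gaussian_factor(k_theta, theta0, beta, 0.0, math.pi, True, False, nodes)
    i_phi = _gaussian_factor(k_phi, phi0, beta, 0.0, 2.0 * math.pi, False, True, nodes)
    return r_star**2 * i_theta * i_phi


def r_star_shift(r_new: float, r_ref: float, thermo: ThermoContext | None = None) -> float:
    """Change (kcal/mol) in the angular-surface contribution when the axial
    restraint is evaluated at ``r_new`` instead of ``r_ref``.

    The accessible surface grows as r², so the shift is kT·ln(r_new²/r_ref²):
    positive when moving outward, negative inward — an asymmetric sensitivity
    of the assembled binding free energy to the arbitrary choice of r*.
    """
    if r_new <= 0 or r_ref <= 0:
        raise ValueError("radii must be positive")
    thermo = thermo or ThermoContext()
    return thermo.kT * math.log(r_new**2 / r_ref**2)
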