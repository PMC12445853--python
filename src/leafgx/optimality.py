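"""Eco-evolutionary optimality predictions for the acclimated leaf.

Three optimality principles are combined:

1. **Least-cost ratio of internal to ambient CO2.**  The time-averaged
   optimum χ = c_i : c_a minimises the summed unit costs of maintaining
   transpiration and carboxylation capacity,

       χ = Γ*/c_a + (1 − Γ*/c_a) ξ / (ξ + √D),
       ξ = sqrt( β (K + Γ*) / (1.6 η*) ),

   with D the vapour pressure deficit (Pa), β the carboxylation :
   transpiration unit-cost ratio and η* the water viscosity relative to
   25 degC.

2. **Coordination of capacities.**  V_cmax acclimates so that the
   Rubisco- and RuBP-limited rates are equal at the acclimated
   c_i = χ c_a under growth light, and J_max is set where the marginal
   carbon return of extra electron-transport capacity equals its
   maintenance cost c_jmax.  With the non-rectangular hyperbolic light
   response (curvature θ) this optimum has the closed form

       ω  = −(1 − 2θ) + sqrt((1 − θ)(1/(c̄(1 − θ c̄)) − 4θ)),  c̄ = 4 c_jmax/m
       ω* = 1 + ω − sqrt((1 + ω)² − 4θω)
       A  = φ0 I m ω*/(2θ),   J_max = 4 φ0 I ω,   V_cmax = A / m_C,

   where m = (c_i − Γ*)/(c_i + 2Γ*) and m_C = (c_i − Γ*)/(c_i + K).
   (The simpler light-use-efficiency correction sqrt(1 − (c*/m)^(2/3))
   is available as ``jmax_method="wang17"``.)

3. **Instantaneous stomatal optimisation.**  On sub-acclimation
   timescales the leaf adjusts g_s at fixed biochemistry to maximise
   carbon gain net of the marginal cost of transpiration,
   F(g_s) = A(g_s) − λ E(g_s), with λ (µmol CO2 per mol H2O) diagnosed
   from the coordinated growth state so that an unperturbed leaf is a
   fixed point of the optimisation.

Stomatal conductances in this module's public API are to *water vapour*
(mol m-2 s-1), matching how operational g_s is reported in the gas
exchange literature; conversion to CO2 conductance (÷1.6) is internal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import (
    EnvironmentState,
    PhotoConstants,
    ValidationError,
    gamma_star,
    michaelis_k,
    viscosity_ratio,
)
from .photosynthesis import (
    SolverError,
    electron_transport,
    net_assimilation,
    solve_ci,
)

__all__ = [
    "OptimalityTerms",
    "AcclimatedState",
    "chi_optimal",
    "acclimated_state",
    "acclimated_vcmax",
    "acclimated_jmax",
    "lue_assimilation",
    "acclimated_gs",
    "marginal_water_cost",
    "instantaneous_gs",
]

#: Diffusivity ratio of water vapour to CO2 through stomata.
H2O_CO2_DIFFUSIVITY = 1.6
#: Absolute tolerance of the golden-section g_s optimisation, mol m-2 s-1.
GS_XATOL = 1e-8
#: Grid size of the pre-bracketing scan for the g_s optimisation.
GS_PREBRACKET_N = 240


@dataclass(frozen=True)
class OptimalityTerms:
    """Least-cost optimum for one environment.

    xi : sensitivity of χ to √VPD, Pa^0.5
    chi : optimal c_i : c_a ratio, dimensionless
    m : CO2 limitation factor of light-limited assimilation at χ c_a
    ci_acclim : acclimated internal CO2, Pa
    """

    xi: float
    chi: float
    m: float
    ci_acclim: float


@dataclass(frozen=True)
class AcclimatedState:
    """Fully coordinated leaf at one growth environment."""

    terms: OptimalityTerms
    a_leaf: float    # µmol CO2 m-2 s-1
    vcmax: float     # µmol m-2 s-1
    jmax: float      # µmol e- m-2 s-1
    j: float         # operating electron transport at growth light
    gs: float        # stomatal conductance to water vapour, mol m-2 s-1


def chi_optimal(env: EnvironmentState,
                constants: PhotoConstants | None = None) -> OptimalityTerms:
    """Least-cost optimal χ and its ingredients for one environment."""
    c = constants or PhotoConstants()
    gstar = gamma_star(env.temp_c, env.patm, c)
    k = michaelis_k(env.temp_c, env.patm, c)
    nstar = viscosity_ratio(env.temp_c)
    xi = math.sqrt(c.beta * (k + gstar) / (H2O_CO2_DIFFUSIVITY * nstar))
    ca = env.ca_pa
    g_over_ca = gstar / ca
    chi = g_over_ca + (1.0 - g_over_ca) * xi / (xi + math.sqrt(env.vpd))
    ci = chi * ca
    m = (ci - gstar) / (ci + 2.0 * gstar)
    return OptimalityTerms(xi=xi, chi=chi, m=m, ci_acclim=ci)


def _capacity_factors(m: float, c: PhotoConstants) -> tuple[float, float]:
    """Return (lue_factor, jmax_over_jlim): the J_max-cost correction of the
    light-limited rate A = φ0 I m · lue_factor, and J_max/(4 φ0 I)."""
    if c.jmax_method == "wang17":
        arg = 1.0 - (c.cstar_wang17 / m) ** (2.0 / 3.0)
        if arg <= 0.0:
            return 0.0, 0.0
        return math.sqrt(arg), 1.0 / math.sqrt(1.0 / arg - 1.0)
    # smith19-style optimum of the non-rectangular hyperbola
    theta = c.theta
    cbar = 4.0 * c.c_jmax / m
    v = 1.0 / (cbar * (1.0 - theta * cbar)) - 4.0 * theta
    if v <= 0.0 or cbar * theta >= 1.0:
        return 0.0, 0.0
    omega = -(1.0 - 2.0 * theta) + math.sqrt((1.0 - theta) * v)
    omega_star = 1.0 + omega - math.sqrt((1.0 + omega) ** 2 - 4.0 * theta * omega)
    return omega_star / (2.0 * theta), omega


def acclimated_state(env: EnvironmentState,
                     constants: PhotoConstants | None = None) -> AcclimatedState:
    """All coordinated traits for one growth environment.

    The returned state satisfies, by construction, A_c = A_j = A_leaf at
    c_i = χ c_a with J evaluated from the returned J_max at growth light,
    and the diffusion identity g_s^CO2 (c_a − c_i)/P = A_leaf.
    """
    c = constants or PhotoConstants()
    if env.ppfd <= 0:
        raise ValidationError("acclimation requires ppfd > 0")
    terms = chi_optimal(env, c)
    gstar = gamma_star(env.temp_c, env.patm, c)
    k = michaelis_k(env.temp_c, env.patm, c)
    ci = terms.ci_acclim
    m = terms.m
    mc = (ci - gstar) / (ci + k)
    lue_factor, jmax_over_jlim = _capacity_factors(m, c)
    if lue_factor <= 0.0:
        warnings.warn("light environment cannot pay J_max maintenance costs; "
                      "assimilation set to zero", RuntimeWarning, stacklevel=2)
        a = 0.0
        jmax = j = float("nan")
        gs = 0.0
    else:
        a = c.phi0 * env.ppfd * m * lue_factor
        jmax = 4.0 * c.phi0 * env.ppfd * jmax_over_jlim
        j = electron_transport(env.ppfd, jmax, c)
        gs = H2O_CO2_DIFFUSIVITY * a * env.patm / ((env.ca_pa - ci) * 1e6)
    vcmax = a / mc
    return AcclimatedState(terms=terms, a_leaf=a, vcmax=vcmax, jmax=jmax,
                           j=j, gs=gs)


def acclimated_vcmax(env: EnvironmentState,
                     constants: PhotoConstants | None = None) -> float:
    """Coordination-hypothesis V_cmax (A_c = A_j at c_i = χ c_a), µmol m-2 s-1."""
    return acclimated_state(env, constants).vcmax


def acclimated_jmax(env: EnvironmentState,
                    constants: PhotoConstants | None = None) -> float:
    """Optimal J_max co-acclimating with V_cmax, µmol e- m-2 s-1."""
    return acclimated_state(env, constants).jmax


def lue_assimilation(env: EnvironmentState,
                     constants: PhotoConstants | None = None) -> float:
    """Acclimated assimilation A_leaf = φ0 I m ω*/(2θ), µmol CO2 m-2 s-1."""
    if env.ppfd == 0:
        return 0.0
    return acclimated_state(env, constants).a_leaf


def acclimated_gs(env: EnvironmentState,
                  constants: PhotoConstants | None = None) -> float:
    """Acclimated stomatal conductance to water vapour, mol m-2 s-1.

    Diffusion identity at the coordinated state:
    g_s = 1.6 A_leaf P / (c_a − χ c_a), expressed per mole fraction.
    """
    return acclimated_state(env, constants).gs


def marginal_water_cost(env: EnvironmentState,
                        constants: PhotoConstants | None = None) -> float:
    """Marginal water-use efficiency λ = ∂A/∂E (µmol CO2 per mol H2O).

    Evaluated at the coordinated state on the RuBP-limited side of the
    co-limitation point (the operative branch for small stomatal
    excursions under unchanged biochemistry).  Tied to β through the
    least-cost state itself: using this λ in the instantaneous stomatal
    optimisation makes the coordinated leaf an exact fixed point.
    """
    c = constants or PhotoConstants()
    st = acclimated_state(env, c)
    gstar = gamma_star(env.temp_c, env.patm, c)
    ci = st.terms.ci_acclim
    ca = env.ca_pa
    # demand slope on the RuBP branch, µmol m-2 s-1 Pa-1
    fprime = (st.j / 4.0) * 3.0 * gstar / (ci + 2.0 * gstar) ** 2
    gs_co2 = st.gs / H2O_CO2_DIFFUSIVITY
    supply_slope = gs_co2 * 1e6 / env.patm  # µmol m-2 s-1 Pa-1
    # chain rule through the supply-demand equilibrium: dA/d(gs_co2)
    dci_dg = (ca - ci) * 1e6 / env.patm / (fprime + supply_slope)
    da_dg = fprime * dci_dg  # µmol CO2 per (mol m-2 s-1 of CO2 conductance)
    # E = 1.6 gs_co2 D / P  (mol H2O m-2 s-1)
    de_dg = H2O_CO2_DIFFUSIVITY * env.vpd / env.patm
    return da_dg / de_dg


def instantaneous_gs(env: EnvironmentState, vcmax_fixed: float, j_fixed: float,
                     constants: PhotoConstants | None = None,
                     lam: float | None = None,
                     gs_hi: float | None = None) -> float:
    """Optimal instantaneous stomatal conductance at fixed biochemistry.

    Maximises F(g_s) = A(g_s) − λ E(g_s) over g_s ∈ (0, gs_hi], where
    A(g_s) solves the FvCB supply-demand intersection at fixed V_cmax and
    J, E = g_s D / P is transpiration per unit leaf area (g_s already on
    a water-vapour basis) and λ is the marginal water cost.  When ``lam``
    is omitted it is diagnosed from the coordinated state of ``env``.

    Derivative-free and deterministic: a grid pre-bracketing scan
    followed by bounded golden-section refinement.  If the objective is
    monotone on the interval the boundary is returned with a warning.
    """
    c = constants or PhotoConstants()
    if vcmax_fixed <= 0:
        raise ValidationError("vcmax_fixed must be positive")
    if lam is None:
        lam = marginal_water_cost(env, c)
    if gs_hi is None:
        gs_hi = 10.0 * acclimated_gs(env, c)

    def objective(gs_w: float) -> float:
        ci = solve_ci(gs_w / H2O_CO2_DIFFUSIVITY, env, vcmax_fixed, j_fixed, c)
        a = net_assimilation(ci, vcmax_fixed, j_fixed, c,
                             env.temp_c, env.patm).a_net
        e = gs_w * env.vpd / env.patm
        return a - lam * e

    lo = gs_hi * 1e-6
    grid = np.linspace(lo, gs_hi, GS_PREBRACKET_N)
    vals = np.array([objective(g) for g in grid])
    k = int(np.argmax(vals))
    if k == 0 or k == len(grid) - 1:
        warnings.warn("instantaneous g_s objective is monotone on the search "
                      "interval; boundary returned", RuntimeWarning,
                      stacklevel=2)
        return float(grid[k])
    res = minimize_scalar(lambda g: -objective(g),
                          bounds=(grid[k - 1], grid[k + 1]),
                          method="bounded",
                          options={"xatol": GS_XATOL})
    return float(res.x)
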