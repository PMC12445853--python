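"""FvCB demand curve, stomatal supply function and the coupled c_i solver.

The biochemical demand for CO2 is the Farquhar-von Caemmerer-Berry model,
A = min(A_c, A_j): the Rubisco-limited rate

    A_c = V_cmax (c_i - Γ*) / (c_i + K)

and the RuBP-regeneration-limited rate

    A_j = (J/4) (c_i - Γ*) / (c_i + 2Γ*),

with J from a non-rectangular hyperbolic light response saturating at
J_max.  TPU limitation is omitted (negligible under the conditions
modelled) and dark respiration is excluded from A by default (optional
``rd_fraction`` subtracts a fixed fraction of V_cmax).

Stomata supply CO2 down the mole-fraction gradient,

    A = g_s^CO2 (c_a - c_i) / P_atm,

with g_s expressed as conductance to CO2 (mol m-2 s-1).  The operating
c_i is the unique intersection of demand and supply, found by bracketed
Brent root-finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import (
    EnvironmentState,
    PhotoConstants,
    gamma_star,
    michaelis_k,
)

__all__ = [
    "AssimilationResult",
    "SolverError",
    "assimilation_rubisco",
    "assimilation_rubp",
    "electron_transport",
    "net_assimilation",
    "supply_rate",
    "solve_ci",
]

#: Lower bracket offset above Γ* for the c_i root search, Pa.
CI_BRACKET_EPS = 1e-6
#: Relative tolerance of the Brent solve on c_i.
CI_RTOL = 1e-12
#: Maximum Brent iterations.
CI_MAXITER = 200


class SolverError(RuntimeError):
    """Raised when the supply-demand intersection cannot be bracketed."""


@dataclass(frozen=True)
class AssimilationResult:
    """Net assimilation with its limiting-process diagnosis.

    ``a_net = min(a_c, a_j)`` (µmol CO2 m-2 s-1); ties are labelled
    ``"rubisco"`` for determinism.
    """

    a_net: float
    limitation: str  # "rubisco" | "rubp"
    a_c: float
    a_j: float


def assimilation_rubisco(ci_pa: float, vcmax: float,
                         constants: PhotoConstants,
                         temp_c: float, patm: float) -> float:
    """Rubisco-limited (carboxylation-limited) assimilation rate.

    Negative below the compensation point (valid sub-compensation state,
    never an exception); saturates at ``vcmax`` for large c_i.
    """
    gs_pa = gamma_star(temp_c, patm, constants)
    k = michaelis_k(temp_c, patm, constants)
    return vcmax * (ci_pa - gs_pa) / (ci_pa + k)


def assimilation_rubp(ci_pa: float, j: float,
                      constants: PhotoConstants,
                      temp_c: float, patm: float) -> float:
    """RuBP-regeneration-limited assimilation rate; saturates at J/4."""
    gs_pa = gamma_star(temp_c, patm, constants)
    return (j / 4.0) * (ci_pa - gs_pa) / (ci_pa + 2.0 * gs_pa)


def electron_transport(ppfd: float, jmax: float,
                       constants: PhotoConstants) -> float:
    """Electron-transport rate J (µmol e- m-2 s-1) at irradiance ``ppfd``.

    Non-rectangular hyperbola in the light-limited rate 4 φ0 I and the
    capacity J_max with curvature θ:

        θ J² − (4 φ0 I + J_max) J + 4 φ0 I J_max = 0   (lower root)

    φ0 is on a CO2 basis, so the light-limited gross rate is φ0·I = J/4
    at low light.
    """
    if ppfd < 0:
        raise ValueError("ppfd must be non-negative")
    if jmax <= 0:
        raise ValueError("jmax must be positive")
    jlim = 4.0 * constants.phi0 * ppfd
    if jlim == 0.0:
        return 0.0
    theta = constants.theta
    b = jlim + jmax
    disc = b * b - 4.0 * theta * jlim * jmax
    return (b - math.sqrt(disc)) / (2.0 * theta)


def net_assimilation(ci_pa: float, vcmax: float, j: float,
                     constants: PhotoConstants,
                     temp_c: float, patm: float) -> AssimilationResult:
    """Net assimilation A = min(A_c, A_j) minus optional dark respiration."""
    a_c = assimilation_rubisco(ci_pa, vcmax, constants, temp_c, patm)
    a_j = assimilation_rubp(ci_pa, j, constants, temp_c, patm)
    rd = constants.rd_fraction * vcmax
    if a_c <= a_j:
        return AssimilationResult(a_c - rd, "rubisco", a_c - rd, a_j - rd)
    return AssimilationResult(a_j - rd, "rubp", a_c - rd, a_j - rd)


def supply_rate(ci_pa: float, gs_co2: float, env: EnvironmentState) -> float:
    """Stomatal CO2 supply g_s (c_a - c_i)/P, µmol m-2 s-1.

    ``gs_co2`` is conductance to CO2 in mol m-2 s-1; the mole-fraction
    driving force (c_a - c_i)/P_atm is scaled to µmol mol-1.
    """
    return gs_co2 * (env.ca_pa - ci_pa) / env.patm * 1e6


def solve_ci(gs_co2: float, env: EnvironmentState, vcmax: float, j: float,
             constants: PhotoConstants) -> float:
    """Operating leaf-internal CO2 partial pressure (Pa).

    Solves demand(c_i) = supply(c_i) on [Γ*+ε, c_a].  The demand curve is
    strictly increasing and the supply line strictly decreasing in c_i,
    so the root is unique; Brent's method converges within the bracket.

    Raises
    ------
    SolverError
        If no sign change exists on the bracket (e.g. gs_co2 <= 0).
    """
    if gs_co2 <= 0:
        raise SolverError(f"gs_co2 must be positive, got {gs_co2}")
    gstar = gamma_star(env.temp_c, env.patm, constants)
    ca = env.ca_pa
    lo = gstar + CI_BRACKET_EPS
    hi = ca
    if lo >= hi:
        raise SolverError(
            f"ambient CO2 ({ca:.3f} Pa) is at or below the compensation "
            f"point ({gstar:.3f} Pa); no operating point exists")

    def residual(ci: float) -> float:
        a = net_assimilation(ci, vcmax, j, constants, env.temp_c, env.patm).a_net
        return a - supply_rate(ci, gs_co2, env)

    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo > 0 and r_hi > 0:
        raise SolverError(
            "no supply-demand intersection in [gamma_star, ca]: demand "
            f"exceeds supply everywhere (residuals {r_lo:.3g}, {r_hi:.3g})")
    if r_lo < 0 and r_hi < 0:
        # Demand below supply even at the compensation point: the leaf
        # operates at (numerically) ci -> ca only if supply vanishes first.
        raise SolverError(
            "no supply-demand intersection in [gamma_star, ca]: supply "
            f"exceeds demand everywhere (residuals {r_lo:.3g}, {r_hi:.3g})")
    return float(brentq(residual, lo, hi, rtol=CI_RTOL, maxiter=CI_MAXITER))
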