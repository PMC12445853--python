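"""Stepwise replay of an environmental perturbation across trait timescales.

A scenario is a single instantaneous step change in ambient CO2 and/or
VPD.  The engine advances the leaf through five labelled states, each the
equilibrium after one further class of traits has had time to respond:

====  =======================  ===================  =========================
step  label                    timescale            what adjusts
====  =======================  ===================  =========================
0     initial_optimum          —                    nothing (coordinated leaf)
1     instantaneous            seconds              c_i (and hence A) only
2     stomatal_physiology      minutes              g_s at fixed biochemistry
3     biochemical_acclimation  weeks                V_cmax, J_max; g_s follows
4     anatomical_development   seasonal and longer  g_smax (new leaves)
====  =======================  ===================  =========================

Between steps the leaf-internal CO2 is always re-solved from the FvCB
demand / stomatal supply intersection, so every state is a physically
consistent operating point.  Step 2 clips the stomatal optimum at the
anatomical ceiling g_smax; step 4 rebuilds g_smax so that the operational
g_s : g_smax ratio returns to the conservative γ, which closes the loop:
the step-4 state equals a freshly coordinated leaf at the new environment.

Stomatal conductances in ``LeafState`` are to water vapour (mol m-2 s-1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable

import pandas as pd

from .constants import EnvironmentState, PhotoConstants, ValidationError
from .optimality import (
    H2O_CO2_DIFFUSIVITY,
    acclimated_state,
    chi_optimal,
    instantaneous_gs,
    marginal_water_cost,
)
from .photosynthesis import (
    SolverError,
    electron_transport,
    net_assimilation,
    solve_ci,
)

__all__ = [
    "LeafState",
    "ScenarioStep",
    "TimeLapse",
    "ScenarioError",
    "STEP_LABELS",
    "STEP_TIMESCALES",
    "TRAIT_COLUMNS",
    "initial_state",
    "run_scenario",
    "gsmax_from_operational",
    "normalize_timelapse",
    "percent_changes",
    "timelapse_frame",
]

STEP_LABELS = (
    "initial_optimum",
    "instantaneous",
    "stomatal_physiology",
    "biochemical_acclimation",
    "anatomical_development",
)
STEP_TIMESCALES = ("initial", "seconds", "minutes", "weeks",
                   "seasonal and longer")

#: Trait columns exported in time-lapse tables (order matters for output).
TRAIT_COLUMNS = ("a_leaf", "chi_opt", "ci", "gs", "vcmax", "jmax", "gsmax",
                 "ratio_ci", "ratio_gs")


class ScenarioError(RuntimeError):
    """A stage of the scenario failed; the message names the stage."""


@dataclass(frozen=True)
class LeafState:
    """Trait vector of the leaf at one scenario step.

    ci : leaf-internal CO2 partial pressure, Pa
    gs : operational stomatal conductance to water vapour, mol m-2 s-1
    vcmax, jmax : biochemical capacities, µmol m-2 s-1
    gsmax : anatomical maximum stomatal conductance (water), mol m-2 s-1
    chi_opt : least-cost optimal c_i:c_a for the current environment
    a_leaf : net assimilation, µmol CO2 m-2 s-1
    """

    ci: float
    gs: float
    vcmax: float
    jmax: float
    gsmax: float
    chi_opt: float
    a_leaf: float
    gs_clipped: bool = False  # True if step-2 optimum exceeded g_smax

    def ratio_ci(self, env: EnvironmentState) -> float:
        """(c_i : c_a) / χ_optimal — recomputed, never stored stale."""
        return (self.ci / env.ca_pa) / self.chi_opt

    def ratio_gs(self) -> float:
        """g_s : g_smax — recomputed, never stored stale."""
        return self.gs / self.gsmax


@dataclass(frozen=True)
class ScenarioStep:
    index: int
    label: str
    timescale: str
    env: EnvironmentState
    leaf: LeafState

    def row(self) -> dict:
        leaf = self.leaf
        return {
            "step_index": self.index,
            "step_label": self.label,
            "timescale": self.timescale,
            "a_leaf": leaf.a_leaf,
            "chi_opt": leaf.chi_opt,
            "ci": leaf.ci,
            "gs": leaf.gs,
            "vcmax": leaf.vcmax,
            "jmax": leaf.jmax,
            "gsmax": leaf.gsmax,
            "ratio_ci": leaf.ratio_ci(self.env),
            "ratio_gs": leaf.ratio_gs(),
        }


@dataclass
class TimeLapse:
    """Ordered scenario steps plus per-trait normalized series."""

    scenario: str
    steps: list[ScenarioStep]
    constants: PhotoConstants
    normalized: dict[str, list[float]] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {"scenario": self.scenario,
             "constants": asdict(self.constants),
             "env0": asdict(self.steps[0].env),
             "env1": asdict(self.steps[-1].env)},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _state_from_acclimation(env: EnvironmentState,
                            constants: PhotoConstants,
                            gsmax: float | None = None) -> LeafState:
    st = acclimated_state(env, constants)
    gs = st.gs
    if gsmax is None:
        gsmax = gsmax_from_operational(gs, constants.gamma_ratio)
    return LeafState(ci=st.terms.ci_acclim, gs=gs, vcmax=st.vcmax,
                     jmax=st.jmax, gsmax=gsmax, chi_opt=st.terms.chi,
                     a_leaf=st.a_leaf)


def initial_state(env: EnvironmentState,
                  constants: PhotoConstants | None = None) -> LeafState:
    """Fully coordinated leaf: the step-0 optimum.

    By construction ratio_ci = 1 and ratio_gs = γ.
    """
    c = constants or PhotoConstants()
    return _state_from_acclimation(env, c)


def gsmax_from_operational(gs_operational: float, gamma_ratio: float) -> float:
    """Anatomical maximum conductance from the operational setpoint and γ."""
    if gs_operational <= 0:
        raise ValidationError("gs_operational must be positive")
    if not 0 < gamma_ratio < 1:
        raise ValidationError("gamma_ratio must lie in (0, 1)")
    return gs_operational / gamma_ratio


def _check_perturbation(env0: EnvironmentState, env1: EnvironmentState) -> None:
    if (env0.temp_c != env1.temp_c or env0.ppfd != env1.ppfd
            or env0.patm != env1.patm):
        raise ScenarioError(
            "only ca and/or vpd perturbations are supported: temperature, "
            "light and pressure must match between env0 and env1")


def run_scenario(env0: EnvironmentState, env1: EnvironmentState,
                 constants: PhotoConstants | None = None,
                 scenario: str = "custom") -> TimeLapse:
    """Replay the five-step trait response to an environmental step change.

    Stage semantics (see module docstring): the marginal water cost λ of
    the stomatal optimisation is diagnosed once at the pre-perturbation
    coordinated state, so a null perturbation is an exact fixed point.
    """
    c = constants or PhotoConstants()
    _check_perturbation(env0, env1)

    def resolve_ci(env, vcmax, jmax, gs_w, stage):
        try:
            j = electron_transport(env.ppfd, jmax, c)
            ci = solve_ci(gs_w / H2O_CO2_DIFFUSIVITY, env, vcmax, j, c)
            a = net_assimilation(ci, vcmax, j, c, env.temp_c, env.patm).a_net
            return ci, a, j
        except (SolverError, ValidationError) as exc:
            raise ScenarioError(f"stage '{stage}' failed: {exc}") from exc

    # step 0 — coordinated leaf at env0
    try:
        leaf0 = initial_state(env0, c)
        lam0 = marginal_water_cost(env0, c)
    except (SolverError, ValidationError) as exc:
        raise ScenarioError(f"stage 'initial_optimum' failed: {exc}") from exc

    # step 1 — environment jumps; all traits frozen; c_i re-equilibrates
    ci1, a1, j1 = resolve_ci(env1, leaf0.vcmax, leaf0.jmax, leaf0.gs,
                             "instantaneous")
    chi1 = chi_optimal(env1, c).chi
    leaf1 = LeafState(ci=ci1, gs=leaf0.gs, vcmax=leaf0.vcmax,
                      jmax=leaf0.jmax, gsmax=leaf0.gsmax, chi_opt=chi1,
                      a_leaf=a1)

    # step 2 — stomatal aperture re-optimised at fixed biochemistry,
    # clipped at the anatomical ceiling
    try:
        gs2 = instantaneous_gs(env1, leaf0.vcmax, j1, c, lam=lam0,
                               gs_hi=10.0 * leaf0.gsmax)
    except (SolverError, ValidationError) as exc:
        raise ScenarioError(f"stage 'stomatal_physiology' failed: {exc}") from exc
    clipped = gs2 > leaf0.gsmax
    gs2 = min(gs2, leaf0.gsmax)
    ci2, a2, _ = resolve_ci(env1, leaf0.vcmax, leaf0.jmax, gs2,
                            "stomatal_physiology")
    leaf2 = LeafState(ci=ci2, gs=gs2, vcmax=leaf0.vcmax, jmax=leaf0.jmax,
                      gsmax=leaf0.gsmax, chi_opt=chi1, a_leaf=a2,
                      gs_clipped=clipped)

    # step 3 — biochemistry acclimates to env1; g_s re-coordinates with it
    # (g_smax still the old anatomy)
    try:
        leaf3 = _state_from_acclimation(env1, c, gsmax=leaf0.gsmax)
    except (SolverError, ValidationError) as exc:
        raise ScenarioError(
            f"stage 'biochemical_acclimation' failed: {exc}") from exc
    if leaf3.gs > leaf3.gsmax:
        ci3, a3, _ = resolve_ci(env1, leaf3.vcmax, leaf3.jmax, leaf0.gsmax,
                                "biochemical_acclimation")
        leaf3 = LeafState(ci=ci3, gs=leaf0.gsmax, vcmax=leaf3.vcmax,
                          jmax=leaf3.jmax, gsmax=leaf0.gsmax,
                          chi_opt=leaf3.chi_opt, a_leaf=a3, gs_clipped=True)

    # step 4 — new leaves rebuild g_smax so that g_s : g_smax returns to γ
    leaf4 = _state_from_acclimation(env1, c)

    envs = (env0, env1, env1, env1, env1)
    leaves = (leaf0, leaf1, leaf2, leaf3, leaf4)
    steps = [ScenarioStep(i, STEP_LABELS[i], STEP_TIMESCALES[i], envs[i],
                          leaves[i]) for i in range(5)]
    return normalize_timelapse(TimeLapse(scenario=scenario, steps=steps,
                                         constants=c))


def normalize_timelapse(timelapse: TimeLapse) -> TimeLapse:
    """Attach per-trait series normalized to their scenario maximum.

    Each trait is divided by its own maximum across the steps, so every
    normalized series lies in [0, 1] with maximum exactly 1.
    """
    if not timelapse.steps:
        raise ValidationError("cannot normalize an empty time lapse")
    rows = [s.row() for s in timelapse.steps]
    normalized: dict[str, list[float]] = {}
    for trait in TRAIT_COLUMNS:
        series = [r[trait] for r in rows]
        peak = max(series)
        if peak <= 0:
            raise ValidationError(
                f"trait {trait!r} has non-positive maximum; cannot normalize")
        normalized[trait] = [v / peak for v in series]
    timelapse.normalized = normalized
    return timelapse


def percent_changes(timelapse: TimeLapse) -> pd.DataFrame:
    """Per-trait relative change across consecutive steps, in percent.

    Computed on full-precision values; rounding happens only in reports.
    """
    rows = []
    step_rows = [s.row() for s in timelapse.steps]
    for k in range(len(step_rows) - 1):
        for trait in TRAIT_COLUMNS:
            v0, v1 = step_rows[k][trait], step_rows[k + 1][trait]
            rows.append({
                "scenario": timelapse.scenario,
                "transition": f"{k}-{k + 1}",
                "trait": trait,
                "percent_change": 100.0 * (v1 - v0) / v0,
            })
    return pd.DataFrame(rows)


def timelapse_frame(timelapse: TimeLapse) -> pd.DataFrame:
    """Long-format table: one row per step x trait, raw and normalized."""
    records = []
    for step in timelapse.steps:
        row = step.row()
        for trait in TRAIT_COLUMNS:
            records.append({
                "scenario": timelapse.scenario,
                "step_index": step.index,
                "step_label": step.label,
                "timescale": step.timescale,
                "trait": trait,
                "value": row[trait],
                "normalized_value":
                    timelapse.normalized[trait][step.index]
                    if timelapse.normalized else float("nan"),
            })
    return pd.DataFrame(records)
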