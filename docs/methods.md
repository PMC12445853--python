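# Methods

## Scope and philosophy

`leafgx` models a single C₃ leaf whose traits are, on a long enough
timescale, optimally coordinated with its environment, and asks how that
coordination is re-established after an instantaneous environmental step
change.  The framework is state-to-state: each scenario step is the
equilibrium once one further class of traits (internal CO₂ → stomatal
aperture → biochemical capacities → stomatal anatomy) has had time to
respond.  No continuous-time dynamics, diurnal cycles, canopy structure,
soil moisture, nutrient limitation or whole-plant hydraulics are
represented; leaf temperature equals air temperature.

## Photosynthesis (demand)

FvCB with two limitations:

* Rubisco: A_c = V_cmax (c_i − Γ*)/(c_i + K), K = K_c(1 + pO₂/K_o).
* RuBP regeneration: A_j = (J/4)(c_i − Γ*)/(c_i + 2Γ*).

A = min(A_c, A_j); ties are labelled "rubisco" for deterministic output.
Triose-phosphate-utilisation limitation is omitted (relevant only at very
high CO₂/low temperature) and dark respiration is excluded from A_leaf by
default (`rd_fraction` subtracts a fixed fraction of V_cmax when set).
Mesophyll conductance is not modelled: c_i is treated as the substrate
concentration at the chloroplast.

J follows the non-rectangular hyperbola
θJ² − (4φ₀I + J_max)J + 4φ₀I·J_max = 0 (lower root), where φ₀ is the
intrinsic quantum yield on a CO₂ basis, so 4φ₀I is the light-limited
electron transport rate.

Temperature responses of Γ*, K_c, K_o are Bernacchi-style Arrhenius
functions of the 25 °C values (4.332, 39.97 and 27480 Pa at standard
pressure; activation energies 37 830, 79 430 and 36 380 J mol⁻¹); the
25 °C values scale linearly with pressure, and pO₂ = 0.2095 P.  The water
viscosity ratio η* uses the Vogel–Fulcher–Tammann correlation
η ∝ 10^(247.8/(T−140 K)); only the ratio to 25 °C enters.

## Supply and units

Stomatal supply is A = g_s^CO₂ (c_a − c_i)/P with the mole-fraction
driving force.  Internally all gas concentrations are partial pressures
(Pa); ppm appears only at the interface.  Public stomatal conductances
are to **water vapour** (mol m⁻² s⁻¹), the unit in which operational g_s
is usually reported; the CO₂ conductance used by the solver is g_s/1.6.
The operating c_i is found by Brent's method on [Γ* + 10⁻⁶ Pa, c_a] with
relative tolerance 10⁻¹²; the demand curve is strictly increasing and the
supply line strictly decreasing, so the root is unique.

## Acclimated optimum

* **χ (least-cost).**  χ = Γ*/c_a + (1 − Γ*/c_a)·ξ/(ξ + √D),
  ξ = √(β(K + Γ*)/(1.6η*)), with D in Pa (the config accepts kPa at the
  CLI and converts).  β = 146 is the standard unit-cost ratio; with the
  Bernacchi constants this puts χ at 0.75 for a temperate reference leaf
  (25 °C, D = 1 kPa, 400 ppm) and 0.69 at D = 2 kPa.
* **V_cmax (coordination).**  A_c = A_j at c_i = χc_a under growth light.
* **J_max (marginal cost).**  J_max is set where the marginal return of
  additional electron-transport capacity equals its maintenance cost
  c_J = 0.05336.  For the non-rectangular hyperbola this optimum has a
  closed form: with c̄ = 4c_J/m and m = (c_i − Γ*)/(c_i + 2Γ*),

      ω  = −(1 − 2θ) + √((1 − θ)(1/(c̄(1 − θc̄)) − 4θ)),
      ω* = 1 + ω − √((1 + ω)² − 4θω),
      A_leaf = φ₀ I m ω*/(2θ),  J_max = 4φ₀ I ω,  V_cmax = A_leaf/m_C,

  with θ = 0.85 and m_C = (c_i − Γ*)/(c_i + K).  By construction the
  returned state satisfies A_c = A_j = A_leaf exactly, and the diffusion
  identity gives the acclimated g_s = 1.6·A_leaf·P/(c_a − χc_a) per mole
  fraction.  An alternative capacity correction,
  A = φ₀Im√(1 − (c*/m)^{2/3}) with c* = 0.41, is available as
  `jmax_method="wang17"`; the ω/ω* form is the default because its
  acclimation responses (V_cmax −23 % under doubled CO₂, +3.6 % under
  doubled VPD at the reference leaf) match the behaviour this simulator
  is designed to exhibit, whereas the alternative damps the CO₂
  downregulation to −15 %.
* **φ₀.**  Default 0.034959 mol CO₂ mol⁻¹ photons, frozen once by
  calibrating the reference leaf to A_leaf = 13.9 µmol m⁻² s⁻¹ — a
  typical unstressed temperate value — under the default constants.
  Overridable in the config like every other constant.
* **γ.**  Plants typically operate near 25 % of their anatomical maximum
  stomatal conductance; g_smax = g_s/γ with γ = 0.25 by default.

## Instantaneous stomatal optimisation

Between acclimation events the leaf controls only g_s.  It maximises
F(g_s) = A(g_s) − λE(g_s), where A(g_s) re-solves the supply–demand
intersection at fixed V_cmax and J, E = g_s·D/P is transpiration per leaf
area, and λ (µmol CO₂ per mol H₂O) is the marginal water-use efficiency
∂A/∂E diagnosed at the coordinated growth state on the RuBP-limited side
of the co-limitation point.  Diagnosing λ from the β-based optimum ties
the fast and slow optimisations together: a leaf whose biochemistry is
already coordinated has its instantaneous optimum exactly at the
acclimated g_s, so a null perturbation is a fixed point of the whole
pipeline.  The optimiser is derivative-free and deterministic: a 240-point
pre-bracketing scan over (0, g_hi] followed by bounded golden-section
refinement (absolute tolerance 10⁻⁸ mol m⁻² s⁻¹); a monotone objective
returns the boundary with a warning.  The min(A_c, A_j) kink makes the
objective piecewise smooth but still unimodal, which the scan-then-refine
scheme handles.

The marginal-λ formulation was chosen over minimising the full unit-cost
ratio (aE + bV_cmax)/A at fixed V_cmax: on the Rubisco-limited branch the
latter is degenerate (V_cmax cancels and the optimum collapses to the
acclimated χc_a, leaving no distinct minute-scale state), and on the
RuBP-limited branch it prices water so steeply that stomata overshoot far
below the acclimated optimum.  The λ model keeps the minute-scale
response partial — closing toward, but not to, the new optimum — which is
the behaviour the timescale separation is meant to expose.

## Scenario engine

Only c_a and/or VPD may differ between env0 and env1 (temperature, light
and pressure perturbations are rejected: the acclimation rules for those
drivers involve additional processes this version does not model).
Steps: (1) re-solve c_i with all traits frozen; (2) g_s ← instantaneous
optimum at fixed biochemistry with λ from step 0, clipped at g_smax (a
`gs_clipped` flag records when the anatomical ceiling binds); (3) V_cmax
and J_max ← acclimated to env1, g_s ← re-coordinated (the diffusion
identity at the new optimum), still clipped at the old g_smax;
(4) g_smax ← g_s/γ.  Step 4 therefore reproduces `initial_state(env1)`
to numerical precision, which is property-tested for random perturbations
up to ±3× in both drivers.

Per-trait series are normalized by their scenario maximum (per trait,
per scenario), giving values in [0, 1] with the maximum exactly 1.
Percent changes are computed on full-precision values and rounded only
for display.  Identical configurations produce bit-identical CSV output;
there is no randomness anywhere in the pipeline.

## Trait catalog

The bundled 17-record table (`src/leafgx/data/leaf_traits.tsv`) is a
synthetic transcription of the ecophysiological literature on trait
response timescales: each trait carries a category (stomata & hydraulics,
photosynthetic biochemistry, morphology & lifespan; dual membership
allowed), a set of response mechanisms (physiological, phenotypic,
evolutionary) and a [min, max] time band from {seconds … millions of
years}, mapped to log₁₀-second midpoints (seconds 0.5, minutes 1.8,
hours 3.6, days 4.9, weeks 5.8, months 6.4, years 7.5, decades 8.5,
centuries 9.5, millennia 10.5, millions of years 13.5) for ordering
arithmetic.  Only g_s, c_i, V_cmax, J_max, χ and g_smax have dynamics in
the engine; the remaining records (K_leaf, Ψ_leaf, LMA, …) are
catalog-only.  The loader validates schema version, enum membership,
band ordering and name uniqueness, and accepts a replacement table so a
corrected transcription needs no code change.

## What the idealized scenarios do and do not show

The two bundled scenarios are clean step doublings applied to a single
unstressed reference leaf.  Passing their checks demonstrates internal
consistency of the coupled optimality machinery — not predictive skill
for real canopies, where co-varying drivers, water stress, nutrient
constraints and mesophyll conductance all modulate the responses.  The
minute-scale stomatal state in particular depends on the instantaneous
objective; alternative published formulations (empirical g_s models,
different water-cost accounting) would shift step 2 while leaving steps
0, 1, 3 and 4 unchanged, since those follow from the FvCB solve and the
acclimated optimum alone.

## Numerical summary

| quantity | choice |
|---|---|
| c_i root solve | Brent on [Γ*+10⁻⁶ Pa, c_a], rtol 10⁻¹², ≤200 iter |
| g_s optimum | 240-pt scan + bounded golden section, xatol 10⁻⁸ |
| A_c = A_j tie | labelled "rubisco" |
| step-2 ceiling | g_s clipped at g_smax, flag set |
| degenerate light | capacity optimum → A = 0 with RuntimeWarning |
| validated ranges | T ∈ [−30, 60] °C (viscosity: (0, 100) °C), D > 0, c_a > 0 |
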