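# Methods

This note records the model equations as implemented, the provenance of
every default parameter, and the places where the design was genuinely open
and a choice had to be made.

## Scope and assumptions

The model describes one steady state of a continuous (chemostat) aerobic
fermentation of ethanol to dry biomass (CH₁.₈O₀.₅N₀.₂) in a cylindrical
bubble column. Its core assumptions:

1. Gas and liquid phases are each perfectly mixed; the off-gas composition
   is the in-column gas composition. The regime module exists precisely to
   say when this assumption starts to fail on scale-up.
2. Cells plus broth are one liquid phase of constant ungassed density
   1000 kg/m³.
3. Growth is zero order in dissolved O₂ above the setpoint (0.069 mmol/kg,
   ≈30% of air saturation at 30 °C) and in NH₃ above 1 g/kg; both are
   treated as held at their setpoints by control.
4. O₂ and CO₂ leave dissolved in the outflow in negligible amounts compared
   with the off-gas; the solver carries the dissolved-O₂ term anyway
   (it is ~10⁻⁵ relative) and quantifies the dissolved-CO₂ neglect (see
   *Carbon balance error*).
5. Ethanol and NH₃ do not evaporate; water leaves the column saturated in
   the off-gas.
6. The broth behaves as a coalescing liquid for mass transfer; a
   `coalescence_factor` multiplier on k_La (default 1) represents
   coalescence-inhibited broths.
7. Dissolved CO₂ is molecular CO₂ only; at pH 6 carbonate speciation is
   negligible.

## Stoichiometry

Herbert–Pirt: −q_S = μ/Y_xs,max(molar) + m_S, with
Y_xs,max(molar) = Y_xs,max(g/g)·M_S/M_x. Monod inversion gives the
chemostat residual: C_S = K_S·(−q_S)/(q_S,max − (−q_S)).

Defaults: μ_max = 0.22 h⁻¹, Y_xs,max = 0.63 g/g, m_S = 0.005 mol_S/(mol_x·h),
K_S = 5·10⁻⁴ mol/kg. q_S,max is not independently known; the default is the
Herbert–Pirt value at μ_max (≈0.191 mol_S/(mol_x·h)), which reproduces the
expected residual of 1.1 mmol/kg at D = 0.15 h⁻¹ and is overridable.

The biomass molar mass uses the conventional rounded value **24.6 g/mol**
(exact atomic masses give 24.63). The rounded value is what makes the
reaction coefficients land on the standard published figures at two
decimals (−0.88, −1.59, 0.76, 2.04, −0.20 at μ = 0.15 h⁻¹); it is a config
field (`composition.biomass_molar_mass_g_per_mol`, set to `null` to use the
exact mass, a 0.1% effect).

Given ν_S = q_S/μ, the four remaining coefficients solve the linear system
of the C, N, electron (γ = 4C + H − 2O − 3N, NH₃ reference) and H balances;
the O balance is redundant and its relative residual (machine precision,
asserted < 10⁻¹⁰) is stored as `closure_residual`. The same solve works for
any C/H/O/N substrate formula (glucose is exercised in the tests).

## Physical properties

Henry solubilities use K_H(T) = K_H(298.15 K)·exp(B·(1/T − 1/298.15)) with
Sander-compilation constants, in mol/(kg·bar):

| gas | K_H(25 °C) | B (K) | note |
|-----|-----------|-------|------|
| O₂  | 1.2·10⁻³  | 1500  | gives K_H(30 °C) = 1.104·10⁻³, consistent with the 0.069 mmol/kg setpoint being 30% of air saturation |
| CO₂ | 3.3·10⁻²  | 2400  | CO₂/O₂ solubility ratio ≈26 at 30 °C |
| N₂  | 6.4·10⁻⁴  | 1600  | used in air mode |
| H₂  | 7.8·10⁻⁴  | 530   | reproduces 0.16·10⁻² g/kg at 1 bar |
| CH₄ | 1.57·10⁻³ | 1900  | upper end of the compilation range, matching the 2.52·10⁻² g/kg solubility-table value |
| CO  | 9.7·10⁻⁴  | 1300  | 2.72·10⁻² g/kg at 1 bar |

Water vapor pressure is an Antoine fit to steam tables,
log₁₀(p/bar) = 5.11564 − 1687.537/(T − 42.98), within 0.3% over 278–373 K.
Diffusivities D_O₂ = 2.10·10⁻⁹, D_CO₂ = 1.92·10⁻⁹ m²/s (25 °C values);
only the ratio enters, through k_La(CO₂) = k_La(O₂)·√(D_CO₂/D_O₂), and the
ratio is directly overridable. Other constants: c_p = 4.18 kJ/(kg·K),
Δ_evap H = 43.5 kJ/mol (30 °C), 460 kJ heat per mol O₂ consumed,
U = 1.4 kW/(m²·K).

## Gas-phase solve

For a bottom/top velocity pair the evaluation is fully nested: mean
velocity (log-mean) → hold-up → bottom pressure (hydrostatic head of the
aerated liquid, 95% of 600 m³) → liquid mass → molar flows (ideal gas) →
evaporation → off-gas composition → transfer rate. The objective is the
difference between the O₂ flux from the total gas balance and
k_La·(K_H·y_O₂·p_eff − C_O₂); a Brent root find on the bottom velocity
(machine-precision tolerances, residual < 10⁻⁹ relative) closes it. When
the operating point is specified by the mean velocity — the natural axis
for reporting — an outer bracketed iteration maps the target onto the top
velocity.

**Pressure averaging.** The equilibrium concentration is evaluated at the
log-mean of the top and bottom total pressures with the well-mixed off-gas
composition. How to average the driving force over the column is genuinely
open (top-pressure and arithmetic-mean variants are selectable via
`correlations.pressure_average`); the log-mean default reproduces the
expected transfer rates across the window.

**Feasibility.** Negative off-gas fractions raise an infeasibility error
in the public residual; a converged root with non-positive transfer (no
driving force above the dissolved-O₂ setpoint) raises a no-steady-state
error, as does an unbracketable objective.

## Liquid side and carbon balance error

With N_O₂ fixed, the liquid side is sequential: M_L = ρ_L(1−ε_G)·0.95·V_R;
F_L,out = D·M_L; biomass from the O₂ conversion through 1/|ν_O₂|; dissolved
CO₂ from the CO₂ transfer analogue; NH₃ feed sized for a 1 g/kg residual at
200 g/kg feed strength; the ethanol feed closes the total liquid balance
including the net gas-to-liquid mass transfer; the feed concentration
closes the ethanol balance.

The staged scheme equates CO₂ production with CO₂ transfer, so the
dissolved CO₂ leaving with the outflow is carbon unaccounted for.
`carbon_balance_error` reports it **relative to the carbon fed with the
substrate stream** (a definitional choice; the error falls monotonically
from ≈1% at 0.04 m/s to ≈0.1% at 0.30 m/s with this denominator).
`solve_simultaneous` solves all balances at once with the dissolved-CO₂
outflow retained and is the agreement cross-check in the test suite.

## Cooling design

A_cool = Q_cool/(U·ΔT_lm) with ΔT_lm = 15 K (broth 30→15 °C against
chilled water 5→20 °C). The number of parallel shell-and-tube units is
⌈A_cool/430 m²⌉ — the catalogue maximum for a single unit — with units then
installed at a 400 m² design area each; this is what makes seven units
cover ≈2800 m². Tube count per unit scales from the catalogue 1269 tubes at
430 m² to the design area (≈1181), giving a single-pass tube velocity of
≈0.40 m/s at the base case. Loop flow from Q = F·c_p·ΔT with a 15 K broth
drop.

The internal-coil alternative uses pipe diameter D_R/30, pitch 2d, turn
count H_aerated/(3d) and helix diameter D_R (≈475 m², insufficient at every
operating point — the quantitative case for the external loop).

The wall-shear estimator is the simple μ·v/d (the laminar 8μv/d is
selectable); pump shear is μ·(tip speed)/clearance for a 0.6 m axial
impeller with 0.3 mm clearance over 60–600 rpm. Depletion times are
reservoir/rate at the bulk consumption rates (zero-order assumption);
residence is (tube length·passes + 10 m piping)/velocity.

## Characteristic times

The liquid mixing flow is the gas-driven circulation
F_mix = 0.3·D_R^(5/3)·(F_G^V)^(1/3)·g^(1/3). Definitions (each a
config-visible strategy, since no single standard exists):

* τ_mix,L = 4 × (ungassed liquid volume)/F_mix — mixing ≈ four
  circulations, the usual tall-vessel rule;
* τ_FG = gas volume / mean volumetric gas flow;
* τ_mix,G = τ_FG/3 — gas back-mixing a few times faster than flow-through.
  This is an order-of-magnitude estimate only (no established correlation
  for churn-turbulent gas back-mixing); conclusions should rest on its
  ratio to τ_FG, not its absolute value;
* τ_S, τ_O₂, τ_CO₂ = dissolved reservoir / bulk rate;
* τ_heat = c_p·ΔT_allowed / specific heat load, ΔT_allowed = 1 K.

Gradient flags fire when τ_mix/τ_mechanism exceeds a threshold (default 10,
one order of magnitude). At the base case the substrate flag fires
(ratio ≈15) and the O₂ ratio is in the hundreds — O₂ turns over far faster
than the column mixes, but since transfer happens throughout the volume the
practical gradient is the bottom/top driving-force ratio, computed
separately: ≈3 well-mixed, rising toward the plug-flow bound (≈56 if the
off-gas O₂ fraction were pushed to 0.1).

## Sensitivity scenarios

Built-ins: `yield10` (Y_xs,max ×1.1 → production +18–20%), `ks10` (K_S/10 →
residual and τ_S tenfold lower, substrate-gradient flag certain), `hot45`
(45 °C with biology unchanged: k_La +39%, O₂ solubility −21%; the full
balance moves N_O₂ only a few percent because the higher water vapor
fraction also dilutes the off-gas — the naive factor product overstates the
gain), `coalescence3` (k_La ×3: utilization gains of ≈55–100% and biomass
gains of ≈75–125% depending on the velocity), `air` (y_O₂,in = 0.21; the
pure-O₂ productivity advantage at 0.30 m/s is ≈6-fold). Scenario runs are
bit-reproducible; the model contains no random elements.

## Numerical choices and limitations

* Root finds are bracketed Brent iterations at machine-precision
  tolerances; all ten material balances close to < 10⁻⁹ relative at any
  converged point (most to ~10⁻¹⁶ by construction).
* The velocity window 0.04–0.30 m/s is the correlations' validity range
  (heterogeneous regime below flooding); outside it the model warns but
  computes.
* Hold-up is capped at 0.99 for pathological velocities.
* Not modelled: CO₂ growth inhibition (the model reports C_CO₂ so the user
  can compare against strain-specific limits), viscosity feedback on k_La
  at very high biomass, bubble-size distributions, spatial gradients
  (flagged, not resolved), foam, economics.
* The air benchmark is feature-complete (N₂ balance active) but its inputs
  are ordinary defaults, so only robust inequalities (lower utilization,
  >3× productivity ratio) should be read from it.
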