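# scpreactor

Steady-state model of an industrial bubble-column bioreactor producing
single-cell protein (SCP) from ethanol with pure O₂ (or air) sparging.

Aerobic SCP fermentations at high dilution rate are O₂-transfer limited:
the achievable biomass production of a column is set by how fast O₂ can be
moved from the bubbles into the broth, and everything downstream — biomass
titer, feed design, heat removal, cell stress in the cooling loop — follows
from that transfer rate. This package is aimed at bioprocess engineers doing
early-stage design and scale-up screening: it answers, for a 600 m³ column
run as a chemostat, what operating window the gas flow allows, what it costs
in unconsumed O₂ and cooling duty, and where concentration gradients will
appear on scale-up.

## Model

* **Stoichiometry.** The chemostat fixes μ = D. Substrate uptake follows
  Herbert–Pirt, −q_S = μ/Y_xs,max + m_S, with the residual ethanol
  concentration from inverting the Monod law q_S = q_S,max·C_S/(K_S + C_S).
  The growth-reaction coefficients (per mole of CH₁.₈O₀.₅N₀.₂ biomass) come
  from the C, H, O, N element balances plus the degree-of-reduction
  (electron) balance γ = 4C + H − 2O − 3N; the redundant balance is kept as
  a closure check.
* **Gas–liquid transfer.** Coalescing-broth correlations
  k_La = 0.32·v_sG^0.7·1.022^(T−20) (s⁻¹) and ε_G = 0.6·v_sG^0.7, with the
  mean superficial velocity the log-mean of top and bottom values, and the
  driving force C* − C from Henry's law at the well-mixed off-gas
  composition and the column log-mean pressure.
* **Steady state.** For a velocity target the solver root-finds the bottom
  superficial velocity until the O₂ flux implied by the gas balances equals
  k_La·(C* − C); the liquid side (liquid mass, outflow, biomass, feed
  flows, feed ethanol concentration) then follows sequentially. A
  simultaneous solve of all balances, including the dissolved-CO₂ outflow
  the staged scheme neglects, is built in as a cross-check.
* **Heat and cooling.** Q_r = 460 kJ per mol O₂ consumed; after subtracting
  evaporation the duty sizes a parallel bank of shell-and-tube exchangers
  (Q = U·A·ΔT_lm) and the loop broth flow (Q = F·c_p·ΔT), plus the shear
  and O₂/substrate depletion times cells face per loop transit.
* **Regime analysis.** Reservoir-over-rate characteristic times for mixing,
  gas flow-through, substrate, O₂, CO₂ and heat; pairs whose ratio exceeds
  an order of magnitude are flagged as likely spatial gradients.

Details, assumptions and parameter provenance: [docs/methods.md](docs/methods.md).

## Worked example

The defaults are the base case: 600 m³ (H/D = 6), pure O₂, 1.2 bar
overhead, 30 °C, D = 0.15 h⁻¹, dissolved O₂ held at 0.069 mmol/kg.

```python
import scpreactor as scp

config = scp.load_config()                      # full default configuration
stoich = scp.configured_stoichiometry(config)   # reaction at mu = 0.15 1/h
print(stoich.nu)   # {'biomass': 1.0, 'substrate': -0.881, 'O2': -1.593,
                   #  'CO2': 0.762, 'H2O': 2.043, 'NH3': -0.2}
sol = scp.solve_config(config)                  # vsG_mean = 0.30 m/s
print(sol.N_O2, sol.C_x, sol.O2_utilization)
# 1.112 mol/(kg h)   114.5 g/kg   27.1 %
```

or from the shell:

```console
$ scp-reactor solve --vsg 0.30
N_O2 [mol/(kg_L h)]       1.112030e+00
y_O2_out [-]              8.188744e-01
C_x [g/kg_L]              1.144994e+02
R_x_kg_h [kg/h]           7.260954e+03
F_L_out [kg/h]            6.341475e+04
C_S_in [g/kg]             2.222513e+02
O2_utilization [%]        2.710372e+01
...
```

Reading: at the top of the velocity window the column transfers
1.11 mol O₂/(kg·h), sustaining 114 g/kg dry biomass and 7.26 t/h of SCP
from a 63 t/h liquid outflow fed with 222 g/kg ethanol — but only 27% of
the sparged O₂ is consumed, and the 60 MW heat load needs seven 400 m²
external exchangers (`scp-reactor cooling`). Other subcommands: `sweep`
(velocity grid), `regimes` (characteristic times and gradient flags),
`scenario` (built-in sensitivity studies: `yield10`, `ks10`, `hot45`,
`coalescence3`, `air`) and `dilution` (yield vs dilution rate).

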