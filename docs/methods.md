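# Methods

## Scope and object of study

`pyccm` computes steady states of a whole-cell reaction–diffusion model
of photosynthetic carbon assimilation, for three organism templates — a
C3 land-plant mesophyll cell, a hornwort thallus cell, and a green-algal
cell in sea water — each with or without a pyrenoid-based
carbon-concentrating mechanism (PCCM). The model's outputs are the
steady-state concentration fields of CO₂, H₂CO₃, HCO₃⁻ and O₂, the global
rubisco carboxylation and oxygenation fluxes, and a derived
ATP/NADPH/photon budget. The transient approach to steady state is not an
object of study; only convergence diagnostics are exposed.

There is no external data anywhere in the pipeline. The scenario builder
(`pyccm.scenarios`) is the input generator: every experiment is a
deterministic function of the in-package constant registry
(`pyccm.parameters.ParameterSet`) plus a handful of scenario switches
(organism, CCM on/off, pump placement, permeability fold, porosity,
external CO₂). No random number generator is used at any point.

## Geometry

The cell is spherically symmetric. Concentric aqueous shells:

| compartment | extent (µm) | pH | viscosity divisor |
|---|---|---|---|
| pyrenoid (CCM only) | 0 – 1.0 | 8.0 (matrix) | 10 |
| stroma | (0 or 1.0) – 4.63 | 8.0 | 10 |
| cytosol | 4.63 – 8.77 | 7.2 | 2 |
| surface water (apoplast / boundary) | 8.77 – 9.09 | 6.0 land, 8.0 ocean | 1 |

The plasmalemma membrane sits at r = 8.77 µm; the cell wall (0.32 µm for
angiosperms and algae, 1.6 µm for hornworts, effective porosity 0.2 and
10⁻⁴ respectively) and the unstirred film are not meshed but enter as a
two-resistance series conductance `((D·A/δ_w)⁻¹ + (D·porosity·A/δ_wall)⁻¹)⁻¹`
between the surface-water layer and the gas phase (land, hornwort) or the
bulk medium (alga). Several tabulated radii are mutually inconsistent at
the ±0.3 µm level (a nominal "plasmalemma surface" at 9.23 µm vs. a cell
radius of 8.77 plus two 0.32 µm layers); the implementation anchors on
the cell radius and the layer thicknesses and keeps the nominal value
only as a validated registry field.

For the land plant, a well-mixed substomatal gas node (shell out to
11.63 µm) exchanges CO₂ and O₂ with the atmosphere through a stomatal
conductance of 0.4375 mol m⁻² s⁻¹ per leaf area; the per-cell share of
leaf area is the exchanging cell surface (half the sphere faces
intercellular airspace) divided by the mesophyll:leaf area ratio of 15.
The hornwort template removes the gas node (undifferentiated thallus —
atmosphere directly outside the wall); the alga replaces it with a
Dirichlet bulk in which dissolved inorganic carbon is speciated at ocean
pH 8.0, making the bulk strongly bicarbonate-dominated (HCO₃⁻/CO₂ = 60).

With a CCM, the thylakoid tubule system is a single well-mixed aqueous
pocket (lumen pH 6.0) shaped as 6 cylinders of radius 0.5 µm and height
4 µm: lateral area 75.40 µm² contacts the stroma, end-cap area 4.712 µm²
contacts the pyrenoid (contact spread volume-weighted over the radial
nodes). The pyrenoid is wrapped in a starch sheath that multiplies every
species' bilayer permeability by 0.1.

## Transport and reaction laws

Membrane permeation is `P·(outside − inside)` per species; bilayer
permeabilities are P(CO₂) = 3500 µm/s (the widely used Gutknecht-type
measurement; scans go up to ~9×), P(H₂CO₃) = 30, P(HCO₃⁻) = 0.05,
P(O₂) = 7.5×10⁵ µm/s. Facilitated HCO₃⁻ routes exist only in CCM models:
bestrophin-like channels add 10⁴ µm/s across both thylakoid interfaces,
and an envelope channel adds 10⁻² µm/s. An optional cyanobacterial-type
bicarbonate pump (BicA, Michaelis–Menten, Vmax 1.85×10⁻⁴ mol m⁻² s⁻¹,
Km 217 µM) can sit at either the chloroplast envelope (cytosol → stroma)
or the plasmalemma (surface water → cytosol), never both.

Local reactions, in every aqueous node:

* spontaneous chemistry, mass action with H⁺ pinned by compartment pH:
  hydration kf = 0.06 s⁻¹ / dehydration kr = 20 s⁻¹;
  deprotonation kf = 10⁷ s⁻¹ / protonation kr = 5×10¹⁰ M⁻¹ s⁻¹;
* carbonic anhydrase (cytosol 135 µM, stroma 270 µM, lumen 135 µM,
  optionally apoplast 135 µM), a reversible uni-uni form
  `[CA]·kcat·([CO₂] − [HCO₃⁻][H⁺]/Keq) / (Km_CO2 + [HCO₃⁻]·Km_CO2/Km_HCO3 + [CO₂])`
  with kcat = 3×10⁵ s⁻¹, Km_CO2 = 1.5 mM, Km_HCO3 = 34 mM. The apparent
  equilibrium constant is stored as 0.56 µM: the registry's nominal unit
  ("mol/m³") would put the constant three orders of magnitude below the
  first dissociation constant of carbonic acid and is treated as a units
  slip; 0.56 µM agrees to within 7% with the equilibrium implied by the
  spontaneous rate constants (0.60 µM), and the CA-catalysis property
  tests run with the two made exactly consistent;
* rubisco, competitive-inhibition Michaelis–Menten with
  Vmax_c = 7600 µM s⁻¹, Vmax_o = 0.21·Vmax_c = 1596 µM s⁻¹. The two
  Michaelis constants are assigned Km_CO2 = 8.6 µM, Km_O2 = 215 µM — the
  ordering consistent with plant rubisco kinetics (specificity factor
  ≈ 119; the swapped ordering gives 0.45 and a compensation point near
  20,000 ppm) — with the alternative selectable via `km_ordering`.

Rubisco lives in the stroma (no CCM) or the pyrenoid (CCM). **Rubisco
placement under condensation is a modeling choice**: the with-CCM cell
carries the same total catalytic capacity as the no-CCM cell, i.e. the
pyrenoid catalytic density is the tabulated volumetric Vmax scaled by the
chloroplast:pyrenoid volume ratio (≈ 99×, consistent with pyrenoids being
dense rubisco condensates). The alternative — tabulated density inside a
1-µm pyrenoid — yields a cell with ~1% of the no-CCM capacity, which
cannot exhibit a net-fixation benefit from the CCM at ambient CO₂ and is
rejected; see "Known limitations".

The lumenal CA of CCM models is placed in the pyrenoid volume but runs at
the thylakoid-lumen pH of 6.0 (in the organism the enzyme sits inside the
tubules that penetrate the pyrenoid); pyrenoid and thylakoid DIC pools
remain distinct. The pyrenoid matrix's own spontaneous chemistry uses the
stroma pH, the pyrenoid being a stromal condensate.

Global couplings (well-mixed sources): photorespiration releases ½ CO₂
per oxygenation in the cytosol (mitochondria are not resolved);
photosynthetic O₂ evolution adds 1 O₂ per carboxylation in the stroma;
the oxygenation reaction consumes 1 O₂ at rubisco and photorespiration a
further ½ O₂ in the cytosol. Net cellular O₂ balance is therefore
Vc − 1.5·Vo; a Farquhar-style preset (`o2_stoichiometry="farquhar"`,
evolution tracking total electron demand, net Vc − 0.5·Vo) is switchable.
The choice is irrelevant near ambient CO₂ (the O₂ field is
near-saturating) but matters at very low wall porosity, where the default
lets internal O₂ run down and thereby *suppresses* photorespiration in a
nearly sealed cell.

## Energetics

Demand: 3 ATP + 2 NADPH per carboxylation, 3.5 ATP + 2 NADPH per
oxygenation. The lumen CA's net dehydration flux J consumes one lumenal
proton per HCO₃⁻ converted and hence costs J·3/14 ATP at the 14:3
H⁺:ATP synthase stoichiometry. Active bicarbonate pumping is costed at
the same 3/14 ATP per HCO₃⁻ (one cation-equivalent translocation per
transport event). This pump cost is deliberately part of the budget: with
a free pump, the quantum yield is provably monotone increasing in pump
activity (the ATP:NADPH ratio is then confined to [1.5, 1.75]), and the
well-documented inefficiency of pump-and-leak futile cycles at high
membrane CO₂ permeability could never appear.

Supply: linear electron flow provides, per 2 NADPH, 8 photons and
12 H⁺ → 18/7 ≈ 2.571 ATP. Any ATP shortfall (floored at zero) is covered
either by cyclic electron flow at 0.43 ATP per extra photon, or by the
malate valve at 5.45 ATP per 2 NADPH-equivalent exported with 4 photons
per NADPH. Photons per rubisco reaction:

```
P_rxn(CEF)    = 8 + max(2·Ratio − 18/7, 0) / 0.43
P_rxn(malate) = 8 + max(2·Ratio − 18/7, 0) / 5.45 · 2 · 4
```

and the quantum yield is φ = [(Vc − ½Vo)/(Vc + Vo)] / P_rxn. The division
(rather than multiplication) by 0.43 in the CEF branch is the parse that
is dimensionally coherent (ATP shortfall ÷ ATP-per-photon = photons) and
reproduces the C3 validation value φ ≈ 0.067 at 412 ppm; reports include
both modes, CEF being the default.

## Numerics

Finite volumes on spherical shells (default spacing dr = 0.05 µm, ~180
nodes × 4 species ≈ 730 unknowns). Interior faces use the exact spherical
shell resistance between node centres; membrane and outer-series faces
compose the membrane conductance in series with the exact half-cell
diffusive resistances on both sides, which removes the leading
first-order flux error at steep interfacial gradients. Gas–liquid faces
carry the Henry partition (dimensionless gas/aqueous ratios H_CO2 = 1.2,
H_O2 = 32 at 25 °C — not tabulated upstream, exposed as parameters; they
reproduce 13.9 µM dissolved CO₂ at 412 ppm and 264 µM dissolved O₂ at
0.2095 atm).

The steady state is found by pseudo-transient continuation: implicit
Euler steps with one Newton iteration each, an analytic sparse Jacobian
(including the dense-ish rows of the global photorespiration/O₂
couplings), and a pseudo-time step grown by switched evolution relaxation;
a pure-Newton polish then drives the residual to the attainable floor.
Positivity is preserved by step-length control — the step is shortened
until no concentration crosses zero — never by clipping, which would
silently violate mass balance. Convergence requires the max-norm residual
below 10⁻¹⁰ of the per-row turnover scale; after polishing, the global
DIC balance (outer-boundary influx = Vc − ½Vo) closes to better than
10⁻⁶ of gross carboxylation in all shipped scenarios, and this is
asserted in the test suite.

Chemistry makes the interfacial layers genuinely thin: the CA
reaction–diffusion length √(D_eff/k_CA) ≈ 0.06 µm in the stroma. At
dr = 0.05 µm a 2× refinement moves net fixation and rubisco saturation of
the C3 land-plant model by ~0.4–0.5%; the CCM models converge more slowly
(~3% per refinement at dr = 0.05) because the pyrenoid fluxes ride on
those layers. Reported CCM-model values therefore carry a few-percent
discretization uncertainty in addition to model uncertainty.

Root-finding (compensation points, C_i targeting, marginal-cost
crossovers) uses Brent's method after a coarse geometric pre-scan to
bracket the sign change; compensation points are resolved to 0.05 ppm.
Every solve starts from the same documented initial condition (chemical
equilibrium with the external CO₂ at each compartment's pH), making scans
order-independent; steady states are verified to be independent of the
initial condition.

## Experiment conventions

* Compensation point: external CO₂ at which net fixation Vc − ½Vo
  crosses zero, reported in gas-phase ppm (aqueous values for the alga
  are converted via the Henry constant and 24.79 L/mol).
* "C4-like" substomatal CO₂: C_i/C_a = 0.35, the midpoint of the 0.3–0.4
  band typical of C4 species, i.e. C_i ≈ 144 ppm at 412 ppm ambient,
  reached by scanning external CO₂ at fixed stomatal conductance.
* Marginal CCM cost: ratio of the marginal photon cost of CCM-driven
  fixation, (ΔPhotons/ΔNetFixation), to the no-CCM average cost
  (Photons/NetFixation); below 1 the CCM is marginally light-efficient.
  The crossover is reported against the substomatal CO₂ of the *no-CCM*
  member of the pair (the ambient C_i a leaf would experience).
* Local sensitivity: ±10% parameter perturbations, averaging the absolute
  percent change of rubisco saturation and quantum yield; geometric
  perturbations rescale areas and volumes while holding per-area and
  per-volume protein densities constant, with a 1%×10 linearized fallback
  when a 10% radius change breaks the solve.

## What the scenario generator does and does not emulate

The generator produces ideal single cells: perfectly spherical, one
chloroplast, fixed compartment pH, no respiration in the light, no RuBP
or J_max limitation (rubisco-limited regime by construction), no
temperature dependence, no dynamic stomata. Passing tests therefore
demonstrate internal consistency of the reaction–transport–energetics
pipeline under these idealizations — not fidelity to any particular
leaf's gas-exchange data. In particular, absolute fluxes scale directly
with the assumed rubisco capacity and geometry, and quantum yields omit
the respiratory and maintenance costs a real leaf pays.

## Known limitations

* **The with-CCM delivery chain is under-determined by the constant
  registry.** The pH-gradient engine built from the tabulated CA
  kinetics, channel permeabilities and geometry gives a definite strength
  to the CCM; with rubisco capacity conserved under condensation, that
  strength lands between the two behaviors the literature describes for
  such cells. At low CO₂ the simulated CCM is weaker than measured
  pyrenoid-bearing organisms (compensation points ~23 ppm rather than
  the few-ppm range), because holding the pyrenoid at the kinetic
  compensation concentration against the full photorespiratory recapture
  load exhausts the lumen-CA capacity and the envelope CO₂ supply. At
  ambient CO₂ it is cheaper than the measured light-use penalty of CCM
  operation (the marginal-cost crossover falls near 1000 ppm substomatal
  rather than ~160), because the same chain produces only ~1.3 lumen-CA
  turnovers per fixation rather than the heavy futile recycling needed
  for a large ATP penalty. No assignment of rubisco between stroma and
  pyrenoid removes both discrepancies simultaneously; resolving them
  likely requires structural details of CCM regulation (e.g. CA
  activity states, channel gating) outside the registry.
* The ~1 µm-scale idealization of the thylakoid tubules is probed by
  `thylakoid_interface_multiplier` (×10 on both tubule interfaces moves
  quantum yield by <10%), but the real many-fine-tubule architecture is
  not resolved.
* At very low wall porosity the model keeps a small positive net fixation
  (whatever trickles through the wall is fixed, and internal O₂ depletion
  under the default stoichiometry suppresses photorespiration); it does
  not reproduce a hard fixation collapse in the no-CCM cell, and the
  choked regime equally starves the CCM's own delivery chain.
* H⁺ is not a state variable; all pH values are clamped, so the free
  energy driving the pH-gradient CCM is implicitly supplied by the
  clamps, and only the lumen-CA and pump proton costs are charged to the
  photon budget.
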