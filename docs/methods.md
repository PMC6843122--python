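# Methods

This note describes the model as implemented: its processes, the
parameters that matter, the numerical choices, what the synthetic
scenarios emulate, and the known limitations.

## Soil P pools and transfers

Soil P in each layer is held in eight pools (kg P ha⁻¹): **soluble**
(labile: solution plus readily desorbable P, immediately
plant-available), **adsorbed**, **precipitated**, **stable inorganic**,
**active organic**, **stable organic**, **microbial** and **mineral** P.
Transformations among the inorganic pools are reversible; mineral P
dissolves into the soluble pool; the organic pools decompose into the
microbial pool, which exchanges with mineral P through
mineralisation/immobilisation.

All pool-to-pool transfers are first-order in the donor pool,
`flux = k · donor · ftemp · fwater`, with every rate constant exposed in
config and an optional cap (kg P ha⁻¹ d⁻¹) per pair.  First-order
donor-proportional kinetics is the dominant convention in this model
family; process-specific equations can replace any pair by overriding its
rate constant or cap.  Default rate constants (d⁻¹):

| transfer | k | time scale |
|---|---|---|
| soluble → adsorbed | 0.06 | days–weeks (sorption) |
| adsorbed → soluble | 0.005 | months (desorption) |
| soluble ↔ precipitated | 5e-4 / 5e-5 | years |
| adsorbed/precipitated ↔ stable inorganic | 1e-4 / 1e-5 | decades |
| mineral → soluble (dissolution) | 0.2 | days |
| active ↔ stable organic | 1.5e-3 / 2e-4 | years |

The sorption pair implies a quasi-equilibrium adsorbed:soluble ratio of
12; the soil generator uses the same ratio so generated profiles start
near sorption equilibrium.

The temperature response is Q10 = 2 referenced to 20 °C; the moisture
response is a trapezoid in water-filled pore space (zero below 0.2,
optimal 0.5–0.85, declining to zero at saturation).  Both are 1 at the
reference environment (20 °C, WFPS 0.6).

**Integration.**  Explicit Euler with automatic sub-stepping: the daily
step is subdivided so no rate constant times the substep exceeds 0.02,
keeping the first-order discretisation error of a daily step below 1 %
for rate constants up to 0.5 d⁻¹.  Within each substep, all outgoing
fluxes from a pool are jointly rescaled if they would overdraw it, so
pools never go negative and a fully drained donor lands exactly at zero.
Internal transfers conserve total P to machine precision.

**Leaching** follows complete-mixing proportionality: the leached
fraction is (drainage leaving the layer)/(layer water volume), capped at
1, times a *mobile fraction* (default 0.05 in the engine) representing
the solution share of the labile pool — roughly θ/b for buffer power b.
Without this factor the whole labile pool would ride with drainage and
winter losses would reach tens of kg P ha⁻¹, two orders above field
observations.  Leachate cascades to the layer below and exits the
profile from the bottom layer.

**Mineralisation/immobilisation.**  Decomposition of each organic pool
releases P to the microbial pool in proportion to the pool's P:C ratio.
The microbial pool is then relaxed toward a target C:P of 60 (configurable):
excess P is mineralised to the mineral pool, deficit P immobilised from
it (capped by the donor).  Mineral P dissolves to soluble P.

## Root uptake (Barber–Cushman)

Solution concentration Cl(r, t) (µmol cm⁻³) in a hollow cylinder
r0 ≤ r ≤ r1 obeys

    ∂Cl/∂t = (1/r) ∂/∂r ( r De ∂Cl/∂r + r0 v0 Cl / b ) − Ih/b

with effective diffusion coefficient De (cm² s⁻¹), buffer power b (–),
root radius r0 (cm), water influx v0 (cm s⁻¹; the convective term uses
the continuity relation v(r) = v0·r0/r), and root-hair sink Ih per soil
volume.  At the root surface the diffusive plus convective delivery
balances Michaelis–Menten uptake,

    De·b·∂Cl/∂r + v0·Cl = Imax (Cl − Cmin) / (Km + Cl − Cmin),

which is zero at and below Cmin and half-saturated where Cl − Cmin = Km.
The outer boundary at r1 = (π·RLD)^(−1/2) (half the mean inter-root
spacing for root length density RLD) is zero-transfer.  Root hairs are
not resolved individually: they act as a distributed Michaelis–Menten
sink (parameters Imaxh, Kmh, shared Cmin) with a uniform hair surface
density in the annulus r0 ≤ r ≤ r0 + hair_zone_radius, using the local
grid concentration.  Hair uptake is therefore not additionally charged at
the root surface, which would double-count it.  Defaults have hairs off
(hair_surface_density = 0), reducing to the classic model.

Reference parameter magnitudes (all configurable): De = 1e-7 cm² s⁻¹,
b = 20, r0 = 0.015 cm, v0 = 1e-7 cm s⁻¹, Imax = 3e-6 µmol cm⁻² s⁻¹,
Km = 6e-3 µmol cm⁻³, Cmin = 2e-4 µmol cm⁻³ — typical for phosphate
around a cereal root in a temperate arable soil.

**Numerics.**  Cell-centred finite volumes on a log-spaced grid (48
cells by default, refined at the root), backward-Euler steps (default
1/96 of the run) with Newton iteration; the nonlinear surface flux is
closed by solving the scalar surface balance for the face concentration
with a bracketed root find at each Newton pass, and its analytic
derivative enters the tridiagonal Jacobian.  Failed Newton steps trigger
automatic step halving, never a silent unstable result.  The scheme is
conservative: solute lost from the annulus equals root plus hair uptake
to solver tolerance (≤1e-6 relative, typically ~1e-15).  An independent
reference path (`solve_radial_reference`: variable-order BDF
method-of-lines on a 10×-finer grid) is used in the tests; the
production solver agrees with it within 1 % cumulative uptake across
random physical parameter sets, and within 2 % of an exact
matrix-exponential solution in the linear-kinetics limit.

**Pool coupling.**  The soluble (labile) pool maps to solution
concentration by the Barber convention: the labile mass per unit soil
volume equals b·Cl, so Cl = pool/(b·V_soil).  The buffer power subsumes
the volumetric water content (b ≈ θ + ρ·k for a linear isotherm).  This
makes the solver's within-day buffered resupply draw on exactly the
soluble pool, so daily withdrawal can never exceed it.  Daily uptake per
layer is the cumulative per-root uptake times root length per ground
area.

## Plant coupling

Decomposition of an organic pool with biomass C (gC m⁻²) proceeds at

    D = kmax · C · ftemp · fwater · min(fCN, fCP)

with fCN = 1 below C:N = 25 and exp(−0.693·(CN−25)/25) above, and fCP = 1
below C:P = 200 and exp(−0.693·(CP−200)/200) above — i.e. the factor
halves for each doubling of the ratio beyond its threshold, and the more
limiting nutrient governs.  The stoichiometric minimum is applied to all
decomposing pools.

The leaf-P photosynthesis factor is fP = 0 at/below Pmin, 1 at/above
Popt, linear between, with leaf P concentration = leaf P / leaf DM.
Values for Popt and Pmin are variety-specific and not available for the
reference cultivar; the defaults Popt = 0.0030 and Pmin = 0.0012 g P g⁻¹
DM sit in the range reported for wheat critical and deficiency leaf P
concentrations and are documented assumptions.

Absorbed P goes to organs by growth-stage partition bands (tillering /
stem elongation / post-anthesis, linearly blended over 5 Zadoks units at
band edges; post-anthesis routes 60 % directly to grain).  After
anthesis, leaf and stem P is remobilised to grain at a constant 0.02 d⁻¹
of the vegetative P, drawn proportionally from the donors and never
below a structural minimum (default 30 % of each donor's current P).
Grain P demand does not drive uptake: the model is supply-driven, with a
whole-plant luxury-uptake ceiling (p_max_conc = 0.0045 g P g⁻¹ DM) above
which the plant downregulates further uptake.

**Host crop model.**  The carbon side is a deliberately minimal driver:
daily assimilation is logistic in accumulated biomass
(`mu · green DM · (1 − DM/dm_max)`), scaled by a linear temperature
ramp (base 0 °C, optimum 22 °C) and multiplied by fP; dry matter goes to
organs by stage bands; development follows thermal time (base 0 °C)
mapped to Zadoks stages by a piecewise-linear table for an autumn-sown
winter wheat (emergence ~150 °Cd, GS 30 ~950, anthesis ~1450, ripening
~2100).  This stub exists so the P feedback has a growth process to act
on; it is not a canopy photosynthesis model, and defaults (mu = 0.12 d⁻¹,
dm_max = 2000 g m⁻²) were chosen to give a realistic ~14 t ha⁻¹ total
aboveground dry matter for an unstressed UK winter wheat crop.

## Daily loop and drivers

Fixed order within a day: derive drivers → apply management events →
decomposition and mineralisation/immobilisation → inorganic pool
transfers → root uptake → plant growth, P partitioning, remobilisation →
leaching → record outputs.  Uptake therefore sees the post-transfer
soluble pool.  The order is a documented convention covered by a
regression (determinism) test.

The water driver is a tipping-bucket cascade: Hargreaves–Samani
reference evapotranspiration (from temperature and extraterrestrial
radiation) times a crop coefficient is drawn from the layers with
moisture stress; rain infiltrates the top layer; each layer sheds
instantaneous overflow above saturation plus half of the water above
field capacity per day.  The soil temperature driver filters the 5-day
running mean of air temperature with an exponential smoother whose gain
decays with depth (damping depth 30 cm), so amplitude falls and lag
grows with depth, and the surface equals the running mean.  Both drivers
sit behind a seam in the engine and can be replaced by fuller physics.
Nitrogen fertilisation events are recorded but inert: N supply is
assumed non-limiting.

**Mass balance.**  The run-level P ledger (soil + plant + leached +
harvested = initial soil + fertiliser + seed P) closes to numerical
precision; the acceptance tests require ≤1e-6 relative over a full
two-season run.  At harvest, aboveground P leaves with the crop and root
P (and root carbon) returns to the topsoil active organic pool.

## Synthetic scenarios

The fixture generator emulates a long-term P-fertilisation contrast on a
temperate silty clay loam, with two soil templates (topsoil Olsen-P
6.9 vs 30.6 mg kg⁻¹, total P 373 vs 584 mg kg⁻¹, organic C 0.93 vs
1.05 %) split into the eight pools: Olsen-P is modelled as
soluble + 0.5 × adsorbed with the adsorbed:soluble ratio at the sorption
quasi-equilibrium (12); organic P comes from organic C at an assumed
C:P of 100 (30 % active, 65 % stable, 5 % microbial); the remainder goes
to precipitated (45 %) and stable inorganic (55 %) P.  Pools sum to the
template total exactly.  The profile has two 23-cm layers; subsoil
Olsen-P is half the topsoil value.

Weather seasons run October–July: a cooler season (mean 7.9 °C, 672 mm,
wet autumn) and a warmer, wetter one (10.1 °C, 814 mm).  Temperature is
a seasonal sinusoid plus AR(1) anomalies; precipitation uses seeded
wet-day occurrence and gamma amounts shaped by monthly weights (wet
Oct–Dec, drier Apr–Jul); realised seasonal means/totals are rescaled to
the targets exactly.  Management: sowing 10 October, 15 kg P ha⁻¹ as
triple superphosphate on 5 October for the P-added treatment only,
300 kg N ha⁻¹ split 50/200/50 over 15 March/April/May, harvest 25 July.
Multi-season runs bridge August–September with mild dry weather.

Pseudo-observations for testing the statistics suite are replicated
multiplicative-lognormal perturbations of a simulated series; at zero
noise they reproduce the perfect-agreement block (r = 1, EF = 1, CD = 1,
RE = 0, RMSE = 0).

What passing tests show — and what they do not: the scenarios exercise
mass conservation, solver accuracy, the direction and timing of the
P-treatment contrast (identical trajectories until stem elongation,
divergence after, P-added ≥ control at harvest) and the ablation
(forcing fP = 1 and fCP = 1 makes the treatments' dry matter identical,
proving the P coupling is the only treatment channel).  They do not
validate magnitudes against field data: synthetic weather has no real
spatial or interannual structure, the crop stub has no canopy, N or
waterlogging physiology, and the pool split of measured total P is an
assumption.

## Evaluation statistics

For simulated values Si paired with replicated observations (per-date
means Oi, grand mean Ō, n dates): Pearson r;
EF = 1 − Σ(Oi−Si)²/Σ(Oi−Ō)²; CD = Σ(Oi−Ō)²/Σ(Si−Ō)² (may exceed 1,
meaning the simulation spreads less about Ō than the data);
RMSE = (100/Ō)·√(Σ(Si−Oi)²/n); RE = (100/n)·Σ(Oi−Si)/Oi, signed so
positive means under-simulation; dates with Oi = 0 are excluded from RE
with a warning.  The 95 % thresholds are a documented reconstruction:
each date contributes the t-based 95 % half-width of its replicate mean,
t₀.₉₇₅,ₙᵢ₋₁·SDᵢ/√nᵢ; RMSE95 aggregates the half-widths exactly as RMSE
aggregates residuals, RE95 as RE aggregates relative residuals.
Statistics with vanishing denominators are reported as NaN ("undefined")
rather than raising inside batch evaluation.

## Known limitations

- No erosion/particulate or surface-runoff P; leaching only, with the
  mobile-fraction approximation above.
- No pH-dependent speciation; pools are phenomenological.
- No mycorrhizal uptake; inter-root competition only through the r1
  cut-off; no 3-D root architecture.
- Crop stub: no canopy light model, no N limitation, no
  waterlogging/pest/disease damage; grain-fill P demand does not drive
  uptake, so late-season grain P can deviate from observations.
- Total seasonal P uptake of the unstressed treatment (~60 kg P ha⁻¹)
  exceeds typical field values (~25–30), a consequence of the constant
  luxury-uptake ceiling; the treatment contrast, not the absolute
  uptake, is the tested quantity.
- Organic C stocks evolve by decomposition but have no litter inputs
  other than harvest-returned roots, so multi-decade runs would drift.
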