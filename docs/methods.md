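# Methods

## Lattice state and cell kinetics

The tumor occupies a regular grid of cubic voxels (default edge 1 mm, i.e.
1 mm³; 2 mm is also standard). A voxel at full packing holds
`capacity = 10⁶ cells/mm³ × voxel volume`. The per-voxel state is a
real-valued occupancy vector over a dense compartment index: for the stem
lineage and each of the `N_LIMP` progenitor generations, the cycling phases
G1/S/G2/M are discretized into age bins of width `dt` (default phase split
of the cycle time `T_c`: G1 40%, S 30%, G2 20%, M 10% — the split is not
biologically canonical and is configurable); each lineage has one G0
compartment; differentiated cells form a single pool; apoptotic and necrotic
products are age-binned over their clearance times `T_A`, `T_N`; and
treatment-hit cells occupy per-drug "doomed" blocks.

Counts are mean-field: the model propagates expected occupancies, not
integer agents. This reproduces the population-level behavior of a
discrete-state lattice simulator at compartment granularity; demographic
noise at very low cell counts is outside scope.

**G0 residence is memoryless.** The quiescent compartment is a single pool
with per-step exit probability `1 − exp(−dt/T_G0)`; exits re-enter G1 with
probability `P_G0toG1` and die through necrosis otherwise. An exponential
dwell (mean `T_G0`) rather than a fixed-duration one is what makes the
analytic growth relation below exact, since its quiescence-return term is
the Laplace transform of an exponential residence time.

**Division bookkeeping.** At mitosis one daughter (the renewing one) always
re-enters G1; only the *additional* daughter — the second stem daughter of a
symmetric division (probability `P_sym`), the LIMP daughter of an asymmetric
one, or the second daughter of a LIMP division — withdraws to G0 with
probability `P_sleep`. The final LIMP generation divides into two
differentiated cells. With per-step survival applied to all living stem/LIMP
compartments (`R_A`) and to differentiated cells (`R_ADiff` to apoptosis,
`R_NDiff` to necrosis, applied as competing risks `1 − exp(−R·dt)`), the
stem compartment's long-run growth rate `a` satisfies

    e^{(a+R_A)T_c} = 1 + P_sym[(1 − P_sleep)
                     + P_sleep (P_G0toG1/T_G0)/(R_A + 1/T_G0 + a)]

in the `dt → 0` limit, and a discrete analogue exactly at finite `dt`
(see *Stationary balance*). Treatment-hit cells traverse their rudimentary
cycles (1 cycle for chemotherapy, ending at the drug's death phase —
vincristine M, actinomycin S by mechanism of action; 2 cycles for
radiotherapy) without net multiplication, then convert to apoptotic or
necrotic products respectively. Whether doomed cells amplify at rudimentary
mitoses is not observable at this level; not multiplying is the conservative
choice.

**Spatial redistribution.** After each step, voxels above capacity export
their excess to the 6-neighbor best aligned with the local least-pressure
direction (ties broken in fixed x→y→z order; voxels without a tumor
neighbor in that half-space, or without a direction, use the least-loaded
neighbor), iterating passes until no voxel is overloaded. Tumor voxels
below `0.1 × capacity` donate their content to their most-loaded neighbor
(shrinkage). All moves transfer proportional slices of the compartment
vector, so total cell count is conserved exactly (tested to 1e−13).

## Stationary balance and virtual-tumor derivation

In free growth the per-step update is linear, so the population enters an
exponential regime `x_{t+1} = z x_t`. Because the hierarchy is feed-forward
(stem → LIMP generations → DIFF → dead pools), every pool size along that
regime has a closed form once `z` is known from the discrete renewal
equation

    (z/s)^n = 1 + P_sym W(z),   W(z) = (1−P_sleep) + P_sleep P_G0toG1 f s/(z − s(1−f))

with `n` cycle bins, `s = e^{−R_A dt}` and `f = 1 − e^{−dt/T_G0}`. The
module uses this balance in both directions:

- *Derivation*: given a doubling-time target `T_d` (so
  `a_target = ln2/(24 T_d)`), `P_sym` is the closed-form inverse; given the
  growth-fraction target `GF`, the required differentiated pool
  `D = C(1/GF − 1) − G` determines `R_NDiff` analytically. A negative
  requirement is exactly the "negative `R_NDiff`" exclusion. `P_sleep`
  comes from the metabolic proliferation rate via the continuous relation
  (with `P_sym = 1`, `R_A = 0`), evaluated at the dt-effective cycle length
  so discretization does not bias the inversion.
- *Verification*: `steady_state_profile` seeds a single voxel at the
  predicted stationary composition and *simulates*, measuring the realized
  rate (log-linear fit) and composition. Any error in the balance would
  appear as drift; the acceptance suite requires simulated `T_d` within 5%
  and `GF` within 2% of their targets for ≥90% of retained tumors.

Virtual tumors are drawn by Latin hypercube sampling (scipy's
`qmc.LatinHypercube`, one point per equal-probability stratum, deterministic
per seed) over the literature ranges shipped as YAML fixtures; the sampled
`T_c` upper end is capped at `ln2/a` (the longest cycle compatible with the
metabolic rate). Exclusions tag tumors with out-of-range derived rates,
stem/living frequency outside the tumor-initiating-cell range, necrotic or
apoptotic fractions above bounds, or `P_sym` above its cap. Under the
NSCLC-like profile (`T_d` 370 d, `GF` 23%) most samples are excluded —
predominantly "negative `R_NDiff`" (the sampled `R_ADiff` alone already
depletes the differentiated pool below what `GF = 23%` requires) — which
mirrors the exclusion classes the source parameter tables anticipate.

## Treatment and outcome metrics

Radiotherapy applies, per phase `p`, a hit fraction
`1 − exp(−m_p(αD + βD²))` to stem/LIMP cells (default `m_p = 1`: equal
radiosensitivity in all phases, including G0). Chemotherapy moves a CKR
fraction of stem/LIMP cells into the drug's doomed block. Combination CKRs
add on the rate-constant scale, `1 − Π(1 − CKRᵢ)`, and patient adjustment
uses `CKR_adj = 1 − (1−CKR_lit)^r` with `r` the patient/control cell-death
probability ratio from the molecular layer. TCP is `exp(−N)` with `N` the
expected surviving stem-cell count (mean-field, not a realized integer).
The equivalent diameter uses the cube-root convention `V^{1/3}` (the
sphere convention `(6V/π)^{1/3}` is available as a flag); the cube-root
reading is the one consistent with the quoted 0.908 mm³ → 0.97 mm.

## Glucose transport

`D∇²c − λPc + ρV(cn − c) = 0` is discretized with the 7-point Laplacian on
tumor voxels; non-tumor voxels (and the grid exterior) are Dirichlet
`c = cn`. Defaults: `D = 0.396 mm²/h`, `λ = 7.6e−10 /cell/h` (quoted for
1 mm³ voxels; other voxel volumes use the cell density per mm³ so the sink
stays per-volume consistent), `ρV = 0.25 /h`, `cn = 0.9 kg/m³`. "Viable
cells" are all living compartments. The sparse SPD system is solved
directly and checked to a relative residual of 1e−8; the solution obeys the
maximum principle `0 ≤ u ≤ 1` and matches the diffusion-free fixed point
`ρV/(λP + ρV)` at the center of a large homogeneous tumor (1e−5 at 21³).
The vessel volume fraction is fixed in time; only the lumped `ρV` product
is exposed.

## Metabolism

A generic stoichiometric engine (TSV model files; scipy/HiGHS linear
programming with flux splitting for the |v| crowding term) implements the
two-step strategy: maximize growth, then maximize lactate subject to
`µ ≥ k µ*`, iterating `k = 0.99, 0.98, …` (floor 0.50) until lactate
clears 0.01 µmol/mgDW/h. Every returned solution is re-verified against
`Sv = 0`, bounds and the crowding constraint independently of the solver,
and the growth optimum is cross-checked against a brute-force
vertex-enumeration oracle in the tests. Michaelis–Menten kinetics
(`Km = 0.2704`, `Cmax = 0.9 kg/m³`) bound glucose uptake, normalized so the
bound reaches `vmax` at `Cmax`. Per-reaction bound overrides express
up-/down-regulation constraints (lower bound 0.1 for up-regulated, upper
bound 0 for down-regulated reactions).

Two fixtures stand in for a genome-scale network, which is out of scope:
a ~6-reaction **toy Warburg network** (cheap glycolysis→lactate vs
crowding-expensive oxidative ATP; biomass flux doubles as growth rate in
1/h) that reproduces the qualitative strategy — lactate secretion at
near-optimal growth (`k` between 0.90 and 0.99) at high glucose, pure
respiration when glucose-limited — and a **synthetic anchored phenotype
table** carrying proliferation times 13.1/20/50 h at high/moderate/very-low
normalized glucose for the downstream coupling. Neither reproduces
genome-scale flux distributions; passing tests demonstrate the optimization
machinery, not metabolic realism.

## Biomechanics

Growth strain `ε(x) = (c/c0)^{1/3} − 1` (positive above the carrying
capacity `c0`, default the voxel capacity) enters a static linear-elastic
solve as an isotropic eigenstrain, `σ = C : (ε_total − ε I)`. The domain is
the labeled bounding box itself — trilinear hexahedral elements, one per
voxel, zero displacement on the outer surface — replacing patient-specific
tetrahedral meshing; on a regular grid the mapping steps between simulators
become identity maps. Per-tissue Young's moduli and Poisson ratios ship as
YAML fixtures (kidney 5.3 kPa, lung/other 5 kPa, bone 1 GPa, tumor
10–20 kPa; ν = 0.3–0.4). Pressure is `p = tr(σ)/3` at element centers,
with tensile stress positive by default; a `compression_positive` toggle
flips the sign (the literature leaves the convention ambiguous — the
direction field below flips accordingly, and the default follows the
printed definition literally). The sparse assembly is verified against a
naive dense per-element reference (finite-difference shape gradients) to
1e−6. The least-pressure direction is the normalized negative pressure
gradient (central differences, one-sided at boundaries; gradients below
1e−12 Pa/mm yield the zero vector, which the redistribution treats as
isotropic).

## Coupling

Every exchange interval (default 24 h) the orchestrator chains: living-cell
map → glucose solve → normalized field `u` → phenotype interpolation →
local proliferation rate `a(u)` → `P_sleep` map (the inversion above;
voxels where the inversion leaves [0, 1] — cycles longer than `ln2/a` —
fall back to the tumor's constant `P_sleep`), and total-cell map → growth
strain → pressure → direction field. Between exchanges both fields are held
constant. Exchanges only set rates and directions; they never change cell
counts. Metabolic glucose consumption is *not* fed back into the transport
solve. The molecular→kinetics coupling is serial: the adjusted CKR is a
plain argument of the treatment schedule.

## Boolean fate engine

Threshold Boolean networks (`s_i(t+1) = 1` iff `Σ_j w_{ji} s_j > θ_i`,
synchronous updates — the update scheme is a modeling choice) are iterated
with visited-state hashing to a point or cyclic attractor (guaranteed in
≤ 2ⁿ steps). Fate predicates map attractors to progression / apoptosis /
senescence; the hybrid mode alternates a user-supplied fast module (held at
pseudo-steady state, discretized by interface thresholds into designated
nodes) with single Boolean steps. Radiation enters through the
damage-sensor node, activated with probability `1 − exp(−αD)`; only the
dose-linear term is representable in a discrete network, so survival is
multiplied by `exp(−βD²)` afterwards. The shipped 8-node network is a
synthetic fixture built to exhibit the three fate classes (damage latch,
p53–Mdm2 negative feedback oscillation, caspase point attractor); it is not
a published ruleset.

## Problem sizes and numerical choices

Shipped studies run on 5³–21³ grids with `dt` 1–2 h (`dt` must resolve the
shortest cycle phase), 7-voxel-radius phantoms and cohorts of 30–60 — sizes
chosen so a full cohort study takes seconds on one core while still giving
≥8 population doublings and well-resolved transport/elasticity fields.
Root finds use Brent's method to 1e−12 or tighter; sparse solves check
residuals at 1e−8; the cytokinetic step clips occupancies at −1e−6 of
capacity (guarding rounding) and aborts on NaN. All workflows are
deterministic given a seed; the simulator itself is mean-field and
seed-independent.

## Known limitations

No oxygen co-limitation or oxygen-dependent radiosensitivity; no
time-evolving vasculature (fixed vessel fraction); no agent-level
stochasticity (TCP uses expected stem counts); healthy tissue does not
remodel; the phantom generator produces homogeneous ellipsoids, not
patient anatomies — conclusions from the shipped fixtures are about the
coupled machinery, not about any clinical case.
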