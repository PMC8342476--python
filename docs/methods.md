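# Methods

## Model structure and assumptions

The package models steady-state leaf CO2 assimilation of C3, C3–C4
intermediate and C4 plants as the minimum of two independently evaluated
limitations: an enzyme-limited rate A_c and a light-limited rate
A_j = min(A_j^ATP, A_j^NADPH).  The leaf is treated as two well-mixed
compartments (mesophyll, bundle sheath) at a fixed mesophyll CO2 partial
pressure; stomata, mesophyll conductance dynamics, transient behaviour,
Rubisco activation state and leaf energy balance (leaf T = air T) are all
outside scope.  Day respiration defaults to zero so that the limitation
equations are reproduced literally; it is a config parameter.

**Nitrogen.** The photosynthetic nitrogen pool N_ps is a fraction of
total leaf nitrogen (`nps_fraction`, default 0.75 of N_t, converted
mmol→µmol; a linear placeholder for the phenomenological nitrogen map,
see *Provisional parameterisation*).  Three fractions summing to one buy
Rubisco catalytic sites (c_E = 1.27·10⁻³ sites per nitrogen), the
co-limiting C4 enzymes PEPC and PPDK (nitrogen per site MW* = 0.16·MW/14,
i.e. the 16% protein nitrogen mass fraction converted to a mole basis
with 14 g mol⁻¹ N — this interpretation keeps the V_pmax expression
dimensionally consistent with N_ps in µmol m⁻², and is configurable) and
the thylakoids.  Chlorophyll is linear in thylakoid nitrogen
(n_Chl = 0.0158887).  The LET proportion p splits PSI between the linear
and cyclic chains, PSII belongs to the linear chain, and the
light-harvesting complexes absorb each chain's remaining chlorophyll;
thylakoid nitrogen beyond the light-harvesting cost is cytochrome f,
which sets Jmax (172 mmol e⁻ per mmol cyt f and second, tripled for the
cyclic chain because it carries no PSII).  Negative light-harvesting
abundances (p below ≈ 0.237 with the default constants) are treated as
infeasible allocations — negative complex counts are unphysical — and the
optimizer's p bound starts there.

**Energy.** NADPH comes only from the linear chain (J_LET/2); ATP from
the linear chain at e_ATP = 4/3 electrons per ATP and from the cyclic
chain at 2 protons per electron with a configurable `h_per_atp`
(default 4, consistent with the linear-chain ratio).  Energy is
partitioned into five pools — Calvin–Benson cycle and photorespiration in
each compartment, plus the C4 cycle — by explicit optimizer variables
(the five fractions), since only the constraint principle (each process
limited by its allocated pool) is specified.  Demand stoichiometry per
carboxylation: 3 ATP and 2 NADPH for the Calvin–Benson cycle, 3.5 ATP and
2 NADPH per oxygenation for photorespiration, and 2 ATP per C4-cycle
turn.  Under light limitation the C4 pump runs at its ATP-pool budget in
both energy branches (the cycle consumes no net NADPH) and is zero for
species that cannot express PEPC.

**Bundle sheath.** The enzyme-limited pump is
V_p = C_m·V_pmax/(C_m + K_p).  Bundle-sheath CO2 solves the balance
pump + glycine-shuttle release (0.5·ξ·Vo_m) + 0.5·Vo_s = Vc_s +
g_s·(C_s − C_m); bundle-sheath O2 is elevated in proportion to the PSII
fraction operating there (set to p): O_s = O_m + p·A/(0.047·g_s), with
0.047 the O2/CO2 diffusivity ratio.  The CO2 balance is solved by
bracketed Brent iteration (absolute tolerance 10⁻¹⁰ µbar) inside a damped
fixed-point iteration on O_s (tolerance 10⁻¹⁰ mbar, 0.5 damping after ten
steps, hard failure raised on non-convergence).  Net assimilation is
Vc_m + Vc_s − 0.5(Vo_m + Vo_s); the shuttle relocates CO2 release without
changing the leaf-level balance.  With V_pmax = 0, ξ = 0 and all Rubisco
in the mesophyll the model reduces exactly to the single-compartment C3
rate, which the tests verify against an independent transcription.

**Rubisco kinetics.** A single turnover number k_ccat per species implies
K_c, K_o and the CO2/O2 specificity through a monotone log–log trade-off
between two anchor parameter sets (k_ccat 2.9 s⁻¹ → K_c 260 µbar,
K_o 179 mbar, S_co 2590; k_ccat 3.8 s⁻¹ → 650, 450, 2280), reflecting the
classical observation that faster Rubiscos are less specific.  The
anchors are configurable per species.

**Temperature.** Every kinetic quantity follows the peaked Arrhenius form
f(T) = k25·exp[E(T−298.15)/(298.15·R·T)] ·
[1+exp((298.15S−H)/(298.15R))]/[1+exp((TS−H)/(TR))], H = ∞ reducing it to
plain Arrhenius.  Defaults (J mol⁻¹): V_pmax (70 373, 117 910, 376),
k_ccat (67 294, 144 568, 472), J_max (77 900, 191 929, 627) as peaked
responses; K_c (79 430), K_o (36 380), K_p (36 300) and S_co (−37 830) as
plain Arrhenius.  All are provisional literature-style values and fully
config-overridable.  Temperatures are Kelvin internally and °C at every
interface.

## Optimization

The decision vector is (n_Etot, n_C4, p, four energy fractions); the
thylakoid fraction and the fifth energy fraction are simplex residuals
constrained by linear inequalities, which removes the equality
constraints.  Because the surface is ridged where the binding limitation
switches, the pipeline is multistart SLSQP (default 20 starts from a
seeded scrambled-Sobol sequence repaired onto the feasible region,
relative objective tolerance 10⁻¹⁰, final polish at 10⁻¹²), bitwise
reproducible for a given seed.  Photosynthetic-type constraints are per-
pool bounds; C3 species have a zero upper bound on n_C4, and allocations
with n_C4 = 0 get their C4 energy fraction projected to zero (no demand).
An exhaustive grid oracle (simplex grid over nitrogen fractions and p,
integer-composition grid over energy fractions) provides an independent
lower bound for testing; it is within its grid spacing of the optimum of
the evaluated surface, so optimizer checks are dominance checks.

## Analyses

δ_n sums |Δn_i| over the three nitrogen pools only (p is not a nitrogen
pool).  Scenario fits are scored by squared residuals normalized to the
per-quantity experimental means and compared by a two-sided Wilcoxon
rank-sum test (exact for combined n ≤ 20 without ties, otherwise normal
approximation with continuity correction); paired δ_n comparisons across
photosynthetic types use a two-sided sign test.  The environment scan
optimizes allocation in every (I, T, C_m) grid cell at fixed O2, predicts
the measured quantities (optionally at a separate measurement
environment) and returns the error surface and its argmin; failed cells
score NaN and are excluded.  Response curves (A–Ci via the Cm/Ci ratio,
A–T, A–N) keep the allocation fixed along the sweep, since protein
re-allocation is far slower than a gas-exchange measurement.

## Synthetic data

`synthetic_measurements` emulates pool-measurement data (A, chlorophyll,
PSII, cytochrome f and the three nitrogen pools) as model predictions
times (1 + ε), ε ~ N(0, noise_sd²), seeded.  It reproduces measurement
noise magnitude but none of the structure of real data: no systematic
instrument bias, no between-plant correlation, no model misspecification.
Passing recovery tests therefore show that the inference machinery is
self-consistent and noise-robust, not that the model is correct for real
leaves.

## Provisional parameterisation

The published species-level parameter sets (β, k_ccat, ξ, K_p, g_s,
allocation bounds), the empirical nitrogen map N_ps(N_t), the chlorophyll
relation and the fitted temperature parameters were not available when
this package was written.  The shipped archetypes are literature-style
stand-ins marked `provisional=True`: C3 (β = 0, k_ccat = 2.9, ξ = 0),
C3–C4 (β = 0.25, ξ = 0.95, n_C4 ≤ 0.1), C4-like (β = 0.95, ξ = 1) and C4
(β = 1, k_ccat = 3.8, ξ = 1), all with K_p = 80 µbar and g_s = 0.003
µmol m⁻² s⁻¹ µbar⁻¹.  The evolutionary preset is 1500 µmol quanta
m⁻² s⁻¹ (an assumption), 30 °C, 280 µbar atmospheric CO2 and 200 mbar O2;
growth presets mirror the three growth-chamber studies.  Default Ca/Ci is
1/0.7 for C3 and C3–C4 and 1/0.4 for C4 types (assumptions, per-species
configurable), with Cm/Ci = 0.85.  Consequently the absolute δ_n table
and cytochrome-f contents computed from these archetypes are not expected
to reproduce the published species-level values; the corresponding
acceptance tests state the published numbers and currently fail under the
provisional archetypes, which is the honest status.  Re-running them
after transcribing a species table is the intended upgrade path.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on single evaluations or ≤ 100 random draws.
The optimizer acceptance check uses five seeded (species, environment)
cases with a resolution-7 nitrogen/p grid and composition-3 energy grid
for the oracle and 10 multistarts for the optimizer.  The environment-
recovery check optimizes a 5×5×5 grid once (4 starts per cell) and scores
20 seeded 5%-noise replicates with the scan's residual rule; the
acceptance script repeats this at 3×3×3.  The δ_n table uses 8 starts per
optimization (32 optimizations).  These sizes are the package defaults
for a laptop-scale run; all are parameters.

## Known limitations

Energy partitioning uses fixed fractions of total supply per pool rather
than a mechanistic metabolic network; the C4 pump's light-limited rate is
tied to the ATP pool alone.  ξ has no energy cost of its own in the
light-limited branch (the shuttle's NADH bookkeeping is not modelled).
The min-structure makes the assimilation surface non-smooth, so SLSQP
occasionally needs its multistart; the grid oracle bounds the miss risk
in tests.  The linear N_ps(N_t) map overstates photosynthetic nitrogen at
high leaf N compared to saturating empirical fits.
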