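# Methods

`ligfrac` simulates one-pot acid-solvent fractionation of hardwood lignin as
a two-scale stochastic process and closes the loop with a model-predictive
controller (MPC) on the molecular outputs. This note records the model, the
numerical choices, the calibration of parameters that have no published
values, and what the synthetic study conditions do and do not represent.

## System representation

Lignin is a population of linear chains of syringyl (S, 227.2 g/mol) and
guaiacyl (G, 179.2 g/mol) monolignols. A chain is its explicit unit
sequence; chain molar mass is the plain sum of unit masses (no linkage
correction — the monomer masses and every molar-mass anchor used here are
consistent with simple additivity). Chains belong to the solid *chip* phase
or the dissolved *liquor* phase. The registry keeps both populations with
incrementally maintained aggregates (counts, ΣM, ΣM², unit and S-unit
counts), so Mn = ΣM/n, Mw = ΣM²/ΣM and S/G are O(1) reads at any time; a
brute-force recomputation is kept as a test oracle. Branched topologies,
carbohydrate co-polymers and spatial structure are out of scope.

## Macroscale: delignification, redeposition, heat

Gross interphase mass flows are first order in the source-phase lignin mass
with Arrhenius coefficients k_D(T_c), k_R(T_f). The two-phase energy
balance couples chip and liquor through an overall heat-transfer
coefficient U; the liquor exchanges heat with an external jacket stream
(temperature T_ext, flow Ṁ_ext) — the two manipulated inputs. Both
balances are integrated by explicit Euler at Δt = 5×10⁻⁴ min; at the
default parameters the fastest eigenvalue times Δt is ~10⁻³, and the
integrator is verified against the closed-form solution of the two-state
exchange system to first-order accuracy over 30 min (with a Richardson
half-step check). Flows accumulate in dissolved/redeposit budgets; whenever
a budget covers the mass of some chain in the source phase, one chain —
uniform among those light enough — changes phase and the budget is charged.
An emergent consequence of this mass-eligibility rule is a slight
light-chain (hence G-rich) bias of early dissolution: the liquor starts
near S/G ≈ 1.70 against the population's 1.76. Diffusion and early
solid-liquid interfacial chemistry are not modeled.

## Microscale: Gillespie direct method over three reaction classes

Dissolved chains react through:

* **Depolymerization** — scission of one β-O-4 bond; propensity
  A_dep·exp(−E_dep/RT_f)/Ω per bond, with E_dep keyed by the flanking
  S/G dyad and temperature (table, linearly interpolated and clamped).
* **Condensation** — merging of two chains; second order, propensity
  A_con·exp(−E_con(M_i+M_j)/RT_f)/Ω² per unordered pair. E_con is
  V-shaped in the combined molar mass with its minimum at 972 g/mol and
  equal linear slopes on both sides.
* **Demethoxylation** — conversion of one S unit to G (−48.0 g/mol);
  propensity A_dem·exp(−E_dem/RT_f)·f_S/Ω per chain, f_S the S fraction.
  With E_dem = 764 kJ/mol this channel is extraordinarily temperature
  sensitive (×1300 from 353 to 363 K): it is what makes the S/G ratio a
  controllable output and it is effectively frozen below ~350 K.

Ω converts chain copy number to concentration (C = 1/Ω per copy); it sets
the absolute event-rate scale but not the shape of the (Mw, S/G) path.
Within each macro step the engine draws exponential waiting times
δt = −ln ξ / r_tot and selects events by cumulative-sum inversion; the
event straddling the interval boundary is discarded and the time redrawn
next interval, which is statistically exact by memorylessness. Between
events, propensities are refreshed when T_f drifts more than 0.005 K
(quasi-static approximation; ≤0.1% rate error).

### Event catalog

Two interchangeable catalog realizations share one canonical event order —
scission events grouped by bond dyad, condensation grouped by unordered
pairs of exact composition classes (n_S, n_G), demethoxylation per chain —
so that the production engine and the explicit per-event oracle can be
compared event for event, and the filtered engine is *bit-identical* to the
full one whenever the filter excludes nothing. Grouping is exact, not an
approximation: all events in a group share one rate coefficient, so
hierarchical inversion plus a uniform member draw reproduces per-event
sampling. The live catalog subscribes to the registry and updates only the
entries of chains touched by an event; a full rebuild is the oracle path.

## Threshold filtering

Events whose coefficients are more than ratio_cutoff (default 1000) slower
than the fastest competitor contribute negligibly to r_tot; by the
Arrhenius form this is an energy margin ΔE_th = R·T_f·ln(ratio_cutoff)
(20.27 kJ/mol at 353 K), recomputed as T_f changes. Per chain, scission
sites with E_dep more than ΔE_th above that chain's most labile site are
excluded; for condensation the margin inverts to a combined-mass window
(at 353 K, up to 1672.33 g/mol, i.e. all-G combined degree of
polymerization 2–9), enumerated through the composition-class index rather
than a pairwise scan. Demethoxylation shares one barrier and is never
filtered. Excluded events are provably ≥1000× slower than their reference;
sampling among retained events is unchanged.

## Stand-in parameters and calibration

The per-dyad scission energies, the condensation energy offset, Ω and all
macroscale rate/thermal parameters have no published values; they are
shipped as documented, fully configurable stand-ins. They were fixed once,
by the following reasoning, and are not tuned per run:

* **E_dep table.** Anchors: with the published A_dep and demethoxylation
  constants, both channels must be active on the 30-min, 343–363 K
  operating window, with depolymerization dominant and the S/G ratio
  strongly temperature sensitive. This places E_dep near 190 kJ/mol
  (187.5–195 across dyads at 353 K, S-rich contexts more labile). The
  363 K column sits 5 kJ/mol above the 353 K column — a mild entropic rise
  of the effective free-energy barrier — so scission still accelerates with
  temperature (×1.9 per 10 K) but more slowly than demethoxylation
  (×1300 per 10 K). This ordering makes the published operating targets
  (weight-average molar mass 1500 g/mol *and* S/G 1.50 reached together
  within 30 min) attainable: on the hot path the S/G = 1.50 crossing
  occurs near Mw ≈ 2100, above the Mw set-point, so a controller can land
  S/G hot and then trim Mw cold with the S/G frozen. With a steeper
  scission channel the crossing would occur near Mw ≈ 1100 and the
  set-point pair would be unreachable in principle.
* **Ω = 3.5×10⁻⁴**, setting the traversal speed so the hot-path crossing
  happens near t ≈ 18 min of a 30-min run.
* **e_min = 228 kJ/mol**, making condensation a real but subdominant
  channel (~1–3% of events). The V-slopes default to
  ΔE_th(353 K)/(1672.33−972) ≈ 0.0289 kJ·mol⁻¹ per g/mol on both sides,
  anchoring the 353 K window; the symmetric lower slope keeps the lower
  window edge (≈272 g/mol) below any two-unit pair, so only the upper
  bound ever binds.
* **Macro stand-ins** (A_D = 8.3×10¹⁰, E_D = 80; A_R = 550, E_R = 30
  kJ/mol; lumped heat capacities for a 10 g chip / 100 g liquor system
  with an aqueous jacket stream; ΔH_R mildly endothermic): delignification
  half-life ~6 min at 353 K, remaining-chip plateau 9–17% set by
  redeposition, faster and deeper at 363 K; jacket time constant ~1 min at
  full flow, ~2.5 min at minimum flow, so the flow rate controls the
  heating slope.

Verification of the calibration is qualitative by design: remaining-lignin
curves fall fast and converge, lie lower at 363 K than at 353 K, and
molecular trajectories bracket the control set-points from both sides.

## Model-predictive control

Every 5 min the controller measures the liquor Mw and S/G (direct state
feedback, no noise or delay), evaluates candidate jacket profiles over the
shrinking horizon to the fixed 30-min terminal time, and applies the first
move of the best profile. The objective is the weighted squared terminal
deviation with weights 1/setpoint² (normalizing both outputs); constraints
are the actuator boxes (343–363 K, 40–100 mL/min) and the 5 K per-interval
ramp limit.

The optimizer is an exhaustive, derivative-free grid search over
*two-block* ramp-feasible profiles: ramp toward a hold target v₁, switch at
some interval, ramp toward v₂. The target grid coarsens with the horizon:
5 K while the only strategic question is when to start heating, 2.5 K with
three intervals left (where the demethoxylation dose is shaped), 1.25 K
with two, and 0.3125 K at the final solve — the demethoxylation dose
shrinks by ×0.8 per 0.3125 K near 363 K, so fine jacket temperatures are
the fractional-dose actuator that lands the S/G ratio between the coarse
5-min input blocks. This family contains the heat-pulse/cool-down shapes
the terminal problem calls for; a hold-last-value move-blocked family
cannot descend after an early heat-up and measurably fails. Candidates are
simulated on an internal replica of the plant — chains thinned by 0.4
(the full population for the last two solves), Ω
unchanged (first-order hazards are population-free; only the subdominant
condensation channel is thereby underestimated), macro step coarsened
×20 — under common random numbers, with a two-stage scheme: every
candidate once per replicate seed, then the leaders re-evaluated with
extra seeds (doubled replicates at the final solve) and ranked by the
pooled mean. While more than two intervals remain, leaders statistically
indistinguishable at the observed replicate scatter are re-ranked to
prefer profiles that finish cool and do their heating early — a cool tail
means low terminal output velocity and early work keeps late-stage
authority in reserve; the last two solves are a pure pooled argmin, since
any preference there systematically biases the landing. Setting the
indifference band to zero reduces the solver to a strict argmin, which is
verified against brute force on a deterministic (macro-only) surrogate.

Closed-loop tracking of the (1500 g/mol, 1.50) set-point pair at the
500-chain plant scale is intrinsically stochastic: the weight-average
molar mass of a few-thousand-chain population fluctuates by roughly 1.5 %
over a hot 5-minute interval, and the S/G dose is quantized by the
measurement blocks, so final relative errors of a few tenths of a percent
up to about two percent are the expected single-run range.

## Synthetic study conditions

The generator creates pristine chip-phase chains with per-unit Bernoulli
composition (S probability 1.76/2.76) and lengths 1 + Poisson(μ−1) with μ
matching a number-average molar mass of 13,000 g/mol. It reproduces the
measured pristine averages but idealizes real hardwood lignin: the length
distribution is much narrower than a real GPC dispersity (~1.02 vs 2–4),
composition is uncorrelated along the chain, and chains are strictly
linear. Passing tests therefore demonstrate correctness of the simulator
and controller under these idealized conditions, not quantitative
agreement with fractionation experiments — the published per-bond energy
library and macro rate constants this would require are not reproduced
here. Default run sizes (500-chain plant, 200-chain internal replicas,
5,000-chain initializer checks, 20 replicate pairs for the filtered-vs-full
comparison) were chosen as the package's desk-scale study conditions.

## Degenerate inputs and numerical conventions

Energies are kJ/mol, converted to J/mol at a single exponent evaluation
point; underflowing coefficients clamp to zero (counted, never NaN).
Single-unit chains have no scission events; all-G chains have zero
demethoxylation propensity; empty phases raise on Mn/Mw and a G-free phase
reports an infinite S/G. Ties in cumulative inversion resolve to the first
index; rounding spill-over selects the last positive-propensity event.
Chain ids are unique across phases for the life of a run. All randomness
flows from seeded generators; a run is reproducible byte-for-byte from its
configuration hash and seed.

## Known limitations

Beyond the synthetic-data idealizations: condensation junctions are
kinetically ordinary β-O-4-type bonds (cleavable, dyad-keyed — a config
switch can make them inert); redeposited chains keep their liquor-phase
modifications; the internal MPC model underestimates condensation by its
thinning fraction; the quasi-static propensity refresh tolerates 0.005 K
of temperature drift; and CPU-time comparisons against other acceleration
schemes are hardware-dependent and deliberately not reproduced — the
benchmark subcommand reports candidate-reduction factors instead.
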