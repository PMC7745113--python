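# Methods

## Physical model

The reactor is a straight PTFE tube (length *L*, inner diameter *ID*,
aspect ratio ≥ 100) immersed in a temperature-controlled bath.  Two neat
reagent streams (M4MAA, density 1118 kg m⁻³, M = 146.14 g mol⁻¹; DMF-DMA,
897 kg m⁻³, 119.16 g mol⁻¹) merge at a tee in a molar ratio χ
(DMF-DMA : M4MAA) and total flow *Q*.  The stream split solves
F₁ = Q₁ρ₁/M₁, F₂ = Q₂ρ₂/M₂, F₂/F₁ = χ, Q₁+Q₂ = Q; the combined stream is
assumed perfectly premixed at the inlet — at the Péclet numbers of these
flows, mixing completes within centimetres of the tee, so the tee itself is
not modelled.

Inside the tube, species transport is

∂cᵢ/∂t + u(r) ∂cᵢ/∂z = D ∇²cᵢ + νᵢ k(T) c_A c_B

with an imposed Poiseuille profile u(r) = 2ū[1 − (r/R)²].  The momentum
equation is deliberately not solved: Re ≈ 0.2–5 over the whole design space
and the density change on reaction is small, so the parabolic profile is an
excellent approximation and removes the most expensive coupling.  The
energy balance is the analogous advection–diffusion equation with
volumetric source (−ΔH)·k c_A c_B, thermal diffusivity α = k_th/(ρ c_p)
from the feed-mixture properties, Dirichlet wall temperature (the bath),
and a room-temperature (295.15 K) inlet.  Stoichiometry is
A + B → P + 2 MeOH; methanol is carried as a species purely so the mass
balance closes.

Kinetics: second order (first order in each reactant),
k(T) = A e^(−Ea/RT) with Ea = 57.93 kJ mol⁻¹ and
A = 2.00 × 10⁸ L mol⁻¹ min⁻¹ (converted once to SI at configuration load).
The rate constant at 40 °C is 4.34 × 10⁻² L mol⁻¹ min⁻¹.

Boundary/initial conditions: symmetry at the axis (zero radial flux), zero
species flux and bath temperature at the wall, Dirichlet premixed inlet,
zero-gradient outflow.  The initial state holds a linear axial gradient of
M4MAA (inlet strength at z = 0, zero at the outlet) at the bath
temperature — a "primed" reactor.  The shape of this gradient is a free
choice (only its endpoints are physically motivated); the steady state is
independent of it.  Runs integrate to five residence times by default;
steady state is declared at the earliest recorded time after which the
outlet yield stays within a relative tolerance (default 1%) of its
final value.

Outlet yield is the mixing-cup (flow-weighted) enamine molar flow divided
by the limiting-reagent feed molar flow — what an outlet HPLC sample
measures.  The limiting reagent is DMF-DMA for χ < 1 and M4MAA for χ > 1.

## Numerics

Finite volumes in r (flux form with radial face metrics, so the axis needs
no special casing: the r = 0 face has zero area), first-order upwind
advection plus central axial diffusion in z, and Lie splitting in time:
explicit advection → explicit axial diffusion → explicit reaction/heat
release → implicit (backward-Euler) radial diffusion, the stiff direction,
solved as batched tridiagonal systems (one `solve_banded` call per step for
all species and axial positions at once; a second for temperature with its
Dirichlet wall row).

The time step is the advective CFL (Courant 0.9), capped by the explicit
axial-diffusion and reaction stability limits (never binding in practice).
At near-unit Courant number, upwind transport is nearly exact along each
row; the residual numerical axial diffusion (~u·Δz/2) is three orders of
magnitude smaller than the axial scale of the yield profile and shifts the
outlet yield by ≲0.1 point (the grid-doubling test bounds the total
discretisation error at < 0.5 point, mirroring the original study's
mesh-independence argument).  Concentrations are clipped at zero after the
reaction substep; a non-finite outlet triggers a solver error carrying the
grid and step context.

Default grids: 32 × 400 (r × z) cells, five residence times, snapshots
every 0.1 τ for single-case studies; 24 × 200 cells, three residence
times, no snapshots for the 32-run factorial campaigns (≈0.6 s per case;
the grid-doubling check shows the campaign grid is converged to
< 0.1 point).  Zero-diffusion studies integrate to 13 residence times: the
slowest resolved streamline moves at ~0.08 ū and must flush its initial
fluid before the segregated steady state is meaningful.

## Validation oracles

Two closed-form reactor models bracket the solver:

* **Plug flow** — the integrated second-order batch law at the mean
  residence time.  The batch law uses
  x(t) = a·b·expm1(Δkt)/(Δ + b·expm1(Δkt)), Δ = b − a, which limits
  smoothly onto the equal-feed form x = a²kt/(1+akt) (handled exactly at
  Δ = 0).  At D = 10⁻⁶ m² s⁻¹ the radial mixing time R²/D is far below τ
  and the solver matches plug flow within one point.
* **Segregated laminar flow** — each streamline an independent batch
  reactor, averaged over the laminar RTD E(t) = τ²/2t³ (t ≥ τ/2).  The RTD
  integral is evaluated after the exact substitution q = τ²/4t² (survival
  mass), which maps it onto (0, 1] and removes any tail truncation; the
  result is cross-checked against 10⁶ Monte-Carlo RTD draws.  At
  D = 10⁻¹² m² s⁻¹ the solver matches this oracle within 1.5 points.

### Diffusion independence: a deliberate red test

The original study reports the outlet yield at the 39.3 min / 40 °C / χ =
0.95 condition as independent of the diffusivity over 10⁻⁶–10⁻¹² m² s⁻¹.
Analytically this cannot hold: those endpoints are exactly the two oracles
above, which at this conversion differ by 3.5 points (88.7% vs 85.3%).
Since this solver reproduces both limits, its measured sweep spread is
≈3.3 points, and the acceptance test encoding the < 2-point claim fails by
construction.  We keep the test red rather than widen the band: the
discrepancy is a finding (the original claim is consistent with numerical
radial diffusion in the original discretisation), not a solver defect.

## Screening analysis

Designs: full 2⁵ (32 runs) or the resolution-V half fraction with generator
E = ABCD (16 runs; two-factor interactions aliased only with three-factor
ones).  Factor levels (low/high): L 1/5 m, ID 0.25/1 mm, Q 0.1/1 mL min⁻¹,
T 10/40 °C, χ 0.95/1.5.

The response is log₁₀ of percent yield with a 0.01% floor (yields span
three decades across the design space; the floor guards degenerate runs).
Effects are orthogonal-contrast estimates (coefficient = effect/2), ranked
on half-normal quantiles, and screened with Lenth's method: s₀ = 1.5 ×
median|effect|, PSE = 1.5 × median of effects below 2.5 s₀, per-effect
margin t(1−α/2, m/3)·PSE.  The per-effect margin controls each contrast's
error rate; for the family-level question "is the flagged set exactly the
active set" the simultaneous margin (SME, quantile (1+(1−α)^{1/m})/2) is
reported alongside and is what the planted-effect validation uses for
exact-set recovery (98% over 200 repetitions, versus 84% for the per-effect
margin — the expected behaviour of eleven null contrasts at ~1% individual
error each).

`FactorialModel` fits the retained terms (parents of retained interactions
are added automatically to maintain hierarchy) by OLS in coded units, and
reports model F/p, per-term p, R², adjusted R², PRESS-based predicted R²,
and — when replicates exist — pure error and the lack-of-fit F test.

## Synthetic bench campaign

The triplicate pseudo-experimental campaign deviates from the clean
simulator through three channels, each a documented stand-in (the true
magnitudes were never measured):

* **Impurity side-channel**: consecutive first-order consumption of the
  enamine, k_imp = A_imp e^(−Ea,imp/RT) with A_imp = 5.5 × 10¹⁰ min⁻¹ and
  Ea,imp = 80 kJ mol⁻¹ — *tuned, and disclosed as tuned*, to reproduce the
  reported abundance pattern: < 0.5% at short residence times, ~5.8% at
  39.3 min / 40 °C (within the reported 2–9% band).  The high activation
  energy concentrates the impurity in hot, long-residence runs.
* **Imperfect bath**: the effective wall temperature relaxes 5% (plus 1%
  growing along the coil) of the way toward ambient (293.15 K), so chilled
  runs sit slightly warm and heated runs slightly cool.  This sign
  structure — not a constant offset — is what produces the reported parity
  pattern of underestimation at low yields and overestimation at high
  yields with a crossover near 20%.
* **Replicate noise**: multiplicative lognormal on yield, CV 3%,
  mean-preserving (HPLC area ratios are positive and roughly
  scale-proportional).  A fixed seed reproduces the campaign bit for bit.

What a green test here establishes: that the *machinery* (campaign →
screening → parity) reproduces the qualitative structure of the reported
comparison under a plausible deviation model.  It does **not** establish
the reported per-run experimental yields, the absolute error extremes
(2.4%/19.1%), the parity slopes 0.85/1.31 as predictions, or the
experimental ANOVA constants — those depend on unpublished per-run data
and are exercised only through constructed fixtures.

## Known limitations

* Straight tube only: coil curvature (Dean vortices), the tee junction,
  and pressure drop are outside scope.
* Species viscosities and heat capacities stand in for unavailable measured
  values; they set Re and the thermal entrance length but no screening
  conclusion.  The heat of reaction (−50 kJ mol⁻¹) is a placeholder
  magnitude used only by the energy balance (the reaction's thermal
  footprint at these scales is < 0.3 K).
* First-order upwind advection is diffusive at low axial resolution; the
  default grids keep this below 0.1 point but very coarse custom grids will
  blur axial profiles.
* The impurity mechanism is an assumed model; only its disclosed, tuned
  abundance pattern is meaningful.
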