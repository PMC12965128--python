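# Methods

## The model

Each titratable aminolipid carries two slow coordinates: the titration
coordinate λ (0 = protonated amine, +1 e; 1 = deprotonated, neutral; site
charge interpolates linearly and is not clamped) and a signed insertion
depth d along the membrane normal (d < 0 inside the membrane). Protonation
states are classified only outside the barrier window: protonated iff
λ < 0.2, deprotonated iff λ > 0.8; intermediate frames are excluded from
both the numerator and denominator of the deprotonated fraction
S_deprot = N_deprot / (N_prot + N_deprot).

Three analytic potentials act on λ:

* **Correction potential** `V_MM(λ) = −ΔG_MM(λ)`, represented as a
  polynomial. Its coefficients come from a least-squares fit (default
  order 9) to negated per-window means of dV/dλ sampled on the 25-window
  grid λ = −0.10 … 1.10 (spacing 0.05), integrated analytically with
  V_MM(0) = 0 — the additive constant is irrelevant because only forces act
  on λ. The toy TI sampler draws Gaussian noise around the analytic
  derivative of a model free energy; window convergence is monitored as a
  running mean, with no automatic stopping rule.
* **Barrier bias** `V_bias(λ) = h (1 − cos(πλ)^(2m))` with h = 7.5 kJ/mol
  and sharpness m = 4, plus quartic soft walls outside [−0.10, 1.10]
  (strength 10⁴ kJ/mol per λ⁴). The form satisfies the required
  invariants — zero at λ ∈ {0, 1}, symmetric about 0.5, maximum exactly h —
  and its parameters were chosen by direct quadrature of the tilted
  potential so that the equilibrium occupancy ratio of the two classified
  wells tracks the ideal Boltzmann factor to < 10⁻³ in S_deprot over a
  ±5 pH-unit driving force. Softer designs measurably flatten the
  titration curve: when a driving force tilts the potential, the favored
  well is pushed into its confining wall and loses partition function, so
  well stiffness (the m exponent) and wall softness jointly control how
  faithfully S(pH) follows the Henderson–Hasselbalch (HH) law.
* **pH driving force** `V_pH(λ) = RT ln10 (pKa_ref − pH) λ` — the unique
  linear form for which an ideal site titrates along the HH curve. One pH
  unit is RT ln10 = 5.934 kJ/mol at 310 K.

λ excursions past the re-initialization threshold 1.15 reset the site to
λ = 1 (mirror rule at −0.15 resets to 0); events are counted and logged.
With the default soft walls this rule recycles outer-tail mass back into
the wells; it conserves the per-class counts, so S_deprot is unaffected,
but the λ-histogram validation (p(λ) ∝ e^(−V_bias/RT)) is run with a fully
confining wall (strength 10⁷) so the stationary law being checked is the
one actually applied.

## The stochastic engine

Both coordinates advance by Metropolis-adjusted overdamped (MALA) moves:
an Euler–Maruyama proposal with mobility D and timestep Δt, accepted with
the standard asymmetric-proposal ratio. The acceptance step makes the
stationary distribution of each conditional move exactly Boltzmann at any
timestep — titration recoveries are then limited by sampling, not by
discretization. Defaults (Δt = 0.1 ps, D_λ = 0.05 ps⁻¹,
D_z = 5·10⁻⁴ nm²/ps) give ≈2·10³ barrier crossings per 100 ns-equivalent
at pH = pKa and a surface-to-core diffusion time ~20× longer than a
protonation flip, reproducing the fast-switching / slow-migration
phenomenology of ionizable lipids in membranes.

The λ and depth moves are the two conditionals of a single joint
Boltzmann measure. Its λ-section is the local titration law with the
depth-dependent apparent pKa; its z-section is a protonated surface well
(Gaussian, depth E_surf, σ = 0.5 nm), a state-independent core attractor
(E_core at d = −2.2 nm), and — by thermodynamic-cycle consistency — a
λ-linear term `λ RT ln10 (pKa_app(d) − pKa_core)` that drives deprotonated
sites down the pKa profile into the core. The local pKa profile is a
logistic interpolation between a surface value (7.5) and a core value
(4.0) with midpoint −0.5 nm and steepness 6 nm⁻¹, monotone non-increasing
into the membrane. Optional anionic mRNA loci add a Gaussian (σ = 0.4 nm)
stabilization of the protonated state at a fixed insertion depth, raising
the local pKa and attracting protonated lipids — loci are parameterized in
depth (not z) so they stay attached to the leaflet as the membrane
thickens. Anti-cooperativity enters as a mean-field penalty
`a (1 − f_prot)` on the deprotonated state, with f_prot the protonated
fraction in the site's 0.25-nm depth bin; this is deliberately not pairwise.

Because the joint measure is explicit, the emergent global titration curve
of a membrane patch can be computed by two-dimensional quadrature without
dynamics. The calibrated surface well depth (11.43 kJ/mol; core attractor
3.6 kJ/mol) is the root of that quadrature for a global apparent pKa of
4.91, the headline value the generators are built to emit
(`scenarios.predict_global_pka`). Membrane-patch runs start from a joint-
equilibrium draw; a protonated-bilayer start equilibrates extremely slowly
near the transition pH (a real feature of these systems that is outside
the generators' scope), and analyses additionally discard an initial
fraction of frames.

Every (pH, replica) system advances as one row of a vectorized batch;
rows are statistically independent and runs are bit-for-bit reproducible
under one master seed (per-stream seeds derive from a SeedSequence split).

## Statistics

* **IRLS.** HH (pKa) and generalized-HH (pKa, n) curves are fitted by
  iteratively reweighted least squares: initial weights 1/σ², then
  `w = h(1−h)/σ²` evaluated at the previous iteration's parameters (the
  constant ln10 or n·ln10 prefactors are omitted — they cancel up to the
  σ² mixing), iterated until the parameter-step two-norm falls below 10⁻⁸
  (default cap 100 iterations). Each inner weighted fit is a damped
  Gauss–Newton solve with analytic Jacobians. If every σ is zero the fit
  falls back to unit weights with a warning; isolated zero σ values are
  clamped to the smallest positive one. Start values come from a
  logit-linear regression of the unsaturated points.
* **Bootstrap.** Parametric: every replicate redraws each point from
  Normal(mean, sem) — without clipping to [0, 1]; the model is evaluated,
  never inverted, so mildly out-of-range draws are harmless — and refits.
  Reported values are bootstrap means with central 95% intervals
  (2.5/97.5 percentiles); a warning is raised if more than 1% of
  replicates fail to converge.
* **Blocked SEM.** Block-averaged SEM estimates over a geometric ladder of
  block sizes are extrapolated to the plateau with a single- or
  double-exponential model (selected by residual sum of squares); the
  plateau is the reported SEM. Exact functional forms of the original
  block-averaging extrapolation are not prescribed here; the contract is
  the plateau value, verified against closed forms for white noise
  (σ/√N) and AR(1) (σ/√N · √((1+φ)/(1−φ))).
* **Equilibration.** For candidate starts 0, k, 2k, … an OLS line is fitted
  to the remaining segment; the drift |ŷ(last) − ŷ(first)| is divided by
  the segment's standard deviation and the first start with ratio < 1 is
  taken. A zero-variance segment counts as equilibrated; a series that
  never passes returns a "not equilibrated" sentinel (None), and a manual
  start override is available and logged. The step defaults to the
  frame-count equivalent of 5 ns.

## Spatial analyses

The surface of each leaflet is the per-frame median z of the DSPC
phosphates (midpoint convention for even counts; frames missing a leaflet
are skipped with a warning). Insertion depth is d = z − median_upper
(upper) or median_lower − z (lower), negative inside the membrane; leaflet
membership is re-evaluated each frame from the midplane sign, so leaflet
crossers are handled, and all spatial statistics are invariant under
mirroring z about the midplane. Depth-binned S_deprot uses 0.25-nm bins
with per-bin blocked SEMs (binomial fallback below 100 frames). Local
(pKa, n) maps fit the generalized HH per bin, keeping only bins with data
at ≥ 3 pH levels and centers in (−1.2, 0.2] nm; non-converged bins are
flagged, not fatal. Core/shell assignment uses the 1.8-nm depth cutoff;
molar fractions cover lipid species, and core water is reported as a
per-frame count. The surface charge density counts protonated aminolipids
within 1.8 nm of the surface per leaflet per frame (a per-area proxy —
only the ratio normalized by ρ_max is used, so constant area factors
cancel; ρ_max defaults to the series maximum, the designated low-pH
reference). Membrane thickness is the time average of the inter-leaflet
median distance over the equilibrated range; the LNP diameter estimate
d = 3t equates a slab's surface-to-volume ratio 2/t with a sphere's 3/r
and is labeled an interpretation in run metadata.

## Calibration constants

All generator targets live in `src/lnptitrate/calibration.yaml`: intrinsic
pKa 9.26, global apparent pKa 4.91, surface pKa_LNP 5.47 with a +0.39
probe offset (→ 5.86), surface cooperativity 0.5 rising to 0.8 at 1.1 nm
depth, local pKa 7.5 (surface) → 4.0 (core), bilayer thickness 2.85 nm
scaling fivefold to ≈14.2 nm in the LNP phase (diameter 3t ≈ 42.6 nm).
Surface-bin titrations use 7 pH points at ±1.8 units around the bin pKa —
for n = 0.5 this covers S from 0.11 to 0.89 and minimizes the variance of
the fitted cooperativity at the 0.02 noise level.

## What the generators do and do not emulate

The synthetic data reproduce the *statistical* structure the analyses
assume: bimodal λ histograms with ns-scale switching, depth-dependent
local titration, monotone deprotonation profiles, surface-enriched helper
lipids, a dry core (hydrated only near mRNA loci), pH-dependent
thickening, and calibrated headline pKa values. They do not emulate
atomistic electrostatics, acyl-chain order, probe orientation, leaflet
asymmetry, or the very slow non-equilibrium convergence near pH 5–6;
passing recovery tests therefore demonstrates the correctness of the
statistical pipeline and the self-consistency of the toy physics, not
force-field accuracy on real trajectories.

## Problem sizes

Default study sizes were chosen so each protocol resolves its target well
inside the stated tolerance: the intrinsic-pKa run uses 11 pH × 10
replicas × 1.5·10⁵ steps (recovery scatter ≈ ±0.02 around a ≤0.01 residual
bias); parametric tables use the printed pH grids with noise 0.01–0.02 and
10⁴ bootstrap replicates; patch runs use 122 sites with 6·10⁴ steps
(> 10⁵ site-frames per pH after the equilibration discard).

## Known limitations

* The alternating-conditional sampler is exact for the joint measure, but
  the mean-field anti-cooperative term couples sites through a bin
  statistic and is therefore only approximately consistent with a global
  Hamiltonian.
* With soft default walls, roughly percent-level λ density sits beyond the
  re-initialization thresholds at strong driving forces; the reset rule
  recycles it within the same protonation class, which leaves titration
  statistics intact but visibly reshapes the λ histogram tails.
* The engine's local cooperativity is qualitative; quantitative n targets
  are owned by the parametric generators.
* Depth coordinates are per-leaflet; sites do not hop between leaflets
  inside the engine (the analyses handle crossers, the generator never
  produces them).
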