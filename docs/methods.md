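# Methods

This note documents the models implemented in `vesifit`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real instrument data.

## Diffusional sizing forward model

The sizing channel is modelled as 1-D diffusion across the channel width
with reflecting (no-flux) walls. Axial transport is plug flow: the profile
imaged a distance *L* downstream corresponds to residence time
*t* = *L*·*W*·*H*/*Q* (width *W*, height *H*, volumetric flow *Q*). The
initial condition is a top-hat occupying the sample-stream fraction *w*₀
of the width at one wall. In normalized coordinates the solution is the
cosine eigenfunction series

c(x, τ) = w₀ + 2 Σₙ sin(nπw₀)/(nπ) · cos(nπx) · exp(−(nπ)²τ),  τ = D·t/W².

**Approximations.** Axial velocity is taken uniform (no parabolic-flow
correction) and height-direction gradients are neglected; both are stated
modelling choices, and the main reason the model should be read as a
self-consistent reconstruction of a sizing instrument rather than a
digital twin of any particular chip. Channel dimensions
(default 300 μm × 50 μm, stream fraction 0.25, 100 μL/h, four imaging
positions at 5–100 mm) are configurable stand-ins chosen so that species
between ~1 and ~150 nm produce usefully distinct profiles.

**Numerics.** The series is truncated adaptively when the next term's
amplitude bound 2/(nπ)·exp(−(nπ)²τ) falls below 10⁻¹⁰, with a floor of 64
terms and a hard cap (exceeding it raises a numerical-accuracy error);
τ = 0 returns the exact top-hat. Mass is conserved to better than 10⁻⁸
over the measurement times, and the solution matches an independent
Crank–Nicolson integrator to < 10⁻⁴ of the peak.

## Radius inversion

Observed profiles are area-normalized (robust to label brightness) and
fit by least squares against simulated single-species profiles on a
60-point log-spaced radius grid (0.5–300 nm by default), with quadratic
interpolation of the residual in log-radius around the grid minimum; a
minimum on the grid boundary is flagged. Profiles may carry small negative
intensity excursions (background-subtracted noise); they are kept, not
clipped — clipping adds spurious tail mass after area normalization and
biases large radii low by several percent. Traces with excursions beyond
20% of the peak are rejected as invalid.

Noise-free round trips close within the grid-interpolation tolerance
(< 0.2% over 1–150 nm). With Gaussian noise of 2% of peak per point the
estimator is unbiased; per-measurement scatter grows with radius (a 74 nm
species barely diffuses over the channel transit, so its profiles carry
the least shape information) and reaches about ±5% there.

## Apparent radius of a partially bound sample

A partially bound sample is a two-component mixture; what a single-species
fit reports for it is the model
f·profile(r_bound) + (1−f)·profile(r_free) run through the same inversion.
This apparent radius is monotone in the bound fraction but strongly
super-linear: small species dominate profile-shape changes, so the
apparent radius stays near r_free until most protein is bound. Two
conversions back to bound fraction are provided:

* **linear** — (R_h − r_f)/(r_b − r_f), clamped to [0, 1]; adequate when
  the free→bound contrast is small (oligomers, ~12 → ~16 nm), where the
  residual conversion bias is a few percent in fraction units;
* **calibrated** — inversion of the tabulated mixture forward model by a
  monotone PCHIP interpolant through 21 anchor fractions, required for
  monomers (3.3 → 15–65 nm) where the linear map is biased by up to ~0.4
  in fraction units. A least-squares quadratic in apparent radius is also
  stored as a descriptive summary, but it is not used for conversion: for
  large contrasts no global quadratic gets below ~0.03 maximum bias,
  which would propagate directly into the affinity estimate, while the
  monotone inverse closes off-anchor to < 10⁻³.

The conversion clamps to [0, 1] because measurement noise can place radii
outside [r_f, r_b].

## Two-state binding equilibrium

One protein particle (b monomers; b = 1 for monomeric protein) binds one
membrane site; sites are proportional to total lipid with a particles per
lipid, so 1/a is the lipids-per-site stoichiometry reported alongside
K_D. With particle concentration P₀ = [B]₀/b and site concentration
S₀ = a·[A]₀, the bound-complex concentration is the physical root of the
1:1 mass-action quadratic, evaluated in the cancellation-safe form

[PS] = 2·P₀·S₀ / (P₀ + S₀ + K_D + sqrt((P₀ + S₀ + K_D)² − 4·P₀·S₀)),

and the bound fraction is [PS]/P₀ (identical for particles and monomer
equivalents). K_D is in molar particle–site interaction units. The closed
form agrees with a bisection root finder to < 10⁻¹⁰ over wide random
parameter ranges and reduces to the weak-binding isotherm S₀/(S₀+K_D)
when P₀ ≪ K_D.

**Competition.** Two species share the lipid surface: each bound particle
of species i consumes 1/aᵢ lipids, and the free-site concentration seen
by species i is aᵢ·[A]_free. Mass action per species plus lipid
conservation gives one strictly increasing scalar equation in [A]_free,
solved by Brent bracketing on [0, [A]₀] at machine precision. This is the
simplest model consistent with both species competing for the same
membrane area; it reduces exactly to the single-species closed form when
either total is zero. No cooperativity, membrane remodelling, or kinetics
are modelled.

## Bayesian inference

The likelihood is independent Gaussian on converted bound fractions with
the noise scale σ inferred (flat prior on (0, 1]); the mean is the
equilibrium model. Priors are flat in log₁₀-space for K_D (default bounds
10⁻¹²–10⁻³ M) and a (10⁻⁸–1, i.e. 1–10⁸ lipids per site) — deliberately
wide, since the data localize both parameters when the titration spans
the depletion regime. The subunit count b uses a discrete prior (uniform
30–40 for oligomers by default, reflecting the known oligomer size range;
a user-supplied empirical size distribution, e.g. from sedimentation
velocity, can replace it) and is marginalized by exact summation at every
likelihood evaluation rather than sampled — the support is small and this
removes a poorly mixing discrete dimension. For reporting, b is drawn per
posterior sample from its conditional distribution.

Sampling is affine-invariant ensemble MCMC (emcee; 24 walkers, 1600
steps, 600 burn-in by default) over (log₁₀ K_D, log₁₀ a, σ), initialized
in a tight ball around a coarse 40×40 grid minimum — with flat priors
spanning 8–9 decades, scattering walkers across the prior wastes most of
the chain on migration. Runs are deterministic given the seed.
Convergence is gated at split-chain R̂ < 1.05 and bulk ESS > 400 computed
across walkers; because walkers of one ensemble are correlated this gate
is conservative, and short default chains occasionally flag marginal
convergence while the summaries are already stable. Non-converged runs
are returned with the flag set, never silently discarded. Pileup of more
than 10% of draws within 2% of a prior bound is flagged separately (the
expected signature of non-identifiable data, e.g. a flat titration).

Summaries report medians with central 68%/95% intervals; lipids per site
is computed per draw as 1/a and then summarized, since moment-type
summaries do not commute with the reciprocal for skewed posteriors.

## Electrophoresis chain

The effective field in the μFFE chamber is E = (V − I·R)/W, with R the
electrode series resistance from device calibration. Stream positions are
Gaussian-mixture fits (component count by BIC, up to 2 by default,
initialized from detected peak positions and half-maximum widths;
components below 3× the robust noise floor are dropped). Deflections are
referenced to the 0 V stream position (all species co-locate at zero
field, so the merged 0 V peak serves as the common reference), species
are matched across voltages by positional order (linear deflection
preserves order for non-crossing streams), and voltages where the
species count is unresolved are skipped. Mobility is the least-squares
slope of deflection velocity vs field through the origin, sign preserved.

ζ-potentials invert μ = 2εε₀ζ f(κa)/(3η) with Henry's function in
Ohshima's closed-form approximation
f(κa) = 1 + ½·[1 + 2.5/(κa(1+2e^{−κa}))]⁻³ (exact Hückel and
Smoluchowski limits; ζ→μ→ζ closes to < 0.1 mV across ±100 mV and
κa ∈ 0.1–10³). The Debye length comes from the buffer's ionic strength
with phosphate speciation at fixed 25 °C pK values (2.15/7.21/12.33, no
activity correction) and electroneutral Na⁺; H⁺/OH⁻ are omitted as
negligible near neutral pH. The default model is Henry with the
particle's measured hydrodynamic radius; Smoluchowski and Hückel are
selectable. No electroosmotic-flow or relaxation corrections are applied.

Device geometry defaults (2 × 5 mm chamber, 100 μm height, ~1310 μL/h
total flow, 40 kΩ electrode resistance) are configurable stand-ins that
put deflections at 0–80 V in the few-hundred-μm range typical of such
devices.

## Synthetic data

Generators produce titrations (equilibrium fraction → mixture apparent
radius → additive Gaussian noise, on the radius scale by default or the
fraction scale to match the likelihood assumption exactly), two-stage
competition measurements, and voltage-stepped electropherogram series
(currents from a series-resistance device model, so the analysis
reconstructs exactly the field the generator used). All generators are
pure functions of (spec, seed). Shipped scenario presets fix the working
conditions used throughout: 2 μM protein (monomer equivalents), 12
log-spaced lipid concentrations over 1 μM–2 mM, 3 replicates,
fraction-bound noise σ = 0.03, free/bound radii 3.3/14.9 nm (monomer–SUV),
3.3/64.5 (monomer–LUV), 12.3/16.3 (oligomer–SUV), 12.3/48.1
(oligomer–LUV), monomer K_D 750 nM at 30 lipids/site, oligomer K_D 5 nM
at 10⁴ lipids/site with b = 35 — a 150-fold affinity contrast at matched
protein concentration. The monomer stoichiometry (30 lipids per bound
monomer) is of the order of reported α-synuclein membrane footprints and
more than an order of magnitude below the oligomer's.

What the synthetic closure shows: the analysis inverts its own forward
model correctly at realistic noise, recovers affinities within 2-fold
and resolves the 150-fold contrast with non-overlapping credible
intervals. What it does not show: robustness to instrument features the
generator omits — photobleaching, label stoichiometry, baseline drift,
non-Gaussian image noise, flow asymmetries — nor agreement with any
specific chip geometry, which is unpublished for the instruments this
reconstruction is patterned on.

## Problem sizes

Validation and the acceptance script run at desk scale by design: 60-point
radius bases, 2000-cell/2000-step finite-difference references, 1000-draw
equilibrium cross-checks, 20-seed recovery repeats, and single inference
runs of ~38 000 post-burn draws. These sizes were chosen so the full
validation suite completes in minutes on one core while leaving every
statistical conclusion (unbiasedness, 2-fold recovery, interval coverage)
comfortably resolved.
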