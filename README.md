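# vesifit

Quantitative analysis of protein–lipid-vesicle binding from microfluidic
measurements, built around the biophysics of α-synuclein: how tightly do
monomers and small oligomers (~30–40 subunits) bind anionic lipid
membranes, how many lipids does each bound particle occupy, and what
happens when the two species compete for the same membrane surface?

The package implements the full analysis chain for two complementary
microfluidic assays:

* **Microfluidic diffusional sizing (MDS).** An analyte stream co-flows
  with buffer under laminar flow and spreads across the channel by
  diffusion alone; the lateral intensity profile at a known residence time
  encodes the diffusion coefficient and hence the hydrodynamic radius
  *R*<sub>h</sub> (Stokes–Einstein). `vesifit` solves the forward
  advection–diffusion problem as a cosine eigenfunction series and inverts
  observed profiles by least squares against a simulated radius basis.
* **Binding inference.** Titrating lipid vesicles against labelled protein
  shifts the apparent radius between the free value *r*<sub>f</sub> and the
  fully bound value *r*<sub>b</sub>. Apparent radii are converted to bound
  fractions (linearly for small radius contrasts, through a forward-model
  calibration for large ones) and fit with a two-state, no-cooperativity
  equilibrium: a particle of *b* monomers binds a membrane site, sites
  being proportional to lipid with *a* particles per lipid
  (1/*a* = lipids per site). With *P*₀ = [B]₀/*b* and *S*₀ = *a*·[A]₀ the
  bound fraction is the physical root of the 1:1 mass-action quadratic,

  *f*<sub>b</sub> = 2 *P*₀*S*₀ / (*P*₀ + *S*₀ + *K*<sub>D</sub> +
  √((*P*₀ + *S*₀ + *K*<sub>D</sub>)² − 4 *P*₀*S*₀)) / *P*₀.

  Posteriors over (log *K*<sub>D</sub>, log *a*, σ) are sampled by ensemble
  MCMC with the subunit count *b* marginalized over its prior
  (point mass at 1 for monomer, 30–40 for oligomers).
* **Competitive displacement.** Two species drawing sites from a shared
  lipid pool (each bound particle consuming its own 1/*a* lipids) are
  solved by monotone root finding on the free-lipid concentration,
  reproducing the signature displacement experiment: adding high-affinity
  oligomer strips pre-bound monomer off a subsaturating membrane.
* **Free-flow electrophoresis (μFFE) and ζ-potential.** Streams deflect in
  an electric field in proportion to their electrophoretic mobility;
  `vesifit` corrects applied voltages for the electrode ohmic drop, tracks
  Gaussian stream components across a voltage series, regresses deflection
  velocity on field strength, and inverts Henry's electrokinetic relation
  (Ohshima closure; Hückel/Smoluchowski selectable) for the ζ-potential.

A synthetic-data module generates every input the pipeline consumes
(titrations, diffusion profiles, electropherograms, competition stages)
from ground-truth parameters with the noise structure the analysis
assumes, so every stage is testable end to end without instrument data.

## Worked example

Simulate an oligomer titration (truth: K_D = 5 nM, 10⁴ lipids per site,
b = 35; 12 lipid concentrations from 1 μM to 2 mM, 3 replicates,
fraction-bound noise σ = 0.03) and recover the binding parameters:

```bash
vesifit simulate --scenario oligomer_suv_ph6.5 --seed 11 --out titration.csv
cat > priors.yaml <<'YAML'
b: {min: 30, max: 40}
YAML
vesifit fit-binding --titration titration.csv --protein-total "2 uM" \
    --r-free 12.3 --r-bound 16.3 --priors priors.yaml \
    --seed 21 --steps 4000 --out fit/
```

which prints

```
wrote 36 titration points to titration.csv
K_D median 3.04e-09 M, lipids/site median 1.26e+04 (converged=True)
```

The posterior median dissociation constant (3.0 nM against a true 5 nM)
and stoichiometry (1.3 × 10⁴ against a true 10⁴ lipids per binding site)
recover the ground truth within the scatter expected at this noise level;
`fit/summary.json` holds the full marginal quantiles and convergence
diagnostics, `fit/posterior_draws.csv` the raw draws.

The displacement experiment, at the bench concentrations (2 μM monomer
pre-equilibrated with 150 μM lipid, then 2 μM oligomer added, affinities
750 nM vs 5 nM):

```bash
vesifit compete --monomer-kd "750 nM" --oligomer-kd "5 nM" \
    --lipid-total "150 uM" --monomer-total "2 uM" --oligomer-total "2 uM"
```

```json
{
  "monomer_fraction_before": 0.8177204458019429,
  "monomer_fraction_after": 0.36061760512154983,
  "oligomer_fraction_after": 0.20242728600425827,
  "displacement": 0.4571028406803931
}
```

— the oligomer, despite occupying ~10⁴ lipids per particle, pulls more
than half of the bound monomer off the membrane.

Other subcommands: `size` (radius from diffusion-profile CSV),
`fit-mobility` (mobility from a voltage-stepped electropherogram series),
`zeta` (ζ-potential from mobility, size and buffer), and `run` (a whole
configured pipeline with a deterministic report bundle).

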