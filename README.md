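# fametraj

Analysis pipeline for fatty-acid (FAME/GC-FID) profiles of a marine fungal
endophyte grown under a factorial stress design: two algal hosts
(*Laminaria digitata*, LD; *Saccharina latissima*, SL) × three temperatures
(10, 18, 25 °C) × three salinities (23.5, 50, 70 PSU), in biological
triplicates. It is written for lipid ecologists who want the full chain —
peak quantification, compositional summaries, assumption-gated univariate
tests, the C18 unsaturation index with its ANCOVA, and multivariate lipid
trajectories — as tested, scriptable Python rather than a one-off analysis
script.

## What it computes

- **Quantification.** GC-FID peak areas are converted to μg·g⁻¹ via the
  tricosanoic-acid (23:0) internal standard:
  `cᵢ = (areaᵢ / area_IS) · m_IS · 1000 / m_sample`.
- **Composition.** Fatty acids are parsed from `X:Yn-Z` shorthand,
  classified SFA/MUFA/PUFA, and expressed as % of total fatty acids (TFA),
  with an explicit policy for below-detection-limit cells.
- **Univariate screen.** Per fatty acid and host × salinity stratum,
  concentrations are compared across temperatures by one-way ANOVA whose
  flavour is chosen by a Bartlett pre-test (classical vs Welch), with
  Shapiro–Wilk residual checks and `n.s./*/**/***` star annotations. The
  index additionally gets a balanced three-way factorial ANOVA and a
  Levene (Brown–Forsythe) homogeneity test.
- **Unsaturation index and α angle.** Per sample,
  `FAI18-C = [18:2n-6] / [18:1n-9]` (scale-free: identical on μg·g⁻¹ or
  % of TFA). Within each salinity the index is regressed on temperature per
  host; an ANCOVA interaction test decides whether the two slopes are
  homogeneous. If they differ, the angle between the regression lines
  (α = |arctan s₁ − arctan s₂|, in degrees) quantifies how strongly the
  host shapes thermal acclimation; a stratified bootstrap gives α
  uncertainties and the trend of α along the salinity gradient.
- **Lipid trajectories.** Per salinity, a centred + scaled PCA of the
  compositional profiles; per host, the temperature-ordered centroid path
  in the PC1–PC2 plane; the angle between the two hosts' net displacements
  classifies the responses as aligned (<60°), orthogonal, or opposed
  (>120°).
- **Synthetic data.** A packaged parameter table carries the published
  per-cell means/sds for all 22 detected fatty acids; a seeded generator
  draws truncated-normal replicates from it, so every stage is testable
  without raw data. A second generator produces index-vs-temperature
  records with known slopes (hence a known α) for parameter-recovery
  checks.

## Worked example

```python
from fametraj import (load_reference_parameters, mean_profiles, fai18c,
                      FAIScenario, simulate_fai_scenario, slope_homogeneity)

params = load_reference_parameters()
cells = {(p.meta.host, p.meta.temperature, p.meta.salinity): p
         for p in mean_profiles(params)}
for host in ("LD", "SL"):
    lo = fai18c(cells[(host, 10.0, 23.5)]).fai
    hi = fai18c(cells[(host, 25.0, 23.5)]).fai
    print(f"{host}: FAI18-C 10°C = {lo:.3f}, 25°C = {hi:.3f}")

scn = FAIScenario(slope_ld=0.02, slope_sl=-0.02, sigma=0.05)
dec = slope_homogeneity(simulate_fai_scenario(scn, seed=7), salinity=23.5)
print(f"interaction F = {dec.interaction_F:.2f}, p = {dec.interaction_p:.2e}")
print(f"alpha = {dec.alpha_deg:.2f} deg (analytic {scn.analytic_alpha(23.5):.2f} deg)")
```

prints

```
LD: FAI18-C 10°C = 1.503, 25°C = 1.832
SL: FAI18-C 10°C = 1.923, 25°C = 1.437
interaction F = 60.64, p = 1.87e-06
alpha = 1.79 deg (analytic 2.29 deg)
```

The first block shows the published cell means already contain the central
result: the index rises with temperature for the LD strain and falls for
the SL strain — opposite acclimation directions under the two hosts. The
second block simulates records from two lines of known opposed slopes
(±0.02 index units per °C), detects the slope difference by ANCOVA, and
recovers an α close to the generating 2.29°.

The same analyses run from the shell:

```bash
fametraj simulate --seed 4 --out sim.csv
fametraj all --input sim.csv --out-dir results --seed 4 --n-boot 1000
```

which writes `composition.csv`, `univariate_screen.csv`,
`ancova_per_salinity.csv`, `alpha_trend.csv`, per-salinity PCA
scores/loadings/inertia, `trajectory_summary.csv`, and a `manifest.json`
from which the run can be reproduced exactly.

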