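# Methods

## Data model

A sample is a vector of fatty-acid concentrations (μg per g extracted
biomass) keyed by factorial metadata: host strain (LD or SL), growth
temperature (10/18/25 °C), salinity (23.5/50/70 PSU) and replicate. Fatty
acids are identified by the `X:Yn-Z` shorthand (X carbons, Y double bonds,
Z position of the ultimate double bond from the methyl end); both the
ASCII hyphen and the typographic minus are accepted on input, the canonical
label uses ASCII. Zero, one, and two-or-more double bonds map to SFA, MUFA
and PUFA. Matrix construction always orders fatty acids by (carbons,
double bonds, omega) so downstream ordinations are deterministic.

Cells reported below the detection limit carry an explicit sentinel rather
than a number. Sums and proportions resolve the sentinel through a policy:
`zero` (default), `half` (dl/2, requires a stated detection limit), or
`exclude`. The default is `zero` because the source tables report "<dl"
without stating a treatment; with trace-level cells the three policies
differ negligibly relative to replicate noise. The packaged parameter table
additionally flags as `missing` the eight cells of one design row that the
published table does not print; missing cells are omitted, never imputed.

## Quantification

Flame-ionization response is taken as proportional to mass with equal
response factors for all FAMEs (a per-compound factor table can be
supplied). Concentration is the peak-area ratio to the 23:0 internal
standard scaled by standard mass over sample mass. Both masses are required
inputs — the published protocol states the standard's concentration
(0.5 mg·mL⁻¹) but not the extracted biomass, so absolute μg·g⁻¹ magnitudes
of the original study are not reproducible from peak tables and are not
attempted.

## Univariate decision tree

For each fatty acid within a host × salinity stratum, replicate
concentrations are grouped by temperature. Bartlett's test gates the
comparison at p < 0.05 (configurable): heterogeneous variances route to
Welch's unequal-variance one-way ANOVA, otherwise classical one-way ANOVA.
Shapiro–Wilk on the residuals is reported as a warning only; it never
changes the routing, since the protocol describes a normality check without
an alternative branch. Groups that are entirely below detection, absent
(the unprinted design row), or of zero variance are skipped with a logged
notice — the comparison is undefined there. Stars follow the usual
thresholds (\* <0.05, \*\* <0.01, \*\*\* <0.001). No multiple-testing
correction is applied across fatty acids, matching the original analysis;
the screen is descriptive, not confirmatory.

The index gets a full three-way factorial ANOVA (host × temperature ×
salinity with all interactions). Balance is required and checked; on a
balanced design the decomposition is unique (all sums-of-squares types
coincide — the implementation uses statsmodels type-II, and tests verify
equality with a brute-force cell-means decomposition). A constant response
is returned as the all-zero decomposition with F = 0 rather than 0/0.
Levene's homogeneity test over the 18 design cells uses the
Brown–Forsythe median-centred variant, the default of the R tooling used
in the original analysis; mean-centring is selectable.

## FAI18-C and the α angle

`FAI18-C = [18:2n-6]/[18:1n-9]` is computed per replicate (the ANCOVA
needs per-sample responses; computing it on cell means instead is a
coarser alternative the API also supports via `mean_profiles`). The ratio
cancels any global rescaling, so concentrations and % of TFA give the same
value. Samples with either component below detection are skipped with a
logged notice; the index is then undefined, not zero.

Within each salinity, `fai ~ temperature * host` is fit by OLS and the
interaction F decides slope homogeneity at p < 0.05. The threshold matches
the original decisions (an interaction at p = 0.115 was treated as
homogeneous). When slopes differ, α is the angle between the two host
regression lines, `|arctan s_LD − arctan s_SL|` in degrees folded into
[0, 180). Slopes enter in raw units (index per °C) without axis
standardization — the index is plotted against °C and no standardization
is stated in the source; the choice is recorded in output metadata so
alternative conventions remain comparable. When slopes are homogeneous the
model is refit without the interaction and adjusted temperature and host
effects are reported; observations with standardized residuals beyond ±3
are flagged (report-only), as the source mentions an outlier check without
defining its rule.

Uncertainty on α and its salinity trend come from a stratified bootstrap:
replicates are resampled with replacement within each host × temperature
cell, α is recomputed per draw and salinity, and the trend statistic is
the least-squares slope of α on salinity with a one-sided p equal to the
fraction of draws with non-negative slope. The point estimates are the
primary output; the bootstrap trend is a pragmatic construction, chosen
over inventing the original study's unspecified test.

## Trajectory PCA

Per salinity, samples' relative proportions are centred and scaled to unit
variance (correlation PCA — the conventional default of the ordination
tools the source used; covariance PCA is a config option, and the
explained-inertia figures are sensitive to this choice). Constant and
unobserved fatty acids are dropped with a notice. Axis signs follow a
deterministic convention (largest-magnitude loading per axis made
positive), eliminating seed-dependent mirror flips. Per host, centroids of
the PC1–PC2 scores are ordered by temperature into a trajectory; the
divergence between hosts is the angle between net displacement vectors
(first→last centroid), classified aligned (<60°), orthogonal (60–120°) or
opposed (>120°). Net displacement, rather than per-segment angles, is used
so a three-temperature path reduces to one robust vector; per-segment
geometry is available from the paths themselves.

## Synthetic data generator

The generator emulates the study conditions: the balanced 2 × 3 × 3 design
in biological triplicate over 22 fatty acids, with each replicate
concentration drawn from a normal distribution with the published per-cell
mean and sd, truncated at zero. Truncated normal (not lognormal) is the
default because the source reports arithmetic mean ± sd; lognormal is
selectable. Below-detection cells are emitted as the sentinel, missing
cells omitted. Everything is driven by one integer seed.

What the generator does **not** emulate: between-fatty-acid covariance
within a replicate (only marginal sds are published). Real profiles are
strongly positively correlated across fatty acids (shared biomass and
extraction efficiency), which concentrates PCA variance on the leading
axes and tightens the 18:2n-6/18:1n-9 ratio. Consequently, on synthetic
replicates (i) first-two-axes inertia runs some 5–10 percentage points
below values measured on real replicates at the salinity where real
trajectories were cleanest, and (ii) per-replicate FAI noise is inflated,
so ANCOVA interaction F values far smaller than those reported from real
replicates are expected. Passing tests on synthetic data therefore
validate the machinery and its statistical guarantees, not the original
effect sizes. Truncation at zero also biases trace cells (mean ≲ sd)
upward by the Mills-ratio term; for quantitatively dominant cells
(mean ≥ 2.5 sd) the bias stays below 1 %.

A separate scenario generator draws index records from two lines with
known per-host slopes, per-salinity slope multipliers and normal residuals
(truncated positive), giving an analytic ground-truth α for
parameter-recovery tests.

## Problem sizes and numerical choices

Stochastic test batteries use 20-seed averages for ordination inertia,
200 seeds for slope recovery, 100 seeds for divergence classification, and
500–1000 bootstrap draws — sizes at which the checked statistics are
stable to well within their asserted tolerances. Proportions are computed
ratio-first so values stay within [0, 100] to the last ulp; compositional
closure makes one proportion linearly dependent, which PCA handles
naturally (one zero eigenvalue). Output CSVs round to 6 significant
digits; tests compare numerically, never by string.

## Known limitations

- No covariance model between fatty acids (see above); no chromatogram
  processing (input is an integrated peak table); no multiple-testing
  correction or post-hoc tests; no constrained ordination.
- The α convention (raw-unit slopes) is one of several defensible choices;
  published α values to disambiguate against do not exist.
- Wide-format CSV cannot distinguish "absent" from "below detection" for a
  fatty acid missing in some samples; the long format is lossless and is
  the canonical interchange.
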