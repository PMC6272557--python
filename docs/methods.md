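# Methods

## The sweetness index

Sweetness of a dried root is modelled as a linear, non-negative
combination of its measured sweet components,

S = Σᵢ Tᵢ · cᵢ,

with contents cᵢ on the canonical mg per g dry-root scale and relative
sweetness weights Tᵢ (dimensionless, sucrose ≡ 1.0). The default weight
table is the published one: glucose 0.75, fructose 1.7, inositol 0.5,
sorbitol 0.55, dulcitol 0.3, sucrose 1.0, betaine 0.5. The index is
reported in mg sucrose-equivalents per g; this is the only scale on
which the published group sweetness column is reproduced by the
formula, although the original table prints bare numbers.

Trace components are kept in the sum even though their joint
contribution is ~0.02–0.06 units: they are stated to make a minor — not
zero — contribution, and dropping them would silently change the index
definition. A component absent from a sample's record is scored as 0
with a logged warning (an assay may be skipped); a measured component
with no weight in the reference table is an error.

Linearity is the index's load-bearing property: group-mean sweetness
equals the sweetness of the group-mean contents, and unit conversion
before or after scoring cannot change the result. Both are asserted as
property tests.

### The three inconsistent published rows

Recomputing S from the printed group-mean contents reproduces the
printed sweetness for the Sx, Ssx, Gs, 5-year and 7-year groups within
0.1 (the slack expected from one-decimal rounding of the inputs), but
not for Nm (recomputed ≈ 12.95 vs printed 13.7), Hlj (≈ 13.43 vs 13.9)
or 2-year (≈ 12.74 vs 13.7). Because S is linear, averaging order
cannot explain a 0.4–1.0 discrepancy, and no plausible alternative unit
for any component closes the gap for exactly these three rows. They are
treated as an inconsistency in the published table: transcribed as-is,
excluded from the reproduction targets, and covered by a test that pins
the recomputed values so any silent "fix" would fail.

## Units and I/O

Contents arrive on three decade-separated scales (μg/g trace sugars,
mg/g sucrose/betaine, g/g polysaccharides/extracts) and are converted
to mg/g on ingest; one canonical unit prevents silent 1000× errors.
Conversion multiplies or divides by the exactly representable integer
power of ten; a conversion round trip is correct to within one ulp,
which is the best binary floating point permits for decade factors.
CSVs are comma-separated UTF-8 with "." decimals. Component and
indicator names form a closed registry; unknown columns are carried
through untouched and excluded from computation. Group summaries use
the n−1 sample SD, matching mean ± SD reporting convention, and report
SD as unavailable for singleton groups.

## Calibration module

Linear standard curves (absorbance assays) and log–log curves (ELSD and
HPLC power-law responses) are fitted by OLS; base-10 logs are used — the
base cancels in round-trip prediction, and base 10 is the analytical
chemistry convention. Curves are fitted response-on-amount and inverted
for prediction (the conventional orientation; the source protocol is
ambiguous about which variable is regressed on which). Inverse
predictions outside the calibration range are flagged, not rejected: no
range-policing rule is stated for the assays, and flagging preserves
information without inventing one. The aqueous-extract percentage is
the closed-form gravimetric scale-up
100 · residue · (total/aliquot) / sample mass.

## Composite index

The model is an eigendecomposition of the 4×4 correlation (default) or
covariance matrix of the indicator panel. Correlation preprocessing is
the default because the indicators span three decades of scale and the
published analysis is silent on standardisation; covariance mode is
kept because the published coefficient equation applies raw contents,
suggesting its authors may not have standardised. The retention rule is
the smallest k whose cumulative contribution reaches the threshold
(default 0.85 — on the original data the achieved rate was 89.26%, so
the stated achievement is consistent with this rule, which the source
does not spell out). Weights are the contribution-weighted sum of
retained eigenvectors with no further normalisation — the most literal
reading of "eigenvectors weighted by each component's contribution".
Eigenvector signs are fixed so each retained PC's largest-magnitude
loading is positive, making results deterministic across solvers.
Whether the published "contribution" weights were fractions or
percentages only rescales F globally and cannot change rankings; the
package uses fractions.

The published coefficients (43.563, 27.067, 6.978, −2.553) derive from
the unpublished 48-sample raw matrix and are *not* recoverable from any
synthetic cohort; they are supported as an importable explicit-weights
model that scores raw contents, and the test suite asserts both that
this path reproduces the published arithmetic exactly and that a fitted
desk-scale model makes no claim to match it.

## Association stage

OLS with the indicator as response and sweetness as predictor — the
published orientation; the inverse is deliberately not offered.
p-values come from the exact t reference distribution (not a normal
approximation). No multiple-testing correction is applied: four raw
per-indicator tests are reported, matching the published presentation;
users comparing against a family-wise error rate should Bonferroni
at 4. The published p-values themselves are inconsistent with an n = 48
t-test (r = 0.486 would give p ≈ 0.0005, not 0.147); the package
implements the standard test and does not target those numbers.

## Synthetic cohorts

The generator emulates the published study structure, not any real
root: per-group independent normals with the published component
means/SDs, truncated at zero by rejection (cap 1000 draws per value;
the cap only ever binds for pathological configurations, since the
default means sit ≥ 3 SDs above zero for the dominant components, and
exhaustion is an explicit error). Indicator panels follow
indicator = a·S + b + ε with the published slopes/intercepts, ε normal
with SD calibrated as σ_ε = |a|·σ_S·√(1/ρ₀² − 1) so the population
indicator–sweetness correlation is exactly the target ρ₀ (defaults: the
published correlation coefficients, signed to match their slopes — the
extracts association is negative). σ_S is taken from the generated
cohort, so ρ₀ is a recoverable population parameter by construction.

What the generator does **not** emulate: within-group covariances among
the seven components (unpublished; independence is an explicit
assumption), harvest-time/county/soil covariates, replicate-level
measurement error (only replicate-averaged values were ever printed),
and any non-normality of real contents. Passing recovery tests
therefore show that the *pipeline* is correct and well-calibrated under
the stated generative model — not that real roots satisfy that model.

The default configuration has 48 samples: region groups Sx 17, Ssx 7,
Gs 10, Nm 8, Hlj 6 (Hlj is the MJ species, the rest MG), with
growth-year labels assigned so the year groups are 1Y 2, 2Y 18, 5Y 22,
7Y 6. The source material does not pin down the exact 5Y/7Y split
within Sx and Ssx (one Shaanxi sample is listed as 6-year, several
Shanxi ones as "≥5"); the package uses Sx = 12 + 5 and Ssx = 6 + 1,
one split consistent with both marginals. Draws are driven by the
region-group parameters; the year-row summary statistics are shipped as
reference data but are not a second generation target, since each
sample can be drawn from only one distribution.

## Pipeline and determinism

All randomness flows from a single integer seed through one
`numpy.random.Generator`; fixed-seed runs write byte-identical numeric
artifacts (asserted in the acceptance suite). Wall-clock timestamps are
confined to the run log, which also records one machine-parsable line
per skipped sample. The composite stage fits on the cohort's own
indicator matrix by default and accepts explicit weights as an
alternative, because both views — fitting, then quoting fixed
coefficients — are legitimate uses.

## Problem sizes in the test and acceptance runs

The suites use desk-scale sizes chosen to make sampling error
negligible relative to the tolerance being asserted: 100 random 48×4
matrices for the eigen-oracle comparison (1e-9), 200 seeded replicates
at n = 48 for correlation-recovery coverage against the Fisher 95%
interval, and single n = 5000 cohorts for CLT-bound mean checks and the
±0.03 empirical-correlation check. The full default run is n = 48, the
study's own size.

## Known limitations

- The composite model's preprocessing choice (correlation vs
  covariance) changes fitted weights materially on real-scale data;
  both are first-class, but cross-study comparison requires fixing one.
- Truncation at zero makes the generated component distributions
  slightly right-shifted for near-zero trace components (visible in the
  fructose stress test); group means in the default configuration are
  far enough from zero that the bias is below sampling error at n = 48.
- `growth_years` is an integer label; fractional ages and harvest
  season are out of scope.
- The calibration module handles final instrument responses only — no
  chromatogram integration or peak identification.
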