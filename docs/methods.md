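# Methods

## Scope and data

The package implements the statistical layer of a culture-condition
optimization and dissipation-kinetics study: design construction, quadratic
response-surface modelling, optimum and transformation analysis, and
first-order decay fitting. The only bundled data are the study's published
24-run central composite design table (coded levels, per-run mean ± SE of
three replicates, run order exactly as published) and a constants record of
its published headline numbers with provenance notes and comparison
tolerances. The table is verified against a SHA-256 checksum at load time.
Raw concentration–time measurements and per-replicate responses were never
published, so anything depending on them (the kinetics R² values 0.926/0.850,
replicate-level ANOVA) is out of reach and is not claimed.

## Design construction and coding

`generate_ccd` builds the three-block CCD (2^k factorial vertices, 2k axial
points, n_center center replicates) in standard block order; `randomize_runs`
applies a seeded permutation. The rotatable axial distance α = (2^k)^¼ is
stored at full precision (1.681793 for k = 3) and rounded to two decimals
only for display. Coded/actual conversion is x = (X − X₀)/ΔX with exact
inverse; validation checks the run-count partition, zero column sums, and
pairwise orthogonality of the coded columns.

The published table never states which actual factor values the coded ±1
levels correspond to. The package defaults — pH step 1.0 about center 6.0,
temperature step 4 °C about 26 °C, incubation-time step 1 day about 5 days —
are consistent with the study's single-factor screening ranges and its stated
optimum (all-zero coded point = pH 6.0, 26 °C, 5 days), but they are package
assumptions, user-overridable, and nothing downstream of the coded fit
depends on them.

## Quadratic fit and ANOVA

The ten-term coded quadratic is fitted by OLS (statsmodels). The default
basis is the 24 run means: this choice reproduces the published coded
equation coefficient-for-coefficient, which is the empirical evidence that
the original analysis fitted means. A balanced replicate basis (each run
expanded into pseudo-replicates that reproduce its mean exactly and its
sample SD = SE·√n) is available; on a balanced design it leaves the
coefficients unchanged and alters only dispersion statistics.

Statistics follow the standard definitions: F = (SSR/df_model)/(SSE/df_resid)
with df 9 and 14; R² = 1 − SSE/SST; adjusted R² penalized by df;
predicted R² = 1 − PRESS/SST with the closed-form leave-one-out
PRESS = Σ(eᵢ/(1 − hᵢᵢ))² (runs at leverage 1 are excluded and flagged);
CV = 100·√MSE/Ȳ. Two labelling caveats about the published numbers are
annotated wherever they surface: the value published as "R² = 0.9823" is the
*adjusted* R² of the means fit (the raw R² is ≈ 0.989, which is also what
makes the published F ≈ 143 cohere), and the published +2.00 pH×time
interaction has the opposite sign to the one the published table itself
supports (−2.00); the package reports the fitted value and compares
magnitude only. p-values come from the F and t distributions at the fitted
degrees of freedom with no multiplicity correction (none was used in the
source analysis).

Influence diagnostics (leverage, internal/external studentized residuals,
Cook's distance) come from the OLS hat matrix via statsmodels' influence
machinery and are cross-checked in the test suite against explicit
leave-one-out refits. The published Cook's-distance range (0.01–0.048) and
studentized-residual span (±3.8) are inconsistent with any fit of the
published table and look like plot-axis artifacts; they are not used as
checks.

Letter grouping uses Fisher's LSD with the pooled within-run variance
(df = Σ(nᵢ−1)) — the published table's footnote names both LSD and Duncan;
LSD is the simpler deterministic rule. The compact letter display is built by
an interval sweep over means sorted ascending (exact for the constant-
threshold LSD relation) and is property-tested against brute-force all-pairs
tests. Zero pooled variance degenerates to exact mean equality.

## Optimum, Box–Cox, grids

The stationary point is xₛ = −½B⁻¹b; eigenvalues of B with magnitude below
1e-10 are treated as zero, triggering the ridge classification and a
pseudo-inverse fallback with a warning. `constrained_optimum` maximizes the
fitted polynomial within a coded cube or sphere by multi-start L-BFGS-B /
SLSQP (seeded starts plus the center and the clipped stationary point); a
two-stage dense grid search (coarse 0.05 grid, then a 0.005 grid around its
argmax) serves as the independent oracle in tests.

On the bundled table the fitted surface is a concave maximum at coded
(−0.065, −0.173, 0.484) predicting 95.24%. The published claim of "95.6% at
the stationary point" equals the best observed run mean, not the published
equation evaluated anywhere (at its stated optimum (0,0,0) it yields its
intercept, 94.23); the reproduction report shows both values with a note.

The Box–Cox scan refits the quadratic to (y^λ − 1)/λ (log at λ = 0) over a
λ grid (default −3…5, step 0.01) and records the profile log-likelihood
−n/2·log(SSE/n) + (λ−1)Σlog y, which is continuous through λ = 0. For the
confidence interval two cutoff rules are offered. The default is the
residual-SS threshold SSE_min·(1 + F(conf; 1, df_resid)/df_resid) used by
the Box–Cox plots of response-surface DoE software; on the bundled table it
gives best λ = 1.68 with interval (−0.51, 4.33), matching the published
plot's 1.72 and (−0.45, 4.24) to within a grid step and ~0.1 respectively.
The asymptotic profile-likelihood cutoff χ²(1)/2 is available as
`ci_rule="chi2"`; it gives a markedly narrower interval (0.04, 3.58) and was
evidently not the convention behind the published plot, which is why it is
not the default.

## Kinetics

How the source analysis estimated k (log-linear vs nonlinear, means vs
replicates) is unstated; the default here is nonlinear least squares on
replicate-mean concentrations, initialized from the log-linear estimate and
bounded to k ≥ 0, with the log-linear method available. Zero concentrations
(non-detects) cannot enter a log fit and are excluded from it with a warning;
the nonlinear fit uses them as-is. R² is computed on the concentration scale.
Half-life is ln 2/k, infinite at k = 0. Reported precision mirrors the
source: k to 4 significant figures, half-lives to 2 decimals.

The published treatment values are mutually inconsistent — t₁/₂ = 26.05 h vs
ln 2/0.0193 = 35.91 h, while the control pair (0.0013 h⁻¹, 533.19 h) is
exactly consistent — and which of k or t₁/₂ carries the typo cannot be
determined. The reproduction report prints both and flags the discrepancy;
the half-life-reduction record (507.1 h) is computed from the two published
half-lives, as the source evidently did.

## Synthetic data

`simulate_response_surface` draws per-run replicates from a true quadratic
surface plus homoscedastic Gaussian noise, clipped to [0, 100] with a clip
counter (the published data give only means ± SE, so no heteroscedastic
structure is estimable; a different SD can be passed). The default truth is
the refit of the bundled table with replicate SD 0.6 and 3 replicates, chosen
so that simulated standard errors fall in the 0–1.7 range the published table
shows. `simulate_decay` draws C₀e^(−kt) + N(0, SD) at 24 h intervals over
0–144 h with a 0.5 mg/L detection floor (draws below it read 0). Under these
defaults the 144 h mean is 3.1 mg/L, so zero endpoints are rare; the study's
observed "no residue at 144 h" therefore reflects terminal behaviour faster
than a single exponential, and the generator does not force it. Both
generators are bit-reproducible given a seed, and mycelial growth curves are
not modelled (no growth model was published).

What passing the simulation tests shows — and does not show: the estimators
are unbiased and well-calibrated under the assumed Gaussian, homoscedastic,
independent-replicate noise at the published design geometry. Real plate
data with skewed or variance-linked noise, carry-over between runs, or
model misspecification (true response not quadratic, decay not first-order)
are outside what the generator emulates.

## Numerical choices and problem sizes

Coefficient-recovery and Box–Cox-coverage checks use 200 seeded datasets and
the kinetics accuracy check 500 seeded curves; the recovery criterion uses
the exact coefficient SEs implied by the simulation truth
(σ²/n_rep·(XᵀX)⁻¹), so each standardized deviation is a z-score rather than
a t(14) statistic and "within 3 SEs" has its nominal ≈99.7% per-coefficient
meaning. Rank deficiency is detected by matrix rank and reported with the
collinear columns identified by pivoted QR. A fit with SSE below 1e-10·SST
is flagged perfect (F reported as infinite rather than a meaningless large
number). Degenerate inputs — flat Box–Cox profiles, zero pooled variance in
letter grouping, all-zero decay series, leverage-one runs — are flagged or
rejected with specific errors rather than propagating NaNs.

## Known limitations

Single-response optimization only (no desirability functions or ridge-path
following); no lack-of-fit/pure-error decomposition beyond PRESS (not
reconstructible from the published summary); no Box–Behnken or fractional
designs; first-order kinetics only (no biphasic or growth-linked models);
the two-way concentration×treatment ANOVA of the source could not be
reproduced because its raw data were never published.
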