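# Methods

## Model and procedure

The analysis asks whether a mean regression of normalized brain tissue
volume on age represents the *distribution* of volumes, not just its
centre. Volume is the TIV-normalized tissue fraction
`v = (GM+WM)/(GM+WM+CSF)`; age enters as a coded band
`x ∈ {1..5}` (<70, 70–74, 75–79, 80–84, 85–89 years) because
single-year strata are too sparse for percentile estimation. Two model
families are fitted on subject-level rows, unweighted:

* **mean trend** `ŷ_μ(x) = c_μ + b₁x + b₂x²`, ordinary least squares;
* **rank trends** `ŷ_τ(x) = c_τ + b₁x + b₂x²` for
  τ ∈ {.05, .25, .50, .75, .95}, minimizing the check (pinball) loss
  `Σ ρ_τ(yᵢ − ŷ(xᵢ))`, whose population minimizer is the conditional
  τ-quantile.

The implicit premise of mean-based normative charts is the
*parallel-shift* rule: every rank curve is the mean curve translated
vertically. Its prediction of rank τ at band i is therefore the rank's
own intercept moved along the mean betas,
`ŷ_μτ,i = c_τ + b₁_μ·i + b₂_μ·i²`. Disagreement with the rank's direct
prediction is expressed relative to the overall mean change
`Δ_μ = ŷ_μ(1) − ŷ_μ(5)`:

    percent error = 100 · (ŷ_μτ,i − ŷ_dτ,i) / Δ_μ.

Positive errors mean the mean model overestimates volume at that rank
and age (it understated the decline); negative the reverse. The
5th–95th band spread at the oldest versus youngest band classifies the
rank fan as diverging, converging or flat (tolerance 1e-6 on the spread
change). The cross-arm statistic divides the normal-arm rank change
`ŷ_d(τ, 1) − ŷ_d(τ, 5)` by the other arm's Δ_μ, minus one, as a percent.

Empirical percentiles (used for band-level estimates) follow the
order-statistic rule `np = j + g`: midpoint `(x_j + x_{j+1})/2` when
`g = 0`, else `x_{j+1}` (the "averaged inverted CDF" estimator, SAS's
default). `np < 1` degenerates to `x₁`. Ties are kept as repeated order
statistics. A fractional part within 1e-9 of an integer is treated as
exact, since `n·t/100` is decimal-exact in intent.

## Model-choice and diagnostic conventions

The published models print only linear and squared betas, so degree 2
is the default (degree 1 available; cubic not implemented — the printed
tables are the reproducible artifact). The linearity check mirrors the
residual-plot inspection it replaces: per band, counts of positive and
negative residuals from the *linear* mean fit are tested with a
two-sided binomial sign test; the linearity flag raises when any band
is significant at α = 0.05. Skewness is adjusted Fisher–Pearson,
undefined (NaN) for n < 3 or near-constant residuals.

## Quantile solver

The check-loss problem is solved as an exact LP. Because the covariate
takes at most five distinct values, the loss separates into one convex
piecewise-linear function per distinct x; the LP minimizes the sum of
one epigraph variable per distinct value, each constrained by the
function's supporting lines (slope `k − τ·n_g` after the k-th order
statistic). This condensed form has the same optimum as the classical
split-residual primal but only `(degree+1) + #distinct-x` columns, and
HiGHS solves the 22,700-subject instances used in testing in ~0.15 s.
Every returned fit is certified a posteriori by the quantile
subgradient condition — `#{r < 0} ≤ τ·n ≤ #{r ≤ 0}` within the
`degree+1` observations that may sit exactly on the fit (residual
tolerance 1e-8 relative to the data scale) — and a failed certificate
raises with the achieved loss and counts. Degenerate optima (flat
faces) can differ from other solvers' vertices; tests therefore compare
achieved loss, not coefficient paths.

Display convention: coefficients and predictions are reported to four
significant figures, percent errors to the nearest integer with halves
away from zero; all internal arithmetic is full precision.

## Synthetic cohorts

The generator emulates the post-segmentation volume table, not images.
Per band it draws normalized volumes from a Gaussian with the published
(n, mean, SD) of the matching arm — normal: n = (25, 89, 56, 34, 23),
SD rising from 0.0130 to 0.0210; AD: n = (43, 56, 49, 49, 22), SD
falling from 0.0236 to 0.0187 — and expands each draw into a raw
(GM, WM, CSF) triple (tissue split 60/40, TIV ~ N(1.4×10⁶, 7×10⁴²)
voxel-equivalents, floored at 8×10⁵) that reproduces the drawn value
exactly under normalization; ages are uniform within bands (band 1
spans [60, 70) for the normal arm, [55, 70) for AD, following the two
arms' reported age ranges). A `scale` factor multiplies band sizes
(ceil) for large-sample experiments. An optional "skewed" family
subtracts an exponential tail (scale 1.5·SD) from a 15% mixture
component, giving the negatively skewed residuals real cohorts show;
the Gaussian family is the minimal model consistent with the published
summaries, and its spread-with-age pattern is the only feature of real
data the defaults claim to capture. What synthetic tests consequently
do **not** show: behaviour under scanner/segmentation artifacts,
non-Gaussian tails in real volumes, or within-band age trends.

All randomness flows from the spec's single seed through numpy's
default generator; identical specs give byte-identical tables.
`draw_grouped` is a fast path that draws only the normalized values
(its draw sequence differs from the full record generator, but is
likewise deterministic per seed).

## Known limitations and honest misfits

* **Quadratic-in-code misspecification.** The published per-band
  parameters do not lie on quadratics. The population-optimal quadratic
  (computed from the closed-form Gaussian expected check loss) misses
  the generating band quantiles `μ_g + z_τ σ_g` by up to ~0.0051
  normalized-volume units at τ = 0.95 in the normal arm (~0.0045 AD;
  ≤ 0.0017 at τ = 0.05 normal). Recovery tests against generating
  quantiles at a 0.003 tolerance therefore fail at upper ranks *by
  model bias, not solver error*; the identical machinery recovers
  quantiles within 0.003 on cohorts whose band mean and SD are
  themselves quadratic in the code (where conditional quantiles are
  exactly quadratic). The corresponding large-scale acceptance check is
  left failing, deliberately, as a record of this approximation error.
* **Published-table internal precision.** The AD mean betas as printed
  evaluate to Δ_μ = 0.0220 while the source reports 0.0222, and a few
  AD parallel-shift cells differ by one unit in the fourth significant
  figure — the source computed with more coefficient digits than it
  printed. The normal-arm grid reproduces exactly from printed
  coefficients; the AD gap is asserted as a known discrepancy rather
  than forced to agree. The cross-arm 38.7% figure uses the printed
  AD Δ_μ (full-precision evaluation gives ≈ 40%).
* **Problem sizes in tests.** Replicate experiments use 100 cohorts per
  arm at 100× band sizes (≈ 2.27M subject draws per arm in total) for
  fan-direction and error-sign frequencies, and single 100× cohorts for
  recovery checks; the exhaustive percentile oracle covers all n ≤ 60
  and integer t ∈ [1, 99]. These sizes make the binomial assertions
  (≥ 90/100, ≥ 80%·200) sharp while keeping the suite quick.
* No inference (SEs, CIs) is attached to percent errors or quantile
  coefficients; the statistic is descriptive, as published. No variance
  transformation (e.g. Box–Cox) is applied — heteroscedasticity is the
  object of study, not a nuisance.
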