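# Methods

## The model

Each cell contributes two QC metrics: library complexity `x` (number of
genes with at least one count) and mitochondrial percentage `y` (percent
of the cell's counts in mitochondrially encoded genes, on the 0–100
scale).  A latent state `Z ∈ {0 intact, 1 compromised}` with mixing
weights `π_z` governs which of two regression curves the cell's `y`
scatters around:

    y | Z = z, x  ~  N(f_z(x), σ_z²)

The curves can be, per component:

* **linear** (default): `f_z(x) = β₀z + β₁z x` — a latent-class
  (mixture-of-regressions) model;
* **spline**: intercept plus a cubic B-spline basis in `x`; the shipped
  CLI pairs a linear intact component with a spline compromised one,
  since the compromised population is the one with pronounced curvature
  at low complexity;
* **intercept_only**: `f_z(x) = μ_z`, which for both components reduces
  the model to a one-dimensional two-component Gaussian mixture on `y`.

The model is deliberately blind to *why* mitochondrial content is high;
it only asks whether a cell is better explained by the low,
complexity-insensitive intact band or by the high band at low
complexity.  It assumes `π` is constant across `x` — see
"Known limitations".

## Estimation

Parameters are fit by expectation–maximization.

* **Initialization.** Deterministic by default: cells above the 75th
  percentile of `y` start with responsibility 0.95 for the tentative
  compromised state, the rest 0.05.  This makes a single run exactly
  reproducible.  `restarts > 1` adds seeded uniform-random
  initializations and keeps the fit with the highest final
  log-likelihood; EM is only guaranteed a local optimum, so checking a
  few starts is cheap insurance.
* **E-step.** Posteriors are computed entirely in log-density space
  with log-sum-exp normalization; `y` values far from a component line
  underflow plain Gaussian densities.  If both log-densities overflow
  to −∞ the cell's responsibility falls back to the mixing weights,
  with a warning.
* **M-step.** Mixing weights are mean responsibilities; coefficients
  solve the responsibility-weighted least-squares problem (via a
  QR/lstsq factorization of the √weight-scaled design, with an explicit
  rank check); variances are weighted mean squared residuals.
* **Convergence.** Relative log-likelihood change < 1e−8, at most 1000
  iterations.  The model is tiny, so a tight tolerance costs nothing;
  typical default-condition fits converge in ~10 iterations.
* **Labeling.** The likelihood is symmetric in the components, so which
  is "compromised" is resolved after fitting: the component with the
  greater y-intercept (greater `μ_z` for the constant form; greater
  predicted `y` at the minimum observed `x` when a spline is involved).
  An exact tie is an error — the components are indistinguishable.

### Spline details

Interior knots (`df − degree` of them, default 0) sit at equally spaced
quantiles of the training `x`; boundary knots at the observed min/max.
The design follows the usual regression-spline convention: of the
`df + 1` complete basis functions (which sum to one at every `x`), the
first is dropped so the basis is not collinear with the intercept.
Prediction outside the training range clamps to the boundary with a
warning rather than extrapolating a cubic.

### Degenerate fits

On samples that are really a single population, the EM happily splits
one cloud into two near-identical components, and the resulting
posteriors are unstable noise.  A fit is flagged degenerate when any of:

* a mixing weight falls below 0.05 (one component has effectively
  collapsed);
* a variance hits the 1e−6 floor (a component has pinched onto a line);
* the two fitted mean curves are too close to describe distinct
  populations — average `|f₁(x) − f₀(x)|` over the sample below 1
  pooled standard deviation, or below 5 percentage points in absolute
  terms.  The absolute floor matters: on single-population data the EM
  tends to split off the clamp-at-zero spike, producing two "distinct"
  lines ~2 points apart that are meaningless as cell populations on the
  fixed percent scale.

If every restart is degenerate, fitting raises an error that points the
user at MAD filtering — on clean samples with a handful of damaged
cells a robust univariate rule is the right tool, and pretending the
mixture told you something is worse than failing loudly.

## Filtering

`filter_cells` applies, in fixed order:

1. **Posterior cutoff** (default 0.75, inclusive: remove when
   γ ≥ cutoff).
2. **Below-boundary rescue** (default on): any cell strictly below the
   intact line is kept.  Cells far *under* the intact line near the
   compromised line's x-intercept can receive a high compromised
   posterior purely because the broad compromised density reaches them;
   a cell with less mitochondrial content than a typical intact cell of
   its complexity is not compromised.
3. **Left cutoff** (default on): take the removed cell with minimum
   `y` (ties broken toward the largest `x`, the most permissive
   choice), and remove every cell at least as bad on both metrics
   (`x ≤`, `y ≥`, non-strict so the rule is idempotent and the
   reference cell stays removed).  This fixes U-shaped boundaries under
   which cells worse on both metrics than a removed cell would survive.
   It is applied whenever enabled rather than behind a shape-detection
   heuristic, which would add an undefined test for little gain.

Every decision carries a reason code naming the last rule that touched
it, so a decisions table is auditable line by line.

Comparators: a uniform percent threshold (remove when `y` strictly
exceeds the cutoff) and an upper-tail MAD rule (remove when
`y > median + 3 × 1.4826 × MAD`; the 1.4826 factor makes the MAD a
consistent σ estimate for normal data, and only the upper tail is
filtered because low mitochondrial content is never a defect).

A hard prefilter (fewer than 500 total counts or 100 detected genes)
removes unambiguous failures before any model sees the data.

## The synthetic generator

`simulate_qc_metrics` mirrors the model's own story, with the latent
state recorded: `Z ~ Bernoulli(π₁)`; `x` from a state-specific law —
intact roughly lognormal around 2500 detected genes, compromised
around 800, echoing that damaged cells sit at low complexity;
`y = β₀z + β₁z x + N(0, σ_z²)` clamped to [0, 100].  Defaults: 5000
cells, π₁ = 0.25, intact line (1.5, 0.0005) with σ 1.5, compromised
line (45, −0.01) with σ 8.  Total counts are a deterministic per-state
multiple of `x` (4× intact, 3× compromised) so the prefilter is
exercisable; the compromised factor stays ≥ 3 so that even a
high-mito, low-complexity cell can give each of its detected genes at
least one count when a count matrix is synthesized.

`simulate_count_matrix` turns a metrics table into a sparse
gene-by-cell matrix reproducing each cell's total, detected-gene count
(exactly) and mito percentage (to integer rounding — well under half a
point at totals ≥ 1000): totals are fixed first, the mito genes get
`round(total × pct/100)` counts, and counts are spread multinomially
with a one-count floor per detected gene.  Mito genes are named
`MT-1…` so prefix matching finds them.

What the generator does *not* emulate: gene–gene correlation, dropout
structure, batch effects, ambient RNA, doublets, or any specific
tissue's empirical distributions.  Passing tests on this generator
demonstrate that the estimator and filters behave correctly when the
model's assumptions hold, not that the model is adequate for any
particular real dataset.

### A note on the fitted mixing weight

On default synthetic data the fitted π₁ sits near 0.29 rather than
0.25.  This is a property of the model, not an estimation bug (the
likelihood at the fitted parameters exceeds the likelihood at the
generating ones): the generator couples state with complexity while
the likelihood assumes `π` constant in `x`, and the compromised
component's σ is >5× the intact one's, so soft assignment hands a few
percent of intact-tail mass to the broad component.  Hard
classification at the 0.75 cutoff is essentially unaffected
(≥ 99% accuracy against the generator's labels), as are the fitted
intercepts (~5% relative error).

## Defaults worth knowing

| parameter | default | why |
| --- | --- | --- |
| posterior cutoff | 0.75, inclusive | keeps the most potentially informative cells while removing confident compromised calls |
| prefilter | < 500 counts or < 100 genes | unambiguous failures; strict inequalities |
| EM tolerance / max iter | 1e−8 relative / 1000 | cheap model, tight tolerance |
| weight floor | 0.05 | below this a "component" is a handful of cells |
| variance floor | 1e−6 | guards zero-residual collapse |
| separation floors | 1 pooled sd, 5 pct points | see "Degenerate fits" |
| spline df / degree | 3 / 3 | cubic, no interior knots; df ≥ degree enforced |
| MAD scale | 1.4826, upper tail only | Gaussian-consistency convention |

## Problem sizes

The shipped tests and the acceptance script run on synthetic samples of
2000–5000 cells (and 20–50 replicate fits), which the defaults handle
in seconds; the EM is vectorized and scales linearly in cells, so
typical real samples (10⁴–10⁵ cells) pose no difficulty.

## Known limitations

* `π` constant in `x` is a modeling simplification; in reality the
  compromised fraction is concentrated at low complexity (see the
  mixing-weight note above).
* Exactly two components; no covariates beyond detected genes; no
  per-cell-type stratification (fitting within clusters selected on
  expression would bias the QC it feeds).
* The mito-gene rule defaults to the `MT-` symbol prefix; annotations
  that use chromosome fields or other conventions need an explicit
  gene list.
* The left-cutoff correction is applied unconditionally when enabled;
  there is no automatic U-shape detection, and no automatic switching
  between the mixture filter and MAD — the degeneracy error surfaces
  the recommendation, the user decides.
* Data already filtered upstream (public datasets especially) can look
  single-population and trigger the degeneracy path even though the
  original sample was mixed.
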