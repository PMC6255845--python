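# Methods

## The problem

During early fly embryogenesis the proteome is largely decoupled from the
transcriptome: mRNA and protein time courses correlate only weakly, which is
often read as evidence for widespread post-transcriptional regulation.  An
alternative explanation is kinetic: protein pools integrate their mRNA input
through synthesis and turnover, so even a constitutively translated gene can
show protein dynamics that look nothing like its mRNA.  `protdyn` implements
the model-based test of that alternative: it asks, gene by gene, whether a
small family of constant-parameter kinetic models driven by the *measured*
mRNA can quantitatively explain the *measured* protein time course, and only
labels a gene as a candidate for post-transcriptional control when none can.

## Kinetic model family

For one gene with mRNA input `u(t)` (piecewise-linear interpolation of the
measured values) and protein level `y(t)`:

| variant              | ODE                                      | free parameters   |
|----------------------|------------------------------------------|-------------------|
| stationary           | dy/dt = 0                                | y0                |
| degradation          | dy/dt = −λy                              | y0, λ             |
| production           | dy/dt = αu(t) − λy                       | y0, λ, α          |
| delayed production   | dy/dt = αH(t−τ)u(t) − λy                 | y0, λ, α, τ       |

With `u = mt + b` on each interval between measurements, every variant has
the closed-form solution

    y(t) = P(t)·[translation active] + (y_s − P(t_s)·[active at t_s])·e^{−λ(t−t_s)},
    P(t) = (α/λ)(b + mt − m/λ),

propagated interval by interval (the interval is split at `t = τ` when the
onset falls inside it).  The Heaviside convention is `H(0) = 1`, which makes
production the `τ → 0` limit of delayed production without a measure-zero
discontinuity.  The implementation is validated against adaptive
Runge–Kutta integration of the ODE (segment-wise, so the integrator never
crosses a kink): agreement to better than 1e−6 relative over the parameter
boxes.  Evaluation outside the measured mRNA span is an error, not an
extrapolation, because fitting only ever touches measured times.

Derived per-gene quantities: half-life `ln 2/λ` (infinite for stationary),
and steady states `y_ss = αu(t)/λ` at the first and last time points.  A gene
is "in steady state at t0" when its measured protein is within 20% of
`αu(0)/λ`.

## Error model and fitting

Label-free proteomics noise scales with signal.  Relating replicate standard
deviation to replicate mean across all (gene, time) cells gives a linear
error model `σ = slope·mean + intercept`; the default slope 0.169 and zero
intercept describe four biological replicates of the embryo proteome.  When
replicate data are supplied, the model is re-estimated by ordinary least
squares (intercept clamped at ≥ 0; fewer than 10 usable cells falls back to
the default with a warning).

Fitting minimises `χ² = Σ_i (y_model(t_i) − y_i)²/σ_i²` over the non-missing
protein points, with `σ_i` evaluated at the *measured* value so the weights
are fixed and the problem is true weighted least squares.  Protein matrices
are first rescaled by their global mean (the proportional error model makes
χ², λ and τ invariant under this; y0 and α are reported back-transformed).
Parameters are optimised on a log10 scale inside the boxes
y0 ∈ [1e−1, 5e3], λ ∈ [ln2/1e3, ln2/1e−1] h⁻¹, α ∈ [1e−5, 1e−1], τ ∈
[1e−5, 10] h with a trust-region-reflective solver; multistart uses
latin-hypercube samples (5 for degradation and production, 25 for delayed
production; the stationary fit is the closed-form weighted mean).  Each
richer variant's multistart additionally includes the simpler variant's
optimum with the extra parameter at its box minimum, so fitted χ² values are
nested along the complexity chain up to a small, quantifiable leak (see
below).  Primary fits use ftol = xtol = 1e−10 (gtol 1e−8); genes with fewer
than 10 of 14 non-missing protein points are not fitted at all and are
reported as `insufficient_data`.

### Box-floor nesting leak

The four variants are strictly nested only in the limit α → 0 (and τ → 0 or
τ → ∞), but the boxes keep α ≥ 1e−5 and τ ≤ 10 h.  With raw-unit mRNA inputs
in the hundreds and rescaled protein near 1, the irreducible production term
of a "degradation-like" production fit can cost a few χ² units, so the LR
statistic `Λ = χ²_simple − χ²_complex` can be legitimately (mildly)
negative.  The selection walk treats any non-significant Λ — including
negative values — as "keep the simpler model", and raises an optimizer-
failure error only when the gap exceeds 25 (a gap that large cannot come
from the box floors on these data scales).

## Goodness of fit and feasibility

Because n ≤ 14 and parameters are estimated, the χ² statistic is far from
its asymptotic distribution; both test statistics are therefore calibrated
by a parametric bootstrap (default B = 1000; the desk-scale analyses and
tests use B = 100–200).  Each resample adds Gaussian noise (σ from the error
model at the original data values) to the best-fit trajectory at the
non-missing points and refits the same variant from the original estimates
(single start, tolerances 1e−6 — the bootstrap needs the statistics only to
~1e−3).  The refit keeps the *original* data's σ weights: re-evaluating σ at
the resampled values would let a resample near zero acquire a floored σ and
an astronomical χ² contribution, corrupting the empirical null in both
directions.  Empirical p-values use the plus-one rule, so p is never exactly 0:

* `p_χ²`: upper tail — large misfit rejects;
* `p_DW`: lower tail of the Durbin–Watson statistic
  `d = Σ(r_i − r_{i−1})²/Σr_i²` — positive serial correlation of the
  time-ordered weighted residuals (d → 0) indicates a systematic deviation.
  For a perfect fit (all residuals zero) d is undefined and reported as 2.
  An upper-tail option is not exposed; the test exists to catch systematic
  deviations, which manifest as positive autocorrelation.

p-values are Benjamini–Hochberg adjusted across genes, separately per
(variant, statistic) — this matches the per-variant feasibility decision; a
variant is feasible for a gene iff both adjusted values are ≥ 0.05.  Fits
that never converged are infeasible by fiat and excluded from the BH pool.

## Model selection and re-assignment

Among the feasible variants the walk
stationary → degradation → production → delayed production applies the LRT
at each adjacent feasible pair (df = difference in free-parameter counts, so
skipped infeasible links accumulate df; critical value `χ²_{1−α, df}`,
α = 0.05 one-tailed, i.e. 3.841 for df = 1) and stops at the first
non-significant step.  No AIC/BIC is involved.  A gene with no feasible
variant is `rejected` — the candidate set for post-transcriptional
regulation.

Biologically, production is the *unregulated* scenario even though it has
more parameters: stationary or degradation dynamics require an extra factor
that blocks translation (or both synthesis and turnover).  A gene selected
as stationary or degradation is therefore re-assigned to production when the
production variant is feasible *and* its translation rate is bounded away
from zero — operationalised as the lower end of α's 95% profile-likelihood
CI lying above the α box minimum (not merely clipped to it).  The original
study describes this correction only in a supplement not available here;
the α-CI rule is this package's operationalisation of "could not be
rejected with a nonzero protein translation rate".

A post-MZT mode (`min_time = 3`) refits on the sub-grid of time points
≥ 3 h with the same boxes; y0 then denotes protein at the window start.

## Uncertainty

95% profile-likelihood CIs: the parameter is stepped on a log10 grid from
its estimate to each box edge (40 steps per direction), re-optimising the
remaining free parameters at each step (warm-started from the neighbouring
step); the interval ends where the profiled χ² crosses χ²_min + 3.841
(df = 1), located by bisection between bracketing grid points (tolerance
1e−3 in log10).  Bounds that never cross are clipped to the box edge and
flagged — the flag is what the re-assignment rule checks.  Profiling is done
on the log scale, consistent with the log-scale sampling and optimisation.

Half-life CIs are the monotone transform of the λ CI (endpoints swap).  A
gene is `short`-lived when its half-life CI upper bound lies below the
median of all point-estimate half-lives in the dataset at hand (recomputed,
never hard-coded) and `long`-lived when the lower bound lies above it;
everything else is `indeterminate`.

## Correlation and clustering analyses

* Global cross-time correlation: genes ranked by maximum |log2 fold change|
  of protein vs 0 h, the top 500 kept; Spearman ρ across genes for every
  (mRNA time, protein time) pair, missing values skipped pairwise.  The
  ranking uses the protein layer only.
* Per-gene shifted correlation: even time points only
  (0, 2, …, 20 h); shift i ∈ [−5, +5] grid steps matches mRNA at t_n with
  protein at t_{n+i}; ≥ 6 complete pairs required; two-sided p from the
  Student-t approximation `t = ρ√((n−2)/(1−ρ²))`; ties get average ranks.
* Per-gene maximum correlation over shifts 0…+10 h, regardless of
  significance, with the cohort median reported.
* Trajectory-pair clustering: each gene's mRNA and protein vectors are
  normalised by their 0 h value, log10-transformed and min-max scaled to
  [−1, 1], then concatenated (joint clustering of the pair); complete-
  linkage agglomeration on Euclidean distance, tree cut at k = 4.  Genes
  with missing or non-positive values are dropped (the 0 h normalisation
  requires positivity).
* Hypergeometric overlap: expected overlap `Kn/N`, fold enrichment
  `k/expected`, upper-tail p `P(X ≥ k)`.

## Synthetic data: the stated world

The generator emulates the statistical structure of the embryogenesis
dataset so the whole pipeline is testable without the deposited data:

* Grid: the study's 14 points {0…6 h hourly, then every 2 h to 20 h}.
* mRNA: `u(t) = M e^{−δt} + Z/(1 + e^{−(t−t_on)/w})` — maternal decay plus
  a logistic zygotic wave; M, Z log-uniform in [50, 500], δ uniform in
  [0.1, 1] h⁻¹, onset t_on uniform in [2.5, 3.5] h (the MZT), width w
  uniform in [0.3, 1] h.  mRNA is treated as noise-free input, as the
  pipeline does.
* Noise: per replicate (4 replicates) Gaussian with σ = 0.169·value; the
  reported value is the replicate median.
* Missingness: entries whose *noiseless* value falls below the 5% global
  quantile are masked (detection limit, not missing-at-random), at most 4
  of 14 per gene.
* Kinetics are sampled log-uniformly but inside identifiable sub-ranges of
  the fitting boxes — a draw in a degenerate corner (e.g. a "production"
  gene whose production term is invisible) would make the ground-truth
  label meaningless: y0 ∈ [1, 100]; turnover half-lives 1–10 h; production
  steady state 0.3–3× y0 (2–10× for delayed production, whose protein
  accumulates after onset); τ ∈ [2, 8] h; α additionally floored at 3× its
  box minimum.
* Because the pipeline rescales protein by the cohort's global mean, the
  *recoverable* parameters are y0/scale and α/scale.  After the initial
  draw, genes of the four model classes whose rescaled parameters would
  leave the fitting boxes (3× safety margin) are re-drawn, with the cohort
  mean recomputed between rounds.  The box floor y0 ≥ 0.1 (rescaled units)
  amounts to asserting that no reproducibly detected protein starts below
  ~10% of the cohort mean — consistent with the ≤4-missing inclusion filter
  selecting well-quantified proteins.
* Decoy class (`regulated_decoy`): a production backbone whose translation
  rate α steps by a factor 5–10 (up or down, equally likely) at a random
  time in (2, 14) h.  Because a step-up from a negligible base is
  *indistinguishable* from delayed production, the class definition —
  dynamics outside every constant-parameter variant — is enforced directly:
  draws are rejected until the best zero-noise fit over all four variants
  leaves χ² ≥ 25 (≈ the 95th percentile of χ² with 14 points, i.e.
  detectable at the stated noise).  The decoy's α(t) may leave the fitting
  box; the four model classes never do.

What a green benchmark does **not** establish: recovery on real LFQ/RPKM
data (intensity distributions, peptide-level effects, imputation artefacts
and count noise are not simulated), nor the study's published class
fractions, which depend on the deposited datasets.

## Numerical choices

* Seeds: one master seed drives per-gene `SeedSequence` spawns; identical
  config + seed reproduces classification tables byte-identically
  (provenance records deliberately contain no timestamps).
* Bootstrap refit cap: 300 function evaluations; failed refits are dropped
  (warning above 10% failures).
* σ floor 1e−8 guards against zero weights at zero signal.
* BH scope, DW tail, feasibility level, LRT α, multistart counts and the
  inclusion threshold are all configurable; defaults are the values above.

## Known limitations

* The bootstrap refits once from the original optimum (as the original
  procedure specifies); a full multistart per resample would be ~25× more
  expensive and occasionally find deeper optima, making the tests slightly
  more conservative as implemented.
* Profile CIs assume a unimodal profile; flat profiles (unidentifiable
  parameters) are reported as box-spanning with flags, not errors.
* The LRT chain compares adjacent *feasible* models; anchoring always at the
  simplest feasible model is a plausible alternative reading of the original
  procedure and would differ only when an intermediate variant is feasible
  but both its neighbours are chosen.
* With ~14 points the DW statistic has little power against weak serial
  correlation; it is a guard against gross systematic misfit.
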