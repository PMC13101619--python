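# Methods

This note documents the statistical model behind `carenet`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Data model and preprocessing

The unit of analysis is the **case** — one inpatient stay. Input records
carry one row per documented application of a care activity
(`Patient_ID, Care_Activity, Date_Time, N_Provider, Care_Time`), with care
time in minutes at minute-resolution timestamps in a single declared format
(`YYYY-MM-DD HH:MM:SS`; an override flag exists because guessing dialects
silently corrupts timestamps).

Validation is exclusion-only and never imputes: rows with nonpositive care
time, care time above a plausibility cap (default 340 minutes per
application, configurable), or fewer than one provider are dropped and
logged with a reason. The cap is a sanity bound against documentation
artifacts, not a clinical statement.

Aggregation sums care time per (case, activity) over the whole stay. A zero
cell is an **observed zero** — the activity was not applied to that case —
not missing data, because the estimand is the correlation of care-time
allocation across *all* cases. Aggregation conserves total minutes exactly
and is invariant to record order (rows/columns are sorted
lexicographically). By default no prevalence filter is applied and only
constant columns are removed before estimation; the pruning of weakly
connected activities happens *after* thresholding, as removal of isolated
network nodes. A pre-estimation prevalence filter is available
(`min_prevalence`) for users who prefer to exclude rare activities up
front; the two choices are not equivalent and the default makes the
reduction from recorded activities to network nodes explicit in the output
log.

## Network estimation

The estimation chain is correlation → graphical lasso → partial
correlations → hard threshold.

* **Correlation scale.** The graphical lasso runs on the Pearson
  correlation matrix of activity totals (equivalently, z-scored totals).
  Totals span minutes to hundreds of minutes across activities; estimating
  on the covariance scale would let high-volume activities dominate the
  penalty.
* **Penalty scope.** The L1 penalty covers the diagonal by default,
  matching the classical reference implementation of the algorithm;
  `penalize_diagonal=False` switches to the off-diagonal-only convention
  used by some other implementations (e.g. scikit-learn). Default
  `λ = 0.05`. No model selection over λ is performed — λ is a reporting
  choice that trades sparsity against visibility of weaker bundles, and the
  package treats it as a configuration value.
* **Edge rule.** Edges are the Θ-supported pairs (|partial| above a 1e-8
  numerical floor) with `|partial correlation| ≥ τ`, inclusive, default
  `τ = 0.15`. Weights are *signed partial* correlations. Thresholding the
  marginal Pearson correlation instead is available
  (`threshold_on="marginal"`) since the two conventions genuinely differ;
  partial correlations are the default because they are what the sparse
  precision estimate actually parametrizes. Nodes with no surviving edge
  are removed and logged.

### Solver

Block coordinate descent over columns (Friedman-style), inner lasso by
coordinate descent on a maintained residual. Deterministic column order, no
randomness anywhere in the analysis path. Convergence requires **both**

1. mean absolute change of Θ between sweeps < 1e-4 × mean |off-diagonal R|
   (floored at 1e-8 for near-diagonal inputs), and
2. KKT (subgradient) residual of the penalized log-likelihood ≤ 1e-4
   (tightened to 1e-10 when λ = 0, where the exact solution is `R⁻¹` and a
   loose W-scale residual would still allow Θ-scale errors above 1e-6 on
   ill-conditioned inputs).

The Δ-Θ rule alone does not certify stationarity, so every returned fit
carries its KKT residual; non-convergence within 500 sweeps raises with
diagnostics rather than returning a silent approximation. Positive
definiteness of the returned Θ is verified by eigendecomposition.

## Structural metrics

All metrics are computed on the **binarized** graph; weights are retained
for export only. Conventions, chosen to match how such networks are
reported:

* Degree is the integer edge count per node.
* Node and edge betweenness are **raw** Brandes accumulations over
  unordered pairs with fractional counting over tied shortest paths
  (endpoints excluded for nodes). Raw rather than normalized values are the
  default because bundle-bridging is easier to read off counts; a
  normalized variant sits behind a flag.
* Diameter and characteristic path length are computed over *connected*
  pairs only, so a disconnected module (e.g. a discharge bundle) does not
  make them undefined. The full shortest-path-length distribution is
  reported alongside.
* Transitivity is 3·triangles / connected triples; the average local
  clustering counts degree-<2 nodes as 0 (flag to exclude them instead).
* Community detection is a deterministic greedy modularity agglomeration:
  start from singletons, repeatedly merge the connected pair of communities
  with the largest positive gain, break ties lexicographically on the
  smallest node label. It is seedless and reproducible, and it is a
  heuristic: on tiny graphs the tests compare it against exhaustive
  enumeration over all partitions and report the (usually zero) gap, but Q
  values from different heuristics are generally not comparable at the
  second decimal.
* Summary tables report median [lower, upper quartile] (linear
  interpolation), rounded to 2 decimals for display only.

## Synthetic data

The generator exists because real care-activity datasets are hospital
records and cannot be shipped. It is written to emulate the *shape* of
routine postnatal care-activity data, with a fully known ground truth:

* **Truth.** A block-diagonal, unit-diagonal precision matrix. Each block
  is a care bundle with prescribed within-block partial correlations:
  positive partials encode co-escalating care time (classic bundles);
  negative partials encode *time competition* within a bundle (minutes
  spent on one activity displace minutes on another). Positive
  equal-partial cliques of size k require ρ < 1/(k−1) for positive
  definiteness, so large bundles use a sparse triangle-rich backbone
  (chain + second-neighbour chords) instead of cliques; negative-partial
  cliques are positive definite for any size and magnitude < 1. Requested
  structures that are not positive definite raise immediately with advice
  to reduce magnitudes.
* **Margins.** Per-case totals are drawn through a Gaussian copula: latent
  Gaussians with covariance Θ⁻¹ mapped through per-activity log-normal
  total-minutes distributions. Zeros come from a hurdle on the same latent
  scale, so prevalence and correlation stay jointly controllable. Totals
  are rounded to whole minutes (≥ 1), matching how care time is
  documented.
* **Records.** Each positive cell of T minutes is split into
  `max(1, round(T / 3.7))` parts (capped at T) drawn uniformly from the
  integer compositions of T — so disaggregation → aggregation conserves
  minutes *exactly* — with timestamps uniform in the case's stay window
  (1–5 days by default) and 1–2 providers per record. Identical seeds
  reproduce identical record sets bit for bit; all stages use independent
  substreams of one seed.

The default `maternity_like_spec` has 113 activities over 2 346 cases: a
26-activity standard-care bundle and a 20-activity specialized-care bundle
(positive partials 0.16–0.24 on the sparse backbone), an isolated
4-activity discharge clique (0.25–0.30), three strongly tied pairs, and a
57-activity tail of rare (2–40% prevalence) isolated activities.
Per-application durations under the splitting rule average ≈3.6 minutes
with the default margins, consistent with the few-minute applications of
routine care-activity documentation.

What the generator does **not** emulate: documentation artifacts beyond an
optional uniform record-dropout rate, within-stay temporal structure
(timestamps are exchangeable within the window), provider-level effects,
case-mix heterogeneity, and any dependence between stay length and care
volume. Passing tests therefore show that the *estimator and metrics* are
correct under a known truth — not that real hospital networks will look
like the synthetic ones. In particular, with the default bundle strengths
and zero-inflation, the fitted synthetic network is sparser and more
fragmented than networks reported from real maternity data; the generator
prioritizes a controllable, provably positive-definite truth over matching
any particular published network's density.

## Benchmark fixtures

Two canonical planted truths are used by the tests, the power study and the
acceptance script; both have 30 activities and truth density ≈ 0.15
(67/435 edges) and were designed once, from the population-limit analysis
below, then frozen:

* `benchmark_recovery_spec` — every |partial| ≥ 0.3: four 6-activity
  competition cliques at −0.80 plus a +0.30..0.32 clique and a +0.40..0.42
  pair, with mildly variable log-normal margins (σ = 0.25) and full
  prevalence. A density-0.15 truth with all-positive partials ≥ 0.3 is
  mathematically impossible on 30 nodes (the support's spectral radius
  would have to stay below 1/ρ, capping the edge count near 50), which is
  why the design leans on competition cliques. At n = 5 000, λ = 0.05,
  τ = 0.15 the pipeline recovers this truth with sensitivity and
  specificity ≈ 1.
* `benchmark_power_spec` — mixed strengths: two detectable competition
  cliques at −0.50 whose population-limit estimated partials (≈0.18) sit
  just above τ, two weak cliques at −0.20 far below it, plus the same
  positive blocks. Sensitivity therefore rises with sample size and
  plateaus near 0.52 — a deliberately *partially* recoverable network, the
  regime in which routine sample sizes detect only the stronger half of the
  structure.

The population-limit analysis composes three exact steps: Σ = Θ⁻¹ for an
equicorrelated block in closed form, the exact bivariate-log-normal
attenuation of Pearson correlation
`r_X = (e^{σ²ρ} − 1)/(e^{σ²} − 1)`, and the graphical lasso of the
resulting population correlation matrix. Useful rule of thumb from it: the
marginal correlation inside an equal-partial negative k-clique is capped
near −1/(k−1), so large competition bundles are intrinsically hard to
recover at a fixed partial-correlation threshold.

## Power study

`run_power` draws, for every (sample size, replicate), a fresh totals
matrix from the truth, runs the full pipeline at the given (λ, τ), and
scores the thresholded edge set: sensitivity over true edges, specificity
over true non-edges, and the Pearson correlation between true and
estimated partials on the recovered true edges (reported separately, since
"detecting an edge" and "estimating its weight" are different questions).
Sensitivity is undefined (NaN) for a truth without edges. Replicates use
independent substreams of one seed and are bit-reproducible. Sample sizes
below 10 cases per activity trigger a warning rather than an error.

## Degenerate inputs and numerical edges

* Correlation requires ≥ 3 cases and no zero-variance column (the error
  names the column; `filter_activities` removes such columns and logs
  them).
* An empty record set or a filter that removes every column raises an
  explicit empty-matrix error.
* Distances are an error on an edgeless graph; every retained network node
  has degree ≥ 1 by construction.
* τ comparisons are inclusive (`|P| ≥ τ`); Θ-support uses a 1e-8 floor.
* Modularity merge gains use a 1e-12 tie window with lexicographic
  tie-breaking, making partitions platform-independent.

## Limitations

* The network is a population-level, static description: it cannot say
  which activities follow one another within a stay, and edges are
  conditional associations, not causal claims.
* λ and τ are fixed reporting choices; no data-driven selection (EBIC,
  cross-validation, stability selection) is provided.
* Pearson correlations of skewed, zero-inflated totals understate latent
  association (the attenuation above); the package estimates what it
  reports — correlations of observed totals — and makes no latent-scale
  correction.
* The greedy modularity heuristic can be suboptimal on graphs with shallow
  modularity landscapes; its Q should be read to one decimal.
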