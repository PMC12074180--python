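# Methods

This note records the statistical model behind `calconsensus`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Calibration model

Each fortified calibration curve is modelled as a straight line
`y = a·x + b + ε` between nominal concentration `x` (ng g⁻¹, strictly
positive; the blank level never enters) and the analyte/IS peak-area ratio
`y`.  Fitting is unweighted ordinary least squares, never forced through the
origin.  Standard errors, and 95 % confidence intervals with the Student-t
quantile on n−2 df, come from the standard OLS theory (statsmodels).
Weighted fitting is deliberately not offered as a default: the workflow's
equivalence test (below) compares residual sums of squares and assumes a
common homoscedastic error; weighting would have to be applied consistently
across every stage and is left out of scope.

Degenerate inputs are rejected rather than silently fitted: fewer than three
distinct levels raises a degenerate-input error, identical levels a
singular-design error.  A constant response is allowed (the fit `a = 0,
b = ȳ` is well defined); its R² is reported as 1 because the model error is
exactly zero.

Residual diagnostics report QQ coordinates, fitted-vs-residual pairs, and an
omnibus normality p-value: Shapiro–Wilk below n = 20, D'Agostino–Pearson at
n ≥ 20 (the omnibus skewness/kurtosis moments are unstable in very small
samples).  Residual vectors whose spread is at rounding-noise level are
reported with p = 1; no normality question arises for an exact fit.

## Validation metrics

* `LOD = 3.3·SD/|a|`, `LOQ = 10·SD/|a|` with SD the standard error of the
  intercept.  The absolute slope keeps both limits positive for
  inverted-response (negative-slope) curves, so `LOQ/LOD = 10/3.3` exactly,
  always.
* `SE = (CI_upper − CI_lower)/3.92` converts a reported 95 % interval back
  to a standard error (3.92 = 2·1.96).
* Accuracy tables report, per nominal level: mean back-calculated
  concentration, `%RSD = 100·s/mean` (sample SD), `%Rec = 100·mean/nominal`
  and a t-based 95 % CI of %Rec.  Display rounding (mean 2 dp, %RSD 1 dp,
  %Rec integer) is applied only at rendering; internal values keep full
  precision.
* Matrix effect: `%ME = 100·(a_matrix/a_solvent − 1)`.  Positive means
  ionisation enhancement, negative suppression; |%ME| strictly above 20 %
  is flagged strong.  Note the direction of the ratio: matrix-matched slope
  over solvent slope is the form that makes the sign convention come out
  right, and is the convention adopted here.
* Threshold rules: selectivity passes when the blank signal is strictly
  below 20 % of the LLOQ signal; IS interference passes when the blank
  signal in the IS channel is at most 5 % of the IS signal (the boundary
  itself passes, since only exceedance is flagged); carryover passes when
  the post-ULOQ blank is strictly below the LOD signal.
* Chromatography: capacity factor `k = (t_r − t_0)/t_0` and selectivity
  factor `α = k₁/k₂` (later-eluting analyte over reference).  The dead time
  `t_0` is a user input — it cannot be recovered from a capacity factor
  alone.

## Equivalence and consensus

The extra sum-of-squares F test compares two nested OLS models on m curves
with N points total: the null "one shared slope and intercept" (RSS₀, N−2
df) against "an individual line per curve" (RSS₁ = Σ RSSᵢ, N−2m df):

    F = [(RSS₀ − RSS₁) / 2(m−1)] / [RSS₁ / (N − 2m)]

with the p-value from the F tail (regularized incomplete beta, via scipy).
Sharing *both* parameters is the null of interest because the question being
answered is "may one consensus curve quantify all these runs"; equivalence
is declared at p ≥ α, α = 0.05 by default and configurable.  Nestedness
guarantees RSS₀ ≥ RSS₁ and hence F ≥ 0; tiny negative rounding differences
are clamped.  A consensus curve is simply the OLS fit to the pooled points
of an equivalent set.

## Clustering of curve parameters

Curves are embedded as (slope, intercept) pairs — univariate slope-only and
intercept-only embeddings are computed alongside for concordance, since all
three views should agree when the day structure is real.  Distances use the
Canberra metric, whose per-coordinate normalisation |xᵢ−yᵢ|/(|xᵢ|+|yᵢ|)
handles the different magnitudes of slopes and intercepts without explicit
standardisation; no further scaling is applied.  One caveat follows directly
from the metric: a coordinate equal to exactly zero is at distance 1 from
every nonzero value, so near-zero parameters compress badly.  Calibration
slopes and intercepts are bounded away from zero in practice.

Agglomeration is complete linkage, written out explicitly (the input is a
handful of curves) so the contract can be deterministic: on equal merge
heights the pair containing the smallest original curve indices merges
first.  Complete-linkage heights are monotonically non-decreasing.

Cluster-count selection scans k = 2..min(5, m−1) with two validity indices:

* **Dunn index** — minimum between-cluster distance over maximum
  within-cluster diameter (larger is better); undefined when every cluster
  is a singleton.
* **Mean silhouette width** — per point `(b−a)/max(a,b)`; singleton-cluster
  points contribute 0.

The chosen k maximises both indices when they agree; on disagreement the
silhouette wins, because it is bounded in [−1, 1] and comparable across k,
whereas the Dunn index has a known pathology at k = m−1: cutting a
hierarchical tree one step below the root makes the Dunn index the ratio of
the two smallest pairwise distances, which is always ≥ 1 and heavy-tailed,
so it can spuriously favour the almost-all-singletons partition.  Partitions
whose best silhouette stays below 0.5 (the conventional boundary below which
structure is "weak, possibly artificial") carry a low-confidence flag.

## Method comparison

Two curve sets are compared as reference (x) vs test (y) methods on their
per-level mean responses over the shared concentration grid — the only
pairing construction available when the two methods are calibration curves
rather than sample-by-sample measurements.

* **Deming regression** with error-variance ratio λ (y:x), default 1.  The
  closed-form slope `[s_yy − λs_xx + √((s_yy−λs_xx)² + 4λs_xy²)]/(2s_xy)`
  minimises Σ(y−ax−b)²/(λ+a²).  Standard errors come from the leave-one-out
  jackknife with t-based 95 % intervals (n−2 df) — standard practice for
  method-comparison sample sizes.
* **Passing–Bablok regression**: all C(n,2) pairwise slopes, pairs with
  equal x skipped (slope undefined), slopes equal to −1 excluded; the
  estimate is the median shifted by K = #{S < −1}, which makes the fit
  symmetric in x and y.  Even slope counts take the *lower* median.  CIs use
  the rank-based normal approximation with
  `w = 1.96·√(n(n−1)(2n+5)/18)`; the intercept is `median(y − slope·x)`
  with its CI induced by the slope bounds.  No CUSUM linearity test is
  provided.
* **Bland–Altman**: bias = mean(y−x), limits of agreement bias ± 1.96·s
  (sample SD), with per-point differences and means exported for plotting.

## Workflow decision logic

The global equivalence gate runs before any clustering: if all curves
already share a line, clustering equivalent curves would only manufacture
spurious structure.  Otherwise the pipeline clusters, tests each cluster
internally, fits consensus curves for the clusters that pass, compares
clusters pairwise and profiles back-calculation error.  A cluster that fails
its internal test is excluded from consensus fitting (with a warning) but
still participates in the pairwise comparison, which needs only the observed
per-level means.  The verdict is total: `single_consensus` when the global
gate passes, `no_consensus` when no cluster is internally consistent,
`per_cluster_consensus` otherwise.  The whole pipeline is deterministic
given the input data and configuration.

## Synthetic data

`simulate_curves` draws `response = a_day·level + b_day + ε` with
`ε ~ N(0, σ_add² + (σ_prop·|truth|)²)` per (day, replicate, level), fully
reproducible from an integer seed.  The default grid is the 8-point
2.5–20 ng g⁻¹ design; default noise (σ_add = 0.003 response units,
σ_prop = 3 %) yields back-calculated replicate %RSD in the 3–6 % range
typical of fortified-tissue QC data.  Setting σ_prop = 0 gives a
homoscedastic model, σ_add = 0 a purely proportional one.

`two_day_liver_preset` is the reference scenario used throughout the tests:
two days × three replicate curves with true lines
(−24.96·10⁻³, −3.29·10⁻²) and (−18.81·10⁻³, −1.38·10⁻²) — a between-day
response ratio of 0.754 — and homoscedastic noise σ_add = 0.004.  The purely
additive choice is deliberate: the residual diagnostics this design is meant
to emulate are homoscedastic, and the F test the workflow relies on assumes
it; a proportional component of realistic size measurably inflates the
within-day false-rejection rate above its nominal 5 %.  Under these
conditions (measured over 200 seeds): per-curve R² > 0.99, day-membership
recovery ≈ 97 %, within-day F rejection ≈ 5 %, cross-day rejection ≈ 100 %,
median silhouette profile over k = 2..5 ≈ (0.84, 0.66, 0.46, 0.26) with the
peak at k = 2.

What the generator does *not* emulate: level-dependent extraction recovery,
drift within a run, non-Gaussian heavy-tailed outliers, censoring at the
detection limit, or correlation between replicate curves of the same day
beyond their shared true line.  Passing tests therefore demonstrate that the
statistical machinery behaves correctly under its stated assumptions, not
that real tissue data satisfies those assumptions — the residual and QQ
diagnostics exist precisely to check that on real data.

Because single draws fluctuate, stochastic end-to-end properties (joint
index peak at k = 2, per-cluster retention at p ≥ 0.05) are asserted as
rates and medians over a fixed seed panel rather than on one draw; a
single-seed assertion of a 95 %-probability event would fail one run in
twenty by construction.

## Numerical conventions and edge cases

* All threshold comparisons are documented above as strict or inclusive;
  boundary cases are tested.
* `extra_ss_f_test` with RSS₁ = 0 (noiseless data): F = 0 and p = 1 when the
  pooled fit is also exact, otherwise F = ∞, p = 0.
* Deming with s_xy = 0 raises an indeterminate-orientation error when
  s_yy = λ·s_xx (no preferred direction) or a vertical-orientation error
  when s_yy > λ·s_xx; the flat line is returned when s_yy < λ·s_xx.
* Passing–Bablok CI ranks are clipped to the available slope range at very
  small n.
* Report rounding is cosmetic only; JSON output carries full precision.

## Problem sizes

The test suite and the acceptance script size their simulations to the
statistics they need: 1000 null datasets for the type-I error of the F test
(Monte-Carlo SE ≈ 0.7 %), 200 draws for cross-day power, a 20-seed panel for
the end-to-end workflow, and ≤ 10-point inputs for the exhaustive
Passing–Bablok/clustering oracles, which are factorial in n.
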