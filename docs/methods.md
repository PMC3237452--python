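# Methods

## Data model

A *batch* is one perfusion: a J×K matrix of perfusate concentrations
(J = 25 metabolites, K = 6 hourly samples). A study is an I×J×K array with
per-batch class labels (`fresh` / `wi` for warm-ischemic). All modelling
happens on the *batchwise unfolding*: an I×JK matrix whose row i is
[x_i(·,1), x_i(·,2), …, x_i(·,K)] — the J metabolites of hour 1, then
hour 2, and so on (the column↔(metabolite, hour) map is kept explicit so
diagnostics can be re-aggregated per metabolite). A variable-wise IK×J
unfolding is provided for batch-progress analyses but is not used by the
monitoring path.

Scaling is mean-centring and unit-variance scaling per (metabolite, hour)
column, learned on the training batches only and applied unchanged to new
batches — including warm-ischemic ones, whose deviations must be measured
in the fresh model's coordinates for projection to mean anything.
Columns with zero training variance get sd forced to 1 and a degeneracy
flag, so pathological configurations cannot divide by zero. Negative or
non-finite cells (impossible assay read-outs) are repaired to the training
mean trajectory before analysis; no other imputation is performed.

## The monitoring model

MPCA is PCA of the scaled, batchwise-unfolded fresh-liver matrix, computed
by singular value decomposition; the loadings **P** (JK×R) are the top R
right singular vectors, with each column's sign fixed so its
largest-magnitude entry is positive (scores and biplots reproduce across
SVD implementations). The default R = 3 reflects the low-rank structure of
the data; an explained-variance stopping rule (drop components adding
< 5%) can be applied by the caller but is not the default.

**Offline SPE.** For a new batch, SPE = ‖**x**(I−**PP**′)‖² over all JK
entries, with log₁₀(SPE) reported as a continuous ischemia index. The
log base and the 1.35 alarm threshold are configurable; 1.35 matches SPE
magnitudes in the tens, which is where per-hour SPE values of ischemic
perfusions sit under the default conditions.

**Online SPE.** At hour k only hours 1..k exist. Scores are the
least-squares solution on the leading J·k loading rows (the
"missing future data" projection; a pseudo-inverse handles possible rank
deficiency of the truncated block). SPE_k is, by default, the residual sum
over the J metabolites of hour k alone — each hour then has its own
control limit — with a cumulative variant (hours 1..k) selectable.

**Control limits.** Limits at α ∈ {0.05, 0.01} use the scaled-χ²
approximation: limit = g·χ²_{h,1−α} with g = v/2m and h = 2m²/v from the
mean m and variance v of a normal-operation SPE sample. The sample is
computed **leave-one-out**: each training batch's SPE (offline and per
hour) is evaluated against a scaler and loadings refit without that batch.
In-sample residuals are optimistically biased — the scaler and the fitted
subspace both adapt to the very batches being scored — and limits built
from them under-cover new batches noticeably; leave-one-out samples remove
that bias (empirically, ~95% of held-out null batches fall under the fitted
95% limit at I = 200). Limits need at least 4 training batches; below
that they are infinite and flags never raise. The offline limit uses the
same construction as the online ones.

**Contributions.** The offline residual decomposes exactly into
per-(metabolite, hour) squared terms e²_jk summing to SPE, reported next
to the signed normalized errors e_jk/ŝ_jk (identical to the residuals of
the scaled data, since ŝ is the training sd). The contributor screen
flags a metabolite at hour k when its *signed normalized* contribution
leaves the mean ± 3σ band of the fresh reference contributions at that
cell; the reference is the leave-one-out residual stack of the training
batches. The band on the signed statistic keeps the null flag rate at the
classic ~0.3% per cell (well under one metabolite-hour per batch);
screening the squared contributions against mean + 3σ — equivalent to a
±2.3σ two-sided rule, with several spurious cells per batch — is available
as `statistic="squared"` but is not the default.

**Outlier screening.** Batches are screened in the (t₁, t₂) score plane
with a Hotelling ellipse: T² = t₁²/s₁² + t₂²/s₂² against
2(I−1)/(I−2)·F_{2,I−2,1−α}; batches outside the 99% ellipse are reported
for exclusion before the final fit. Per-axis bands would be an
alternative reading of biplot limits; the elliptical region is the
standard choice and is what is implemented. Note the masking bound of any
non-robust screen: a single arbitrarily extreme batch saturates at
T² = (I−1)²/I, which stays below the 99% limit for I ≲ 16, so the screen
is only informative at study-sized I (the intended use has I ≈ 16–18).

## The classifier

MPLS-DA is PLS2 between the scaled unfolded trajectories and a mean-centred
dummy class matrix (fresh → [1,0], wi → [0,1]; fresh first). Components
are extracted by NIPALS with X- and Y-block deflation; convergence requires
the weight vector to move < 1e-10 between iterations (500-iteration cap,
error naming the component on failure). Weight signs follow the same
largest-entry-positive convention. If the Y block is numerically exhausted
before R components, remaining components take the dominant right singular
direction of the deflated X (pure X-variance directions with ~zero Y
loading). Regression coefficients **B** = **W**(**P**′**W**)⁻¹**C**′ give
the one-shot prediction ŷ = **x B** + ȳ, algebraically identical to the
sequential score path — both routes are kept and tested against each other.

Predictions are normalized to sum to one; the fresh-class entry is the
quality estimate. Class = argmax of the normalized vector, equivalently
quality > 0.5 for fresh; a tie at exactly 0.5 is called warm-ischemic
(an ambiguous organ is treated as injured). Y is mean-centred for fitting
and the centre restored before normalization.

VIP for column c: √(JK·Σ_r SS_Y(r)·w²_{c,r} / Σ_r SS_Y(r)), with SS_Y(r)
the response sum of squares captured by component r; mean squared VIP is 1
by construction, and per-metabolite scores are the RMS over that
metabolite's K columns.

**Online classification** defaults to *truncated refit*: one model per
hour k, fit on hours 1..k of the training trajectories, because hourly
quality estimates are naturally hour-specific. A *zero-deviation fill*
variant (scale the partial batch with the full-length model and treat
unseen hours as sitting on the training mean) is selectable.

## Cross-validation

Case resampling: per run, 5 fresh and 5 WI training batches are drawn with
replacement, capped at 2 occurrences of any batch within one training set
(a without-replacement mode exists); the test set is every batch never
drawn in that run, so test counts vary by draw rather than being fixed.
Offline CV fits one full-trajectory model per run; online CV fits the
hourly models and classifies every test batch at every hour. Confusion
counts accumulate per hour and pool over runs; sensitivity =
WI-called-WI / WI tested, specificity = fresh-called-fresh / fresh tested.
Runs whose fits fail are recorded and skipped, not silently dropped; runs
with empty test sets are skipped with a warning. Everything is
deterministic given the seed.

## The synthetic generator

The generator supplies study-shaped data with the statistical features the
method assumes; defaults are the study conditions used throughout the
tests.

* **Design**: 10 fresh + 6 warm-ischemic batches, 25 metabolites, 6 hours
  (the post-outlier-screen design of the motivating study).
* **Fresh batches**: x_jk = a_j + b_j·k + Σ_r t_r·L_r(j,k) + ε, with
  linear mean trajectories (levels ~5, drifts ~±0.3 per hour, arbitrary
  concentration units — all analysis is scale-free after column scaling;
  levels sit far from zero so negative values are genuinely anomalous),
  three latent metabolic factors with smooth deterministic sinusoidal
  loading surfaces (scale 0.4) shared across all columns — these create
  the cross-metabolite, cross-time correlation — and iid noise
  (sd 0.30 per column). With these values the latent factors carry ~73%
  of each column's variance, so three principal components capture the
  dominant share (above 65%) without the within-class variability
  swamping everything else.
* **Warm-ischemic batches**: fresh-style draws plus a deterministic
  additive injury surface expressed in units of the fresh per-column sd
  (scale-free effect sizes). The named profiles encode the injury
  phenotype — albumin below fresh at every hour; ornithine below at 1 h
  then strongly above from 2 h; arginine declining mid-perfusion with its
  minimum at 4 h; tyrosine rising late; lactate surging in hour 1;
  glutamate/glutamine shifts — and every other metabolite carries a
  smooth drift of 1.7 sd, the network-wide shadow of the injury:
  individually around the detection threshold, collectively what makes
  whole-profile classification nearly error-free, mirroring the premise
  that ischemia perturbs an integrated metabolic network rather than a
  few isolated assays.
* **Anomalies**: negative-cell corruption and whole-batch shifts (in
  dataset-sd units) for testing repair and outlier screening.

What the generator does **not** emulate: real assay noise structure
(heteroscedastic, occasionally censored), nonlinear saturation of
trajectories, inter-animal covariates, or any pharmacokinetics; and WI
livers here share the fresh factor model rather than showing the
decreasing liver-to-liver variability real ischemic grafts display late in
perfusion. Green tests therefore certify the statistical machinery and
its behaviour under the assumed structure, not performance on real
perfusion data.

## Numerical choices

* Rank and degeneracy: singular values below max(I, JK)·eps·s₁ count as
  zero; identical training batches raise a degenerate-data error; R above
  the rank is rejected.
* Limits/flags need ≥ 4 (limits) or ≥ 3 (reference) training batches.
* Ties: quality exactly 0.5 → warm-ischemic; loading/weight signs fixed by
  the largest-magnitude entry.
* CSV round trips write floats at full precision (`%.17g`) and read with
  round-trip parsing, so file → memory → file is lossless.
* Model files are versioned JSON; arrays are stored as nested lists.

## Problem sizes in the shipped checks

The end-to-end statistical tests run the study design at its native size
(10 + 6 batches, 100 CV runs) and use 200-batch training / 2000-batch
evaluation sets for limit calibration, averaged over three replicates to
suppress the Monte-Carlo noise of a single 200-sample limit estimate;
single-fault diagnosis uses 100 replicates on a 200-batch model. These
sizes keep the full suite and the acceptance script in the seconds-to-a-
minute range on one CPU.
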