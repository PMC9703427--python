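# Methods

## Problem and approach

`statecast` studies a question from early-warning monitoring in intensive
care: given a patient's multivariate bedside signals on a regular time grid
and a binary circulatory-failure state s_t ∈ {0, 1}, how well can the state
be forecast *gap* grid steps ahead, and does re-expressing the response as a
**transition class** improve the forecast?

The transition encoding classifies each consecutive state pair:

| code | pair (s_t, s_{t+1}) | meaning |
|------|---------------------|-----------------|
| 0 | (0, 0) | stay stable |
| 1 | (1, 0) | recovery |
| 2 | (0, 1) | onset |
| 3 | (1, 1) | stay in failure |

The encoded sequence s*_t has length T − 1 (the final observation has no
successor, so its transition is undefined and dropped). Forecasting is done
per individual: features at time t (the K monitored values at t only — no
lag windows) predict either s_{t+gap} (*original* mode) or s*_{t+gap}
(*transformed* mode). Transformed predictions are decoded back to 0/1 so
both modes are evaluated on the same scale.

### Decode convention

A transition class pins down both the current and the next state, so two
decode conventions exist. The default maps classes {1, 3} → 1 (the state
*at* the target index), because the evaluation compares the prediction at
target time t with s_t. The alternative ("next-state", classes {2, 3} → 1)
is available via the `convention` argument but is not used by default.
Similarly, continuous state-1 scores in transformed mode are
P(class 1) + P(class 3); hard labels come from the 4-class argmax followed
by decoding, mirroring the binary practice of thresholded labels for
confusion counts and continuous scores for AUC. Argmax-then-decode and
thresholding the summed score can disagree when no class holds an outright
majority; the argmax route is authoritative for hard labels.

### Supervised design

Per individual: pairs are built by lagging (feature time t, target time
t + gap), split chronologically with the first ⌊0.7·n⌋ pairs for training
("around 70%" is implemented as an exact floor for determinism), and the
remainder for testing. The transformed mode has one fewer usable target, so
the final target index is excluded from the original mode as well; both
modes therefore score identical test time points, which is what makes the
per-individual paired t-tests valid.

Individuals are filtered out if their whole state sequence, or the training
portion of their targets in either mode, contains fewer than two distinct
classes; removal reasons are logged. Residual degenerate cases (e.g. a
single-class test window) yield NaN metrics that are excluded pairwise from
cohort statistics.

### Classifier backends

The three backends are used as libraries behind one contract (deterministic
given a seed; probability outputs; absent transition classes receive
probability exactly 0):

* **logistic** — scikit-learn `LogisticRegression`, unpenalized
  (C = ∞), lbfgs, 1000 iterations, preceded by per-feature
  standardization inside the backend;
* **adaboost** — scikit-learn `AdaBoostClassifier`, 100 depth-1 stumps,
  SAMME multiclass weighting;
* **xgboost** — `XGBClassifier`, 100 trees, depth 6, learning rate 0.3,
  histogram tree method, single thread.

No hyperparameter search is performed; these are recorded defaults, and any
of them can be overridden through `backend_settings`. XGBoost emits float32
probability rows that can miss summing to one by ~1e-7, so the pipeline
renormalizes each row before decoding and scoring.

## Metrics and cohort statistics

Confusion counts follow f(i,j) pair counting with [TP, FP, FN, TN] =
[f(1,1), f(0,1), f(1,0), f(0,0)]; sensitivity, specificity, precision and
F1 follow the standard ratios, with any 0/0 reported as NaN rather than
coerced (coding such cases 0 or 1 would bias cohort means). AUC is the
Mann–Whitney concordance with half credit for ties (equivalently the
trapezoidal area under the empirical ROC curve), undefined for single-class
truth.

Method comparison: per (model, gap, metric ∈ {AUC, F1, sensitivity}), the
mean and SD per mode over individuals and a two-sided **paired** t-test on
per-individual differences d = original − transformed (negative t means the
transformed mode is better). Pairing is the default because both modes are
evaluated on the same individuals and identical test times; an unpaired
Welch option exists. Degenerate tests (< 2 complete pairs, zero difference
variance) are reported as such, not raised.

Subgroup analysis (default: the xgboost/transformed cell): for sex, a
one-way ANOVA of the per-individual metric between groups; for age, weight
and height, a simple linear regression with its overall F-test (equal to
the squared slope t) and fitted slope. For a two-level factor the ANOVA F
equals the squared pooled t, so both analyses are "ANOVA" in the classical
sense. Raw p-values are reported; a Benjamini–Hochberg helper is provided
but off by default. A constant response is defined as F = 0.

## The synthetic cohort

Access-controlled ICU data cannot ship with the package, so a simulator
with the same statistical structure stands in for it everywhere (tests,
acceptance runs, examples). Per individual:

* **State process** — a two-state Markov chain, P(0→1) = `p_onset` = 0.008,
  P(1→0) = `p_recover` = 0.03 per step, started from its stationary law.
  Stationary prevalence is p_onset/(p_onset+p_recover) ≈ 0.21 and mean
  episode length 1/p_recover ≈ 33 steps, so a failure episode outlasts the
  largest forecast horizon (20 steps) — the persistence that makes
  long-horizon forecasting possible at all, as with real decompensation
  episodes spanning hours on a 5-minute grid.
* **Monitored variables** — K = 18 unit-variance Gaussians whose means
  shift by ±`effect_size` (default 2.0 SD) between states, with alternating
  signs (some vitals run high in failure, some low). The last variable is
  binarized by thresholding its latent Gaussian, mimicking a drug-presence
  indicator.
* **Pre-onset drift** — in the `drift_lead` = 25 steps before each onset,
  means ramp linearly toward the failure direction, reaching `drift_size`
  (default 2.0 SD, i.e. exactly the failure-state mean) just before onset.
  This makes imminent onsets visible in the features at every configured
  horizon and is the mechanism by which the transformed response can
  outperform: the 4-class model represents the onset boundary explicitly.
* **Baseline covariates** — sex ~ Bernoulli(0.5), age ~ U[18, 90],
  weight ~ N(75, 15) truncated above 30 kg, height ~ N(170, 10). Age and
  sex multiply the individual's signal strength by
  (1 + 0.3·z_age)(1 + 0.15·1{male}), giving the subgroup analysis a real
  effect to detect without asserting any particular clinical direction.
* **Lengths** — T_n ~ U[150, 400]; the default cohort has N = 100
  individuals, i.e. a few times 10^4 observations. These sizes are the
  package's working scale for simulation studies; all quantities of
  interest (metric means over individuals, t and F statistics) are
  estimated with usable precision at this scale, and everything accepts
  larger values.

All randomness flows from one root seed through named `SeedSequence`
substreams: each individual has its own substream (so an individual is
reproducible regardless of cohort size), and each backend fit derives its
seed from the root seed and the (individual, model, gap, mode) cell.
Cohorts are byte-identical across runs after CSV export.

Degenerate configurations are expressible where scientifically meaningful:
`p_onset = 0` yields the all-stable chain (no onsets), and
`effect_size = drift_size = 0` yields an information-free null cohort used
to verify that the pipeline is unbiased (mean AUC ≈ 0.5 everywhere).

### What the simulator does not emulate

Real monitored variables are autocorrelated within state, heavy-tailed,
cross-correlated, recorded with missingness and imputation artifacts, and
named/united clinically; the simulator's state-conditional Gaussians have
none of these properties. Recovery (1→0) has no precursor drift. Tests
passing on this cohort therefore demonstrate the correctness and internal
consistency of the analysis machinery and the qualitative phenomena built
into the generator (skill decaying with horizon, a transformed-response
advantage at long horizons, baseline-modulated performance) — not clinical
performance on real ICU data.

## Numerical and design notes

* Probability-vector validation tolerance is 1e-9; backend rows are
  renormalized before validation (see above).
* AUC ties receive half credit; this matches the trapezoidal ROC area.
* `train_fraction` splits use floor; both sides must be nonempty.
* Per-individual failures inside an experiment grid (too-short series,
  degenerate training windows, backend errors) are logged and skipped; only
  a grid in which *every* cell fails raises.
* The paired t-test refuses fewer than 2 complete pairs or zero-variance
  differences and reports the reason instead.
* The study orchestrator writes a JSON manifest with SHA-256 digests and
  row counts of every output file; identical config + seed reproduces
  identical digests.

## Known limitations

* One model per individual (as the per-individual formulation implies);
  cohort-pooled modeling is out of scope.
* No probability calibration, cross-validation, or hyperparameter search.
* AdaBoost with depth-1 stumps is a weak 4-class learner; its transformed
  mode trails its original mode at short gaps. This is a property of the
  backend, reported as-is.
* The subgroup analysis is associational; no causal reading is intended.
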