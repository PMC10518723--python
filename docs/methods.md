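# Methods

## Model

The regressor is a first-order Takagi–Sugeno fuzzy system trained as an
ANFIS. Inputs are assumed scaled to [0,1] (the preprocessing module
enforces this for continuous columns; 0/1 indicators pass through).
Each input carries `m` membership functions; grid partitioning
enumerates all `m^d` rules in lexicographic order of their
membership-index tuples. Per rule, the firing strength is the product
t-norm of the selected membership degrees, layer 3 divides by the sum
of strengths (so the output is a convex combination of the per-rule
linear consequents), and layer 5 sums the weighted consequents.

Product t-norm and sum-normalization are the canonical ANFIS choices;
both are differentiable, which the premise gradient requires. A
per-sample min-max rescaling of the firing strengths is available as
`layer3_norm="minmax"` for fidelity experiments, but it makes the rule
weights non-convex and the output no longer a weighted mean, so it is
not the default; in that mode premise gradients fall back to central
finite differences automatically.

### Membership functions

* generalized bell, `μ(x) = 1/(1 + |(x−c)/a|^{2b})`, parameters
  (a width > 0, b slope > 0, c center);
* Gaussian, `μ(x) = exp(−(x−c)²/(2σ²))`, parameters (σ > 0, c).

Initialization tiles [0,1]: centers equally spaced at `k/(m−1)`, bell
width `a` equal to the center spacing with slope `b = 2`, Gaussian σ at
half the spacing so neighbouring functions cross near degree 0.6. Any
fixed scheme works; this one keeps every point of [0,1] covered with
substantial overlap, which protects the product t-norm from underflow.

### Hybrid learning

Each epoch: (1) solve the consequent coefficients by linear least
squares on the design matrix whose row `i` concatenates, per rule,
`w̄_ir · [x_i, 1]`; (2) record the training MSE; (3) take one
gradient-descent step on the premise parameters with the consequent
frozen. The least-squares solve uses `numpy.linalg.lstsq`
(minimum-norm pseudo-inverse), so rank-deficient systems — including
the zero columns produced by masked rules — are well-defined and masked
rules get exactly-zero coefficients.

Premise gradients are analytic by default (chain rule through the
normalized firing strengths; derivatives of both membership kinds in
closed form) and are cross-checked against central finite differences
in the tests. Defaults: learning rate 0.01, halved whenever the
recorded training MSE rises (`adaptive_lr`), 150 epochs, widths/slopes
floored at 1e−3 to keep membership functions valid. The epoch budget
follows the published protocol; the original training tool's learning
rate schedule is not public, so exact loss-curve replication is not
attempted.

## Rule selection by binary PSO

Grid partitioning generates every rule, relevant or not. The selector
selects a binary mask over rule firing strengths — the mask is applied
*before* layer-3 normalization so de-selected rules consume no weight —
and scores a mask by the training MSE after re-solving the consequent
under it with the premise frozen. Each fitness evaluation is therefore
one closed-form solve, which is what makes the search affordable.
Freezing the premise during the search (and not re-running hybrid
training after mask adoption) is one consistent reading of the
published protocol and the one compatible with its reported training
time reduction; joint premise re-optimization per candidate mask would
be combinatorially expensive.

Swarm defaults (all config-exposed; the source publication gives
none): 20 particles, 100 iterations, inertia weight decaying linearly
0.9 → 0.4, cognitive and social factors c1 = c2 = 2, velocity clamp ±6,
early stop after 25 iterations without strict global-best improvement.
r1/r2 are drawn per particle per iteration (the velocity equation
subscripts only the particle), r3 per dimension. Ties keep the
incumbent best, which together with strict improvement makes the
global-best trace non-increasing by construction. The all-zero mask is
an invalid candidate (fitness +∞); the all-ones mask is valid and means
no reduction was achieved.

Because adding a rule adds columns to the least-squares system, the
training-MSE fitness is (weakly) minimized by large masks; in practice
the swarm settles near — but rarely exactly at — the full rule base,
which is why reported selected-rule counts are means over CV folds
(e.g. ~28/32) rather than large reductions.

## Preprocessing

Rows containing any missing value (NaN or empty CSV cell) are dropped
whole; continuous columns are min-max scaled to [0,1]; held-out data is
always transformed with the training portion's constants (the
alternative leaks test statistics into training). Features are kept
when `p ≤ 0.05` **or** `|r| ≥ 0.1` (Pearson r against the target,
two-sided p from the t-statistic on n−2 df). The disjunction is
deliberate: it is the only rule consistent with the published selected
set, which contains a feature significant but weak and a feature
non-significant but of |r| > 0.1. The second-scan infarct volume is
excluded via an explicit exclude-list (it is unavailable at prediction
time, not statistically uninformative), never hard-coded.

Feature selection runs on the full cleaned dataset before
cross-validation, mirroring the published sequence. This is a mild
leakage source (selection sees future test rows); within folds, all
normalization uses training-fold constants only.

## Synthetic cohorts

The real cohort (204 stroke patients, 11 features) is private. The
generator emulates its *structure*: 5 binary indicators, 6 continuous
measurements, a continuous target. With mutually independent features,
the target `z = Σ ρ_j (x_j − μ_j)/σ_j + ε`, `ε ~ N(0, √(1 − Σρ²))`,
has unit variance and population correlation exactly `ρ_j` with feature
j whenever `Σρ_j² < 1`; the published per-feature correlations sum in
squares to ≈ 0.87, so all eleven are representable simultaneously. The
default fixture uses them all, then maps the target affinely to a
plausible growth-rate scale (mean 4, sd 2 cm³/h) — correlations are
affine-invariant. Prevalences (HTN 0.60, DM 0.35, dyslipidemia 0.40,
uncal herniation 0.25, temporal involvement 0.30) and continuous
moments are structural stand-ins chosen once for clinical
plausibility; the cohort publishes neither. The per-cell missing rate
0.013 makes roughly 13% of rows incomplete, matching the cohort's
204 → 177 attrition under whole-row removal.

What the fixture does **not** emulate: feature dependence (real
comorbidities co-occur), non-Gaussian tails, outliers, and any
nonlinearity in the feature–target relationship. Its target is linear
plus Gaussian noise by construction, so a linear regressor is the
Bayes-optimal model family on it; passing tests show the pipeline's
correctness and reproducibility, not that the fuzzy models would beat
baselines on clinical data.

A second generator draws a random 2-input Sugeno system and emits
noiseless targets; hybrid training must recover it (training RMSE
< 0.05 on [0,1]-scaled targets in 150 epochs), which exercises the
full learning loop against a known ground truth.

## Experiment protocol

"80% training / 20% testing with 5-fold cross-validation" is read as
5-fold CV in which each fold's held-out 20% is the test portion — the
two statements coincide under this reading; a fixed 80/20 holdout mode
is available via `holdout=True`. Baselines (linear regression, a
one-hidden-layer network with 10 units, an RBF support-vector
regressor) are scikit-learn estimators consuming the identical
preprocessed folds; they are comparators, not re-implementations.
Per-model failures are isolated: one model failing logs the error and
leaves the others' results intact.

Reports carry per-fold metrics (MSE, MAE, RMSE, cosine distance — all
population-1/n conventions — plus Pearson r and p between predictions
and targets, rule count, wall time) and mean ± population-std
aggregates. Reproducibility is defined over `canonical_json()`, which
excludes wall-clock fields: identical config and seeds give a
byte-identical canonical report; wall times are recorded in the full
report but never asserted anywhere (hardware-dependent).

## Numerical choices

* Minimum-norm `lstsq` for every consequent solve (rank deficiency is
  routine: masked rules, and under-determined systems, see below).
* Membership degrees clipped at 1e−300 only in the gradient's division;
  the forward pass never divides by a membership degree.
* The cosine similarity is the standard `Σŷᵢyᵢ / (‖ŷ‖‖y‖)`; the
  distance is 1 minus it, in [0, 2].
* Targets are min-max scaled with training-fold constants by default
  (`normalize_target=True`), putting the error metrics on the [0,1]
  scale used throughout.
* Derived fold/model seeds are reduced mod 2³¹.

## Known limitations

* **Under-determination at the published cohort size.** Five selected
  features with 2 membership functions give 32 rules × 6 = 192
  consequent coefficients, against ≈ 140 training rows per fold. The
  minimum-norm solve then interpolates the training data, training MSE
  is ~0, and test error is variance-dominated — on the linear synthetic
  cohort the fuzzy models lose badly to the linear baseline (see the
  README example). No regularization is added because the protocol
  specifies the pseudo-inverse solve; users with small cohorts should
  reduce features or membership functions until rows exceed
  coefficients.
* The training-MSE fitness cannot reward parsimony, so rule reduction
  is modest by construction (a complexity penalty would change the
  published protocol and is deliberately not added).
* Grid partitioning is exponential in the feature count; a configurable
  rule cap (default 10 000) fails fast rather than thrash.
* Wall-time comparisons between the conventional and pruned models are
  reported, never tested: they depend on hardware and BLAS.
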