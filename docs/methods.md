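# Methods

## Schedule model

Training runs for `T` optimizer iterations divided into `s` stages. Stage
durations follow a geometric progression `D_i = D₀·λⁱ` with dynamics factor
`λ = 1/γ ≥ 1`; the real-valued first stage is
`D₀ = T(λ−1)/(λˢ−1)` (equal division at λ = 1). Within stage `i` the noise
multiplier is `σ_i = σ₀·β^{-i}` and the clipping threshold `C_i = C₀·aⁱ`.
`T` and `D_i` are counted in optimizer iterations, not epochs — the
accountant charges per sampled batch, so iterations are the
privacy-meaningful unit; `epochs_to_iterations` converts an epoch budget as
`epochs × ⌈N/B⌉`.

Three analytic facts structure the design, and all are property-tested:

- `D_i/σ_i²` (the per-stage Rényi cost proxy) is constant iff `λβ² = 1`,
  i.e. `β = √γ`; with the conservative `β < √γ` the profile strictly
  decreases.
- Requiring `D₀ ≥ ρT` under the geometric progression bounds the stage
  count: `n = ⌊log_λ(1 + (λ−1)/ρ)⌋`. For every λ ∈ (1, 2], ρ ∈ [0.05, 0.9]
  the derived `n` satisfies the constraint on real-valued durations
  (checked on a grid).
- The injected noise power `V_i = (σ_i C_i)²` evolves at exact ratio
  `(a/β)²`: geometric decay whenever `a < β`.

### Conventions for two ambiguities

The stage-count parameter admits two readings, both implemented:

- `stage_convention`: `n_stages` (default) realizes exactly `n` stages;
  `n_plus_1_stages` realizes `n+1`. The default is the self-consistent
  choice: it is the one under which the derived `n` honors `D₀/T ≥ ρ` and
  under which moderate dynamics (λ = 1.1, ρ = 0.3) give the canonical
  three-stage schedule.
- `n_variant`: `floor` (default) vs `floor_minus_1`, the stricter variant
  of the same derivation.

The recurrence "σ_{i+1} = σ_i β" is implemented as division (`σ_i =
σ₀β^{-i}`): the noise multiplier must *grow* for late-stage privacy, and
only that reading is consistent with the closed form. β defaults to γ (the
coupled one-dial setting); `√γ` is the exactly-neutral value and 0.8 the
conservative experimental choice at γ = 0.9.

### Integerization

Real-valued cumulative stage boundaries are rounded half-up and
differenced, which conserves `T` exactly and is deterministic; a
configuration whose integerized stages would be empty raises instead of
silently merging stages. Analytic identities (uniform expenditure, the
`D₀/T` fraction) are checked on real-valued tables
(`build_table(..., integerize=False)`) where they are exact.

## Privacy accounting

Each step adds `N(0, (σ_t C_t)² I)` to a clipped gradient sum of L2
sensitivity `C_t`, so the threshold cancels and the per-step cost is the
Gaussian-mechanism RDP `α/(2σ_t²)`. Costs compose additively (adaptive
sequential composition), and the final curve converts through
`ε = min_α [rdp(α) + ln(1/δ)/(α−1)]` over a default grid of
α ∈ {1.1, 1.2, …, 10.9} ∪ {2, …, 64} ∪ {128, 256}.

The default mode applies **no subsampling amplification** — it is the
conservative reading of the per-step mechanism and never understates ε. An
opt-in `subsampled` mode implements the standard integer-order binomial
upper bound for the Poisson-subsampled Gaussian (exact at order 2, verified
against numerical quadrature of the order-2 divergence); it reduces to the
plain cost at q = 1 and never exceeds it.

`σ = 0` is accepted as an explicit no-privacy debugging limit; the
accountant then reports infinite RDP, which is the true guarantee of a
noiseless release.

Calibration bisects σ₀ over [10⁻², 10⁴] until the achieved ε is within
10⁻³ of the target (or the bracket is below 10⁻⁹) — both tolerances far
below any reported precision. ε is strictly decreasing in σ₀, which makes
the bisection valid; an unreachable target reports the achievable range.

## Training loop

Per-sample gradients are exact (hand-derived backprop, vectorized):
softmax regression (convex; zero initialization) and a one-hidden-layer
tanh MLP (scaled-uniform initialization from the recorded seed). Clipping
is `g·min(1, C_t/‖g‖₂)`; the zero vector passes through.

Noise placement: the accounted-for mechanism adds std-`σ_t C_t` noise to
the clipped **sum**, then divides by the batch divisor (the expected batch
size `B` under Poisson sampling; `B` under fixed-size sampling). The
`literal_mean` convention — same-scale noise on the batch mean — is kept
for fidelity experiments but injects an effectively B-times larger noise
and is not what the ledger certifies. Default sampling is Poisson with
rate `q = B/N` (the rate the accountant uses); fixed-size uniform subsets
are an option. Empty Poisson batches contribute pure noise on the sum.

One seeded generator per run is split into independent streams for
initialization, sampling and noise, so changing the batch size does not
perturb the noise stream; runs are bitwise reproducible from the seed. The
ledger records one entry per stage `(σ_i, q, D_i)` — composition is linear
in counts, so this is identical to per-iteration entries — and always sums
to the executed iteration count. A non-finite loss aborts with the
iteration index.

The static baseline is the same loop with the schedule collapsed to one
constant stage (β = 1, a = 1), which makes the β = 1, a = 1 degenerate
equivalence a bitwise test rather than an approximate one.

## Synthetic data

The generator reproduces the *imbalance structure* of dermoscopy
benchmarks, not their images: class counts from largest-remainder
apportionment (conserves n exactly; proportions recovered within 1/n),
class centroids on a sphere of radius `class_mean_separation` (orthonormal
random directions when K ≤ d, so pairwise centroid distance is
`separation·√2`), isotropic Gaussian features with std `noise_sd`, rows
shuffled — all deterministic in the seed.

Presets: `ham10000_like` (7 classes, dominant 0.67, four classes ≤ 5%,
default n = 10015) and `isic2019_like` (8 classes, dominant 0.51, default
n = 25331). Both are documented approximations of the real per-class
shares; the single dominant class is marked `large_shot`, all others
`few_shot`.

What passing tests on this data do **not** show: anything about
hierarchical feature learning, pretrained-backbone fine-tuning dynamics, or
real image statistics. The synthetic classes are unimodal and isotropic;
the harness demonstrates the *optimizer mechanism* — minority-gradient
preservation under matched privacy — in a controlled setting.

## Evaluation

Metrics are computed from the confusion matrix: accuracy, multiclass MCC in
covariance form (0 by convention when a marginal is degenerate), macro
F1/recall (per-class one-vs-rest, unweighted mean; F1 = 0 for classes with
neither true nor predicted positives), and group accuracy defined as the
unweighted mean of per-class recall within the large-shot and few-shot
groups ("average accuracy on a group" is not otherwise standardized; mean
per-class recall is the reading adopted and documented). Comparison runs
report mean ± sd over seeds; no significance testing.

`run_comparison` calibrates each algorithm's schedule shape to the same
target ε before training, shares the data split across algorithms, and
varies only the schedule and the per-seed randomness.

## Desk-scale defaults and problem sizes

The shipped comparison conditions are: 7-class dataset of n = 3500
(dominant 0.67), d = 10 features, separation 3.0, noise sd 1.0, 80/20
stratified split, softmax regression, T = 2000 iterations, B = 128,
η = 0.05, δ = 10⁻³, ε = 3 via calibration, seeds {1..5}. Schedule
parameters follow the method's experimental values: γ = 0.9, β = 0.8,
a = 0.6, ρ = 0.3, n = 3, with C₀ = 5.0 chosen so the initial threshold
sits just above the maximal softmax-regression per-sample gradient norm
(≈ √2·‖x̃‖ ≈ 4.7 at this feature scale) — the "high initial threshold,
clipping inactive early" regime the schedule is designed around. η = 0.05
was chosen for stable non-private convergence at this scale. The whole
ten-run comparison takes a few seconds on one CPU core.

## Known limitations

- Plain-mode accounting is deliberately conservative; budgets that assume
  subsampling amplification will calibrate to larger σ₀ here.
- The subsampled bound is integer-order only; no privacy-loss-distribution
  or moments accounting, and no conversion tighter than the standard
  RDP→DP lemma.
- In the noise-dominated regime (vanishing ε) the zero-initialized convex
  model degrades to chance-level predictions, not to majority-class
  collapse — symmetric noise gives the bias terms no systematic drift.
- No learning-rate scheduling, no gradient-norm-based automatic clipping,
  no deep architectures or image pipelines.
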