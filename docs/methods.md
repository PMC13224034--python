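# Methods

`dauplift` estimates individual uplift — the difference in expected binary
outcome between a treatment/exposure condition and its comparison condition —
across heterogeneous study populations, and evaluates how well that estimate
transfers to a population never seen with labels. This note documents the
model, the evaluation conventions, the synthetic benchmark, and the numerical
and design choices a maintainer would want to know.

## Model

### Uplift target

For covariates x, binary treatment proxy T and binary outcome proxy Y, the
estimand is the conditional average treatment effect for binary outcomes,

    u(x) = P(Y = 1 | X = x, T = 1) − P(Y = 1 | X = x, T = 0),

approximated plug-in style by two outcome models sharing a representation.
With observational proxies this is a *ranking* target (who appears most
differentially vulnerable), not a certified causal effect: ignorability,
overlap and SUTVA are assumed, not verified.

### Architecture

* **Encoder** f_θ: a two-layer MLP, widths 128 → 64 with ReLU, dropout 0.30
  applied after the first hidden layer only. The 64-unit output is the
  embedding used by every other component.
* **Potential-outcome heads** h₁, h₀: one affine layer plus sigmoid each
  (no hidden layer). û(x) = h₁(f_θ(x)) − h₀(f_θ(x)) ∈ (−1, 1).
* **Domain discriminator** g_φ: one hidden layer of width m = 64 (ReLU) and a
  K-way softmax, attached through a gradient-reversal layer (GRL). The
  discriminator architecture is a design choice — capacity comparable to the
  encoder tail, standard adversarial-alignment practice.
* **GRL contract**: identity forward; in the backward pass the domain-loss
  gradient reaching the encoder is the discriminator-side gradient scaled by
  −λ_D, while the discriminator's own parameters receive the unreversed
  gradient. λ_D = 0 therefore reproduces the non-adapted baseline exactly.

The whole network is implemented in numpy with hand-written forward/backward
passes; every gradient path (uplift loss, fairness penalty, adversarial CE,
conditional-adversarial CE, covariance and kernel alignment) is verified
against central finite differences in the test suite.

### Losses

The composite objective is

    L = L_uplift + λ_D · L_align + λ_F · L_fair.

* **L_uplift**: mean binary cross-entropy between Y and the *exposed* head's
  prediction ŷ_obs = T·ŷ(1) + (1−T)·ŷ(0). The gradient flows only through
  the factually observed head per sample. Probabilities are clamped to
  [1e−7, 1−1e−7] for stability.
* **L_align**, one of five variants sharing the same backbone:
  * `noda` — none (a two-head neural T-learner).
  * `dann` — K-way domain cross-entropy through the GRL.
  * `cdan` — the discriminator consumes [f(x), ŷ(0), ŷ(1)] (plain
    concatenation, not an outer-product map), so the reversed gradient also
    reaches the heads.
  * `coral` — ‖C_s − C_t‖²_F / (4m²) over the sample covariances of the
    source and target embedding batches.
  * `mmd` — squared maximum mean discrepancy, Gaussian kernel, biased
    V-statistic. The bandwidth is the median pairwise distance over the
    joint batch (fallback 1.0 when all distances are zero) and is treated
    as a constant in the gradient, as is standard for the median heuristic.
* **L_fair**: squared group-mean uplift parity,
  (ū_{G=0} − ū_{G=1})² + (ū_{E=0} − ū_{E=1})², over gender and education
  masks. A term is evaluated only when both cells of that attribute are
  non-empty in the evaluation scope. Default scope is *epoch-level*: after
  each epoch a deterministic full-pass gradient step is taken on λ_F·L_fair;
  batch scope is selectable. The training penalty uses all in-scope samples;
  the diagnostic *report* restricts to treated subsets (the metric, not the
  regularizer, carries that restriction).

### Training protocol

Adam (torch-style L2-in-gradient weight decay), defaults lr 3e−4 and weight
decay 5e−5 (midpoints of the documented search ranges: lr 1e−4–5e−4
log-uniform, λ_D 0.1–0.8, λ_F 1–15, weight decay 1e−5–1e−4). Batch size 64,
40 epochs, patience 10 — declared defaults, since the protocol leaves them
open. Early stopping monitors validation AUUC on a 20% split of the pooled
source rows, stratified jointly on (T, source domain), and restores the best
parameters.

λ_D follows a schedule in training progress p = epoch / epochs:
fixed → λ_max; linear → λ_max·p; sigmoid → λ_max·(2/(1+e^{−γp}) − 1) with
γ = 10 (the classical ramp; 0 at p = 0, ≈λ_max at p = 1). Progress is the
completed-epoch fraction, chosen over batch fraction for simpler logging and
testing.

Gradients are clipped at norm 1.0 **per parameter group** (encoder+heads
vs. discriminator). A single global norm would let the discriminator's
gradient magnitude perturb the uplift-path update even at λ_D = 0, breaking
the exact NoDA ≡ DANN(λ_D = 0) trajectory equivalence; per-group clipping
preserves it, and the equivalence is asserted bit-exactly in the tests.
Determinism: batch order, dropout masks (separate streams for source and
target passes) and the validation split all derive from the run seed, so two
runs with the same config and data are identical.

When an alignment method is selected but no unlabeled target is supplied,
CORAL/MMD align the first two source domains present in each batch, and the
adversarial variants discriminate among the source domains. With a target,
the discriminator sees K = (#source domains) + 1 classes — the unlabeled
target's domain identity is known even though its outcomes are not.

## Harmonization

Per-cohort tables are merged by: lowercasing column names → deriving binary
proxies → exclusions → impute → one-hot encode → z-score (the order is a
package convention). Numeric columns are imputed with the median and
categorical with the mode; columns absent in a cohort are *missing-by-design*
and filled with the fit-set median; categorical levels are learned on the fit
rows (unseen levels become all-zero rows with a warning); zero-variance
columns are centered only. All statistics are computed over a caller-chosen
`fit_on` set of domains. The leakage-safe choice is the training domains
only; passing every domain reproduces pooled preprocessing, which is simpler
but lets held-out rows influence the transform.

Proxy conventions: exhaustion-based treatment uses the linear-interpolation
empirical 75th-percentile threshold with at-or-above ties mapping to T = 1;
depression outcome uses score ≥ 10; the three-level stress item maps
yes/maybe → 1, no → 0 (applied to the raw responses, before any imputation);
diagnosis-based proxies use category membership. The education mask is
E = 1 iff years ≥ 12; when education is missing-by-design the bin comes from
the imputed median and is flagged unreliable in `feature_meta`. Non-binary
gender codes are excluded from the medical-style cohort only (the binary
fairness mask requires it); the exclusion never changes the column set.

Diagnostic-label columns in a psychiatric-style cohort are *retained* as
one-hot features by default — this reproduces the leakage failure mode that
the audit is designed to catch — with `drop_proxy_sources=True` to remove
them. The 2×2 proxy audit reports counts, Prev(T), Prev(Y) and the
conditional outcome probabilities (undefined, not 0, on an empty margin;
display rounding is half-even to 3 decimals), and flags mutual exclusivity
when the (T=1, Y=1) cell is zero while both margins are occupied.

## Evaluation

### Uplift curve and AUUC

Samples are ranked by û descending (stable sort; ties break by original
index). For each targeting fraction f ∈ {0.1, …, 1.0} the prefix is the top
⌈f·n⌉ samples (computed in exact integer arithmetic to avoid float boundary
artifacts), and NetUplift(f) is the treated-mean minus control-mean outcome
within the prefix, defined as 0 when either arm is empty (keeping AUUC
finite on low-prevalence folds). The random baseline is the overall ATE.

**AUUC scale**: trapezoidal area of NetUplift(f) − ATE over the ten
fractions, divided by the 0.1 step — i.e. summed per-bin excess uplift. On
binary outcomes this ranges over roughly ±9, matching the magnitude regime
of multi-unit AUUC values reported in cross-cohort uplift work; it is *not*
a [0,1]-normalized area, and only signs and orderings should be compared
against AUUC values computed under other conventions.

### Protocols and statistics

LODO holds out each domain in turn, trains on the rest (held-out features
passed unlabeled to adapting methods), and scores AUUC, treated-subset
fairness gaps and the proxy audit on the held-out domain, aggregated over
seeds × folds with mean, sample sd, se = sd/√n and a 1.96·se 95% CI
half-width. Single-source transfer trains on one labeled domain.

Paired method comparisons over matched seed × fold runs report the median
difference, a percentile-bootstrap 95% CI of the median (1,000 seeded
resamples of pairs), a two-sided Wilcoxon signed-rank test (exact null for
n ≤ 25, zero differences dropped; all-zero differences reported as p = 1
with a degenerate-data flag) and Cliff's δ over all cross-pairs. No
multiple-comparison correction is applied; comparisons are exploratory.

## Synthetic benchmark

The generator emulates the three-cohort structure: per domain k, features are
Gaussian with mean k·shift (default 0.3, a moderate shift) and scale 1; a
per-domain block of columns (default 15%) is zeroed and flagged
missing-by-design; treatment is Bernoulli with the study prevalences
(0.300, 0.689, 0.171) at the study sizes (881, 824, 919) by default, and is
independent of x unless the optional confounding tilt is enabled. The
response surface is

    p_t(x) = σ(β·x + t · a · tanh(w·x)),   u*(x) = p₁(x) − p₀(x),

with β, w drawn once per seed from a standard Gaussian and scaled to unit
norm, and amplitude a = 0.6 by default. Bernoulli sampling is the only
noise; u* is exact and computed from the observed (post-zeroing) features so
the injected effect is identifiable from what a model sees. The benchmark
emulates distribution shift, missing-by-design blocks and proxy prevalences;
it does **not** emulate real psychometric item structure, label-shift or
concept-shift, so passing it shows the pipeline behaves correctly under its
own assumptions, not that real-data effects are recovered.

The recovery experiment scores per-fold CATE RMSE of the LODO-trained model
against two reference predictors, û ≡ 0 and û ≡ training ATE. A caveat
established empirically with this package's own oracles: at the
small-benchmark scale (900 samples total, amplitude 0.6), sd(u*) ≈ 0.07
while the error floor of *any* estimator of this surface from ~480 Bernoulli
training outcomes — including a regularized maximum-likelihood fit of the
true functional form — is ≈ 0.09–0.13, so the zero predictor is statistically
unbeatable there; the references become beatable as n grows or the injected
amplitude rises, and the network does extract the signal at the full study
sizes (rank correlation with u* up to ≈ 0.35).

The leakage scenario makes the last domain's treatment and outcome mutually
exclusive classes of one categorical diagnosis variable that is also one-hot
encoded into X (all-zero in the clean domains, like any missing-by-design
block). Class prevalences match the audited cross-tabulation (outcome class
28.5%, treatment class 17.1%). The outcome class is assigned to the
highest-u* individuals and the treatment class to the next band: clinically,
the "already deteriorated" diagnosis attaches to the most vulnerable
profiles. A model that learned the clean domains' effect surface therefore
ranks outcome-class controls at the top, measures negative net uplift, and
produces the characteristic below-baseline uplift curve — while the audit
flags the empty joint cell before any training.

## Degenerate inputs and numerical conventions

* BCE clamp 1e−7; softmax computed with max-shift; sigmoid evaluated
  branch-wise to avoid overflow.
* Uplift curves require n ≥ 10 and both arms overall; empty-arm prefixes
  contribute 0.
* CORAL requires ≥ 2 rows per side (sample covariance); MMD requires
  non-empty sides and falls back to bandwidth 1.0 on all-zero distances.
* Zero-variance columns are centered, not scaled; conditional probabilities
  on empty margins are undefined, never 0.
* Fairness terms with an empty subgroup cell contribute 0 to the penalty and
  are reported as undefined in the diagnostic.
* Checkpoints are a `.npz` parameter archive plus a JSON config sidecar and
  round-trip bit-exactly.

## Known limitations

* CPU-only numpy training; fine for tabular cohorts of this size, not for
  large-scale or deep encoders.
* The fairness penalty is first-order group-mean parity; intersectional and
  allocation-level fairness are out of scope.
* Adversarial training is run with a single optimizer pass per batch (no
  alternating inner discriminator steps); stabilizers such as spectral
  normalization or Wasserstein critics are out of scope.
* The AUUC convention is package-specific (documented above); cross-paper
  numeric comparison of AUUC magnitudes is not meaningful.
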