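# Methods

This note documents the models, defaults and design choices behind `cuehgf`,
and what the synthetic-data checks do and do not establish.

## Task model

The task is a centrally presented motor-cueing paradigm. Each trial shows a
400 ms cue indicating the probable response hand, then — after a stimulus
onset asynchrony jittered uniformly on 1000–1288 ms — a 400 ms target shape
requiring a left- or right-hand press; the inter-trial interval is jittered
on 2012–2300 ms. A cue is *valid* when the required hand matches the cued
hand. Cue predictability (the proportion of valid cues) is constant within a
block and switches between blocks among ≈50/70/90 %.

The canonical main task is 6 blocks of 48/46/48/46/48/48 trials at
p = 0.5/0.9/0.7/0.9/0.5/0.7 (284 trials total); block lengths and order are
a package choice — multiple switches are required for volatility inference
to be identifiable — and are fully configurable. Validity is allocated by
**exact count** (round-half-up of p·length, order shuffled by the seed)
rather than Bernoulli draws, so realized contingencies are controlled and
every per-block count is testable. The practice block is 54 trials at a
constant 80 % (43 valid). The target-shape→hand mapping (default
square→right) is a configuration flag; the mid-task self-timed break has no
computational consequence and is not modelled.

## Perceptual model (3-level binary HGF)

States: x₁(t) ∈ {0,1} is trial validity; P(x₁=1) = s(x₂); x₂ and x₃ follow
Gaussian random walks with step variances exp(κx₃ + ω₂) and exp(ω₃).
Variational inversion under a mean-field approximation yields the standard
one-step update equations (precision-weighted prediction errors) implemented
in `hgf.hgf_filter`; the trial-wise prediction μ̂₁(t) = s(μ₂(t−1)) is the
"model-derived cue predictability" regressor used downstream.

Defaults: κ = 1 (the usual binary-HGF convention; the coupling is not
separately identifiable from ω₂ here), initial beliefs μ₂=0, σ₂=1, μ₃=1,
σ₃=1. Non-positive posterior precisions raise a `ModelDivergence` error
rather than propagating NaNs — parameter regions that drive the filter
unstable (e.g. ω₂ ≳ −1 on this sequence) are treated as implausible, and the
cohort generator rejection-samples subject parameters until the filter is
stable on the task sequence.

## Response model and estimation

RS = 1/RT (units 1/s, keeping ζ's O(1)). RS is linear in μ̂₁ with separate
intercept/slope per validity branch, plus Gaussian residual noise on the RS
scale. Estimation is **MAP**: Gaussian likelihood over correct, non-missed
trials (belief updates still run on all trials, because the cue–target
contingency is observed regardless of the response), Gaussian priors on the
unconstrained scale — ω₂ ~ N(−3,16), ω₃ ~ N(−6,16), ζ ~ N(0,100),
log σ² ~ N(−2,16) — and seeded multi-start L-BFGS-B (5 restarts, gradient
tolerance 1e−6, box bounds keeping the exp transforms finite). Restart 1
starts at the prior means with intercepts moved to the observed mean RS;
later restarts perturb by unit Gaussian noise. MAP over these priors is a
deterministic, fully specifiable surrogate for variational toolbox
inversion; posterior variances are not produced (a stated non-goal).

Parameter recovery at the defaults (284 trials, residual RS sd 0.35 — about
the trial-to-trial RT variability of a 60–70 ms spread at RT ≈ 0.4 s):
Spearman true-vs-recovered ρ ≈ 0.87 (ω₂), 0.95 (ζ₂ᵥ), 0.89 (ζ₂ᵢ) over 60
agents drawn from ω₂ ∈ (−5,−1.5), ω₃ ∈ (−8,−4), ζ₁ ∈ (1.5,3), ζ₂ ∈ (0.5,2).
ω₃ is essentially unrecoverable from a single 284-trial session (ρ ≈ 0.02);
it is reported but never gated — a known identifiability limit of
volatility parameters at this scale.

## Synthetic cohort and ERP forward model

Two groups (control-like, TS-like), n = 30 each by default, all sharing the
canonical sequence. Subject parameters are Gaussian draws; TS-like subjects
default to attenuated response slopes (ζ₂ᵥ: 0.4 ± 0.3 vs 1.0 ± 0.3; ζ₂ᵢ:
0.3 ± 0.3 vs 0.8 ± 0.3), which removes most of the validity × predictability
RT interaction while preserving the basic cueing effect. Clinical scores are
Gaussian draws truncated at 0 with group means/SDs in the style of standard
tic/urge/comorbidity instruments.

ERP epochs are produced by a deliberately **minimal forward model** — the
emulated study reports effect directions, not a generative EEG model:

- P3a: Gaussian kernel, peak 358 ms, width 45 ms, channel weights peaking at
  FCz; single-trial amplitude a₀ + a_v·V + a_p·μ̂₁ + a_int·V·μ̂₁ (0/1
  validity coding). Control default a_v = −1.5 µV (invalid > valid),
  a_p = +2 µV; TS-like a_v = −0.3 µV.
- P3b: sigmoid rise (τ = 25 ms) times a Gaussian decay envelope (centre
  500 ms, width 180 ms), weights peaking at CPz; amplitude coefficients
  a₀ = 5, a_v = −2, belief coefficient −2 µV for control-like and **0 for
  TS-like** (the injected group difference); onset shifts −20 ms·V −
  30 ms·V·μ̂₁ so that onset effects express in the 200–300 ms window.
- Noise: white Gaussian, sd 15 µV per channel/sample (optional 1/f shaping
  flag). Window averaging makes the regression stage insensitive to noise
  colour, which is why white noise is the default.

Epochs default to 500 Hz; the replicated power/type-I suites run at 125 Hz
(501 → 126 samples), a resolution choice that leaves window-averaged betas
essentially unchanged while making 100-cohort replications tractable.

What the synthetic cohort does **not** emulate: continuous EEG, realistic
topographies or volume conduction, tic/EMG artefacts, non-Gaussian RT
tails, medication or comorbidity structure. Passing power/recovery checks
therefore demonstrates that the *pipeline* detects effects of the injected
size under idealized noise — not that such effects exist in real data.

## Epoch processing and single-trial GLM

Baseline: per trial and channel, the mean over −200–0 ms pre-target is
subtracted (the synthetic container cannot reach the pre-cue interval; a
config option accepts cue-locked containers with any in-span baseline).
Joint-probability rejection fits a Gaussian per channel/sample across
epochs, scores each epoch by its mean negative log-density and flags scores
above mean + 5 SD — a deterministic Gaussian surrogate for toolbox
kernel-density rejection. The P3a window defaults to the fixed 318–398 ms;
optionally the pipeline recomputes the grand-average FCz peak (search
250–450 ms, ties to the earliest sample) and centres ±40 ms.

The GLM regresses single-trial voltage at one electrode on intercept,
validity coded ±0.5 (valid = +0.5), belief centred per subject, and their
product, by OLS independently at each time point; only correct, non-missed,
non-rejected trials enter. The ±0.5/centred coding keeps main effects and
interaction near-orthogonal; `erp.convert_coefficients` gives the exact
linear map from the forward model's 0/1 coding, and with zero noise the
window-averaged betas reproduce the injected coefficients to < 1e−6
(verified in the tests).

## Group statistics

Two-sample t-tests are pooled-variance (Student), consistent with df = 58
for two groups of 30; `t_from_summary` computes the same statistic from
printed means/SDs/ns. The mixed ANOVA decomposes the balanced
2 × 2 × 3 design with separate error strata per within effect
(effect × subject-within-group); partial η² = SS_effect/(SS_effect +
SS_error-stratum). For within effects involving the 3-level predictability
factor, Greenhouse–Geisser ε is computed from the pooled within-group
covariance of orthonormal contrast scores and applied (to both dfs) when
Mauchly's test rejects at α = .05 (switchable to always/never). Spearman
correlations use midranks with the t-approximation p-value (adequate at
n = 30–60). No multiple-comparison correction is applied across windows or
scales — mirrored from the emulated analysis and documented here.

Numerical details: sums of squares below 10·eps·‖Y‖² are squashed to zero so
constant data yields F = 0 exactly; zero-variance t-tests report p = 1 for
zero mean difference and p < machine-min otherwise; grand-average peak ties
break to the earliest sample; rank-deficient GLM designs raise an error
naming the collinear column(s).

## Pipeline determinism and problem sizes

All randomness derives from one master seed through `numpy` `SeedSequence`
spawning (cohort → group → subject → parameter/behaviour streams; epoch
noise on a parallel keyed stream), so every stage can be rerun in isolation
and complete reruns are byte-identical. Every artifact embeds the seed and a
config hash.

Validation suite sizes (chosen as the package's standard operating points):
parameter recovery, 60 agents; power and type-I, 100 replicate cohorts of
n = 30/group at 125 Hz. Measured at these sizes: power for the injected
P3b-amplitude belief group difference ≈ 1.00 (criterion ≥ 0.80 at α = .05);
all null rejection rates within α + 2 Monte-Carlo SEs.

## Known limitations

- MAP point estimates only; no posterior uncertainty or model comparison.
- ω₃ is not identifiable from one session; group tests on ω₃ are reported
  but carry little information at this scale.
- The ERP forward model is phenomenological; its effect sizes are calibrated
  to the power property above, not to any empirical voltage scale.
- The mixed ANOVA supports balanced designs only (equal group sizes, no
  missing cells); unbalanced data raise an explicit error.
- Joint-probability rejection is a Gaussian surrogate and will under-flag
  heavy-tailed artefacts relative to kernel-density implementations.
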