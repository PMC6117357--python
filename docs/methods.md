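# Methods

## The scientific problem

Two well-documented optimality principles shape human time estimation.
First, when one event produces both an auditory and a visual signal, the
two duration estimates are combined by reliability weighting (maximum
likelihood estimation, MLE), which yields a multisensory estimate with
lower variance than either input.  Second, duration estimates are pulled
toward the mean of recently presented durations — the *central tendency* —
which Bayesian observer models explain as integration of the sensory
likelihood with a prior learned from the stimulus distribution.  This
package implements the analysis pipeline for asking how the two stages
interact: does the prior act within each modality before cue combination,
or once, after the multisensory estimate is formed?

## Observer model

All internal representations are Gaussian.  For a stimulus duration `D`:

- **Likelihood**: `N(D, σ_L²)` with `σ_L = WF · D` (scalar timing: noise
  proportional to duration; `WF` is the Weber fraction of the condition).
- **Prior**: `N(μ_P, σ_P²)` with `μ_P` the mean presented duration `D̄`
  (the observer is assumed to have learned the stimulus distribution).
- **Posterior mean**: `μ_R = μ_L − σ_L²·(μ_L − μ_P)/(σ_P² + σ_L²)`, the
  precision-weighted average.  Regressing estimates on durations at a
  single likelihood width gives the central-tendency slope
  `CT = σ_P²/(σ_P² + σ_L²)`; slope 1 is veridical, smaller slopes mean
  stronger pull toward the mean.
- **Cue combination**: `S_AV = w_A S_A + w_V S_V` with
  `w_A = σ_A⁻²/(σ_A⁻² + σ_V⁻²)`; combined precision is the sum of the
  unisensory precisions, so in Weber-fraction terms
  `WF_AV = √(WF_V²WF_A²/(WF_V² + WF_A²)) ≤ min(WF_V, WF_A)`.

The two architectures differ only in the order of operations:

- **Model 1 (prior first)**: each modality's likelihood is shrunk toward
  its own prior; the two posteriors are MLE-combined, with weights set by
  the *posterior* widths (the quantities actually being combined at that
  stage).
- **Model 2 (combination first)**: the raw unisensory likelihoods are
  MLE-combined; the combined likelihood (width `WF_AV · D`) is shrunk once
  toward a single prior whose width is the average of the two unisensory
  prior widths.  The average — rather than an MLE combination of priors —
  reflects the assumption that the prior lives at a processing stage after
  multisensory integration, not that two priors are integrated as cues.

Because the combined likelihood is narrower than either unisensory
likelihood, model 2's predicted slope is ≥ model 1's for every matched
parameter set with a common prior width (each per-duration mean is shrunk
by a factor that is monotone in the likelihood width); the package
verifies this ordering over an exhaustive grid rather than assuming it.

### Slope predictions with duration-dependent likelihood width

`σ_L = WF · D` varies across levels, so the pull toward the mean is
stronger for longer durations and the exact expected regression slope is
*not* `CT` evaluated at one effective duration.  Both architecture
predictors therefore compute per-duration posterior means and regress them
on the durations (`expected_reproduction_slope` is the unisensory version
of the same computation).  For the default design this exact slope is
≈ 0.800 at `WF = 0.17, σ_P = 238 ms`, whereas the single-width formula at
the arithmetic mean duration gives 0.821 — a 0.02 discrepancy that is
resolvable at the simulated trial counts, which is why the generator/theory
agreement checks use the per-duration regression oracle.  An
`effective_duration_ms` option evaluates the single-width convention
instead, and `estimate_prior_width` deliberately inverts the single-width
formula at `σ_L = WF · D̄` because that is how prior widths are recovered
from one observed (CT, WF) pair in practice; the same-convention round trip
is exact, while recovery from simulated data carries a small (~5–7%)
downward bias inherited from the duration-dependent width.  `D̄` is the
arithmetic mean of the presented levels by default (geometric by flag).

## Experimental design emulated by the generator

- Discrimination: 640 ms standard, comparisons log-spaced over 450–900 ms,
  24 repetitions per comparison; binary "comparison longer" responses.
- Reproduction: stimuli log-spaced over 450–900 ms, 60 repetitions per
  level.
- Conditions: visual, auditory, audiovisual; external noise labeled
  high/low/no per modality, with three audiovisual combinations
  (high,high), (high,low), (low,high).
- The number of levels per task is a design convention: 7 log-spaced
  levels spanning the printed 2:1 range (configurable).

Noise levels enter only as condition labels mapped to Weber fractions.
Defaults: `WF` = 0.13/0.17/0.25 for no/low/high noise in both modalities —
noise degrades sensitivity monotonically and the modalities are matched,
consistent with the absence of a reliable modality difference in empty-
interval discrimination; prior widths 177 ms (visual) and 282 ms
(auditory), so visual timing leans more on the prior.  Audiovisual Weber
fractions default to the optimal combination of the unisensory ones; the
audiovisual prior width defaults to the average of the two.  Motor noise
defaults to 0 (the architecture models contain none); a multiplicative
coefficient-of-variation term is available for robustness studies.
Non-positive reproductions are redrawn; at these parameters the truncation
probability is negligible, so no measurable bias is introduced.

Discrimination responses are drawn, by default, directly from the analysis
model: `P(longer) = Φ((D_c − D_s)/(WF · D_s))`, so the fitted psychometric
function recovers `WF` by construction ("psychometric mode").  An
"estimate mode" draws two noisy interval estimates (per-interval width
scaled by 1/√2) and compares them, for studies of the two-interval noise
decomposition the fitting model ignores.

What the generator does *not* emulate: sequential/order effects, feedback
learning, practice, lapses, the overall modality-dependent reproduction
bias (visual overestimation), and any non-Gaussian internal scale.
Passing tests therefore certify the pipeline's statistical machinery and
internal consistency under the stated generative model — not that real
observers obey it.

## Fitting

- **Psychometric fits** maximize the Bernoulli likelihood of
  `Φ((D_c − PSE)/σ)` with Nelder–Mead from moment-based multi-starts
  (PSE from the 50% crossing, σ from the 25–75% span); free PSE by
  default, optional fixed PSE and fixed lapse rate.  All-identical
  responses raise a degenerate-data error; an optimizer stall returns
  best-effort estimates flagged `converged=False`.  The Weber fraction is
  `σ/standard`; the JND is identified with `σ`.  At the design's trial
  counts (7 × 24) the maximum-likelihood `WF` estimate carries ~9–10%
  median absolute error (the 450–900 ms range leaves few informative
  levels when `WF ≤ 0.10`), with a small (~4%) downward bias.
- **Central tendency** is ordinary least squares of reproduced on stimulus
  duration over pooled trials, after a single-pass exclusion of trials
  more than 3 SDs from their cell mean.  Cells are condition × stimulus
  level by default (the reading that does not conflate level means); a
  per-condition-only mode is available.  Zero-variance cells exclude
  nothing.  OLS (not orthogonal) regression matches the directional
  question "how far do reproductions track stimuli".
- **Prior widths** come from `σ_P = σ_L·√(CT/(1−CT))`, `σ_L = WF·D̄`.
  Slopes ≥ 1 (possible under sampling noise) identify no finite width; the
  pipeline clips them to 0.995 before inversion and the low-level function
  raises instead.

## Statistics

Paired contrasts (audiovisual vs the better unisensory value per noise
combination) use a seeded bootstrap: subject × condition pairs are
resampled with replacement (10,000 replicates by default), with a
two-sided percentile p-value (+1 continuity correction) and Bonferroni
correction across the three combinations.  Cohen's d is
`mean(diff)/sd(diff)`.  With 21 pairs the percentile scheme is mildly
anticonservative (simulated type-I error ≈ 0.065–0.07 at α = 0.05); a
studentized bootstrap would be better calibrated but the simpler percentile
scheme is kept as the documented design choice.  Architecture predictions
are evaluated by paired t tests of predicted vs measured audiovisual
slopes and by OLS of measured on predicted with a 95% confidence band;
model selection uses mean |predicted − measured| central tendency.

## Pipeline and problem sizes

A run simulates a cohort (default 7 virtual subjects; per-subject
parameters jittered log-normally with SD 0.1 around the base values),
fits both tasks, inverts prior widths, predicts the audiovisual central
tendency under both architectures, and writes CSV tables, a JSON stats
report, and a markdown summary.  Identical configurations reproduce
byte-identical CSVs; every random stream is derived from the single
configuration seed, task, condition and subject indices.

Replicate studies use sizes chosen to make their Monte-Carlo error small
relative to the effects under test: 200 datasets for Weber-fraction
recovery (7 × 24 trials each), 200 replicates at 7 × 600 trials for
prior-width recovery, 41 replicates per cell for generator/theory slope
agreement, 100 three-subject cohorts per architecture for selection
self-consistency, and 2000 simulated null experiments for bootstrap
calibration.

## Known limitations

- The prior-width inversion uses a single effective likelihood width while
  the generator's width is duration-dependent; recovered widths are
  systematically ~5–7% low at the default parameters (well inside the 15%
  recovery tolerance, but visible in cohort tables).
- A pure central tendency with duration-dependent noise moves the grand
  mean slightly (≈ −10 ms at default parameters), so small negative
  overall biases in simulated tables are expected and are not a bug.
- The percentile bootstrap's type-I error sits near 0.07 at 21 pairs.
- Model 1's MLE weights use posterior widths; with equal prior widths the
  ordering result is provable, and with unequal widths it is verified
  numerically over grids, not by theorem.
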