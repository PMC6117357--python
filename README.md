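# bayestime

Bayesian-observer simulation and analysis of multisensory time estimation.

Human duration estimates show two signatures of statistically optimal
inference: multisensory signals are combined by reliability weighting
(maximum-likelihood cue combination), and estimates regress toward the
mean of recently presented durations (the *central tendency*, the Bayesian
footprint of a learned prior).  This package is an analysis pipeline for
psychophysicists studying how those two stages interact.  It simulates
ideal-observer duration discrimination and reproduction experiments,
recovers timing sensitivity (Weber fraction, WF) and central tendency
(regression slope, CT) from trial tables, and compares two hierarchical
architectures:

- **Model 1 — prior first**: each modality's likelihood `N(D, (WF·D)²)` is
  shrunk toward its own prior `N(D̄, σ_P²)`; the posteriors are then
  MLE-combined with weights `w ∝ σ⁻²`.
- **Model 2 — combination first**: unisensory likelihoods are MLE-combined
  (`WF_AV² = WF_V²WF_A²/(WF_V² + WF_A²)`), then shrunk once toward a
  single prior of width `(σ_P,V + σ_P,A)/2`.

Central tendency at likelihood width `σ_L` is `CT = σ_P²/(σ_P² + σ_L²)`;
inverting it with an observed (CT, WF) pair recovers the prior width
`σ_P = WF·D̄·√(CT/(1−CT))`.  Because combining first shrinks the
likelihood before the single prior integration, model 2 always predicts a
weaker audiovisual central tendency (larger slope) than model 1 — the
separable signature the pipeline tests for.  See `docs/methods.md` for the
full model, assumptions, parameter defaults and limitations.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the `bayestime` library; trial-level tables land in
`scratch/`, summary tables in `results/tables/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_fit_sensitivity.py
python analysis/03_fit_central_tendency.py
python analysis/04_compare_architectures.py
python analysis/05_architecture_self_consistency.py
```

The second script prints the fitted Weber fractions of the 7-subject
default cohort (seed 7):

```
   condition   mean    sem
        V:no 0.1371 0.0095
       V:low 0.1787 0.0083
      V:high 0.2274 0.0064
        ...
AV:high:high 0.1745 0.0103

audiovisual gain (high/high): AV 0.175 vs best unisensory 0.227
```

Noise degrades sensitivity (V 0.137 → 0.227 from no to high noise), and
the audiovisual WF undercuts the better unisensory WF, as optimal
combination requires.  The fourth script prints the architecture
comparison:

```
model1: predicted-vs-measured CT t(20) = -17.11, p = 2.08e-13, d = -3.73, mean |error| = 0.171
model2: predicted-vs-measured CT t(20) = -2.36, p = 0.0285, d = -0.52, mean |error| = 0.031
selected architecture: model2
```

Model 1 predicts far too much central tendency (mean slope error 0.17)
while model 2's predictions sit close to the measured audiovisual slopes —
the cohort was generated under the combination-first architecture, and the
pipeline recovers that fact.  The fifth script repeats this over replicate
cohorts generated under each architecture (selection accuracy 100% over
20 cohorts at these trial counts).

The same steps are available programmatically and as a CLI:

```python
from bayestime import RunConfig, run_experiment
run_experiment(RunConfig(n_subjects=7, seed=7), "scratch/my_run")
```

```sh
bayestime run --seed 7 --out scratch/my_run
bayestime model-compare --wf-v 0.17 --wf-a 0.17 --prior-v 238 --prior-a 238
```

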