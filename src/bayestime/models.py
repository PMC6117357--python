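"""Gaussian Bayesian machinery for time estimation.

Two optimality principles are combined here.  First, maximum-likelihood
(reliability-weighted) cue combination: when auditory and visual signals
report the same duration, the minimum-variance combined estimate is

    S_AV = w_A * S_A + w_V * S_V,   w_A = sd_A^-2 / (sd_A^-2 + sd_V^-2),

with combined precision the sum of the unisensory precisions.  Because
timing noise is scalar (sd = WF * D, with WF the Weber fraction), the same
rule written in Weber fractions gives the optimal audiovisual Weber
fraction  WF_AV = sqrt(WF_V^2 WF_A^2 / (WF_V^2 + WF_A^2)).

Second, prior integration: the observer holds a Gaussian prior N(mu_P,
sigma_P) over durations, centered on the mean presented duration, and
combines it with the sensory likelihood N(mu_L, sigma_L).  The posterior
mean is pulled toward the prior mean by sigma_L^2 / (sigma_P^2 + sigma_L^2),
which makes the regression slope of estimates on durations (the central
tendency index)

    CT = sigma_P^2 / (sigma_P^2 + sigma_L^2),

a number in (0, 1); 1 means veridical, smaller means a stronger pull to the
mean.  Inverting this with an observed CT and Weber fraction recovers the
prior width.

The two architectures in :func:`predict_model1` and :func:`predict_model2`
differ only in the order of the two steps: prior integration within each
modality followed by cue combination (model 1) versus cue combination
followed by a single prior integration (model 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian internal representation of duration (mean and width, ms)."""

    mean_ms: float
    sd_ms: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_ms):
            raise ValueError("mean_ms must be finite")
        if not (self.sd_ms > 0) or not np.isfinite(self.sd_ms):
            raise ValueError("sd_ms must be positive and finite")


@dataclass(frozen=True)
class MLEWeights:
    """Reliability weights of the auditory and visual cues (sum to 1)."""

    w_a: float
    w_v: float

    def __post_init__(self) -> None:
        if self.w_a < 0 or self.w_v < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.w_a + self.w_v - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class ModelPrediction:
    """Predicted audiovisual behavior under one integration architecture."""

    architecture: str
    predicted_av_slope: float
    predicted_av_wf: float
    per_duration: tuple[tuple[float, float], ...] = field(default_factory=tuple)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not np.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def mle_weights(sd_a: float, sd_v: float) -> MLEWeights:
    """Reliability weights for combining auditory and visual estimates."""
    _require_positive(sd_a=sd_a, sd_v=sd_v)
    pa, pv = sd_a ** -2.0, sd_v ** -2.0
    total = pa + pv
    return MLEWeights(w_a=pa / total, w_v=pv / total)


def mle_combine(a: GaussianBelief, v: GaussianBelief) -> GaussianBelief:
    """Minimum-variance combination of two Gaussian estimates.

    The combined mean is the precision-weighted average and the combined
    precision is the sum of the two precisions, so the combined width is
    always below both input widths.
    """
    w = mle_weights(a.sd_ms, v.sd_ms)
    mean = w.w_a * a.mean_ms + w.w_v * v.mean_ms
    sd = (a.sd_ms ** -2.0 + v.sd_ms ** -2.0) ** -0.5
    return GaussianBelief(mean_ms=mean, sd_ms=sd)


def predict_optimal_wf(wf_v: float, wf_a: float) -> float:
    """Optimal audiovisual Weber fraction from the unisensory ones."""
    _require_positive(wf_v=wf_v, wf_a=wf_a)
    return float(np.sqrt(wf_v ** 2 * wf_a ** 2 / (wf_v ** 2 + wf_a ** 2)))


def likelihood_width(wf: float, duration_ms: float) -> float:
    """Scalar-timing likelihood width: sigma_L = WF * D."""
    _require_positive(wf=wf, duration_ms=duration_ms)
    return wf * duration_ms


def posterior(likelihood: GaussianBelief, prior: GaussianBelief) -> GaussianBelief:
    """Gaussian posterior from a Gaussian likelihood and prior.

    The mean is written as the likelihood mean minus its deviation from the
    prior mean scaled by sigma_L^2 / (sigma_P^2 + sigma_L^2); algebraically
    this is the precision-weighted average of the two means.
    """
    sl2 = likelihood.sd_ms ** 2
    sp2 = prior.sd_ms ** 2
    t = likelihood.mean_ms - prior.mean_ms
    mean = likelihood.mean_ms - sl2 * t / (sp2 + sl2)
    sd = np.sqrt(sl2 * sp2 / (sl2 + sp2))
    return GaussianBelief(mean_ms=float(mean), sd_ms=float(sd))


def ct_slope(prior_sd: float, likelihood_sd: float) -> float:
    """Central-tendency slope sigma_P^2 / (sigma_P^2 + sigma_L^2)."""
    _require_positive(prior_sd=prior_sd, likelihood_sd=likelihood_sd)
    sp2 = prior_sd ** 2
    return float(sp2 / (sp2 + likelihood_sd ** 2))


def estimate_prior_width(ct: float, wf: float, mean_duration_ms: float) -> float:
    """Invert the central-tendency slope for the prior width.

    sigma_P = sigma_L * sqrt(CT / (1 - CT)) with sigma_L = WF * D-bar.
    Round-trips exactly with :func:`ct_slope` evaluated at the same
    effective likelihood width.
    """
    _require_positive(wf=wf, mean_duration_ms=mean_duration_ms)
    if not (0.0 < ct < 1.0):
        raise ValueError(
            f"central-tendency slope must lie strictly in (0, 1) to identify a "
            f"finite prior width; got {ct!r} (ct >= 1 means no measurable pull "
            f"toward the mean, so the prior width is unbounded)"
        )
    sigma_l = likelihood_width(wf, mean_duration_ms)
    return float(sigma_l * np.sqrt(ct / (1.0 - ct)))


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def expected_reproduction_slope(
    wf: float,
    prior_sd: float,
    prior_mean_ms: float,
    durations: Sequence[float],
) -> float:
    """Closed-form regression slope of posterior means on durations.

    With a duration-dependent likelihood width (sigma_L = WF * D) the pull
    toward the prior mean varies across levels, so the exact expected slope
    is obtained by regressing the per-duration posterior means on the
    durations rather than evaluating the single-width slope formula at one
    effective duration.  This is the noise-free oracle for the reproduction
    simulator (motor noise 0) and the backbone of both architecture
    predictors.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 durations")
    _require_positive(wf=wf, prior_sd=prior_sd)
    means = np.array(
        [
            posterior(
                GaussianBelief(d, likelihood_width(wf, d)),
                GaussianBelief(prior_mean_ms, prior_sd),
            ).mean_ms
            for d in durations
        ]
    )
    return _slope(durations, means)


def predict_model1(
    wf_v: float,
    wf_a: float,
    prior_v: GaussianBelief,
    prior_a: GaussianBelief,
    durations: Sequence[float],
    effective_duration_ms: float | None = None,
) -> ModelPrediction:
    """Architecture 1: prior integration within each modality, then combination.

    For each duration the visual and auditory likelihoods are shrunk toward
    their own priors; the two posteriors are then combined with weights set
    by the posterior widths.  The predicted central tendency is the slope of
    the combined means regressed on the stimulus durations.

    If ``effective_duration_ms`` is given, the likelihood widths are held
    fixed at WF times that duration instead of scaling with each stimulus.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 durations")
    combined_means = []
    for d in durations:
        d_eff = effective_duration_ms if effective_duration_ms is not None else d
        post_v = posterior(GaussianBelief(d, likelihood_width(wf_v, d_eff)), prior_v)
        post_a = posterior(GaussianBelief(d, likelihood_width(wf_a, d_eff)), prior_a)
        combined_means.append(mle_combine(post_a, post_v).mean_ms)
    slope = _slope(durations, np.asarray(combined_means))
    return ModelPrediction(
        architecture="model1",
        predicted_av_slope=slope,
        predicted_av_wf=predict_optimal_wf(wf_v, wf_a),
        per_duration=tuple(zip(map(float, durations), map(float, combined_means))),
    )


def predict_model2(
    wf_v: float,
    wf_a: float,
    prior_v_sd: float,
    prior_a_sd: float,
    durations: Sequence[float],
    prior_mean_ms: float,
    effective_duration_ms: float | None = None,
) -> ModelPrediction:
    """Architecture 2: cue combination first, then one prior integration.

    The unbiased unisensory likelihoods are combined into an audiovisual
    likelihood of width WF_AV * D (WF_AV optimal), which is then shrunk
    toward a single prior whose width is the average of the two unisensory
    prior widths.  If ``effective_duration_ms`` is given the slope is the
    single-width central-tendency formula evaluated at that duration;
    otherwise per-duration posterior means are regressed on durations.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 durations")
    _require_positive(prior_v_sd=prior_v_sd, prior_a_sd=prior_a_sd)
    wf_av = predict_optimal_wf(wf_v, wf_a)
    prior_sd = 0.5 * (prior_v_sd + prior_a_sd)
    prior = GaussianBelief(prior_mean_ms, prior_sd)
    if effective_duration_ms is not None:
        slope = ct_slope(prior_sd, likelihood_width(wf_av, effective_duration_ms))
        means = [
            prior_mean_ms + slope * (d - prior_mean_ms) for d in durations
        ]
    else:
        means = [
            posterior(GaussianBelief(d, likelihood_width(wf_av, d)), prior).mean_ms
            for d in durations
        ]
        slope = _slope(durations, np.asarray(means))
    return ModelPrediction(
        architecture="model2",
        predicted_av_slope=float(slope),
        predicted_av_wf=wf_av,
        per_duration=tuple(zip(map(float, durations), map(float, means))),
    )


def ct_wf_curve(
    prior_sd: float,
    wf_grid: Sequence[float],
    mean_duration_ms: float,
) -> list[tuple[float, float]]:
    """Central-tendency slope as a function of the Weber fraction.

    One curve per prior width; families over prior widths 100-500 ms show
    that a wider (flatter) prior yields a slope closer to 1 at every Weber
    fraction, and every curve decreases as the Weber fraction grows.
    """
    wf_grid = np.asarray(wf_grid, dtype=float)
    if np.any(wf_grid <= 0):
        raise ValueError("wf_grid must be positive")
    return [
        (float(wf), ct_slope(prior_sd, likelihood_width(float(wf), mean_duration_ms)))
        for wf in wf_grid
    ]
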