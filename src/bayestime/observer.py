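"""Synthetic Bayesian observer: generates discrimination and reproduction trials.

The observer embodies the generative assumptions of the analysis pipeline:
scalar timing noise (measurement sd = WF * D), a Gaussian prior over
durations centered on the mean presented duration, optimal (precision
weighted) prior integration, and — for audiovisual stimuli — one of two
integration architectures that differ in whether the prior acts before or
after cue combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import NOISE_NA, Condition, DesignSpec
from .models import predict_optimal_wf

DISCRIMINATION_COLUMNS = (
    "subject",
    "modality",
    "vis_noise",
    "aud_noise",
    "standard_ms",
    "comparison_ms",
    "resp_comparison_longer",
)
REPRODUCTION_COLUMNS = (
    "subject",
    "modality",
    "vis_noise",
    "aud_noise",
    "stimulus_ms",
    "reproduced_ms",
)

#: default per-condition Weber fractions; noise monotonically degrades
#: sensitivity and the two modalities are matched (no reliable modality
#: difference in discrimination)
DEFAULT_WF = {
    "V:no": 0.13,
    "V:low": 0.17,
    "V:high": 0.25,
    "A:no": 0.13,
    "A:low": 0.17,
    "A:high": 0.25,
}
#: default prior widths (ms): narrower for vision than audition, i.e. the
#: visual timing leans more on the prior
DEFAULT_PRIOR_WIDTH = {"V": 177.0, "A": 282.0}

_TASK_DISCRIMINATION = 1
_TASK_REPRODUCTION = 2


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth generative parameters of one simulated observer.

    ``wf`` maps condition keys (``"V:low"``, ``"A:high"``, optionally
    ``"AV:high:low"``) to Weber fractions; audiovisual entries that are
    absent are derived from the two unisensory ones by optimal combination.
    ``prior_width_ms`` maps modality (``"V"``, ``"A"``, optionally ``"AV"``)
    to the prior width; a missing ``"AV"`` entry defaults to the average of
    the visual and auditory widths.  ``prior_mean_ms`` may be the string
    ``"auto"``, meaning the mean presented duration of the design.
    """

    wf: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WF))
    prior_width_ms: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRIOR_WIDTH))
    prior_mean_ms: float | str = "auto"
    motor_noise_cv: float = 0.0
    av_architecture: str = "model2"
    seed: int = 0

    def __post_init__(self) -> None:
        for key, value in self.wf.items():
            if not (value > 0):
                raise ValueError(f"Weber fraction for {key!r} must be positive")
        for key, value in self.prior_width_ms.items():
            if not (value > 0):
                raise ValueError(f"prior width for {key!r} must be positive")
        if self.motor_noise_cv < 0:
            raise ValueError("motor_noise_cv must be nonnegative")
        if self.av_architecture not in ("model1", "model2"):
            raise ValueError("av_architecture must be 'model1' or 'model2'")
        if isinstance(self.prior_mean_ms, str) and self.prior_mean_ms != "auto":
            raise ValueError("prior_mean_ms must be a duration in ms or 'auto'")

    def wf_for(self, condition: Condition) -> float:
        """Weber fraction of a condition; audiovisual falls back to Eq-optimal."""
        key = condition.key
        if key in self.wf:
            return float(self.wf[key])
        if condition.modality == "AV":
            wf_v = self.wf_for(Condition("V", vis_noise=condition.vis_noise))
            wf_a = self.wf_for(Condition("A", aud_noise=condition.aud_noise))
            return predict_optimal_wf(wf_v, wf_a)
        raise KeyError(f"no Weber fraction for condition {key!r}")

    def prior_width_for(self, modality: str) -> float:
        if modality in self.prior_width_ms:
            return float(self.prior_width_ms[modality])
        if modality == "AV":
            return 0.5 * (self.prior_width_for("V") + self.prior_width_for("A"))
        raise KeyError(f"no prior width for modality {modality!r}")

    def resolve_prior_mean(self, design: DesignSpec) -> float:
        if self.prior_mean_ms == "auto":
            return design.mean_duration_ms
        return float(self.prior_mean_ms)


def _rng(params: ObserverParams, design: DesignSpec, condition: Condition, task: int, subject_index: int) -> np.random.Generator:
    # Independent, reproducible stream per (seed, task, condition, subject).
    return np.random.default_rng(
        [int(params.seed), task, design.condition_index(condition), int(subject_index)]
    )


def simulate_discrimination(
    design: DesignSpec,
    params: ObserverParams,
    condition: Condition | str,
    mode: str = "psychometric",
    subject: str = "s01",
    subject_index: int = 0,
) -> pd.DataFrame:
    """Simulate one condition of the two-interval duration discrimination task.

    In the default psychometric mode each trial is a Bernoulli draw with
    p = Phi((D_comp - D_std) / (WF * D_std)), so the analysis model (a
    cumulative normal over comparison duration) is exactly recoverable.  In
    estimate mode the observer draws a noisy estimate of each interval
    (per-interval sd scaled by 1/sqrt(2)) and compares them.
    """
    condition = design.condition(condition)
    if mode not in ("psychometric", "estimate"):
        raise ValueError("mode must be 'psychometric' or 'estimate'")
    wf = params.wf_for(condition)
    rng = _rng(params, design, condition, _TASK_DISCRIMINATION, subject_index)
    std = design.standard_ms
    levels = np.repeat(design.comparison_levels_ms, design.reps_discrimination)
    if mode == "psychometric":
        from scipy.stats import norm

        p_longer = norm.cdf((levels - std) / (wf * std))
        resp = (rng.random(levels.size) < p_longer).astype(int)
    else:
        est_std = rng.normal(std, wf * std / np.sqrt(2.0), size=levels.size)
        est_cmp = rng.normal(levels, wf * levels / np.sqrt(2.0))
        resp = (est_cmp > est_std).astype(int)
    return pd.DataFrame(
        {
            "subject": subject,
            "modality": condition.modality,
            "vis_noise": condition.vis_noise,
            "aud_noise": condition.aud_noise,
            "standard_ms": std,
            "comparison_ms": levels,
            "resp_comparison_longer": resp,
        }
    )


def _posterior_means_unisensory(
    d: np.ndarray, m: np.ndarray, wf: float, prior_sd: float, prior_mean: float
) -> np.ndarray:
    sigma_l = wf * d
    w = prior_sd ** 2 / (prior_sd ** 2 + sigma_l ** 2)
    return w * m + (1.0 - w) * prior_mean


def simulate_reproduction(
    design: DesignSpec,
    params: ObserverParams,
    condition: Condition | str,
    subject: str = "s01",
    subject_index: int = 0,
) -> pd.DataFrame:
    """Simulate one condition of the duration reproduction task.

    Unisensory: each trial draws a measurement m ~ N(D, (WF*D)^2) and
    reports the posterior mean  w*m + (1-w)*mu_P  with
    w = sigma_P^2 / (sigma_P^2 + (WF*D)^2).  Audiovisual trials follow the
    architecture in ``params.av_architecture``: per-modality prior
    integration before cue combination (model1), or combination of the raw
    measurements followed by a single prior integration with the averaged
    prior width (model2).  Optional motor noise (CV of the internal
    estimate) is added last; non-positive reproductions are redrawn.
    """
    condition = design.condition(condition)
    rng = _rng(params, design, condition, _TASK_REPRODUCTION, subject_index)
    prior_mean = params.resolve_prior_mean(design)
    d = np.repeat(design.reproduction_levels_ms, design.reps_reproduction).astype(float)
    n = d.size

    def generate(idx: np.ndarray) -> np.ndarray:
        di = d[idx]
        if condition.modality in ("V", "A"):
            wf = params.wf_for(condition)
            prior_sd = params.prior_width_for(condition.modality)
            m = rng.normal(di, wf * di)
            est = _posterior_means_unisensory(di, m, wf, prior_sd, prior_mean)
        else:
            wf_v = params.wf_for(Condition("V", vis_noise=condition.vis_noise))
            wf_a = params.wf_for(Condition("A", aud_noise=condition.aud_noise))
            sp_v = params.prior_width_for("V")
            sp_a = params.prior_width_for("A")
            m_v = rng.normal(di, wf_v * di)
            m_a = rng.normal(di, wf_a * di)
            if params.av_architecture == "model1":
                r_v = _posterior_means_unisensory(di, m_v, wf_v, sp_v, prior_mean)
                r_a = _posterior_means_unisensory(di, m_a, wf_a, sp_a, prior_mean)
                sl_v, sl_a = wf_v * di, wf_a * di
                s_v = np.sqrt(sl_v ** 2 * sp_v ** 2 / (sl_v ** 2 + sp_v ** 2))
                s_a = np.sqrt(sl_a ** 2 * sp_a ** 2 / (sl_a ** 2 + sp_a ** 2))
                pa, pv = s_a ** -2.0, s_v ** -2.0
                est = (pa * r_a + pv * r_v) / (pa + pv)
            else:
                sl_v, sl_a = wf_v * di, wf_a * di
                pa, pv = sl_a ** -2.0, sl_v ** -2.0
                m_av = (pa * m_a + pv * m_v) / (pa + pv)
                sigma_av = (pa + pv) ** -0.5
                prior_sd = params.prior_width_for("AV")
                w = prior_sd ** 2 / (prior_sd ** 2 + sigma_av ** 2)
                est = w * m_av + (1.0 - w) * prior_mean
        if params.motor_noise_cv > 0:
            est = est + rng.normal(0.0, params.motor_noise_cv * np.abs(est))
        return est

    reproduced = generate(np.arange(n))
    # redraw the (practically never occurring) non-positive reproductions
    bad = np.flatnonzero(reproduced <= 0)
    while bad.size:
        reproduced[bad] = generate(bad)
        bad = bad[reproduced[bad] <= 0]
    return pd.DataFrame(
        {
            "subject": subject,
            "modality": condition.modality,
            "vis_noise": condition.vis_noise,
            "aud_noise": condition.aud_noise,
            "stimulus_ms": d,
            "reproduced_ms": reproduced,
        }
    )
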