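"""Cumulative-normal psychometric fitting and Weber fractions.

The discrimination data are binary "comparison judged longer" responses as a
function of comparison duration.  The probability of that judgement is
modeled as Phi((D_c - PSE) / sigma); the point of subjective equality (PSE)
and sigma are fitted by maximizing the Bernoulli likelihood.  Timing
sensitivity is the Weber fraction sigma / standard (the JND is identified
with the fitted sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

CONDITION_COLUMNS = ("modality", "vis_noise", "aud_noise", "standard_ms")


class DegenerateDataError(ValueError):
    """Raised when the psychometric width is unidentifiable (no response mixing)."""


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood cumulative-normal fit of one condition."""

    pse_ms: float
    sigma_ms: float
    weber_fraction: float
    n_trials: int
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if not (self.sigma_ms > 0):
            raise ValueError("sigma_ms must be positive")
        if not (self.weber_fraction > 0):
            raise ValueError("weber_fraction must be positive")


def aggregate_binary_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse trials to one row per comparison level: (comparison_ms, n, k).

    All rows must share one condition (modality, noise levels, standard);
    mixing conditions would average incompatible psychometric functions.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    for col in CONDITION_COLUMNS:
        if trials[col].nunique() > 1:
            raise ValueError(f"mixed conditions: column {col!r} is not constant")
    grouped = (
        trials.groupby("comparison_ms", sort=True)["resp_comparison_longer"]
        .agg(n="size", k="sum")
        .reset_index()
    )
    return grouped


def _neg_loglik(theta: np.ndarray, x: np.ndarray, n: np.ndarray, k: np.ndarray, lapse: float) -> float:
    pse, log_sigma = theta
    sigma = np.exp(log_sigma)
    p = norm.cdf((x - pse) / sigma)
    p = lapse + (1.0 - 2.0 * lapse) * p
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum())


def _moment_start(x: np.ndarray, n: np.ndarray, k: np.ndarray) -> tuple[float, float]:
    """Moment-based start: PSE from the 50% crossing, sigma from the 25-75% span."""
    prop = k / n
    pse0 = float(np.interp(0.5, np.clip(prop, 1e-6, 1 - 1e-6), x)) if np.any(np.diff(prop) != 0) else float(np.mean(x))
    lo = float(np.interp(0.25, np.clip(prop, 1e-6, 1 - 1e-6), x))
    hi = float(np.interp(0.75, np.clip(prop, 1e-6, 1 - 1e-6), x))
    sigma0 = (hi - lo) / (2.0 * norm.ppf(0.75))
    if not (sigma0 > 0) or not np.isfinite(sigma0):
        sigma0 = float(np.std(x)) or float(np.mean(x)) * 0.2
    return pse0, sigma0


def fit_cumulative_normal(
    trials: pd.DataFrame,
    lapse: float = 0.0,
    fix_pse: float | None = None,
) -> PsychometricFit:
    """Fit Phi((D_c - PSE)/sigma) to binary responses by maximum likelihood.

    Uses Nelder-Mead with multiple moment-based starts over (PSE, log sigma);
    returns ``converged=False`` with best-effort estimates rather than
    raising when the optimizer stalls.  A fixed symmetric ``lapse`` rate can
    be supplied; ``fix_pse`` constrains the PSE (e.g. to the standard).
    """
    agg = aggregate_binary_responses(trials)
    x = agg["comparison_ms"].to_numpy(dtype=float)
    n = agg["n"].to_numpy(dtype=float)
    k = agg["k"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 distinct comparison levels")
    total_k = k.sum()
    total_n = n.sum()
    if total_k == 0 or total_k == total_n:
        raise DegenerateDataError(
            "all responses identical: psychometric width is unidentifiable"
        )
    standard = float(trials["standard_ms"].iloc[0])

    pse0, sigma0 = _moment_start(x, n, k)
    starts = [
        (pse0, sigma0),
        (standard, 0.17 * standard),
        (float(np.mean(x)), float(np.ptp(x)) / 4.0),
    ]

    if fix_pse is not None:

        def nll_1d(theta: np.ndarray) -> float:
            return _neg_loglik(np.array([fix_pse, theta[0]]), x, n, k, lapse)

        best = min(
            (
                minimize(nll_1d, [np.log(s0)], method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
                for _, s0 in starts
            ),
            key=lambda r: r.fun,
        )
        pse, sigma = float(fix_pse), float(np.exp(best.x[0]))
    else:
        best = min(
            (
                minimize(
                    _neg_loglik,
                    [p0, np.log(s0)],
                    args=(x, n, k, lapse),
                    method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
                )
                for p0, s0 in starts
            ),
            key=lambda r: r.fun,
        )
        pse, sigma = float(best.x[0]), float(np.exp(best.x[1]))

    return PsychometricFit(
        pse_ms=pse,
        sigma_ms=sigma,
        weber_fraction=sigma / standard,
        n_trials=int(total_n),
        loglik=-float(best.fun),
        converged=bool(best.success),
    )


def weber_fraction(fit: PsychometricFit, standard_ms: float) -> float:
    """Weber fraction: fitted sigma over the standard duration."""
    if not (standard_ms > 0):
        raise ValueError("standard_ms must be positive")
    return fit.sigma_ms / standard_ms
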