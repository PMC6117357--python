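"""Resampling and comparison statistics for paired condition contrasts.

The paired contrasts (e.g. audiovisual vs best-unisensory Weber fraction in
each noise combination) are tested with a seeded bootstrap over pairs, with
Bonferroni correction across the three audiovisual conditions, alongside
classical paired t statistics and predicted-versus-measured regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats
import statsmodels.api as sm


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements keyed by unit (subject or subject x condition)."""

    labels: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("labels, x and y must have equal length")
        if len(self.x) < 2:
            raise ValueError("need at least 2 pairs")

    @classmethod
    def from_arrays(cls, labels: Sequence, x: Sequence[float], y: Sequence[float]) -> "PairedSample":
        return cls(tuple(map(str, labels)), tuple(map(float, x)), tuple(map(float, y)))

    def diffs(self) -> np.ndarray:
        return np.asarray(self.x, dtype=float) - np.asarray(self.y, dtype=float)


@dataclass(frozen=True)
class BootstrapResult:
    p_value: float
    effect_size_d: float
    ci_low: float
    ci_high: float
    n_boot: int


def _cohen_d(diffs: np.ndarray) -> float:
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(diffs.mean() / sd)


def bootstrap_paired_test(
    sample: PairedSample,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Two-sided percentile bootstrap test of a zero mean paired difference.

    Pairs are resampled with replacement; the p-value is
    2 * min(P(mean* <= 0), P(mean* >= 0)) with a +1 continuity correction,
    capped at 1.  Cohen's d is mean(x-y)/sd(x-y) (0 when all differences
    vanish).  Deterministic for a given seed.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    diffs = sample.diffs()
    n = diffs.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = diffs[idx].mean(axis=1)
    p_lo = (1 + np.count_nonzero(boot_means <= 0)) / (n_boot + 1)
    p_hi = (1 + np.count_nonzero(boot_means >= 0)) / (n_boot + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return BootstrapResult(
        p_value=float(p),
        effect_size_d=_cohen_d(diffs),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def bonferroni(p_values: Sequence[float], m: int = 3) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {p!r}")
        out.append(min(1.0, m * p))
    return out


def paired_t(sample: PairedSample) -> tuple[float, int, float, float]:
    """Paired t test on x - y: returns (t, df, p, Cohen's d).

    Zero-variance differences with a nonzero mean yield an infinite t
    (p = 0); an all-zero difference vector yields t = 0, p = 1.
    """
    diffs = sample.diffs()
    n = diffs.size
    df = n - 1
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, df, 1.0, 0.0
        t = float(np.inf) if mean > 0 else float(-np.inf)
        return t, df, 0.0, _cohen_d(diffs)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), df, float(p), _cohen_d(diffs)


@dataclass(frozen=True)
class PredMeasRegression:
    slope: float
    intercept: float
    r: float
    p_value: float
    band_x: tuple[float, ...]
    band_low: tuple[float, ...]
    band_high: tuple[float, ...]


def regress_pred_vs_meas(
    predicted: Sequence[float],
    measured: Sequence[float],
) -> PredMeasRegression:
    """OLS of measured on predicted, with Pearson r and a 95% CI band.

    A slope of 1 through the origin means the model prediction is unbiased;
    the confidence band is for the mean fit line at each predicted value.
    """
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if pred.size != meas.size or pred.size < 3:
        raise ValueError("predicted and measured must have equal length >= 3")
    if np.ptp(pred) == 0:
        raise ValueError("constant predictor: correlation undefined")
    X = sm.add_constant(pred)
    fit = sm.OLS(meas, X).fit()
    r, p = sstats.pearsonr(pred, meas)
    order = np.argsort(pred)
    band = fit.get_prediction(X[order]).conf_int(alpha=0.05)
    return PredMeasRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r=float(r),
        p_value=float(p),
        band_x=tuple(map(float, pred[order])),
        band_low=tuple(map(float, band[:, 0])),
        band_high=tuple(map(float, band[:, 1])),
    )
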