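"""Central-tendency and bias analysis of duration reproduction data.

The central tendency is quantified by ordinary least squares of the
reproduced duration on the stimulus duration; a slope of 1 means veridical
reproduction and smaller slopes mean a stronger pull toward the mean.
Outliers are removed once per condition cell using a 3-standard-deviation
rule before fitting.  The overall bias — mean reproduced minus mean
presented duration — is reported separately: a pure central tendency leaves
the grand mean unchanged, so any overall bias is a distinct effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONDITION_COLUMNS = ("subject", "modality", "vis_noise", "aud_noise")


@dataclass(frozen=True)
class CentralTendencyFit:
    slope: float
    intercept_ms: float
    overall_bias_ms: float
    n_used: int
    n_excluded: int
    r2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


def exclude_outliers(
    trials: pd.DataFrame,
    k: float = 3.0,
    per_level: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Drop reproductions more than ``k`` SDs from their cell mean.

    Cell means and SDs are computed once, from the unfiltered data, per
    condition x stimulus level (``per_level=True``, the default) or per
    condition only.  Zero-variance cells exclude nothing.  Returns the
    filtered table and the number of rows removed.
    """
    if len(trials) == 0:
        return trials, 0
    group_cols = list(CONDITION_COLUMNS)
    if per_level:
        group_cols.append("stimulus_ms")
    grp = trials.groupby(group_cols, sort=False)["reproduced_ms"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    keep = (trials["reproduced_ms"] - mean).abs() <= k * sd
    keep |= sd == 0
    filtered = trials[keep]
    return filtered, int((~keep).sum())


def fit_central_tendency(
    trials: pd.DataFrame,
    exclude: bool = True,
    k: float = 3.0,
    per_level: bool = True,
) -> CentralTendencyFit:
    """OLS of reproduced on stimulus duration, after optional outlier removal.

    Pools trials (rather than averaging per level first) so every
    reproduction contributes; requires at least 2 distinct stimulus levels.
    """
    if exclude:
        used, n_excluded = exclude_outliers(trials, k=k, per_level=per_level)
    else:
        used, n_excluded = trials, 0
    x = used["stimulus_ms"].to_numpy(dtype=float)
    y = used["reproduced_ms"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct stimulus levels after filtering")
    res = stats.linregress(x, y)
    return CentralTendencyFit(
        slope=float(res.slope),
        intercept_ms=float(res.intercept),
        overall_bias_ms=float(y.mean() - x.mean()),
        n_used=int(len(used)),
        n_excluded=int(n_excluded),
        r2=float(res.rvalue ** 2),
    )


def overall_bias(trials: pd.DataFrame) -> float:
    """Mean reproduced minus mean presented duration (ms)."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    return float(trials["reproduced_ms"].mean() - trials["stimulus_ms"].mean())
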