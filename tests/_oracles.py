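"""Independent numerical oracles, kept free of the closed forms they check.

The Gaussian-product oracle multiplies the two densities pointwise on a
fixed 0.01 ms grid over [1, 2000] ms and extracts the peak and curvature of
the log product by least-squares quadratic fit; for Gaussian inputs the log
product is exactly quadratic, so the fit recovers the product's mean and
width to rounding error without ever invoking the precision-weighting
formulas.
"""

import numpy as np

GRID = np.arange(1.0, 2000.0 + 1e-9, 0.01)
# precomputed least-squares operator for a quadratic in (x - 1000)
_XC = GRID - 1000.0
_V = np.column_stack([_XC**2, _XC, np.ones_like(_XC)])
_PINV = np.linalg.pinv(_V)


def _log_density(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def gaussian_product_peak_width(mean1: float, sd1: float, mean2: float, sd2: float):
    """Mean and sd of the normalized product of two Gaussian densities."""
    logp = _log_density(GRID, mean1, sd1) + _log_density(GRID, mean2, sd2)
    a, b, _ = _PINV @ logp
    peak = 1000.0 - b / (2.0 * a)
    sd = float(np.sqrt(-1.0 / (2.0 * a)))
    return float(peak), sd


def oracle_reproduction_slope(wf: float, prior_sd: float, prior_mean: float, durations) -> float:
    """Expected reproduction slope via the grid oracle, one posterior per level."""
    durations = np.asarray(durations, dtype=float)
    means = np.array(
        [gaussian_product_peak_width(d, wf * d, prior_mean, prior_sd)[0] for d in durations]
    )
    return float(np.polyfit(durations, means, 1)[0])
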