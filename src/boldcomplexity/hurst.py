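"""Hurst exponent by dispersional analysis.

Dispersional analysis estimates long-range temporal dependence from how
the dispersion of window-averaged signals shrinks with window size: for a
fractal signal SD(m) ~ SD(1) * m^(H-1), so a least-squares line through
(log m, log SD(m)) has slope H - 1.  H = 0.5 is an uncorrelated (white)
process, H < 0.5 anti-correlated, H > 0.5 persistent.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .series import HurstParams, MetricValue, UniformTimeSeries

__all__ = [
    "hurst_dispersional",
    "hurst_two_scale",
    "classify_hurst",
    "HurstClass",
]


def _window_mean_sd(u: np.ndarray, m: int) -> float:
    """Sample SD of the means of the ⌊N/m⌋ complete windows of size m."""
    n_win = u.size // m
    means = u[: n_win * m].reshape(n_win, m).mean(axis=1)
    return float(np.std(means, ddof=1))


def hurst_dispersional(
    series: UniformTimeSeries, params: HurstParams | None = None
) -> MetricValue:
    """Estimate H from the log-log regression of aggregated-signal SDs.

    For each scale m the series is partitioned into non-overlapping
    complete windows (remainder dropped), the windows are averaged, and
    the sample SD of those means is taken.  H = 1 + slope of the
    least-squares fit of log SD against log m.  Scales with zero SD are
    dropped; fewer than 3 usable scales is an error.  The estimate is
    returned unclipped, flagged degenerate when outside [0, 1].
    """
    params = params or HurstParams()
    u = series.values
    scales = params.resolve_scales(u.size)
    if len(scales) < 3:
        raise ValueError(
            f"only {len(scales)} usable scales for N={u.size} "
            f"(need >= 3 with >= {params.min_windows} windows each)"
        )
    kept, sds = [], []
    for m in scales:
        sd = _window_mean_sd(u, m)
        if sd > 0.0:
            kept.append(m)
            sds.append(sd)
    if len(kept) < 3:
        raise ValueError(
            "fewer than 3 scales with non-zero dispersion; "
            "series is (piecewise) constant"
        )
    slope = np.polyfit(np.log(kept), np.log(sds), 1)[0]
    h = 1.0 + float(slope)
    return MetricValue(h, degenerate=not (0.0 <= h <= 1.0))


def hurst_two_scale(series: UniformTimeSeries, m: int = 2, n: int = 1) -> float:
    """Two-point dispersional estimate H = 1 + log(SD(m)/SD(n)) / log(m/n).

    The special case of the regression estimator that uses only two
    aggregation levels (by default window sizes 2 and 1); exposed for
    comparison with the multi-scale fit.
    """
    if m <= n or n < 1:
        raise ValueError("require m > n >= 1")
    sd_m = _window_mean_sd(series.values, m)
    sd_n = _window_mean_sd(series.values, n)
    if sd_m <= 0 or sd_n <= 0:
        raise ValueError("zero dispersion at a requested scale")
    return 1.0 + float(np.log(sd_m / sd_n) / np.log(m / n))


class HurstClass(str, Enum):
    ANTI_CORRELATED = "anti_correlated"
    RANDOM = "random"
    PERSISTENT = "persistent"
    OUT_OF_RANGE = "out_of_range"


def classify_hurst(h: float, tol: float = 0.01) -> HurstClass:
    """Classify an H estimate: anti-correlated (<0.5), random (≈0.5 within
    ``tol``), or persistent (>0.5).  Values outside (0, 1) signal
    OUT_OF_RANGE instead of raising."""
    if not np.isfinite(h):
        raise ValueError("h must be finite")
    if not (0.0 < h < 1.0):
        return HurstClass.OUT_OF_RANGE
    if abs(h - 0.5) <= tol:
        return HurstClass.RANDOM
    return HurstClass.ANTI_CORRELATED if h < 0.5 else HurstClass.PERSISTENT
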