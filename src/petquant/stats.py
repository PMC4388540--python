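"""Small descriptive-statistics helpers used in evaluation and tests."""

from __future__ import annotations

import numpy as np

__all__ = ["cv_percent", "icc_consistency"]


def cv_percent(mean: float, sd: float) -> float:
    """Percent coefficient of variation, 100·SD/mean."""
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return 100.0 * sd / mean


def icc_consistency(x, y) -> float:
    """Two-way mixed, single-measure consistency ICC for paired ratings."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    mean_rows = data.mean(axis=1)
    mean_cols = data.mean(axis=0)
    grand = data.mean()
    msr = k * np.sum((mean_rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((mean_cols - grand) ** 2) / (k - 1)
    sse = np.sum((data - mean_rows[:, None] - mean_cols[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))
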