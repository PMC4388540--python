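"""Logan graphical analysis: arterial-input form (slope = V_T) and
reference-region form (slope = DVR)."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .tac_core import LoganResult, TimeActivityCurve, cumulative_integral

__all__ = ["logan_arterial", "logan_reference", "mcdvr", "DEFAULT_WINDOW", "DEFAULT_K2PRIME"]

DEFAULT_WINDOW = (30.0, 60.0)
DEFAULT_K2PRIME = 0.16  # reference-region washout, per minute


def _select_window(ct: TimeActivityCurve, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError("fit window must have positive width")
    mid = ct.midpoint
    sel = (mid >= lo) & (mid <= hi)
    if sel.sum() < 2:
        raise ValueError(f"window {window} contains fewer than 2 frame midpoints")
    bad = np.flatnonzero(sel & (ct.values == 0))
    if bad.size:
        raise ZeroDivisionError(f"target curve is zero at frame(s) {bad.tolist()} in window")
    return sel


def _ols(x: np.ndarray, y: np.ndarray, window, n) -> LoganResult:
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("singular graphical design: constant abscissa")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LoganResult(float(slope), float(intercept), tuple(window), int(n), r2)


def logan_arterial(
    ct: TimeActivityCurve,
    cp: TimeActivityCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> LoganResult:
    """Logan plot with arterial input; the slope estimates V_T.

    Ordinary least squares of y = ∫₀ᵀC_T/C_T(T) on x = ∫₀ᵀC_P/C_T(T) over
    frames whose midpoint lies in the closed window.
    """
    if ct.schedule != cp.schedule:
        raise ValueError("tissue and plasma curves must share one schedule")
    sel = _select_window(ct, window)
    int_ct = cumulative_integral(ct)[sel]
    int_cp = cumulative_integral(cp)[sel]
    ct_T = ct.values[sel]
    return _ols(int_cp / ct_T, int_ct / ct_T, window, sel.sum())


def logan_reference(
    ct: TimeActivityCurve,
    cr: TimeActivityCurve,
    k2prime: float = DEFAULT_K2PRIME,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> LoganResult:
    """Logan plot with a reference-region input; the slope estimates DVR.

    OLS of y = ∫₀ᵀC_T/C_T(T) on x = (∫₀ᵀC_R + C_R(T)/k2′)/C_T(T).
    """
    if ct.schedule != cr.schedule:
        raise ValueError("target and reference curves must share one schedule")
    if k2prime <= 0:
        raise ValueError("k2prime must be positive")
    sel = _select_window(ct, window)
    int_ct = cumulative_integral(ct)[sel]
    int_cr = cumulative_integral(cr)[sel]
    ct_T = ct.values[sel]
    x = (int_cr + cr.values[sel] / k2prime) / ct_T
    return _ols(x, int_ct / ct_T, window, sel.sum())


def mcdvr(regional_dvr: Mapping[str, float], roster: Sequence[str]) -> float:
    """Mean cortical DVR: unweighted mean over the roster regions."""
    missing = [r for r in roster if r not in regional_dvr]
    if missing:
        raise KeyError(f"regions missing from DVR map: {missing}")
    if not roster:
        raise ValueError("empty region roster")
    return float(np.mean([regional_dvr[r] for r in roster]))
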