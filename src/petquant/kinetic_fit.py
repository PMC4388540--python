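"""Constrained two-tissue-compartment fitting and per-subject quantification.

The full kinetic fit estimates (K1, K1/k2, k3) directly with the total
distribution volume held fixed at the Logan arterial-input value; k4 follows
from the constraint and DVR_kinetic = V_T / (K1/k2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import logan
from .tac_core import Kinetics2TC, TimeActivityCurve, forward_2tc

__all__ = ["fit_2tc_constrained", "quantify_subject"]

log = logging.getLogger(__name__)

# (lower, upper) optimizer bounds for the direct parameters
DEFAULT_BOUNDS = {
    "K1": (0.01, 1.0),
    "K1_over_k2": (0.5, 10.0),
    "k3": (0.0, 0.5),
}
_EXCESS_TOL = 1e-6  # vt/R - 1 below this collapses to a 1TC model


def _model_values(
    K1: float, R: float, k3: float, vt_fixed: float,
    cp: TimeActivityCurve, dt_internal: float,
) -> np.ndarray:
    k2 = K1 / R
    excess = vt_fixed / R - 1.0
    if excess <= _EXCESS_TOL or k3 <= 0.0:
        kin = Kinetics2TC(K1, k2, 0.0, 0.0)
    else:
        kin = Kinetics2TC(K1, k2, k3, k3 / excess)
    return forward_2tc(kin, cp, dt_internal=dt_internal).values


def fit_2tc_constrained(
    ct: TimeActivityCurve,
    cp: TimeActivityCurve,
    vt_fixed: float,
    *,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 3,
    seed: int = 0,
    weights: np.ndarray | None = None,
    dt_internal: float = 0.05,
) -> tuple[Kinetics2TC, float, dict]:
    """Two-tissue fit with total distribution volume fixed at ``vt_fixed``.

    Free parameters are K1, R = K1/k2 and k3; k4 = k3/(vt_fixed/R − 1) so
    the model's V_T equals ``vt_fixed`` identically.  Returns the fitted
    rate constants, DVR_kinetic = vt_fixed / R, and diagnostics.  If the
    optimum sits at R ≈ vt_fixed the model collapses to one tissue
    (DVR_kinetic → 1); this is flagged, not an error.
    """
    if vt_fixed <= 0:
        raise ValueError("vt_fixed must be positive")
    if ct.schedule != cp.schedule:
        raise ValueError("tissue and plasma curves must share one schedule")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b["K1"][0], b["K1_over_k2"][0], b["k3"][0]])
    hi = np.array([b["K1"][1], min(b["K1_over_k2"][1], vt_fixed), b["k3"][1]])
    if hi[1] <= lo[1]:
        # vt_fixed below the R lower bound: only the boundary 1TC model remains
        lo[1] = 0.5 * vt_fixed
        hi[1] = vt_fixed
    w = None if weights is None else np.sqrt(np.asarray(weights, float))

    def residuals(x: np.ndarray) -> np.ndarray:
        res = ct.values - _model_values(x[0], x[1], x[2], vt_fixed, cp, dt_internal)
        return res if w is None else res * w

    rng = np.random.default_rng(seed)
    starts = [np.sqrt(lo * np.maximum(hi, 1e-12)) if np.all(lo > 0)
              else 0.5 * (lo + hi)]
    while len(starts) < n_starts:
        starts.append(lo + (hi - lo) * rng.random(3))

    best = None
    q_trace = []
    for x_start in starts:
        try:
            sol = least_squares(residuals, np.clip(x_start, lo, hi), bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # pragma: no cover
            q_trace.append(float("nan"))
            log.warning("constrained 2TC start failed: %s", exc)
            continue
        q = float(np.sum(sol.fun**2))
        q_trace.append(q)
        if best is None or q < best[0]:
            best = (q, sol)
    if best is None:
        raise RuntimeError("constrained 2TC fit failed from every start")

    q_best, sol = best
    K1, R, k3 = sol.x
    flags = []

    # nested-model selection: keep k3 > 0 only if the two-tissue fit beats
    # the one-tissue fit (k3 = 0) by a significant margin (F-test, p ~ 0.05)
    if k3 > 0:
        def residuals_1tc(x: np.ndarray) -> np.ndarray:
            res = ct.values - _model_values(x[0], x[1], 0.0, vt_fixed, cp, dt_internal)
            return res if w is None else res * w

        sol0 = least_squares(
            residuals_1tc, np.clip(sol.x[:2], lo[:2], hi[:2]),
            bounds=(lo[:2], hi[:2]), xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        q0 = float(np.sum(sol0.fun**2))
        from scipy.stats import f as f_dist

        dof = max(ct.schedule.F - 3, 1)
        f_stat = (q0 - q_best) / max(q_best / dof, 1e-300)
        if q_best > 0 and f_stat < f_dist.ppf(0.95, 1, dof):
            K1, R = sol0.x
            k3 = 0.0
            q_best = q0
            flags.append("k3_rejected_ftest")

    excess = vt_fixed / R - 1.0
    if excess <= _EXCESS_TOL:
        if k3 > _EXCESS_TOL:
            flags.append("vt_constraint_boundary")
        k3, k4 = 0.0, 0.0
        flags.append("k3_boundary_1tc")
    elif k3 <= 0.0:
        k3, k4 = 0.0, 0.0
        flags.append("k3_boundary_1tc")
    else:
        k4 = k3 / excess
    kin = Kinetics2TC(float(K1), float(K1 / R), float(k3), float(k4))
    dvr_kinetic = float(vt_fixed / R)
    diagnostics = {
        "q": q_best,
        "q_per_start": q_trace,
        "flags": flags,
        "vt_fixed": float(vt_fixed),
        "K1_over_k2": float(R),
        "success": bool(sol.success),
    }
    return kin, dvr_kinetic, diagnostics


def quantify_subject(
    tacs: dict[str, TimeActivityCurve],
    cp: TimeActivityCurve,
    ref_region: str,
    *,
    window: tuple[float, float] = logan.DEFAULT_WINDOW,
    k2prime: float = logan.DEFAULT_K2PRIME,
    mcdvr_regions: list[str] | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Regional quantification table: Logan V_T, DVR_REF, and DVR_kinetic.

    Runs, per region, the arterial-input Logan fit, the reference-region
    Logan fit against ``ref_region``, and the V_T-constrained kinetic fit.
    A final ``MCDVR`` row averages the roster regions (default: every region
    except the reference).  Per-region failures are recorded in ``flags``
    and the pipeline continues.
    """
    if ref_region not in tacs:
        raise KeyError(f"reference region {ref_region!r} not in TAC set")
    fit_kwargs = fit_kwargs or {}
    cr = tacs[ref_region]
    rows = []
    for region, ct in tacs.items():
        row = {
            "region": region, "V_T": np.nan, "Int": np.nan, "DVR_REF": np.nan,
            "DVR_kinetic": np.nan, "K1": np.nan, "K1_over_k2": np.nan,
            "k3": np.nan, "k4": np.nan, "flags": "",
        }
        flags = []
        try:
            art = logan.logan_arterial(ct, cp, window=window)
            row["V_T"], row["Int"] = art.slope, art.intercept
        except Exception as exc:
            flags.append(f"logan_arterial:{exc}")
        try:
            row["DVR_REF"] = logan.logan_reference(ct, cr, k2prime=k2prime, window=window).slope
        except Exception as exc:
            flags.append(f"logan_reference:{exc}")
        if np.isfinite(row["V_T"]) and row["V_T"] > 0:
            try:
                kin, dvr_k, diag = fit_2tc_constrained(ct, cp, row["V_T"], **fit_kwargs)
                row.update(
                    DVR_kinetic=dvr_k, K1=kin.K1, K1_over_k2=kin.K1 / kin.k2,
                    k3=kin.k3, k4=kin.k4,
                )
                flags.extend(diag["flags"])
            except Exception as exc:
                flags.append(f"kinetic_fit:{exc}")
        row["flags"] = ";".join(str(f) for f in flags)
        rows.append(row)
    table = pd.DataFrame(rows)

    roster = mcdvr_regions if mcdvr_regions is not None else [
        r for r in tacs if r != ref_region
    ]
    if roster:
        sub = table[table["region"].isin(roster)]
        mc = {
            "region": "MCDVR",
            "V_T": sub["V_T"].mean(), "Int": np.nan,
            "DVR_REF": sub["DVR_REF"].mean(), "DVR_kinetic": sub["DVR_kinetic"].mean(),
            "K1": np.nan, "K1_over_k2": np.nan, "k3": np.nan, "k4": np.nan, "flags": "",
        }
        table = pd.concat([table, pd.DataFrame([mc])], ignore_index=True)
    else:
        log.warning("empty MCDVR roster; summary row omitted")
    return table
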