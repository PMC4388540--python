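"""Seeded generators for synthetic dynamic-PET inputs.

Everything the pipeline consumes can be produced here: a bolus plasma input,
per-region tissue curves, the mixed arterial-ROI curve, a background curve,
and a curved-tube vessel phantom with its thresholding box.  Generators are
deterministic given a seed; each subject bundle carries a truth record with
every generating parameter for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .arterial_roi import Box, VolumeImage
from .idaif import DEFAULT_T_LATE, IdaifParams, ParentFractionModel, aif_from_tissue, detect_tpeak
from .tac_core import (
    FrameSchedule,
    Kinetics2TC,
    TimeActivityCurve,
    forward_2tc,
    _frame_average,
)

__all__ = [
    "PAPER_FRAME_GROUPS",
    "AifShape",
    "SubjectBundle",
    "VesselPhantom",
    "make_schedule",
    "make_aif",
    "aif_function",
    "cohort_kinetics",
    "make_subject",
    "make_vessel_phantom",
    "make_pet4d",
]

#: 26-frame, 60-minute acquisition: 12 x 10 s, 3 x 1 min, 11 x 5 min.
PAPER_FRAME_GROUPS = ((12, 10.0 / 60.0), (3, 1.0), (11, 5.0))


def make_schedule(groups=PAPER_FRAME_GROUPS) -> FrameSchedule:
    """Frame schedule from (count, duration_minutes) groups."""
    return FrameSchedule.from_groups(groups)


@dataclass(frozen=True)
class AifShape:
    """Bolus input: linear rise to a peak, then a 3-exponential decay.

    Decay amplitudes are normalized to sum to 1 so the curve is continuous
    at the peak.
    """

    peak_time: float = 0.75  # minutes
    peak: float = 25.0
    amplitudes: tuple[float, float, float] = (0.75, 0.20, 0.05)
    rates: tuple[float, float, float] = (4.0, 0.5, 0.02)  # per minute

    def __post_init__(self) -> None:
        if self.peak_time <= 0:
            raise ValueError("peak_time must be positive")
        if self.peak < 0 or any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        total = sum(self.amplitudes)
        if total > 0 and abs(total - 1.0) > 1e-12:
            object.__setattr__(
                self, "amplitudes", tuple(a / total for a in self.amplitudes)
            )


def aif_function(shape: AifShape) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous bolus curve for the given shape parameters."""

    amps = np.asarray(shape.amplitudes)
    rates = np.asarray(shape.rates)

    def cp(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rise = shape.peak * np.clip(t, 0.0, shape.peak_time) / shape.peak_time
        decay = shape.peak * np.sum(
            amps[:, None] * np.exp(-rates[:, None] * np.maximum(t - shape.peak_time, 0.0)[None, :].reshape(1, -1)),
            axis=0,
        ).reshape(t.shape)
        return np.where(t < shape.peak_time, rise, decay)

    return cp


def make_aif(shape: AifShape, schedule: FrameSchedule, dt: float = 0.01) -> TimeActivityCurve:
    """Frame-averaged plasma curve for the bolus shape."""
    func = aif_function(shape)
    t = np.arange(0.0, schedule.span + dt, dt)
    return TimeActivityCurve(schedule, _frame_average(t, func(t), schedule), role="plasma")


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

_COHORTS: dict[str, dict[str, Kinetics2TC]] = {
    # low specific binding everywhere (k3/k4 ~ 0.05-0.3)
    "pib_neg": {
        "cerebellum": Kinetics2TC(0.30, 0.100, 0.015, 0.15),
        "brainstem": Kinetics2TC(0.32, 0.107, 0.045, 0.15),
        "precuneus": Kinetics2TC(0.28, 0.093, 0.012, 0.15),
        "temporal": Kinetics2TC(0.26, 0.087, 0.009, 0.15),
        "prefrontal": Kinetics2TC(0.27, 0.090, 0.0075, 0.15),
        "caudate": Kinetics2TC(0.26, 0.087, 0.012, 0.15),
    },
    # elevated cortical binding (k3/k4 ~ 0.3-0.5), cerebellum unchanged
    "pib_pos": {
        "cerebellum": Kinetics2TC(0.30, 0.100, 0.015, 0.15),
        "brainstem": Kinetics2TC(0.32, 0.107, 0.045, 0.15),
        "precuneus": Kinetics2TC(0.28, 0.093, 0.075, 0.15),
        "temporal": Kinetics2TC(0.26, 0.087, 0.060, 0.15),
        "prefrontal": Kinetics2TC(0.27, 0.090, 0.0675, 0.15),
        "caudate": Kinetics2TC(0.26, 0.087, 0.050, 0.15),
    },
}


def cohort_kinetics(name: str) -> dict[str, Kinetics2TC]:
    """Per-region rate-constant presets ('pib_neg' or 'pib_pos')."""
    if name not in _COHORTS:
        raise KeyError(f"unknown cohort {name!r}; choose from {sorted(_COHORTS)}")
    return dict(_COHORTS[name])


# ---------------------------------------------------------------------------
# subject bundles
# ---------------------------------------------------------------------------


def _integrate_blended_1tc(
    K1: float,
    k2: float,
    k2a: float,
    t_peak: float,
    t_late: float,
    cp_func: Callable[[np.ndarray], np.ndarray],
    span: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve dCt/dt = K1·Cp − k_eff(t)·Ct with the early/late washout blend.

    Exact per step for piecewise-constant k_eff and piecewise-linear Cp.
    """
    n = int(math.ceil(span / dt)) + 1
    t = np.linspace(0.0, span, n)
    cp = cp_func(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    w1 = np.clip((t_late - t_mid) / (t_late - t_peak), 0.0, 1.0)
    k = w1 * k2 + (1.0 - w1) * k2a
    h = t[1] - t[0]
    e = np.exp(-k * h)
    i0 = (1.0 - e) / k
    i1 = (1.0 - (1.0 + k * h) * e) / (k * k)
    y = np.zeros(n)
    for i in range(n - 1):
        seg = cp[i + 1] * i0[i] + (cp[i] - cp[i + 1]) * i1[i] / h
        y[i + 1] = y[i] * e[i] + K1 * seg
    return t, y


@dataclass(frozen=True)
class VesselPhantom:
    """Curved-tube angiography phantom: intensity image, mask, and box."""

    mra: VolumeImage
    vessel_mask: VolumeImage
    box: Box


@dataclass(frozen=True)
class SubjectBundle:
    """One synthetic subject: every curve the pipeline consumes plus truth."""

    schedule: FrameSchedule
    aif_func: Callable[[np.ndarray], np.ndarray]
    true_aif: TimeActivityCurve
    tacs: dict[str, TimeActivityCurve]
    croia: TimeActivityCurve
    cbg: TimeActivityCurve
    truth: dict
    phantom: VesselPhantom | None = None


def make_subject(
    kinetics: Mapping[str, Kinetics2TC] | str = "pib_neg",
    seed: int = 0,
    noise: float = 0.0,
    schedule: FrameSchedule | None = None,
    aif_shape: AifShape | None = None,
    r: float | None = None,
    s: float = 0.15,
    pf: ParentFractionModel | None = None,
    driving_region: str = "cerebellum",
    bg_kinetics: Kinetics2TC = Kinetics2TC(0.12, 0.06, 0.0, 0.0),
    t_late: float = DEFAULT_T_LATE,
    with_phantom: bool = False,
    dt: float = 0.01,
) -> SubjectBundle:
    """Generate a synthetic subject with a fully recorded ground truth.

    The driving region's curve obeys the blended two-washout kinetics the
    AIF estimator inverts, so at the true parameters the arterial-ROI chain
    reproduces the measured ROIa curve exactly (before noise); all other
    regions follow the full two-tissue model.  ``noise`` scales a
    heteroscedastic Gaussian perturbation with variance proportional to
    activity over frame duration.
    """
    if isinstance(kinetics, str):
        kinetics = cohort_kinetics(kinetics)
    if driving_region not in kinetics:
        raise KeyError(f"driving region {driving_region!r} missing from kinetics")
    schedule = schedule or make_schedule()
    aif_shape = aif_shape or AifShape()
    pf = pf or ParentFractionModel()
    rng = np.random.default_rng(seed)
    cp_func = aif_function(aif_shape)

    phantom = None
    if with_phantom:
        phantom = make_vessel_phantom(seed=seed)
    if r is None:
        if phantom is not None:
            from .arterial_roi import build_roi_pair, recovery_coefficient, smooth_to_pet_resolution

            sm = smooth_to_pet_resolution(phantom.vessel_mask)
            roia, _bg = build_roi_pair(sm, phantom.box)
            r = recovery_coefficient(phantom.vessel_mask, roia)
        else:
            r = 0.25

    # driving region: blended-washout generation with a self-consistent t_peak
    drv = kinetics[driving_region]
    k2a = drv.k2a
    t_peak = aif_shape.peak_time + 1.0
    ct_drv = None
    for _ in range(6):
        t_dense, y = _integrate_blended_1tc(
            drv.K1, drv.k2, k2a, t_peak, t_late, cp_func, schedule.span, dt
        )
        ct_drv = TimeActivityCurve(schedule, _frame_average(t_dense, y, schedule), role="tissue")
        tp_new = detect_tpeak(ct_drv)
        if tp_new == t_peak:
            break
        t_peak = tp_new

    tacs: dict[str, TimeActivityCurve] = {}
    for region, kin in kinetics.items():
        if region == driving_region:
            tacs[region] = ct_drv
        else:
            tacs[region] = forward_2tc(kin, cp_func, schedule, dt_internal=dt)

    cbg = forward_2tc(bg_kinetics, cp_func, schedule, dt_internal=dt)
    cbg = cbg.with_values(cbg.values, role="background")

    idaif_truth = IdaifParams(
        K1=drv.K1, k2=drv.k2, k2a=k2a, s=s, r=r, t_peak=t_peak, t_late=t_late
    )
    cp_rec = aif_from_tissue(ct_drv, idaif_truth)
    gain = pf.plasma_to_blood_gain(schedule.midpoint)
    croia = TimeActivityCurve(
        schedule, r * cp_rec.values * gain + s * cbg.values, role="arterial_roi"
    )
    true_aif = make_aif(aif_shape, schedule, dt=dt)

    def noisy(tac: TimeActivityCurve) -> TimeActivityCurve:
        if noise == 0.0:
            return tac
        v = tac.values
        floor = 0.05 * max(float(np.max(np.abs(v))), 1e-12)
        sd = noise * np.sqrt(np.maximum(np.abs(v), floor) / schedule.duration)
        return tac.with_values(v + sd * rng.standard_normal(v.shape))

    tacs_out = {name: noisy(tac) for name, tac in tacs.items()}
    cbg_out = noisy(cbg)
    croia_out = noisy(croia)

    truth = {
        "seed": seed,
        "noise": noise,
        "kinetics": dict(kinetics),
        "vt": {name: kin.vt for name, kin in kinetics.items()},
        "dvr": {name: kin.dvr for name, kin in kinetics.items()},
        "bg_kinetics": bg_kinetics,
        "aif_shape": aif_shape,
        "idaif": idaif_truth,
        "parent_fraction": pf,
        "r": r,
        "s": s,
        "driving_region": driving_region,
    }
    return SubjectBundle(
        schedule=schedule,
        aif_func=cp_func,
        true_aif=true_aif,
        tacs=tacs_out,
        croia=croia_out,
        cbg=cbg_out,
        truth=truth,
        phantom=phantom,
    )


# ---------------------------------------------------------------------------
# vessel phantom
# ---------------------------------------------------------------------------


def make_vessel_phantom(
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tube_radius_mm: float = 2.0,
    bend_amplitude_mm: float = 6.0,
    seed: int = 0,
    noise_sd: float = 2.0,
    tube_intensity: float = 100.0,
    tissue_intensity: float = 20.0,
) -> VesselPhantom:
    """Curved bright tube in a mid-intensity background, with a central box.

    The tube runs along z with a sinusoidal bend in x.  The returned box
    encloses a central tube segment and is sized to admit a 16 cc arterial
    ROI on the default grid.
    """
    nx, ny, nz = shape
    vx, vy, vz = voxel_size_mm
    rng = np.random.default_rng(seed)

    x_mm = (np.arange(nx) + 0.5) * vx
    y_mm = (np.arange(ny) + 0.5) * vy
    z_idx = np.arange(nz)
    # sub-voxel offsets break grid mirror symmetries, so smoothed intensities
    # are all distinct and any voxel count is reachable by thresholding
    cx = 0.5 * nx * vx + 0.29 * vx + bend_amplitude_mm * np.sin(np.pi * z_idx / nz)
    cy = 0.5 * ny * vy + 0.37 * vy
    if np.max(cx) + tube_radius_mm >= nx * vx or np.min(cx) - tube_radius_mm <= 0:
        raise ValueError("tube does not fit inside the grid")
    if cy + tube_radius_mm >= ny * vy or cy - tube_radius_mm <= 0:
        raise ValueError("tube does not fit inside the grid")

    d2 = (x_mm[:, None, None] - cx[None, None, :]) ** 2 + (
        y_mm[None, :, None] - cy
    ) ** 2
    mask = (d2 <= tube_radius_mm**2).astype(np.uint8)

    mra = np.full(shape, tissue_intensity, dtype=float)
    mra[mask > 0] = tube_intensity
    if noise_sd > 0:
        mra = np.clip(mra + noise_sd * rng.standard_normal(shape), 0.0, None)

    z0, z1 = int(nz * 0.375), int(nz * 0.625)
    xc_vox = cx[z0:z1] / vx
    pad_x = int(round((tube_radius_mm + 14.0) / vx))
    pad_y = int(round((tube_radius_mm + 14.0) / vy))
    x0 = max(int(np.floor(np.min(xc_vox))) - pad_x, 0)
    x1 = min(int(np.ceil(np.max(xc_vox))) + pad_x, nx)
    y0 = max(int(cy / vy) - pad_y, 0)
    y1 = min(int(cy / vy) + pad_y, ny)
    box: Box = ((x0, x1), (y0, y1), (z0, z1))

    return VesselPhantom(
        mra=VolumeImage(mra, voxel_size_mm),
        vessel_mask=VolumeImage(mask, voxel_size_mm),
        box=box,
    )


def make_pet4d(
    vessel_mask: VolumeImage,
    blood: TimeActivityCurve,
    tissue: TimeActivityCurve,
) -> VolumeImage:
    """Toy dynamic volume: blood curve inside the vessel, tissue elsewhere."""
    if blood.schedule != tissue.schedule:
        raise ValueError("blood and tissue curves must share one schedule")
    m = vessel_mask.data.astype(bool)
    data = np.empty((*m.shape, blood.schedule.F), dtype=np.float32)
    data[:] = tissue.values.astype(np.float32)
    data[m] = blood.values.astype(np.float32)
    return VolumeImage(data, vessel_mask.voxel_size_mm, schedule=blood.schedule)
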