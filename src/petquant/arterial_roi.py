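"""Arterial-ROI construction from a vessel mask: PSF smoothing,
volume-targeted thresholding, background shell, TAC extraction, and the
partial-volume recovery coefficient."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tac_core import FrameSchedule, TimeActivityCurve

__all__ = [
    "VolumeImage",
    "segment_vessels_simple",
    "smooth_to_pet_resolution",
    "threshold_to_volume",
    "build_roi_pair",
    "extract_tac",
    "recovery_coefficient",
    "FWHM_TO_SIGMA",
]

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
MM3_PER_CC = 1000.0


@dataclass(frozen=True)
class VolumeImage:
    """3-D (or 4-D dynamic) voxel grid with physical voxel size in mm.

    For 4-D data the last axis is time and ``schedule`` gives the frame
    timing.  Masks are any volume whose data is boolean or {0, 1}.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if data.ndim not in (3, 4):
            raise ValueError("volume must be 3-D or 4-D")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be three positive numbers (mm)")
        if data.ndim == 4 and self.schedule is not None and data.shape[3] != self.schedule.F:
            raise ValueError("4-D volume frame count does not match schedule")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def is_mask(self) -> bool:
        return self.data.dtype == bool or set(np.unique(self.data)).issubset({0, 1})

    def volume_cc(self) -> float:
        """Physical volume of the nonzero voxels, in cc (1 cc = 1000 mm³)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_mm3 / MM3_PER_CC

    @classmethod
    def from_nifti(cls, path, schedule: FrameSchedule | None = None) -> "VolumeImage":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj), tuple(float(z) for z in zooms), schedule)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        data = self.data.astype(np.uint8) if self.is_mask() else self.data.astype(np.float32)
        nib.save(nib.Nifti1Image(data, affine), str(path))


def _require_3d(vol: VolumeImage, what: str) -> None:
    if vol.data.ndim != 3:
        raise ValueError(f"{what} must be a 3-D volume")


def segment_vessels_simple(
    mra: VolumeImage,
    percentile: float = 99.0,
    brain_mask: VolumeImage | None = None,
    keep_components: int = 1,
) -> VolumeImage:
    """Threshold-based vessel segmentation of an angiography-like volume.

    Keeps voxels at or above the given intensity percentile (computed within
    the brain mask when one is supplied), then retains the
    ``keep_components`` largest connected components.
    """
    _require_3d(mra, "intensity image")
    data = mra.data.astype(float)
    domain = np.ones(data.shape, bool)
    if brain_mask is not None:
        if brain_mask.data.shape != data.shape:
            raise ValueError("brain mask shape mismatch")
        domain = brain_mask.data.astype(bool)
    thr = np.percentile(data[domain], percentile)
    mask = (data >= thr) & domain
    if not mask.any():
        raise RuntimeError("vessel segmentation produced an empty mask")
    labels, n = ndimage.label(mask)
    if n > keep_components:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[::-1][:keep_components] + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise RuntimeError("vessel segmentation produced an empty mask")
    return VolumeImage(mask.astype(np.uint8), mra.voxel_size_mm)


def smooth_to_pet_resolution(
    mask: VolumeImage,
    fwhm_mm: float = 8.0,
    mode: str = "constant",
    truncate: float = 6.0,
) -> VolumeImage:
    """Gaussian-smooth a binary mask to scanner resolution.

    σ = FWHM/(2·√(2 ln 2)) per axis, converted from mm to voxels.  The
    default boundary mode is zero-padding, which preserves total signal for
    interior structures.
    """
    _require_3d(mask, "mask")
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in mask.voxel_size_mm]
    sm = ndimage.gaussian_filter(
        mask.data.astype(float), sigma=sigma_vox, mode=mode, cval=0.0, truncate=truncate
    )
    return VolumeImage(sm, mask.voxel_size_mm)


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(int(a), int(b)) for a, b in box)  # type: ignore[return-value]


def threshold_to_volume(
    smoothed: VolumeImage,
    target_cc: float,
    box: Box | None = None,
) -> tuple[VolumeImage, float]:
    """Find the threshold whose supra-threshold volume best matches a target.

    The threshold search is restricted to the rectangular voxel-index box
    when one is given (the resulting mask is confined to the box).  Returns
    the mask and the threshold; achievable volumes are the strict-drop
    points of the sorted intensity list, and a solution farther than one
    voxel from the target raises a range error.
    """
    _require_3d(smoothed, "smoothed volume")
    if target_cc <= 0:
        raise ValueError("target_cc must be positive")
    vox_cc = smoothed.voxel_volume_mm3 / MM3_PER_CC
    region = smoothed.data[_box_slices(box)] if box is not None else smoothed.data
    if region.size == 0:
        raise ValueError("empty box")
    vals = np.sort(region.ravel())[::-1]
    n_target = target_cc / vox_cc

    # counts n achievable with a strict threshold: vals[n-1] > vals[n]
    achievable = np.flatnonzero(vals[:-1] > vals[1:]) + 1
    achievable = np.concatenate([achievable, [vals.size]])
    best_idx = int(np.argmin(np.abs(achievable - n_target)))
    # tie -> higher threshold, i.e. the smaller count
    if best_idx > 0 and abs(achievable[best_idx - 1] - n_target) == abs(
        achievable[best_idx] - n_target
    ):
        best_idx -= 1
    n = int(achievable[best_idx])
    if abs(n - n_target) * vox_cc > vox_cc + 1e-9:
        lo_cc = achievable[achievable <= n_target]
        hi_cc = achievable[achievable >= n_target]
        attainable = (
            float(lo_cc[-1] * vox_cc) if lo_cc.size else 0.0,
            float(hi_cc[0] * vox_cc) if hi_cc.size else float(vals.size * vox_cc),
        )
        raise ValueError(
            f"target volume {target_cc} cc unreachable within one voxel; "
            f"nearest attainable volumes are {attainable} cc"
        )
    thr = float(vals[n]) if n < vals.size else float(np.nextafter(vals[-1], -np.inf))
    mask = np.zeros(smoothed.data.shape, np.uint8)
    if box is not None:
        sl = _box_slices(box)
        mask[sl] = (smoothed.data[sl] > thr).astype(np.uint8)
    else:
        mask = (smoothed.data > thr).astype(np.uint8)
    return VolumeImage(mask, smoothed.voxel_size_mm), thr


def build_roi_pair(
    smoothed: VolumeImage,
    box: Box,
    cc_a: float = 16.0,
    cc_b: float = 100.0,
) -> tuple[VolumeImage, VolumeImage]:
    """Arterial ROI (high threshold, inside the box) and background shell.

    ROIa targets ``cc_a`` within the box; a lower global threshold yields a
    ``cc_b`` volume (ROIb) and BG = ROIb minus ROIa.
    """
    if cc_b < cc_a:
        raise ValueError("cc_b must be >= cc_a")
    roia, thr_a = threshold_to_volume(smoothed, cc_a, box)
    roib, thr_b = threshold_to_volume(smoothed, cc_b, None)
    if not np.all(roib.data[roia.data > 0] > 0):
        log.warning("ROIa is not fully contained in ROIb")
    bg = (roib.data.astype(bool) & ~roia.data.astype(bool)).astype(np.uint8)
    if not bg.any():
        log.warning("background mask is empty (cc_a ~ cc_b degenerate case)")
    log.info("ROI thresholds: ROIa %.6g, ROIb %.6g", thr_a, thr_b)
    return roia, VolumeImage(bg, smoothed.voxel_size_mm)


def extract_tac(
    pet4d: VolumeImage, mask: VolumeImage, role: str = "tissue"
) -> TimeActivityCurve:
    """Per-frame unweighted mean of the dynamic volume over the mask voxels."""
    if pet4d.data.ndim != 4:
        raise ValueError("dynamic volume must be 4-D")
    if pet4d.schedule is None:
        raise ValueError("dynamic volume needs a frame schedule")
    if mask.data.shape != pet4d.data.shape[:3] or mask.voxel_size_mm != pet4d.voxel_size_mm:
        raise ValueError("mask grid does not match the dynamic volume")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    values = pet4d.data[m].mean(axis=0)
    return TimeActivityCurve(pet4d.schedule, values, role=role)


def recovery_coefficient(
    vessel_mask: VolumeImage,
    roia: VolumeImage,
    fwhm_mm: float = 8.0,
    mode: str = "constant",
    truncate: float = 6.0,
) -> float:
    """Partial-volume recovery coefficient of the arterial ROI.

    Mean, over ROIa voxels, of the vessel mask convolved with the scanner
    PSF (isotropic Gaussian of the given FWHM).  Lies in (0, 1].
    """
    if vessel_mask.data.shape != roia.data.shape or vessel_mask.voxel_size_mm != roia.voxel_size_mm:
        raise ValueError("vessel mask and ROIa must share one grid")
    m = roia.data.astype(bool)
    if not m.any():
        raise ValueError("empty arterial ROI")
    sm = smooth_to_pet_resolution(vessel_mask, fwhm_mm, mode=mode, truncate=truncate)
    r = float(sm.data[m].mean())
    if not (0.0 < r <= 1.0 + 1e-12):
        raise RuntimeError(f"recovery coefficient {r} outside (0, 1]")
    return min(r, 1.0)
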