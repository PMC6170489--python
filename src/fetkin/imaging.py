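"""Static-image operations: SUV conversion, endpoint averaging, isocontour
segmentation, uptake metrics, and image-derived AIF extraction.

Conventions: images are numpy arrays indexed (x, y, z[, frame]) with 0-based
voxel indices; masks share the image grid (no world-space resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .curves import FrameSchedule, InputFunction

__all__ = [
    "SUVImage",
    "Segmentation",
    "suv_convert",
    "endpoint_static",
    "isocontour_segment",
    "uptake_metrics",
    "extract_input_function",
]


@dataclass
class SUVImage:
    """3-D standardized-uptake-value image (body-weight normalization)."""

    data: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    injected_activity_mbq: float | None = None
    body_weight_kg: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("SUV must be non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")


@dataclass
class Segmentation:
    mask: np.ndarray
    label: str = "lesion"
    threshold: float | None = None  # provenance: absolute threshold applied

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("segmentation is empty")


def suv_convert(activity_image: np.ndarray, injected_activity_mbq: float,
                body_weight_kg: float, spacing_mm=(1.0, 1.0, 1.0)) -> SUVImage:
    """Activity concentration (kBq/ml) -> SUV by body-weight normalization.

    SUV = C / (injected activity / body weight); with C in kBq/ml, activity
    in MBq and weight in kg the unit factors cancel (1 g/ml tissue density).
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be positive")
    img = np.asarray(activity_image, dtype=float)
    suv = img * body_weight_kg / injected_activity_mbq
    return SUVImage(suv, spacing_mm, injected_activity_mbq, body_weight_kg)


def endpoint_static(dynamic_image: np.ndarray, schedule: FrameSchedule,
                    window_min: float = 10.0) -> np.ndarray:
    """Duration-weighted average of the frames in the last ``window_min``
    minutes of the acquisition (frames whose midpoint lies in the window).

    On the clinical schedule the 10-min window selects exactly the last two
    300-s frames.
    """
    dyn = np.asarray(dynamic_image, dtype=float)
    if dyn.shape[-1] != schedule.n:
        raise ValueError("frame axis must match the schedule")
    t_end = schedule.total_end_s
    window_s = window_min * 60.0
    if window_s > t_end:
        raise ValueError("window exceeds the acquisition")
    sel = schedule.midpoints_s >= t_end - window_s
    w = schedule.durations_s[sel]
    return np.tensordot(dyn[..., sel], w / w.sum(), axes=([-1], [0]))


def isocontour_segment(image: np.ndarray, fraction: float = 0.70,
                       seed_region: np.ndarray | None = None,
                       label: str = "I70") -> Segmentation:
    """Threshold at ``fraction`` of the reference maximum, keeping the
    largest 26-connected component.

    The reference maximum is the global image maximum, or the maximum within
    ``seed_region`` when given.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    img = np.asarray(image, dtype=float)
    ref = float(img[np.asarray(seed_region, dtype=bool)].max()) if seed_region is not None \
        else float(img.max())
    thr = fraction * ref
    mask = img >= thr
    if not mask.any():
        raise ValueError("isocontour produced an empty mask")
    structure = np.ones((3,) * img.ndim, dtype=bool)  # 26-connectivity in 3-D
    labels, n = ndimage.label(mask, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return Segmentation(mask, label=label, threshold=thr)


def uptake_metrics(suv: SUVImage, lesion: Segmentation,
                   background: Segmentation) -> tuple[float, float, float]:
    """(SUV_max, SUV_bg, SUR): lesion maximum, background mean, and their ratio."""
    if (lesion.mask & background.mask).any():
        raise ValueError("lesion and background masks must be disjoint")
    suv_max = float(suv.data[lesion.mask].max())
    suv_bg = float(suv.data[background.mask].mean())
    if suv_bg == 0:
        raise ValueError("background uptake is zero")
    return suv_max, suv_bg, suv_max / suv_bg


def extract_input_function(dynamic_image: np.ndarray, artery_mask: np.ndarray,
                           schedule: FrameSchedule, plasma_factor: float = 0.10,
                           top_k_by_peak: int | None = None) -> InputFunction:
    """Image-derived AIF: per-frame mean over artery voxels, converted from
    whole blood to plasma by a fixed fractional factor.

    ``top_k_by_peak`` optionally restricts the average to the k voxels with
    the highest peak activity (partial-volume mitigation near the vessel
    centre).
    """
    dyn = np.asarray(dynamic_image, dtype=float)
    mask = np.asarray(artery_mask, dtype=bool)
    if not mask.any():
        raise ValueError("artery mask is empty")
    if dyn.shape[-1] != schedule.n or mask.shape != dyn.shape[:-1]:
        raise ValueError("image, mask and schedule are inconsistent")
    tacs = dyn[mask]  # (n_voxels, n_frames)
    if top_k_by_peak is not None and top_k_by_peak < tacs.shape[0]:
        order = np.argsort(tacs.max(axis=1))[::-1]
        tacs = tacs[order[:top_k_by_peak]]
    whole_blood = tacs.mean(axis=0)
    whole_blood = np.clip(whole_blood, 0.0, None)
    plasma = whole_blood * (1.0 + plasma_factor)
    return InputFunction(schedule, plasma, state="plasma")
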