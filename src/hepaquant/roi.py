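"""ROI protocols and the RE / FFQ biomarkers.

Two aggregation protocols are supported, mirroring common liver-T1rho
reading practice:

* **circular right-lobe ROIs** (``circular_rll``) — up to three circular
  ROIs of 2–3 cm diameter per slice on up to two slices (six total),
  placed in vessel-free parenchyma; the biomarker is the unweighted mean
  of per-ROI means ("T1rho-cROI").
* **whole-liver ROI** (``whole_liver``) — one ROI covering the liver on
  each slice, eroded ~1 cm from the organ edge, with vessels and
  tumor/ablation areas excluded; the biomarker is the mean across slices
  ("T1rho-wl").

Relative enhancement compares hepatobiliary-phase to unenhanced signal on
whole-liver ROIs, ``RE = (SI_post - SI_pre) / SI_pre``, and the fibrosis
function quotient divides the morphological by the functional marker,
``FFQ = T1rho-cROI / RE`` (ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .relaxometry import T1RhoMapResults

CIRCULAR_KIND = "circular_rll"
WHOLE_LIVER_KIND = "whole_liver"

#: Default circular-ROI diameter (the protocol uses 2-3 cm).
DEFAULT_CROI_DIAMETER_MM = 25.0
#: Default liver-edge margin maintained by both protocols.
DEFAULT_EDGE_MARGIN_MM = 10.0


@dataclass(frozen=True)
class Roi:
    label: str
    slice_id: str
    mask: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class RoiSet:
    """A labelled collection of pixel masks of one protocol kind.

    ``exclusion_mask`` marks pixels that must never contribute (vessels,
    tumor/ablation areas, the eroded edge margin); ROIs are required not to
    overlap it.
    """

    rois: tuple[Roi, ...]
    kind: str
    exclusion_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        if self.kind not in (CIRCULAR_KIND, WHOLE_LIVER_KIND):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if not self.rois:
            raise ValueError("RoiSet needs at least one ROI")
        shape = self.exclusion_mask.shape
        for roi in self.rois:
            if roi.mask.shape != shape:
                raise ValueError(f"ROI {roi.label!r} shape mismatch")
            if not roi.mask.any():
                raise ValueError(f"ROI {roi.label!r} is empty")
            if (roi.mask & self.exclusion_mask).any():
                raise ValueError(f"ROI {roi.label!r} intersects the exclusion mask")
        slices = {}
        for roi in self.rois:
            slices.setdefault(roi.slice_id, []).append(roi)
        if self.kind == CIRCULAR_KIND:
            if len(slices) > 2 or any(len(v) > 3 for v in slices.values()):
                raise ValueError("circular protocol allows <=3 ROIs per slice on <=2 slices")
        else:
            if any(len(v) != 1 for v in slices.values()):
                raise ValueError("whole-liver protocol allows exactly 1 ROI per slice")

    @property
    def slice_ids(self) -> list[str]:
        out: list[str] = []
        for roi in self.rois:
            if roi.slice_id not in out:
                out.append(roi.slice_id)
        return out


class RoiMean(NamedTuple):
    mean: float
    n_pixels: int


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def erode_margin(mask: np.ndarray, margin_mm: float, pixel_spacing_mm: float) -> np.ndarray:
    """Shrink a liver mask by a physical margin (morphological erosion).

    Reproducible surrogate for the manual "stay ~1 cm from the liver edge"
    rule; the structuring element is a disk of the margin radius.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    r_px = int(round(margin_mm / pixel_spacing_mm))
    if r_px == 0:
        return mask.copy()
    selem = disk_mask((2 * r_px + 1, 2 * r_px + 1), (r_px, r_px), r_px)
    return ndimage.binary_erosion(mask, structure=selem, border_value=0)


def roi_mean(
    values: np.ndarray,
    roi: Roi | np.ndarray,
    valid_mask: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> RoiMean:
    """Arithmetic mean of ``values`` over the usable pixels of one ROI.

    Usable pixels are the ROI minus the exclusion mask, intersected with
    ``valid_mask`` (e.g. the relaxometry validity map).  Raises if nothing
    usable remains, naming the ROI.
    """
    if isinstance(roi, Roi):
        label, mask = roi.label, roi.mask
    else:
        label, mask = "<anonymous>", np.asarray(roi, dtype=bool)
    eff = mask.copy()
    if exclusion_mask is not None:
        eff &= ~exclusion_mask
    if valid_mask is not None:
        eff &= valid_mask
    n = int(eff.sum())
    if n == 0:
        raise ValueError(f"ROI {label!r} has no usable pixels")
    return RoiMean(mean=float(np.asarray(values, dtype=float)[eff].mean()), n_pixels=n)


def _as_map_and_valid(map_like) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(map_like, T1RhoMapResults):
        return map_like.t1rho, map_like.valid_mask
    if isinstance(map_like, tuple) and len(map_like) == 2:
        values, valid = map_like
        return np.asarray(values, dtype=float), np.asarray(valid, dtype=bool)
    return np.asarray(map_like, dtype=float), None


def aggregate_croi(map_like, rois: RoiSet, method: str = "mean_of_means") -> float:
    """T1rho-cROI: aggregate circular-ROI means into one value (ms).

    ``mean_of_means`` (default) treats each ROI as one observation;
    ``pooled`` averages over all contributing pixels instead.  The two
    coincide exactly when all ROIs contain the same number of pixels.
    """
    if rois.kind != CIRCULAR_KIND:
        raise ValueError(f"aggregate_croi requires kind={CIRCULAR_KIND!r}, got {rois.kind!r}")
    return _aggregate(map_like, rois, method)


def aggregate_wl(map_like, rois: RoiSet, method: str = "mean_of_means") -> float:
    """T1rho-wl: mean whole-liver value across slices (ms)."""
    if rois.kind != WHOLE_LIVER_KIND:
        raise ValueError(f"aggregate_wl requires kind={WHOLE_LIVER_KIND!r}, got {rois.kind!r}")
    return _aggregate(map_like, rois, method)


def _aggregate(map_like, rois: RoiSet, method: str) -> float:
    values, valid = _as_map_and_valid(map_like)
    per_roi = [
        roi_mean(values, roi, valid_mask=valid, exclusion_mask=rois.exclusion_mask)
        for roi in rois.rois
    ]
    if method == "mean_of_means":
        return float(np.mean([m.mean for m in per_roi]))
    if method == "pooled":
        total = sum(m.mean * m.n_pixels for m in per_roi)
        count = sum(m.n_pixels for m in per_roi)
        return float(total / count)
    raise ValueError(f"unknown aggregation method {method!r}")


def compute_re(
    pre_images: "np.ndarray | Sequence[np.ndarray]",
    post_images: "np.ndarray | Sequence[np.ndarray]",
    rois: RoiSet,
) -> float:
    """Relative enhancement from whole-liver ROI means.

    ``pre_images`` / ``post_images`` are one image per slice (a single 2D
    array is accepted for a one-slice study).  SI_pre and SI_post are each
    the average across slices of the per-slice whole-liver ROI mean; RE is
    ``(SI_post - SI_pre) / SI_pre``.
    """
    if rois.kind != WHOLE_LIVER_KIND:
        raise ValueError("compute_re requires whole-liver ROIs")
    pre_list = _as_image_list(pre_images)
    post_list = _as_image_list(post_images)
    if len(pre_list) != len(post_list):
        raise ValueError("pre/post slice counts differ")
    if len(pre_list) != len(rois.rois):
        raise ValueError(
            f"{len(rois.rois)} whole-liver ROIs for {len(pre_list)} slices"
        )
    for a, b in zip(pre_list, post_list):
        if a.shape != b.shape:
            raise ValueError("pre/post images are not co-registered (shape mismatch)")
    si_pre = float(np.mean([
        roi_mean(img, roi, exclusion_mask=rois.exclusion_mask).mean
        for img, roi in zip(pre_list, rois.rois)
    ]))
    si_post = float(np.mean([
        roi_mean(img, roi, exclusion_mask=rois.exclusion_mask).mean
        for img, roi in zip(post_list, rois.rois)
    ]))
    if si_pre <= 0:
        raise ValueError(f"unenhanced signal must be positive, got SI_pre={si_pre}")
    return (si_post - si_pre) / si_pre


def _as_image_list(images) -> list[np.ndarray]:
    arr = np.asarray(images, dtype=float) if not isinstance(images, (list, tuple)) else images
    if isinstance(arr, np.ndarray):
        if arr.ndim == 2:
            return [arr]
        if arr.ndim == 3:
            return list(arr)
        raise ValueError("images must be 2D or a stack of 2D slices")
    return [np.asarray(a, dtype=float) for a in arr]


def compute_ffq(t1rho_croi: float, re: float) -> float:
    """Fibrosis function quotient, ``T1rho-cROI / RE`` (ms).

    Propagates NaN if either input is undefined; a non-positive RE is an
    error (the quotient is only meaningful for enhancing liver).
    """
    if np.isnan(t1rho_croi) or np.isnan(re):
        return float("nan")
    if re <= 0:
        raise ValueError(f"RE must be > 0 to form FFQ, got {re}")
    return t1rho_croi / re


def build_phantom_rois(
    shape: tuple[int, int],
    pixel_spacing_mm: float,
    vessel_mask: np.ndarray | None = None,
    slice_ids: Sequence[str] = ("cranial", "caudal"),
    croi_diameter_mm: float = DEFAULT_CROI_DIAMETER_MM,
    edge_margin_mm: float = DEFAULT_EDGE_MARGIN_MM,
    liver_mask: np.ndarray | None = None,
) -> tuple[RoiSet, RoiSet]:
    """Place the two ROI protocols automatically on a phantom.

    Three circular ROIs per slice go in the right half of the grid
    (anterior / central / posterior positions); the whole-liver ROI is the
    liver mask eroded by the edge margin.  Vessel pixels are put on the
    exclusion mask, and circular ROIs are shifted off any excluded pixel
    rather than overlapping it (mirroring how a reader avoids vessels).
    Returns ``(circular_set, whole_liver_set)``.
    """
    if liver_mask is None:
        liver_mask = np.ones(shape, dtype=bool)
    exclusion = np.zeros(shape, dtype=bool)
    if vessel_mask is not None:
        exclusion |= vessel_mask
    eroded = erode_margin(liver_mask, edge_margin_mm, pixel_spacing_mm)
    exclusion_wl = exclusion | ~eroded

    r_px = max(1.0, croi_diameter_mm / 2.0 / pixel_spacing_mm)
    nr, nc = shape
    col = 0.70 * (nc - 1)  # right lobe = right half of the grid
    anchors = [0.25, 0.50, 0.75]
    circ_rois = []
    for sid in slice_ids:
        for name, frac in zip(("anterior", "central", "posterior"), anchors):
            center = _find_clear_center(
                shape, (frac * (nr - 1), col), r_px, exclusion_wl
            )
            if center is None:
                continue
            circ_rois.append(
                Roi(label=f"{sid}_{name}", slice_id=sid, mask=disk_mask(shape, center, r_px))
            )
    circular = RoiSet(rois=tuple(circ_rois), kind=CIRCULAR_KIND, exclusion_mask=exclusion_wl)

    wl_mask = eroded & ~exclusion
    wl_rois = tuple(
        Roi(label=f"{sid}_whole_liver", slice_id=sid, mask=wl_mask.copy())
        for sid in slice_ids
    )
    whole = RoiSet(rois=wl_rois, kind=WHOLE_LIVER_KIND, exclusion_mask=np.zeros(shape, dtype=bool))
    return circular, whole


def _find_clear_center(shape, center, radius, exclusion) -> tuple[float, float] | None:
    """Nudge a candidate ROI center until its disk avoids excluded pixels."""
    r0, c0 = center
    for dr in np.arange(0.0, max(shape) / 2, max(1.0, radius / 2)):
        for sr in (+1, -1):
            for dc in np.arange(0.0, shape[1] / 4, max(1.0, radius / 2)):
                for sc in (+1, -1):
                    rr, cc = r0 + sr * dr, c0 + sc * dc
                    if not (radius <= rr <= shape[0] - 1 - radius):
                        continue
                    if not (radius <= cc <= shape[1] - 1 - radius):
                        continue
                    disk = disk_mask(shape, (rr, cc), radius)
                    if not (disk & exclusion).any():
                        return (rr, cc)
    return None
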