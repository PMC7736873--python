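"""Automated phantom ROI placement and HMR computation.

The HMR is the mean count per pixel in a circular cardiac ROI divided by
the mean count per pixel in a rectangular upper-mediastinal ROI (means,
not sums, so the ratio is independent of ROI pixel count for homogeneous
regions). ROI sizes are fixed in physical units — a 25 mm radius heart
disc and a 20 x 60 mm mediastinal box — and converted to pixels via the
image pixel pitch.

Automatic placement on phantom images proceeds in three steps: the body
outline is thresholded at 5% of the 99th-percentile count; the heart is
located with a disc-template search restricted to the upper body half on
the heart side of the midline, taking the centroid of near-maximal
template positions (exact on the flat plateau of an ideal rendering and
stable under Poisson noise); the mediastinal box is placed on the body
midline at a fixed offset below the detected body top. All constants are
configurable keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .phantom import ActivityMap
from .simulate import CountImage

#: Default automatic-ROI constants (physical units). The body threshold
#: sits midway between the off-body level (~0) and the body-background
#: level (~10% of the 99th percentile), so the outline is stable under
#: count quantization and Poisson noise.
BODY_THRESHOLD_FRAC = 0.05
HEART_ROI_RADIUS_MM = 25.0
MED_ROI_WIDTH_MM = 20.0
MED_ROI_HEIGHT_MM = 60.0
MED_ROI_TOP_OFFSET_MM = 60.0
HEART_CORE_FRAC = 0.85


@dataclass(frozen=True)
class ROISet:
    """Heart disc + mediastinal rectangle, in 0-based pixel coordinates."""

    heart_center: tuple[int, int]  # (row, col)
    heart_radius_px: float
    med_top_left: tuple[int, int]  # (row, col)
    med_height_px: int
    med_width_px: int

    def heart_mask(self, shape: tuple[int, int]) -> np.ndarray:
        r0, c0 = self.heart_center
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        return (rows - r0) ** 2 + (cols - c0) ** 2 <= self.heart_radius_px**2

    def med_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        r, c = self.med_top_left
        mask[r : r + self.med_height_px, c : c + self.med_width_px] = True
        return mask

    def validate(self, shape: tuple[int, int]) -> None:
        heart = self.heart_mask(shape)
        med = self.med_mask(shape)
        r0, c0 = self.heart_center
        rad = self.heart_radius_px
        if (
            r0 - rad < 0
            or c0 - rad < 0
            or r0 + rad >= shape[0]
            or c0 + rad >= shape[1]
        ):
            raise ValueError("heart ROI extends outside the image")
        r, c = self.med_top_left
        if r < 0 or c < 0 or r + self.med_height_px > shape[0] or c + self.med_width_px > shape[1]:
            raise ValueError("mediastinal ROI extends outside the image")
        if heart.sum() < 20 or med.sum() < 20:
            raise ValueError("each ROI must contain at least 20 pixels")
        if (heart & med).any():
            raise ValueError("heart and mediastinal ROIs overlap")

    def to_dict(self) -> dict:
        return {
            "heart_center": list(self.heart_center),
            "heart_radius_px": self.heart_radius_px,
            "med_top_left": list(self.med_top_left),
            "med_height_px": self.med_height_px,
            "med_width_px": self.med_width_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROISet":
        return cls(
            tuple(d["heart_center"]),
            float(d["heart_radius_px"]),
            tuple(d["med_top_left"]),
            int(d["med_height_px"]),
            int(d["med_width_px"]),
        )


@dataclass
class HMRResult:
    """HMR and the per-ROI mean counts it was computed from."""

    hmr: float
    heart_mean: float
    mediastinum_mean: float
    rois: ROISet = field(repr=False)


def compute_hmr(image: CountImage, rois: ROISet) -> HMRResult:
    """Mean counts/pixel in the heart ROI over the mediastinal ROI."""
    counts = np.asarray(image.counts, dtype=float)
    rois.validate(counts.shape)
    heart_mean = float(counts[rois.heart_mask(counts.shape)].mean())
    med_mean = float(counts[rois.med_mask(counts.shape)].mean())
    if med_mean <= 0:
        raise ValueError("mediastinal ROI mean is zero; cannot form a ratio")
    return HMRResult(heart_mean / med_mean, heart_mean, med_mean, rois)


def _disc_kernel(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    rows, cols = np.ogrid[-r : r + 1, -r : r + 1]
    disc = (rows**2 + cols**2 <= radius_px**2).astype(float)
    return disc / disc.sum()


def auto_roi_phantom(
    image: CountImage,
    view: str,
    *,
    body_threshold_frac: float = BODY_THRESHOLD_FRAC,
    heart_radius_mm: float = HEART_ROI_RADIUS_MM,
    med_width_mm: float = MED_ROI_WIDTH_MM,
    med_height_mm: float = MED_ROI_HEIGHT_MM,
    med_top_offset_mm: float = MED_ROI_TOP_OFFSET_MM,
    heart_core_frac: float = HEART_CORE_FRAC,
) -> ROISet:
    """Place the heart and mediastinal ROIs automatically on a phantom image.

    Raises ``ValueError`` if no body outline can be found (empty or
    effectively uniform image). In the anterior view the heart is sought
    left of the midline; the posterior view mirrors the search side.
    """
    if view not in ("anterior", "posterior"):
        raise ValueError(f"unknown view {view!r}")
    counts = np.asarray(image.counts, dtype=float)
    if counts.size == 0 or counts.max() <= 0:
        raise ValueError("unusable image: no counts")
    pixel = image.pixel_size_mm

    # Body outline on a lightly smoothed image (averages Poisson noise),
    # keeping only the largest connected component so stray haze counts
    # far from the body cannot stretch the bounding box.
    smooth_sigma_px = 5.0 / pixel
    smoothed = ndimage.gaussian_filter(counts, smooth_sigma_px)
    p99 = np.percentile(smoothed, 99)
    threshold = body_threshold_frac * p99
    if threshold <= 0:
        raise ValueError("unusable image: no body outline found")
    body = smoothed >= threshold
    labels, n_labels = ndimage.label(body)
    if n_labels > 1:
        sizes = ndimage.sum_labels(body, labels, index=np.arange(1, n_labels + 1))
        body = labels == (1 + int(np.argmax(sizes)))
    frac = body.mean()
    if frac < 0.05 or frac > 0.97:
        raise ValueError(
            "unusable image: body outline covers "
            f"{frac:.0%} of the field of view"
        )
    body_rows = np.flatnonzero(body.any(axis=1))
    body_cols = np.flatnonzero(body.any(axis=0))
    rmin, rmax = int(body_rows[0]), int(body_rows[-1])
    cmin, cmax = int(body_cols[0]), int(body_cols[-1])
    midcol = 0.5 * (cmin + cmax)

    # --- heart: disc-template search in the upper body half, heart side ---
    radius_px = heart_radius_mm / pixel
    template = signal.fftconvolve(counts, _disc_kernel(radius_px), mode="same")
    search = np.zeros_like(body)
    upper = rmin + int(round(0.5 * (rmax - rmin)))
    if view == "anterior":
        search[rmin : upper + 1, cmin : int(np.floor(midcol)) + 1] = True
    else:
        search[rmin : upper + 1, int(np.ceil(midcol)) : cmax + 1] = True
    masked = np.where(search, template, -np.inf)
    peak = masked.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("unusable image: heart search region is empty")
    core = masked >= heart_core_frac * peak
    rows_sel, cols_sel = np.nonzero(core)
    heart_center = (int(round(rows_sel.mean())), int(round(cols_sel.mean())))

    # --- mediastinum: midline box at a fixed offset below the body top ---
    med_w = max(1, int(round(med_width_mm / pixel)))
    med_h = max(1, int(round(med_height_mm / pixel)))
    med_top = rmin + int(round(med_top_offset_mm / pixel))
    med_left = int(round(midcol)) - med_w // 2

    rois = ROISet(heart_center, radius_px, (med_top, med_left), med_h, med_w)
    rois.validate(counts.shape)
    return rois


def reference_roiset(activity: ActivityMap, matrix: int | None = None) -> ROISet:
    """ROISet at the phantom's exact reference geometry, scaled to a matrix.

    Used where ROI-placement variability should be excluded (e.g. the
    collimator-design sweep).
    """
    n = matrix or activity.shape[0]
    pixel = activity.pixel_size_mm * activity.shape[0] / n
    rois = activity.phantom.reference_rois()
    hx, hy, hr = rois["heart"]
    mx0, mx1, my0, my1 = rois["mediastinum"]

    def to_px(mm: float) -> int:
        return int(round(mm / pixel - 0.5))

    return ROISet(
        heart_center=(to_px(hy), to_px(hx)),
        heart_radius_px=hr / pixel,
        med_top_left=(to_px(my0), to_px(mx0)),
        med_height_px=max(1, int(round((my1 - my0) / pixel))),
        med_width_px=max(1, int(round((mx1 - mx0) / pixel))),
    )
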