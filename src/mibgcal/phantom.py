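"""Digital analogue of the acrylic HMR calibration phantom.

The physical phantom is a flat 380 × 380 × 50 mm acrylic slab whose
compartments (heart, mediastinum, liver, lungs, thyroid, body background)
hold activity concentrations tuned so that the heart-to-mediastinum ratio
presented to the camera is *designated*: 2.60 in the anterior view and
3.50 in the posterior view. Because the calibration mathematics consumes
only the two per-view measured HMRs, each view is modelled here as an
independent 2D relative-activity map; the anterior/posterior difference
is baked into the per-view heart density rather than into depth-dependent
attenuation. The posterior layout is the left–right mirror of the
anterior one (row 0 = superior; column 0 = patient-right in the anterior
view).

Compartment shapes are this module's own simple geometry (the designated
ratios are the only normative constraint); every density other than the
heart/mediastinum pair is merely plausible scenery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Physical side length of the phantom, mm.
EXTENT_MM = 380.0

#: Designated heart-to-mediastinum ratios per view.
DESIGNATED_HMR = {"anterior": 2.60, "posterior": 3.50}

#: Relative activity densities (mediastinum ≡ 1); the heart density is the
#: per-view designated ratio and is filled in at build time.
DEFAULT_DENSITIES = {
    "background": 0.3,
    "lungs": 0.5,
    "mediastinum": 1.0,
    "thyroid": 2.0,
    "liver": 3.0,
}

# Anterior-view geometry in mm: (x = column direction, y = row direction).
_BODY = (40.0, 340.0, 30.0, 350.0)  # xmin, xmax, ymin, ymax
_THYROID = (190.0, 55.0, 25.0, 15.0)  # cx, cy, rx, ry
_MEDIASTINUM = (170.0, 210.0, 80.0, 160.0)  # 40 x 80 mm midline box
_LUNG_L = (110.0, 130.0, 38.0, 52.0)
_LUNG_R = (270.0, 130.0, 38.0, 52.0)
_HEART = (142.0, 175.0, 30.0)  # cx, cy, r — 60 mm disc left of midline
_LIVER = (90.0, 250.0, 255.0, 320.0)

# Reference ROIs used to define the designated ratio; strictly interior to
# their compartments so the ratio is exact at any admissible pixel size.
_REF_HEART = (142.0, 175.0, 25.0)  # cx, cy, r
_REF_MED = (180.0, 200.0, 90.0, 150.0)  # xmin, xmax, ymin, ymax


def designated_hmr(view: str) -> float:
    """Designated HMR of the calibration phantom for ``view``."""
    try:
        return DESIGNATED_HMR[view]
    except KeyError:
        raise ValueError(
            f"unknown view {view!r}: expected 'anterior' or 'posterior'"
        ) from None


def _grid(pixel_size_mm: float) -> tuple[int, np.ndarray, np.ndarray]:
    if pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    n = int(round(EXTENT_MM / pixel_size_mm))
    if n < 64:
        raise ValueError(
            f"pixel size {pixel_size_mm} mm too coarse: {n} < 64 pixels across"
        )
    centers = (np.arange(n) + 0.5) * pixel_size_mm
    x, y = np.meshgrid(centers, centers)  # x varies along columns
    return n, x, y


def _ellipse(x, y, cx, cy, rx, ry):
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _rect(x, y, xmin, xmax, ymin, ymax):
    return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)


@dataclass
class DigitalPhantom:
    """Rasterized compartment masks of the phantom for one view.

    Masks are mutually disjoint (painted in priority order heart >
    mediastinum > thyroid > lungs > liver > background) and their union
    is the body outline.
    """

    pixel_size_mm: float
    view: str
    masks: dict[str, np.ndarray] = field(repr=False)
    densities: dict[str, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks["background"].shape

    def reference_rois(self) -> dict[str, tuple]:
        """Reference heart disc (cx, cy, r) and mediastinal box (mm).

        Coordinates are in physical mm of this view (already mirrored for
        the posterior view).
        """
        hx, hy, hr = _REF_HEART
        mx0, mx1, my0, my1 = _REF_MED
        if self.view == "posterior":
            width = self.shape[1] * self.pixel_size_mm
            hx = width - hx
            mx0, mx1 = width - mx1, width - mx0
        return {"heart": (hx, hy, hr), "mediastinum": (mx0, mx1, my0, my1)}


@dataclass
class ActivityMap:
    """Noise-free relative-activity rendering of the phantom for one view."""

    values: np.ndarray = field(repr=False)
    pixel_size_mm: float
    view: str
    densities: dict[str, float]
    phantom: DigitalPhantom = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reference_roi_ratio(self) -> float:
        """Mean heart density / mean mediastinum density in the reference ROIs."""
        n, x, y = _grid(self.pixel_size_mm)
        rois = self.phantom.reference_rois()
        hx, hy, hr = rois["heart"]
        mx0, mx1, my0, my1 = rois["mediastinum"]
        heart = (x - hx) ** 2 + (y - hy) ** 2 <= hr**2
        med = _rect(x, y, mx0, mx1, my0, my1)
        return float(self.values[heart].mean() / self.values[med].mean())


def build_digital_phantom(
    pixel_size_mm: float, view: str, densities: dict[str, float] | None = None
) -> DigitalPhantom:
    """Rasterize the compartment masks and per-view densities."""
    ratio = designated_hmr(view)  # validates the view label
    n, x, y = _grid(pixel_size_mm)
    if view == "posterior":
        # mirror columns about the rendered grid (n·pixel wide, which can
        # differ from 380 mm by a fraction of a pixel) so the posterior
        # masks are exact array mirrors of the anterior ones
        x = n * pixel_size_mm - x

    body = _rect(x, y, *_BODY)
    heart = (x - _HEART[0]) ** 2 + (y - _HEART[1]) ** 2 <= _HEART[2] ** 2
    med = _rect(x, y, *_MEDIASTINUM)
    thyroid = _ellipse(x, y, *_THYROID)
    lungs = _ellipse(x, y, *_LUNG_L) | _ellipse(x, y, *_LUNG_R)
    liver = _rect(x, y, *_LIVER)

    # paint in priority order so masks are disjoint and inside the body
    masks: dict[str, np.ndarray] = {}
    taken = np.zeros_like(body)
    for name, m in [
        ("heart", heart),
        ("mediastinum", med),
        ("thyroid", thyroid),
        ("lungs", lungs),
        ("liver", liver),
    ]:
        m = m & body & ~taken
        masks[name] = m
        taken |= m
    masks["background"] = body & ~taken

    dens = dict(DEFAULT_DENSITIES)
    if densities:
        dens.update(densities)
    dens.setdefault("heart", ratio * dens["mediastinum"])
    if any(v < 0 for v in dens.values()):
        raise ValueError("compartment densities must be non-negative")
    return DigitalPhantom(pixel_size_mm, view, masks, dens)


def build_phantom(
    pixel_size_mm: float,
    view: str,
    densities: dict[str, float] | None = None,
) -> ActivityMap:
    """Render the noise-free activity map of the phantom for one view.

    Parameters
    ----------
    pixel_size_mm:
        Pixel pitch; must resolve the 380 mm extent into at least 64
        pixels (256 pixels at 1.485 mm).
    view:
        ``"anterior"`` or ``"posterior"``. The posterior layout is the
        left-right mirror of the anterior one and carries the posterior
        designated heart density.
    densities:
        Optional per-compartment density overrides (e.g. a uniform
        phantom with every compartment at 1.0). By default the heart
        density equals the view's designated HMR with mediastinum at 1.
    """
    phantom = build_digital_phantom(pixel_size_mm, view, densities)
    values = np.zeros(phantom.shape, dtype=float)
    for name, mask in phantom.masks.items():
        values[mask] = phantom.densities[name]
    return ActivityMap(values, pixel_size_mm, view, phantom.densities, phantom)
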