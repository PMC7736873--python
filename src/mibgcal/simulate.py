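"""Simplified planar gamma-camera simulator for the calibration phantom.

The full physics of 123I planar imaging — photon transport, energy
spectra, detector response — is deliberately out of scope. What the
calibration workflow needs is the *collimator-dependent degradation* of
the heart-to-mediastinum ratio, and that is captured with a three-part
analytic model:

1. geometric resolution of a parallel-hole collimator, a Gaussian PSF of
   FWHM ``d (L_eff + z) / L_eff`` (hole diameter ``d``, effective length
   ``L_eff = L - 2/mu_159``, source distance ``z``);
2. septal penetration of the 529 keV emission of 123I (branching 1.39%,
   against 83.3% for the 159 keV photopeak), modelled as a broad Gaussian
   haze (fixed 150 mm FWHM) carrying a fraction ``f`` of the counts,
   ``f`` determined by the minimal septal path ``w = L t / (2 d + t)``
   and the lead attenuation at 529 keV, scaled by a window-acceptance
   factor that grows with the photopeak window half-width;
3. Poisson counting noise at a total-count level set by activity,
   duration and a fixed sensitivity constant.

The model is claimed to reproduce the *directions* of the collimator and
acquisition effects (penetration haze lowers HMR; thin septa, wide holes,
short collimators and wide windows lower it further), not per-pixel
realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .phantom import EXTENT_MM, ActivityMap
from .window import EnergyWindow

#: 123I emission branching ratios (529 keV high-energy line, 159 keV photopeak).
BRANCHING_529 = 0.0139
BRANCHING_159 = 0.833

#: Default septal (lead) linear attenuation coefficients, per mm.
MU_159_PER_MM = 2.3
MU_529_PER_MM = 0.17

#: Penetration-haze FWHM, mm. The haze must be broad relative to the
#: phantom structures to act as a diffuse background that depresses the
#: measured HMR; a narrow haze merely redistributes counts locally (and
#: can even drain the mediastinal valley faster than the heart, raising
#: the ratio). Its width is a fixed physical scale — septal penetration
#: is a large-angle, detector-scale effect — which also keeps the
#: HMR response monotone in the penetration fraction.
HAZE_FWHM_MM = 150.0

#: Detected counts per MBq·s: 55.5 MBq for 300 s yields ~1.0e6 counts.
SENSITIVITY_CPS_PER_MBQ = 1.0e6 / (55.5 * 300.0)

#: Half-width (%) at which the window-acceptance factor is 1.
REFERENCE_HALFWIDTH_PCT = 7.5

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class CollimatorSpec:
    """Parallel-hole collimator geometry and septal attenuation.

    ``group`` is the multicenter collimator-class label (e.g. "LEHR",
    "MEGP") used by the database pipeline; it does not affect physics.
    """

    name: str
    hole_diameter_mm: float
    septal_thickness_mm: float
    length_mm: float
    group: str | None = None
    mu_159_per_mm: float = MU_159_PER_MM
    mu_529_per_mm: float = MU_529_PER_MM

    def __post_init__(self) -> None:
        d, t, L = self.hole_diameter_mm, self.septal_thickness_mm, self.length_mm
        if not (0.5 <= d <= 5.0):
            raise ValueError(f"hole diameter {d} mm outside [0.5, 5]")
        if not (0.05 <= t <= 2.0):
            raise ValueError(f"septal thickness {t} mm outside [0.05, 2]")
        if not (10.0 <= L <= 80.0):
            raise ValueError(f"collimator length {L} mm outside [10, 80]")
        if self.mu_159_per_mm <= 0 or self.mu_529_per_mm <= 0:
            raise ValueError("septal attenuation coefficients must be positive")


#: Representative collimator specs (hole/septa/length in mm).
COLLIMATORS = {
    "lehr": CollimatorSpec("LEHR", 1.11, 0.16, 24.05, group="LEHR"),
    "legp": CollimatorSpec("LEGP", 1.90, 0.30, 30.0, group="LEGP"),
    "lmegp": CollimatorSpec("LMEGP", 1.80, 0.40, 34.0, group="LMEGP"),
    "megp": CollimatorSpec("MEGP", 2.94, 1.14, 48.0, group="MEGP"),
}


@dataclass(frozen=True)
class AcquisitionSettings:
    """Acquisition protocol for one planar view."""

    window: EnergyWindow = EnergyWindow(159.0, 10.0)
    matrix: int = 256
    pixel_size_mm: float | None = None  # default: 380 mm / matrix
    duration_s: float = 300.0
    distance_mm: float = 30.0
    activity_mbq: float = 55.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.matrix not in (64, 128, 256, 512):
            raise ValueError(f"matrix {self.matrix} not in {{64, 128, 256, 512}}")
        if self.duration_s <= 0:
            raise ValueError("acquisition duration must be positive")
        if self.distance_mm < 0:
            raise ValueError("camera distance must be non-negative")
        if self.activity_mbq < 0:
            raise ValueError("activity must be non-negative")

    @property
    def pixel_mm(self) -> float:
        return self.pixel_size_mm or EXTENT_MM / self.matrix

    def with_seed(self, seed: int | None) -> "AcquisitionSettings":
        return replace(self, seed=seed)


@dataclass
class CountImage:
    """Planar count image plus the acquisition context that produced it."""

    counts: np.ndarray = field(repr=False)
    pixel_size_mm: float
    settings: AcquisitionSettings | None = None
    collimator: CollimatorSpec | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be integer")
        if c.size and c.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = c

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def geometric_fwhm(collimator: CollimatorSpec, distance_mm: float) -> float:
    """Geometric PSF FWHM (mm) of a parallel-hole collimator at a distance.

    Uses the effective length ``L_eff = L - 2/mu_159`` (clamped to at
    least ``L/2``) so that the FWHM equals the hole diameter at the
    collimator face and doubles at ``z = L_eff``.
    """
    if distance_mm < 0:
        raise ValueError("distance must be non-negative")
    L = collimator.length_mm
    L_eff = max(L - 2.0 / collimator.mu_159_per_mm, L / 2.0)
    return collimator.hole_diameter_mm * (L_eff + distance_mm) / L_eff


def window_acceptance(window: EnergyWindow) -> float:
    """Acceptance factor for down-scattered/penetrating high-energy events.

    Normalized to 1 at ±7.5% and linear in the half-width: wider windows
    accept more of the downscatter continuum under the photopeak.
    """
    return window.halfwidth_pct / REFERENCE_HALFWIDTH_PCT


def penetration_fraction(
    collimator: CollimatorSpec, window: EnergyWindow | None = None
) -> float:
    """Fraction of detected counts attributed to 529 keV septal penetration.

    The minimal septal path of a photon crossing one septum is
    ``w = L t / (2 d + t)``; the surviving high-energy intensity is
    weighted by the 529/159 keV branching ratios and the window
    acceptance. Monotone: decreasing in septal thickness and length,
    increasing in hole diameter and window half-width.
    """
    window = window or EnergyWindow()
    d = collimator.hole_diameter_mm
    t = collimator.septal_thickness_mm
    L = collimator.length_mm
    w = L * t / (2.0 * d + t)
    high = BRANCHING_529 * window_acceptance(window) * math.exp(
        -collimator.mu_529_per_mm * w
    )
    return high / (high + BRANCHING_159)


def _blur(values: np.ndarray, sigma_px: float) -> np.ndarray:
    if sigma_px <= 1e-6:
        return values
    return ndimage.gaussian_filter(values, sigma_px, mode="constant", cval=0.0)


def expected_image(
    activity: ActivityMap,
    collimator: CollimatorSpec | None,
    settings: AcquisitionSettings,
) -> tuple[np.ndarray, float]:
    """Expected (noise-free, unquantized) count image and its pixel size.

    ``E = S [ (1-f) G_geo * A + f G_haze * A ]`` with the total expected
    counts conserved exactly (counts blurred off the field of view are
    renormalized back). This is the Poisson mean that
    :func:`simulate_planar` draws from; it is also useful directly when
    count quantization would mask sub-count differences (e.g. the
    collimator-design sweep).
    """
    values = np.asarray(activity.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty activity map")

    pixel = settings.pixel_mm
    n = settings.matrix
    if values.shape != (n, n):
        zoom = n / values.shape[0]
        values = ndimage.zoom(values, zoom, order=1)
        pixel = activity.pixel_size_mm / zoom

    expected_total = (
        settings.activity_mbq * settings.duration_s * SENSITIVITY_CPS_PER_MBQ
    )
    if expected_total <= 0:
        raise ValueError("expected total counts must be positive")

    if collimator is None:
        shape = values
    else:
        fwhm = geometric_fwhm(collimator, settings.distance_mm)
        sigma_px = fwhm * _FWHM_TO_SIGMA / pixel
        f = penetration_fraction(collimator, settings.window)
        haze_sigma_px = HAZE_FWHM_MM * _FWHM_TO_SIGMA / pixel
        shape = (1.0 - f) * _blur(values, sigma_px) + f * _blur(
            values, haze_sigma_px
        )

    total_shape = shape.sum()
    if total_shape <= 0:
        return np.zeros_like(shape), pixel
    return shape * (expected_total / total_shape), pixel


def simulate_planar(
    activity: ActivityMap,
    collimator: CollimatorSpec | None,
    settings: AcquisitionSettings,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> CountImage:
    """Simulate one planar acquisition of an activity map.

    The expected image is ``S [ (1-f) G_geo * A + f G_haze * A ]`` where
    ``G_geo`` has the collimator's geometric FWHM, ``G_haze`` is a broad
    penetration kernel (fixed ``HAZE_FWHM_MM`` width), ``f`` is the
    penetration fraction and ``S`` scales the image to the expected total
    counts (activity x duration x sensitivity); the scaling renormalizes
    counts blurred off the field of view back into it, so total expected
    counts are conserved exactly. ``collimator=None`` simulates an ideal
    system (no blur, no penetration).

    With ``noise=True`` each pixel is an independent Poisson draw seeded
    from ``settings.seed`` (or an explicit ``rng``); with ``noise=False``
    the expectation is returned rounded half-to-even to keep counts
    integral. Same seed and inputs give a bit-identical image.
    """
    expected, pixel = expected_image(activity, collimator, settings)

    if noise:
        if rng is None:
            rng = np.random.default_rng(settings.seed)
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)

    return CountImage(
        counts.astype(np.int64),
        pixel,
        settings=settings,
        collimator=collimator,
        provenance={"simulated": True, "noise": noise, "seed": settings.seed},
    )


def sweep_collimator_designs(
    activity: ActivityMap,
    diameters_mm,
    thicknesses_mm,
    lengths_mm,
    settings: AcquisitionSettings,
    hmr_fn=None,
):
    """Noise-free HMR for every (d, t, L) collimator design on a grid.

    Returns a pandas DataFrame with columns ``d, t, L, hmr`` ordered by
    (L, t, d). By default the HMR is the heart/mediastinum mean ratio of
    the *expected* image in the phantom's reference ROIs: known ROI
    geometry isolates the collimator physics from ROI-placement
    variability, and the unquantized expectation keeps sub-count
    differences between neighbouring designs resolvable. Pass
    ``hmr_fn(image: CountImage) -> float`` to quantify rounded images
    with a different pipeline instead.
    """
    import pandas as pd

    from .quantify import reference_roiset

    ds = sorted(set(float(d) for d in diameters_mm))
    ts = sorted(set(float(t) for t in thicknesses_mm))
    Ls = sorted(set(float(L) for L in lengths_mm))
    if not (ds and ts and Ls):
        raise ValueError("sweep grid must be non-empty")

    rois = reference_roiset(activity, settings.matrix)
    shape = (settings.matrix, settings.matrix)
    heart_mask = rois.heart_mask(shape)
    med_mask = rois.med_mask(shape)

    rows = []
    for L in Ls:
        for t in ts:
            for d in ds:
                spec = CollimatorSpec(f"d{d:g}t{t:g}L{L:g}", d, t, L)
                if hmr_fn is not None:
                    image = simulate_planar(activity, spec, settings, noise=False)
                    value = hmr_fn(image)
                else:
                    expected, _ = expected_image(activity, spec, settings)
                    value = float(expected[heart_mask].mean() / expected[med_mask].mean())
                rows.append({"d": d, "t": t, "L": L, "hmr": value})
    return pd.DataFrame(rows, columns=["d", "t", "L", "hmr"])
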