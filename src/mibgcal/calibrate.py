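"""Conversion-coefficient calibration and HMR standardization.

A camera-collimator system is characterized by a single conversion
coefficient

    CC = ((HMR_Ant + HMR_Post) / 2 - 1) / ((2.60 + 3.50) / 2 - 1),

the ratio of the measured mean phantom HMR excess over 1 to the
designated mean excess (denominator 2.05). A perfect system has CC = 1;
septal penetration and blur compress the excess ratio and give CC < 1.
Institutional HMR values are mapped onto the medium-energy
general-purpose reference scale (CC_std = 0.88) by the affine
standardization

    HMR_std = CC_std / CC_i * (HMR_i - 1) + 1,

which fixes HMR = 1 and preserves patient ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DESIGNATED_HMR, build_phantom

#: Conversion coefficient of the medium-energy (MEGP) reference scale.
CC_STD = 0.88

#: Designated mean HMR excess, (2.60 + 3.50)/2 - 1.
DESIGNATED_MEAN_EXCESS = (DESIGNATED_HMR["anterior"] + DESIGNATED_HMR["posterior"]) / 2 - 1


@dataclass(frozen=True)
class ConversionCoefficient:
    """Calibration factor CC with the phantom HMRs it came from.

    Pathological inputs can give CC outside (0, 1]; no clamping is
    applied — ``suspicious`` flags such values for QC.
    """

    value: float
    hmr_ant: float
    hmr_post: float
    provenance: str = "institutional"

    @property
    def suspicious(self) -> bool:
        return not (0.0 < self.value <= 1.2)


def conversion_coefficient(
    hmr_ant: float, hmr_post: float, provenance: str = "institutional"
) -> ConversionCoefficient:
    """Conversion coefficient from anterior/posterior phantom HMRs."""
    if hmr_ant <= 0 or hmr_post <= 0:
        raise ValueError("phantom HMR values must be positive")
    value = ((hmr_ant + hmr_post) / 2.0 - 1.0) / DESIGNATED_MEAN_EXCESS
    return ConversionCoefficient(value, hmr_ant, hmr_post, provenance)


def standardize_hmr(hmr_i: float, cc_i: float, cc_std: float = CC_STD) -> float:
    """Map an institutional HMR onto the reference (MEGP) scale.

    ``HMR_std = cc_std / cc_i * (hmr_i - 1) + 1``. Values below 1 are
    possible for ``hmr_i < 1`` and preserved: the affine map itself is
    the normative content.
    """
    cc_i = float(cc_i)
    if not np.isfinite(cc_i) or cc_i <= 0:
        raise ValueError(f"institutional conversion coefficient must be positive, got {cc_i}")
    if cc_std <= 0:
        raise ValueError("reference conversion coefficient must be positive")
    return cc_std / cc_i * (hmr_i - 1.0) + 1.0


def end_to_end_cc(
    collimator,
    settings,
    noise: bool = False,
) -> ConversionCoefficient:
    """Simulate both phantom views and calibrate the simulated system.

    Runs the full institutional procedure: anterior and posterior phantom
    acquisitions under ``settings``, automatic ROI placement, HMR
    computation, and the conversion-coefficient formula. With
    ``noise=True`` per-view seeds are derived from ``settings.seed``.
    """
    from .quantify import auto_roi_phantom, compute_hmr
    from .simulate import simulate_planar

    ss = np.random.SeedSequence(settings.seed if settings.seed is not None else 0)
    view_seeds = ss.generate_state(2)
    hmrs = {}
    for view, seed in zip(("anterior", "posterior"), view_seeds):
        activity = build_phantom(settings.pixel_mm, view)
        view_settings = settings.with_seed(int(seed)) if noise else settings
        image = simulate_planar(activity, collimator, view_settings, noise=noise)
        rois = auto_roi_phantom(image, view)
        hmrs[view] = compute_hmr(image, rois).hmr
    return conversion_coefficient(hmrs["anterior"], hmrs["posterior"])
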