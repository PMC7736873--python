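"""Simulate phantom images through different collimators and compare HMR.

Low-energy high-resolution (LEHR) septa are thin, so the 529 keV line of
123I penetrates them and adds a diffuse haze that depresses the measured
HMR; medium-energy (MEGP) collimators suppress it. The script simulates
the anterior phantom through an ideal system and through LEHR, LMEGP and
MEGP collimators (noise-free, long acquisition), runs the automatic ROI
pipeline, and prints the measured HMR: it should fall furthest below the
designated 2.60 for LEHR and least for MEGP.
"""

from mibgcal import build_phantom
from mibgcal.quantify import auto_roi_phantom, compute_hmr
from mibgcal.simulate import COLLIMATORS, AcquisitionSettings, penetration_fraction, simulate_planar

settings = AcquisitionSettings(duration_s=3600.0)
activity = build_phantom(settings.pixel_mm, "anterior")

for label, coll in [("ideal", None)] + list(COLLIMATORS.items()):
    image = simulate_planar(activity, coll, settings, noise=False)
    hmr = compute_hmr(image, auto_roi_phantom(image, "anterior")).hmr
    f = penetration_fraction(coll, settings.window) if coll else 0.0
    print(f"{label:6s}: penetration fraction {f:.4f}, measured anterior HMR {hmr:.4f}")
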