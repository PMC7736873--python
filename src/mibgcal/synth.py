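"""Synthetic multicenter databases and clinical tables.

No public download of the multicenter phantom database or the clinical
validation set exists; these generators emit tables with the same
*structure and composition* — stratum sizes, group-level conversion-
coefficient distributions, vendor/camera layout, and the reference
reclassification outcome — so that every pipeline stage is testable.

The defaults ARE the study conditions: a 1648-record database whose
exclusion strata (scatter correction 145, small matrix 79, minor energy
window 297 with the per-setting breakdown, minor equipment 14, failed
22, planted outliers 20, ±7.5% window 366) leave 705 eligible records,
with group conversion coefficients drawn from the published group
mean/SD/n values; and a 33-subject clinical set (12 heart failure, 21
normal; two images each) that reproduces the reference reclassification
layout of 4/24 event and 1/42 nonevent upward moves.

Conversion coefficients are back-solved into HMR pairs as
``(1 + 1.6 CC, 1 + 2.5 CC)``, preserving the designated 1.60/2.50
excess-ratio split so the calibration formula recovers the planted CC
exactly. Inlier coefficients of records that reach the outlier-detection
stage are laid out as a shuffled quantile grid of a normal truncated at
mean ± 2 SD: the grid pins the sample extremes at 2 SD while the sample
Tukey fence sits near 2.56 SD, so no inlier can be fence-flagged, for
any seed. Planted outliers are displaced at least 3 SD beyond the
nominal fence, so outlier detection recovers exactly the planted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clinical import ClinicalScan
from .database import PhantomRecord
from .window import EnergyWindow

#: Published group-level conversion-coefficient statistics (mean, SD, n).
#: The ME/MEGP/MEGAP count is 180 rather than the published 179 so the
#: seven groups sum to the 705 eligible records.
GROUP_CC_STATS: dict[str, tuple[float, float, int]] = {
    "CHR": (0.545, 0.0268, 21),
    "LEHR": (0.545, 0.0414, 167),
    "LEGP": (0.631, 0.0455, 57),
    "ELEGP": (0.745, 0.0268, 149),
    "LMEGP": (0.823, 0.0437, 102),
    "MEGP": (0.879, 0.0429, 180),
    "MELP": (0.894, 0.0349, 29),
}

#: Minor energy-window settings with their published record counts;
#: ``None`` marks records with missing window metadata.
MINOR_WINDOW_BREAKDOWN: list[tuple[tuple[float, float] | None, int]] = [
    ((154, 10), 4),
    ((155, 10), 4),
    ((156, 7.5), 1),
    ((156, 10), 32),
    ((157, 10), 28),
    ((158, 10), 101),
    ((158, 10.5), 1),
    ((158, 12), 2),
    ((158, 7), 1),
    ((158, 7.5), 23),
    ((159, 10.5), 3),
    ((159, 12), 1),
    ((159, 6.3), 2),
    ((159, 8), 1),
    ((159, 9), 1),
    ((160, 10), 80),
    ((160, 7.5), 8),
    (None, 4),
]

#: Minor-equipment stratum: (vendor, camera, collimator, count).
MINOR_EQUIPMENT_BREAKDOWN: list[tuple[str, str, str, int]] = [
    ("Siemens", "e.cam/Symbia", "123I", 1),
    ("Siemens", "e.cam/Symbia", "Cardiac", 2),
    ("Siemens", "e.cam/Symbia", "LELP", 1),
    ("Siemens", "e.cam/Symbia", "LPHR", 1),
    ("Siemens", "e.cam/Symbia", "MEDIUM", 2),
    ("GE", "Infinia", "HEGP", 1),
    ("Toshiba", "e.cam/Symbia", "Cardio", 1),
    ("Toshiba", "e.cam/Symbia", "MEHR", 3),
    ("Picker", "PRISM", "LEUHR", 1),
    ("Hitachi", "RC-1500I", "LEGP", 1),
]

#: (vendor, camera, collimator-name) cells per group, cycled when
#: assigning eligible records; names exercise the pooled-group aliases.
GROUP_CAMERAS: dict[str, list[tuple[str, str, str]]] = {
    "CHR": [("Philips", "BrightView", "CHR")],
    "LEHR": [
        ("GE", "Discovery/Optima", "LEHR"),
        ("GE", "Infinia", "LEHR"),
        ("GE", "Millennium MG", "LEHR"),
        ("GE", "Millennium VG", "LEHR"),
        ("Picker", "PRISM", "LEHR"),
        ("Siemens", "e.cam/Symbia", "LEHR"),
        ("Siemens", "Evo Excel/Intevo", "LEHR"),
        ("Toshiba", "e.cam/Symbia", "LEHR"),
    ],
    "LEGP": [
        ("GE", "Millennium MG", "LEGP"),
        ("GE", "Millennium VG", "LEAP"),
        ("Picker", "PRISM", "LEGAP"),
    ],
    "ELEGP": [("GE", "Discovery/Optima", "ELEGP"), ("GE", "Infinia", "ELEGP")],
    "LMEGP": [
        ("Siemens", "e.cam/Symbia", "LMEGP"),
        ("Toshiba", "e.cam/Symbia", "LMEGP"),
    ],
    "MEGP": [
        ("GE", "Discovery/Optima", "MEGP"),
        ("GE", "Infinia", "MEGP"),
        ("GE", "Millennium MG", "ME"),
        ("GE", "Millennium VG", "MEGAP"),
        ("Philips", "BrightView", "MEGP"),
        ("Picker", "PRISM", "MEGP"),
        ("Siemens", "e.cam/Symbia", "MEGP"),
        ("Siemens", "Evo Excel/Intevo", "MEGP"),
        ("Toshiba", "e.cam/Symbia", "MEGP"),
    ],
    "MELP": [
        ("Siemens", "e.cam/Symbia", "MELP"),
        ("Toshiba", "e.cam/Symbia", "MELP"),
    ],
}

#: ±7.5%-window stratum layout (vendor, camera, collimator, count):
#: predominantly Siemens and Toshiba, as published (227 + 134 + 2 + 3).
WINDOW75_BREAKDOWN: list[tuple[str, str, str, int]] = [
    ("Siemens", "e.cam/Symbia", "LMEGP", 113),
    ("Siemens", "e.cam/Symbia", "MEGP", 114),
    ("Toshiba", "e.cam/Symbia", "LMEGP", 67),
    ("Toshiba", "e.cam/Symbia", "MEGP", 67),
    ("Philips", "BrightView", "MEGP", 2),
    ("Picker", "PRISM", "MEGP", 3),
]

#: Groups that carry the planted outliers (large groups keep sample
#: Tukey fences stable) and how many each gets.
OUTLIER_LAYOUT: dict[str, int] = {"LEHR": 6, "ELEGP": 5, "LMEGP": 4, "MEGP": 5}

_W10 = EnergyWindow(159.0, 10.0)
_W75 = EnergyWindow(159.0, 7.5)

#: Back-solve split of a CC into (anterior, posterior) HMR excesses,
#: preserving the designated 1.60 / 2.50 proportions.
_ANT_EXCESS, _POST_EXCESS = 1.6, 2.5

#: Inlier truncation, in SDs: keeps every inlier well inside the
#: expected sample Tukey fence (~2.6 SD for a normal sample).
_INLIER_TRUNC_SD = 2.0

#: Nominal Tukey fence offset of a normal distribution (1.5 IQR beyond
#: the quartile = 2.698 sigma), plus the minimum planting margin.
_NORMAL_FENCE_SD = 2.698
_OUTLIER_MARGIN_SD = 3.0


@dataclass
class SynthDBSpec:
    """Composition of a synthetic multicenter phantom database."""

    n_scatter: int = 145
    n_small_matrix: int = 79
    minor_windows: list = field(default_factory=lambda: list(MINOR_WINDOW_BREAKDOWN))
    minor_equipment: list = field(
        default_factory=lambda: list(MINOR_EQUIPMENT_BREAKDOWN)
    )
    n_failed: int = 22
    outlier_layout: dict = field(default_factory=lambda: dict(OUTLIER_LAYOUT))
    window75: list = field(default_factory=lambda: list(WINDOW75_BREAKDOWN))
    group_stats: dict = field(default_factory=lambda: dict(GROUP_CC_STATS))
    n_institutions: int = 600

    @property
    def n_minor_window(self) -> int:
        return sum(n for _, n in self.minor_windows)

    @property
    def n_minor_equipment(self) -> int:
        return sum(n for *_, n in self.minor_equipment)

    @property
    def n_outliers(self) -> int:
        return sum(self.outlier_layout.values())

    @property
    def n_window75(self) -> int:
        return sum(n for *_, n in self.window75)

    @property
    def n_eligible(self) -> int:
        return sum(n for _, _, n in self.group_stats.values())

    @property
    def total(self) -> int:
        return (
            self.n_scatter
            + self.n_small_matrix
            + self.n_minor_window
            + self.n_minor_equipment
            + self.n_failed
            + self.n_outliers
            + self.n_window75
            + self.n_eligible
        )

    def validate(self) -> None:
        for group, (mean, sd, n) in self.group_stats.items():
            if sd <= 0 or n < 1:
                raise ValueError(f"group {group}: SD must be > 0 and n >= 1")
        for group in self.outlier_layout:
            if group not in self.group_stats:
                raise ValueError(f"outlier group {group} has no CC distribution")
        for counts in (
            self.n_scatter,
            self.n_small_matrix,
            self.n_failed,
        ):
            if counts < 0:
                raise ValueError("stratum counts must be non-negative")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled normal draws restricted to (lo, hi)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw > lo) & (draw < hi)]
        take = min(len(draw), size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _truncated_quantile_grid(mean: float, sd: float, trunc_sd: float, n: int) -> np.ndarray:
    """Evenly-spaced quantiles of a normal truncated at ±trunc_sd SDs.

    A quantile grid is an exact-looking sample whose extremes sit at the
    truncation bound while its interquartile range matches the truncated
    distribution, so Tukey fences (~2.56 SD here) can never flag a member.
    """
    from scipy import stats

    q = (np.arange(n) + 0.5) / n
    z = stats.truncnorm.ppf(q, -trunc_sd, trunc_sd)
    return mean + sd * z


def _cc_to_hmrs(cc: float) -> tuple[float, float]:
    return 1.0 + _ANT_EXCESS * cc, 1.0 + _POST_EXCESS * cc


class _InstitutionCycle:
    def __init__(self, n: int) -> None:
        self.n = n
        self.i = 0

    def __call__(self) -> str:
        self.i += 1
        return f"inst{((self.i - 1) % self.n) + 1:03d}"


def generate_database(
    spec: SynthDBSpec | None = None, seed: int = 0
) -> list[PhantomRecord]:
    """Generate a full synthetic multicenter phantom database.

    Deterministic under ``seed``. With the default spec the output has
    1648 records, of which exactly 705 survive the QC filter (1071 when
    the ±7.5% window is retained).
    """
    from .database import classify_collimator

    spec = spec or SynthDBSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    inst = _InstitutionCycle(spec.n_institutions)
    matrices = [256, 512]
    times = [300.0, 240.0, 600.0, 60.0, 900.0]
    records: list[PhantomRecord] = []

    # Records that reach the outlier-detection stage (eligible and the
    # ±7.5%-window stratum) get their CCs from shuffled quantile grids of
    # the truncated group distribution — one complete grid per stratum,
    # so both the pooled first detection pass and any re-filter of the
    # eligible records alone see sample extremes pinned at 2 SD, strictly
    # inside the group's Tukey fence (~2.56 SD), for any seed.
    w75_sizes: dict[str, int] = {}
    for vendor, _camera, name, count in spec.window75:
        group = classify_collimator(name, vendor)
        w75_sizes[group] = w75_sizes.get(group, 0) + count

    def make_pool(group: str, size: int) -> list[float]:
        mean, sd, _ = spec.group_stats[group]
        grid = _truncated_quantile_grid(mean, sd, _INLIER_TRUNC_SD, size)
        return list(rng.permutation(grid))

    pools = {
        "eligible": {g: make_pool(g, n) for g, (_, _, n) in spec.group_stats.items()},
        "w75": {g: make_pool(g, n) for g, n in w75_sizes.items()},
    }

    def clean_cc(group: str, pooled: str | None) -> float:
        if pooled:
            return pools[pooled][group].pop()
        # strata excluded before outlier detection: plain truncated draws
        mean, sd, _ = spec.group_stats[group]
        lo, hi = mean - _INLIER_TRUNC_SD * sd, mean + _INLIER_TRUNC_SD * sd
        return float(_truncated_normal(rng, mean, sd, max(lo, 1e-6), hi, 1)[0])

    def add(group_for_cc, vendor, camera, collimator, window, matrix=None, pooled=None, **kw):
        cc = clean_cc(group_for_cc, pooled)
        ant, post = _cc_to_hmrs(cc)
        records.append(
            PhantomRecord(
                institution=inst(),
                vendor=vendor,
                camera=camera,
                collimator=collimator,
                window=window,
                matrix=matrix if matrix is not None else matrices[len(records) % 2],
                acquisition_s=times[len(records) % len(times)],
                hmr_ant=ant,
                hmr_post=post,
                **kw,
            )
        )

    # 1. scatter-corrected records (otherwise clean LEHR-style systems)
    for i in range(spec.n_scatter):
        mode = "dual-window" if i % 2 == 0 else "triple-window"
        add("LEHR", "GE", "Infinia", "LEHR", _W10, scatter_correction=mode)

    # 2. small acquisition matrices
    for i in range(spec.n_small_matrix):
        add("LEHR", "Toshiba", "e.cam/Symbia", "LEHR", _W10, matrix=64 if i % 2 else 128)

    # 3. minor energy windows (published per-setting breakdown)
    for setting, count in spec.minor_windows:
        window = None if setting is None else EnergyWindow(*setting)
        for _ in range(count):
            add("LEHR", "Siemens", "e.cam/Symbia", "LEHR", window)

    # 4. minor collimators / cameras
    for vendor, camera, collimator, count in spec.minor_equipment:
        for _ in range(count):
            add("LEHR", vendor, camera, collimator, _W10)

    # 5. failed experiments
    for _ in range(spec.n_failed):
        add("LMEGP", "Siemens", "e.cam/Symbia", "LMEGP", _W10, failed=True)

    # 6. planted conversion-coefficient outliers
    side = 1
    for group, count in spec.outlier_layout.items():
        mean, sd, _ = spec.group_stats[group]
        vendor, camera, name = GROUP_CAMERAS[group][0]
        for _ in range(count):
            offset = (_NORMAL_FENCE_SD + _OUTLIER_MARGIN_SD + rng.uniform(0, 1)) * sd
            cc = mean + side * offset
            side = -side
            if cc <= 0.02:
                cc = mean + abs(offset)
            ant, post = _cc_to_hmrs(cc)
            records.append(
                PhantomRecord(
                    institution=inst(),
                    vendor=vendor,
                    camera=camera,
                    collimator=name,
                    window=_W10,
                    matrix=matrices[len(records) % 2],
                    acquisition_s=times[len(records) % len(times)],
                    hmr_ant=ant,
                    hmr_post=post,
                )
            )

    # 7. clean records acquired at 159 keV ± 7.5%
    for vendor, camera, name, count in spec.window75:
        group = classify_collimator(name, vendor)
        for _ in range(count):
            add(group, vendor, camera, name, _W75, pooled='w75')

    # 8. eligible records
    for group, (mean, sd, n) in spec.group_stats.items():
        cells = GROUP_CAMERAS[group]
        for i in range(n):
            vendor, camera, name = cells[i % len(cells)]
            add(group, vendor, camera, name, _W10, pooled='eligible')

    rng.shuffle(records)  # interleave strata as a real registry would
    return records


def generate_group_samples(
    group: str, n: int, mean: float, sd: float, seed: int = 0
) -> np.ndarray:
    """n pseudo-normal conversion-coefficient draws, truncated to (0, 1.2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n, mean)
    return _truncated_normal(rng, mean, sd, 0.0, 1.2, n)


#: Reference hospital conversion coefficients (institutional, multicenter).
HOSPITAL_CCS: dict[str, dict[str, float]] = {
    "A": {"institutional": 0.631, "multicenter": 0.621},
    "B": {"institutional": 0.840, "multicenter": 0.838},
}

#: Uncorrected HMR values planted to move toward abnormal at hospital B
#: (inside the flip band [2.17, ~2.42) for cc around 0.84).
_PLANT_EVENTS = [2.20, 2.25, 2.30, 2.35]
_PLANT_NONEVENT = 2.28


def generate_clinical_set(
    n_hf_subjects: int = 12,
    n_normal_subjects: int = 21,
    hospital_ccs: dict | None = None,
    layout: str | None = "reference",
    seed: int = 0,
) -> list[ClinicalScan]:
    """Synthetic clinical HMR table: two images (early/delayed) per subject.

    True standardized-scale HMR values are drawn per diagnosis stratum
    (heart failure low, normal high) and de-standardized through each
    hospital's institutional conversion coefficient to produce the
    stored uncorrected HMR. ``layout="reference"`` additionally plants
    the published reclassification outcome: 4 heart-failure and 1 normal
    image at the higher-CC hospital moved toward abnormal, no downward
    moves, with all remaining images kept outside the flip bands.
    """
    ccs = hospital_ccs or HOSPITAL_CCS
    hospitals = sorted(ccs)
    rng = np.random.default_rng(seed)
    scans: list[ClinicalScan] = []

    def de_standardize(hmr_std: float, cc: float) -> float:
        return 1.0 + (hmr_std - 1.0) * cc / 0.88

    def make(prefix, count, mean, sd, lo, hi, diagnosis):
        for i in range(count):
            hospital = hospitals[i % len(hospitals)]
            cc = ccs[hospital]
            cc_i = cc["institutional"] if isinstance(cc, dict) else float(cc)
            cc_mc = cc.get("multicenter", cc_i) if isinstance(cc, dict) else float(cc)
            for phase in ("early", "delayed"):
                true = float(_truncated_normal(rng, mean, sd, lo, hi, 1)[0])
                scans.append(
                    ClinicalScan(
                        subject=f"{prefix}{i + 1:02d}",
                        hospital=hospital,
                        phase=phase,
                        hmr=de_standardize(true, cc_i),
                        diagnosis=diagnosis,
                        cc_i=cc_i,
                        cc_multicenter=cc_mc,
                    )
                )

    # Draw bands chosen so no un-planted image crosses a threshold pair:
    # heart failure stays abnormal, normals stay normal, before and after
    # standardization, for either coefficient source.
    make("hf", n_hf_subjects, 1.6, 0.25, 1.2, 2.0, "heart_failure")
    make("nl", n_normal_subjects, 3.0, 0.30, 2.7, 3.6, "normal")

    if layout == "reference" and scans:
        target = "B" if "B" in ccs else hospitals[-1]
        hf_b = [s for s in scans if s.diagnosis == "heart_failure" and s.hospital == target]
        nl_b = [s for s in scans if s.diagnosis == "normal" and s.hospital == target]
        if len(hf_b) < len(_PLANT_EVENTS) or not nl_b:
            raise ValueError("not enough scans at the target hospital to plant the layout")
        for scan, value in zip(hf_b, _PLANT_EVENTS):
            scan.hmr = value
        nl_b[0].hmr = _PLANT_NONEVENT
    return scans
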