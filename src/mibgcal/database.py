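"""Multicenter phantom-record model, QC filter pipeline, and aggregation.

A multicenter phantom database holds one record per institutional phantom
experiment: the camera/collimator system, acquisition protocol, and the
measured anterior/posterior HMR pair from which the conversion
coefficient follows. Records pass a fixed sequence of eligibility rules
(scatter correction, small matrices, minor energy windows, minor
equipment, failed experiments, conversion-coefficient outliers, and
optionally the 159 keV ± 7.5% window), each record tallied under the
first rule it violates. Surviving coefficients are aggregated per
(vendor, camera, collimator-group) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .calibrate import conversion_coefficient
from .window import EnergyWindow, parse_window

#: Canonical collimator-group labels, low to medium energy rating.
COLLIMATOR_GROUPS = ["CHR", "LEHR", "LEGP", "ELEGP", "LMEGP", "MEGP", "MELP"]

#: Display labels for pooled groups.
GROUP_DISPLAY = {"LEGP": "LEGP/LEAP/LEGAP", "MEGP": "ME/MEGP/MEGAP"}

_ALIASES = {
    "CHR": "CHR",
    "LEHR": "LEHR",
    "LEGP": "LEGP",
    "LEAP": "LEGP",
    "LEGAP": "LEGP",
    "ELEGP": "ELEGP",
    "LMEGP": "LMEGP",
    "ME": "MEGP",
    "MEGP": "MEGP",
    "MEGAP": "MEGP",
    "MELP": "MELP",
}

# Minor-equipment list: (vendor, collimator) combinations excluded from the
# multicenter analysis. Hitachi systems are excluded wholesale.
_MINOR_EQUIPMENT = {
    ("SIEMENS", "123I"),
    ("SIEMENS", "CARDIAC"),
    ("SIEMENS", "LELP"),
    ("SIEMENS", "LPHR"),
    ("SIEMENS", "MEDIUM"),
    ("GE", "HEGP"),
    ("TOSHIBA", "CARDIO"),
    ("TOSHIBA", "MEHR"),
    ("PICKER", "LEUHR"),
}

#: Accepted primary energy-window settings.
_PRIMARY_WINDOWS = {(159.0, 10.0), (159.0, 7.5)}

WINDOW_75 = EnergyWindow(159.0, 7.5)


def _norm(text: str | None) -> str:
    return "" if text is None else str(text).strip().upper().replace(" ", "").replace("-", "")


def classify_collimator(name: str, vendor: str = "") -> str | None:
    """Map a collimator name to its group label, or ``None`` if excluded.

    Names on the vendor-specific minor-equipment list and unknown names
    both map to ``None``; unknown names additionally emit a warning.
    """
    n = _norm(name)
    v = _norm(vendor)
    if v == "HITACHI":
        return None
    if (v, n) in _MINOR_EQUIPMENT:
        return None
    group = _ALIASES.get(n)
    if group is None:
        warnings.warn(
            f"unknown collimator name {name!r} (vendor {vendor!r}); record excluded",
            stacklevel=2,
        )
    return group


def is_minor_energy_window(window) -> bool:
    """True if the window is missing or not a primary 159 keV setting."""
    w = parse_window(window)
    if w is None:
        return True
    return (w.center_kev, w.halfwidth_pct) not in _PRIMARY_WINDOWS


@dataclass
class PhantomRecord:
    """One institutional phantom experiment."""

    institution: str
    vendor: str
    camera: str
    collimator: str
    window: EnergyWindow | None
    matrix: int
    acquisition_s: float
    scatter_correction: str = "none"  # none | dual-window | triple-window
    failed: bool = False
    hmr_ant: float = float("nan")
    hmr_post: float = float("nan")

    @property
    def cc(self) -> float:
        """Conversion coefficient from this record's phantom HMR pair."""
        if not (np.isfinite(self.hmr_ant) and np.isfinite(self.hmr_post)):
            return float("nan")
        return conversion_coefficient(self.hmr_ant, self.hmr_post).value

    @property
    def group(self) -> str | None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return classify_collimator(self.collimator, self.vendor)


@dataclass
class ExclusionTally:
    """Counts per exclusion reason; first matching rule wins."""

    scatter_correction: int = 0
    small_matrix: int = 0
    minor_energy_window: int = 0
    minor_collimator_or_camera: int = 0
    failed_experiment: int = 0
    cc_outlier: int = 0
    window_75: int = 0
    eligible: int = 0

    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    def excluded(self) -> int:
        return self.total() - self.eligible

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def detect_cc_outliers(records: list[PhantomRecord]) -> list[bool]:
    """Tukey-fence outlier flags for conversion coefficients, per group.

    Within each collimator group, a record is flagged when its CC falls
    outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (quartiles by linear
    interpolation). Groups with fewer than 4 members yield no flags, as
    do records without a group or without finite CC.
    """
    flags = [False] * len(records)
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        g = rec.group
        if g is not None and np.isfinite(rec.cc):
            groups.setdefault(g, []).append(i)
    for indices in groups.values():
        if len(indices) < 4:
            continue
        ccs = np.array([records[i].cc for i in indices])
        q1, q3 = np.percentile(ccs, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for i, cc in zip(indices, ccs):
            if cc < lo or cc > hi:
                flags[i] = True
    return flags


def qc_filter(
    records: list[PhantomRecord], include_75_window: bool = False
) -> tuple[list[PhantomRecord], ExclusionTally]:
    """Apply the multicenter eligibility rules in their fixed order.

    Order: scatter correction, small matrix (64/128), minor energy
    window, minor collimator/camera, failed experiment, CC outliers
    (Tukey fences, iterated to a fixed point so the filter is
    idempotent), and finally — unless ``include_75_window`` — the
    159 keV ± 7.5% window. A record is tallied under the first rule it
    violates; eligible + exclusions always equals the input size.
    """
    tally = ExclusionTally()
    survivors: list[PhantomRecord] = []
    for rec in records:
        if rec.scatter_correction not in (None, "", "none"):
            tally.scatter_correction += 1
        elif rec.matrix in (64, 128):
            tally.small_matrix += 1
        elif is_minor_energy_window(rec.window):
            tally.minor_energy_window += 1
        elif rec.group is None:
            tally.minor_collimator_or_camera += 1
        elif rec.failed:
            tally.failed_experiment += 1
        else:
            survivors.append(rec)

    # Tukey-fence exclusion, iterated: removing an extreme value shrinks
    # the fences, so a single pass is not idempotent in general.
    while True:
        flags = detect_cc_outliers(survivors)
        if not any(flags):
            break
        tally.cc_outlier += sum(flags)
        survivors = [r for r, f in zip(survivors, flags) if not f]

    if not include_75_window:
        kept = []
        for rec in survivors:
            w = rec.window
            if w is not None and (w.center_kev, w.halfwidth_pct) == (159.0, 7.5):
                tally.window_75 += 1
            else:
                kept.append(rec)
        survivors = kept

    tally.eligible = len(survivors)
    return survivors, tally


@dataclass
class CameraCollimatorTable:
    """Mean ± SD conversion coefficient per (vendor, camera, group) cell."""

    frame: pd.DataFrame = field(repr=False)  # vendor, camera, group, mean_cc, sd_cc, n

    def cell(self, vendor: str, camera: str, group: str):
        sel = self.frame[
            (self.frame.vendor == vendor)
            & (self.frame.camera == camera)
            & (self.frame.group == group)
        ]
        if sel.empty:
            return None
        row = sel.iloc[0]
        return float(row.mean_cc), float(row.sd_cc), int(row.n)

    def group_means(self) -> pd.DataFrame:
        """Pooled mean/SD/n per collimator group across all cameras."""
        rows = []
        for g, sub in self.frame.groupby("group", sort=False):
            ccs = np.concatenate([np.full(int(r.n), r.mean_cc) for r in sub.itertuples()])
            rows.append({"group": g, "n": int(sub.n.sum()), "mean_cc": float(ccs.mean())})
        return pd.DataFrame(rows)

    def to_wide(self, decimals: int = 2) -> pd.DataFrame:
        """Table-style rendering: rows (vendor, camera), one column per group.

        Absent cells render as "–", mirroring the printed presentation;
        values are rounded to ``decimals`` only at this layer.
        """
        wide = self.frame.pivot_table(
            index=["vendor", "camera"], columns="group", values="mean_cc", aggfunc="first"
        )
        for g in COLLIMATOR_GROUPS:
            if g not in wide.columns:
                wide[g] = np.nan
        wide = wide[COLLIMATOR_GROUPS]
        return wide.map(lambda v: "–" if pd.isna(v) else f"{v:.{decimals}f}")

    def to_markdown(self, decimals: int = 2) -> str:
        return self.to_wide(decimals).to_markdown()


def aggregate_table(records: list[PhantomRecord]) -> CameraCollimatorTable:
    """Arithmetic mean, SD and n of CC per (vendor, camera, group).

    ``records`` are expected to be pre-filtered (the eligible output of
    :func:`qc_filter`); cells with no members simply do not appear.
    """
    rows = []
    for rec in records:
        g = rec.group
        if g is None or not np.isfinite(rec.cc):
            continue
        rows.append({"vendor": rec.vendor, "camera": rec.camera, "group": g, "cc": rec.cc})
    if not rows:
        return CameraCollimatorTable(
            pd.DataFrame(columns=["vendor", "camera", "group", "mean_cc", "sd_cc", "n"])
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["vendor", "camera", "group"], sort=True)["cc"]
        .agg(mean_cc="mean", sd_cc=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    return CameraCollimatorTable(agg)


# ---------------------------------------------------------------------------
# CSV interchange

_CSV_COLUMNS = [
    "institution",
    "vendor",
    "camera",
    "collimator",
    "window",
    "matrix",
    "acquisition_s",
    "scatter_correction",
    "failed",
    "hmr_ant",
    "hmr_post",
]


def records_to_frame(records: list[PhantomRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "institution": r.institution,
                "vendor": r.vendor,
                "camera": r.camera,
                "collimator": r.collimator,
                "window": "" if r.window is None else str(r.window),
                "matrix": r.matrix,
                "acquisition_s": r.acquisition_s,
                "scatter_correction": r.scatter_correction,
                "failed": r.failed,
                "hmr_ant": r.hmr_ant,
                "hmr_post": r.hmr_post,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PhantomRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PhantomRecord(
                institution=str(row.institution),
                vendor=str(row.vendor),
                camera=str(row.camera),
                collimator=str(row.collimator),
                window=parse_window(None if pd.isna(row.window) else row.window),
                matrix=int(row.matrix),
                acquisition_s=float(row.acquisition_s),
                scatter_correction=str(row.scatter_correction),
                failed=bool(row.failed),
                hmr_ant=float(row.hmr_ant),
                hmr_post=float(row.hmr_post),
            )
        )
    return records


def write_records_csv(records: list[PhantomRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[PhantomRecord]:
    return frame_to_records(pd.read_csv(path, keep_default_na=True))
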