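"""Clinical standardization, reclassification, and NRI.

Clinical HMR tables carry one row per planar image (early and delayed
phases of one subject count as separate images). Each image is
classified as abnormal when its HMR falls strictly below a threshold:
2.17 for uncorrected values and 2.49 on the standardized scale (both
thresholds come from ROC analyses and are inputs here, not derived).
The net reclassification improvement contrasts how standardization moves
events (heart failure) and nonevents (normal) across these thresholds:

    NRI = [(up_e - down_e)/n_e - (up_ne - down_ne)/n_ne] x 100  (%)

where "up" is a move toward the abnormal class — an improvement for
events and a worsening for nonevents.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calibrate import standardize_hmr

THRESHOLD_UNCORRECTED = 2.17
THRESHOLD_STANDARDIZED = 2.49


@dataclass
class ClinicalScan:
    """One clinical planar image and its institutional calibration."""

    subject: str
    hospital: str
    phase: str  # early | delayed
    hmr: float
    diagnosis: str  # heart_failure | normal
    cc_i: float | None = None
    cc_multicenter: float | None = None

    def cc(self, source: str = "institutional") -> float | None:
        if source == "institutional":
            return self.cc_i
        if source == "multicenter":
            return self.cc_multicenter
        raise ValueError(f"unknown conversion-coefficient source {source!r}")


@dataclass(frozen=True)
class ReclassTable:
    """Up/down reclassification counts by event status.

    "Up" counts images that moved toward the abnormal class between the
    uncorrected and the standardized classification; "down" the reverse.
    """

    up_events: int
    down_events: int
    n_events: int
    up_nonevents: int
    down_nonevents: int
    n_nonevents: int

    def __post_init__(self) -> None:
        for v in (
            self.up_events,
            self.down_events,
            self.n_events,
            self.up_nonevents,
            self.down_nonevents,
            self.n_nonevents,
        ):
            if v < 0:
                raise ValueError("reclassification counts must be non-negative")
        if self.up_events + self.down_events > self.n_events:
            raise ValueError("event moves exceed event count")
        if self.up_nonevents + self.down_nonevents > self.n_nonevents:
            raise ValueError("nonevent moves exceed nonevent count")


def classify(hmr: float, threshold: float) -> str:
    """"abnormal" when hmr < threshold, else "normal" (ties are normal)."""
    if hmr <= 0 or threshold <= 0:
        raise ValueError("hmr and threshold must be positive")
    return "abnormal" if hmr < threshold else "normal"


def reclassification_table(
    scans: list[ClinicalScan],
    thr_uncorrected: float = THRESHOLD_UNCORRECTED,
    thr_standardized: float = THRESHOLD_STANDARDIZED,
    cc_source: str = "multicenter",
) -> ReclassTable:
    """Tally class moves between uncorrected and standardized HMR.

    Every scan needs a conversion coefficient from ``cc_source``
    (``"multicenter"``, as in the reference analysis, or
    ``"institutional"``); a missing coefficient raises an error naming
    the scan.
    """
    counts = {"heart_failure": [0, 0, 0], "normal": [0, 0, 0]}  # up, down, n
    for scan in scans:
        cc = scan.cc(cc_source)
        if cc is None:
            raise ValueError(
                f"scan {scan.subject}/{scan.phase} has no {cc_source} conversion coefficient"
            )
        before = classify(scan.hmr, thr_uncorrected)
        after = classify(standardize_hmr(scan.hmr, cc), thr_standardized)
        bucket = counts[scan.diagnosis]
        bucket[2] += 1
        if before == "normal" and after == "abnormal":
            bucket[0] += 1
        elif before == "abnormal" and after == "normal":
            bucket[1] += 1
    ev, ne = counts["heart_failure"], counts["normal"]
    return ReclassTable(ev[0], ev[1], ev[2], ne[0], ne[1], ne[2])


def nri(table: ReclassTable) -> float:
    """Net reclassification improvement, in percent.

    Events reclassified toward abnormal count as improvement; nonevents
    reclassified toward abnormal count against. Bounded in [-200, 200].
    """
    if table.n_events == 0 or table.n_nonevents == 0:
        raise ValueError("NRI requires at least one event and one nonevent")
    event_net = (table.up_events - table.down_events) / table.n_events
    nonevent_net = (table.up_nonevents - table.down_nonevents) / table.n_nonevents
    return (event_net - nonevent_net) * 100.0


def hospital_comparison(
    scans: list[ClinicalScan], mode: str = "institutional"
) -> pd.DataFrame:
    """Per-hospital, per-phase mean ± SD of uncorrected and corrected HMR.

    ``mode`` selects which conversion coefficient corrects the values
    (``institutional`` or ``multicenter``).
    """
    if mode not in ("institutional", "multicenter"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for scan in scans:
        cc = scan.cc(mode)
        if cc is None:
            raise ValueError(
                f"scan {scan.subject}/{scan.phase} has no {mode} conversion coefficient"
            )
        rows.append(
            {
                "hospital": scan.hospital,
                "phase": scan.phase,
                "uncorrected": scan.hmr,
                "corrected": standardize_hmr(scan.hmr, cc),
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["hospital", "phase"], sort=True)
        .agg(
            n=("uncorrected", "size"),
            mean_uncorrected=("uncorrected", "mean"),
            sd_uncorrected=("uncorrected", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            mean_corrected=("corrected", "mean"),
            sd_corrected=("corrected", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        )
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# CSV interchange

_CSV_COLUMNS = [
    "subject",
    "hospital",
    "phase",
    "hmr",
    "diagnosis",
    "cc_i",
    "cc_multicenter",
]


def scans_to_frame(scans: list[ClinicalScan]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": s.subject,
                "hospital": s.hospital,
                "phase": s.phase,
                "hmr": s.hmr,
                "diagnosis": s.diagnosis,
                "cc_i": s.cc_i,
                "cc_multicenter": s.cc_multicenter,
            }
            for s in scans
        ],
        columns=_CSV_COLUMNS,
    )


def frame_to_scans(df: pd.DataFrame) -> list[ClinicalScan]:
    scans = []
    for row in df.itertuples(index=False):
        scans.append(
            ClinicalScan(
                subject=str(row.subject),
                hospital=str(row.hospital),
                phase=str(row.phase),
                hmr=float(row.hmr),
                diagnosis=str(row.diagnosis),
                cc_i=None if pd.isna(row.cc_i) else float(row.cc_i),
                cc_multicenter=None
                if pd.isna(row.cc_multicenter)
                else float(row.cc_multicenter),
            )
        )
    return scans


def write_scans_csv(scans: list[ClinicalScan], path) -> None:
    scans_to_frame(scans).to_csv(path, index=False)


def read_scans_csv(path) -> list[ClinicalScan]:
    return frame_to_scans(pd.read_csv(path))
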