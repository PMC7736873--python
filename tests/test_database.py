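"""Multicenter record model, QC filtering, outlier detection, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibgcal.database import (
    ExclusionTally,
    PhantomRecord,
    aggregate_table,
    classify_collimator,
    detect_cc_outliers,
    frame_to_records,
    is_minor_energy_window,
    qc_filter,
    read_records_csv,
    records_to_frame,
    write_records_csv,
)
from mibgcal.window import EnergyWindow, parse_window


def record(cc=0.7, collimator="MEGP", vendor="Siemens", window=(159, 10),
           matrix=256, scatter="none", failed=False):
    return PhantomRecord(
        institution="inst001",
        vendor=vendor,
        camera="e.cam/Symbia",
        collimator=collimator,
        window=None if window is None else EnergyWindow(*window),
        matrix=matrix,
        acquisition_s=300.0,
        scatter_correction=scatter,
        failed=failed,
        hmr_ant=1 + 1.6 * cc,
        hmr_post=1 + 2.5 * cc,
    )


class TestClassifyCollimator:
    @pytest.mark.parametrize(
        "name, vendor, group",
        [
            ("LEAP", "GE", "LEGP"),
            ("LEGAP", "Picker", "LEGP"),
            ("lehr", "GE", "LEHR"),
            ("ME", "GE", "MEGP"),
            ("MEGAP", "Toshiba", "MEGP"),
            ("CHR", "Philips", "CHR"),
            ("ELEGP", "GE", "ELEGP"),
            ("MELP", "Siemens", "MELP"),
        ],
    )
    def test_alias_grouping(self, name, vendor, group):
        assert classify_collimator(name, vendor) == group

    @pytest.mark.parametrize(
        "name, vendor",
        [
            ("MEHR", "Toshiba"),
            ("Cardiac", "Siemens"),
            ("LELP", "Siemens"),
            ("HEGP", "GE"),
            ("LEUHR", "Picker"),
            ("LEGP", "Hitachi"),
        ],
    )
    def test_minor_equipment_excluded(self, name, vendor):
        assert classify_collimator(name, vendor) is None

    def test_unknown_name_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_collimator("", "GE") is None
        with pytest.warns(UserWarning):
            assert classify_collimator("FANBEAM", "GE") is None


class TestEnergyWindow:
    @pytest.mark.parametrize(
        "text, center, half",
        [
            ("159 ± 10%", 159, 10),
            ("159keV±10%", 159, 10),
            ("159:10", 159, 10),
            ("158 ± 7.5%", 158, 7.5),
            ("158 k ± 7%", 158, 7),
        ],
    )
    def test_dialect_parsing(self, text, center, half):
        w = parse_window(text)
        assert (w.center_kev, w.halfwidth_pct) == (center, half)

    def test_missing_parses_to_none(self):
        assert parse_window("") is None
        assert parse_window(None) is None

    @pytest.mark.parametrize(
        "window, minor",
        [
            ((159, 10), False),
            ((159, 7.5), False),
            ((158, 10), True),   # center matched exactly, no rounding
            ((160, 7.5), True),
            ((159, 12), True),
            (None, True),        # missing data
        ],
    )
    def test_minor_window_rule(self, window, minor):
        w = None if window is None else EnergyWindow(*window)
        assert is_minor_energy_window(w) is minor


class TestOutliers:
    def test_identical_values_unflagged(self):
        recs = [record(cc=0.7) for _ in range(10)]
        assert not any(detect_cc_outliers(recs))

    def test_single_planted_outlier_flagged(self):
        """Hand check: jittered cluster near 0.55 with one value at 0.90
        sits far outside Q3 + 1.5 IQR."""
        ccs = [0.54, 0.55, 0.56, 0.55, 0.545, 0.555, 0.90]
        recs = [record(cc=c) for c in ccs]
        q1, q3 = np.percentile(ccs, [25, 75])
        assert 0.90 > q3 + 1.5 * (q3 - q1)  # fence confirms the construction
        flags = detect_cc_outliers(recs)
        assert flags == [False] * 6 + [True]

    def test_small_groups_never_flagged(self):
        recs = [record(cc=c) for c in (0.1, 0.7, 5.0)]
        assert not any(detect_cc_outliers(recs))

    def test_groups_are_independent(self):
        lehr = [record(cc=c, collimator="LEHR") for c in (0.54, 0.545, 0.55, 0.555, 0.56)]
        megp = [record(cc=c) for c in (0.87, 0.875, 0.88, 0.885, 0.89)]
        flags = detect_cc_outliers(lehr + megp)
        assert not any(flags)


class TestQcFilter:
    def test_empty_input(self):
        eligible, tally = qc_filter([])
        assert eligible == [] and tally.total() == 0

    def test_first_matching_rule_wins(self):
        # scatter-corrected AND small-matrix: tallied under scatter only
        rec = record(scatter="dual-window", matrix=64)
        _, tally = qc_filter([rec])
        assert tally.scatter_correction == 1
        assert tally.small_matrix == 0

    @pytest.mark.parametrize(
        "rec, reason",
        [
            (record(scatter="triple-window"), "scatter_correction"),
            (record(matrix=128), "small_matrix"),
            (record(window=(158, 10)), "minor_energy_window"),
            (record(window=None), "minor_energy_window"),
            (record(collimator="MEHR", vendor="Toshiba"), "minor_collimator_or_camera"),
            (record(failed=True), "failed_experiment"),
        ],
    )
    def test_each_rule_fires(self, rec, reason):
        _, tally = qc_filter([rec])
        assert getattr(tally, reason) == 1
        assert tally.eligible == 0

    def test_window_75_toggle(self):
        recs = [record(window=(159, 7.5)) for _ in range(5)]
        _, strict = qc_filter(recs, include_75_window=False)
        _, loose = qc_filter(recs, include_75_window=True)
        assert strict.window_75 == 5 and strict.eligible == 0
        assert loose.window_75 == 0 and loose.eligible == 5


records_strategy = st.lists(
    st.builds(
        record,
        cc=st.floats(min_value=0.05, max_value=1.15),
        collimator=st.sampled_from(["LEHR", "MEGP", "LMEGP", "CHR", "MEHR", "???"]),
        vendor=st.sampled_from(["GE", "Toshiba", "Siemens"]),
        window=st.sampled_from([(159, 10), (159, 7.5), (158, 10), None]),
        matrix=st.sampled_from([64, 128, 256, 512]),
        scatter=st.sampled_from(["none", "dual-window"]),
        failed=st.booleans(),
    ),
    max_size=60,
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(records=records_strategy, include_75=st.booleans())
def test_tally_conservation_and_idempotence(records, include_75):
    """On arbitrary record sets the tally partitions the input exactly,
    and re-filtering the eligible output excludes nothing further."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eligible, tally = qc_filter(records, include_75_window=include_75)
        assert tally.total() == len(records)
        assert tally.eligible == len(eligible)
        again, tally2 = qc_filter(eligible, include_75_window=include_75)
        assert tally2.excluded() == 0
        assert len(again) == len(eligible)


class TestAggregate:
    def test_two_record_mean(self):
        recs = [record(cc=0.74, vendor="GE"), record(cc=0.76, vendor="GE")]
        table = aggregate_table(recs)
        mean, sd, n = table.cell("GE", "e.cam/Symbia", "MEGP")
        assert mean == pytest.approx(0.75)
        assert n == 2

    def test_empty_input(self):
        assert aggregate_table([]).frame.empty

    def test_absent_cells_render_dash(self):
        table = aggregate_table([record(cc=0.88)])
        wide = table.to_wide()
        assert (wide.loc[("Siemens", "e.cam/Symbia")] == "–").sum() == 6
        assert wide.loc[("Siemens", "e.cam/Symbia"), "MEGP"] == "0.88"


def test_csv_round_trip(tmp_path):
    recs = [record(), record(window=None, failed=True), record(matrix=64)]
    path = tmp_path / "records.csv"
    write_records_csv(recs, path)
    back = read_records_csv(path)
    assert records_to_frame(back).equals(records_to_frame(recs))
    assert back[1].window is None and back[1].failed


def test_tally_serialization_fields():
    tally = ExclusionTally(scatter_correction=2, eligible=3)
    d = tally.as_dict()
    assert d["scatter_correction"] == 2 and d["eligible"] == 3
    assert tally.total() == 5 and tally.excluded() == 2
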