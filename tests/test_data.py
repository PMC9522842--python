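"""Cohort I/O, cleaning rules and LD-to-cell-number conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kuznefit.data import (
    Cohort,
    PatientRecord,
    SchemaError,
    cells_to_ld,
    clean,
    filter_cohort,
    ld_to_cells,
    normalize,
    read_cohort,
    truncate,
    write_cohort,
)
from kuznefit.model import ScaleConstants

SCALES = ScaleConstants()
HEADER = "patient_id,study,arm,treatment,time_days,ld_mm\n"


def write_csv(tmp_path, body, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


def record(pairs, pid="P1", **kw):
    t, ld = zip(*pairs) if pairs else ((), ())
    return PatientRecord(patient_id=pid, time_days=np.array(t, float),
                         ld_mm=np.array(ld, float), **kw)


class TestReadCohort:
    def test_groups_rows_per_patient(self, tmp_path):
        body = "".join(
            f"P{i},S1,A1,drug,{42*j},{10+j}\n" for i in (1, 2) for j in range(8)
        )
        cohort = read_cohort(write_csv(tmp_path, body))
        assert len(cohort) == 2
        assert all(len(r) == 8 for r in cohort)
        assert cohort.get("P2").study_id == "S1"

    def test_empty_file_with_header(self, tmp_path):
        assert len(read_cohort(write_csv(tmp_path, ""))) == 0

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,study,arm,treatment,time_days\nP1,S,A,d,0\n")
        with pytest.raises(SchemaError, match="ld_mm"):
            read_cohort(path)

    def test_unparseable_numeric_reports_row(self, tmp_path):
        body = "P1,S,A,d,0,10\nP1,S,A,d,42,abc\n"
        with pytest.raises(ValueError, match="row.*1"):
            read_cohort(write_csv(tmp_path, body))

    def test_null_ld_allowed_and_kept_as_nan(self, tmp_path):
        body = "P1,S,A,d,0,10\nP1,S,A,d,42,\nP1,S,A,d,84,NA\n"
        rec = read_cohort(write_csv(tmp_path, body)).get("P1")
        assert np.isnan(rec.ld_mm[1]) and np.isnan(rec.ld_mm[2])

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "alt.csv"
        path.write_text("id,study,arm,treatment,day,LD\nP1,S,A,d,0,10\n")
        cohort = read_cohort(
            path, column_map={"id": "patient_id", "day": "time_days", "LD": "ld_mm"}
        )
        assert len(cohort.get("P1")) == 1


class TestClean:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            # exact duplicate rows collapse
            ([(0, 10), (0, 10), (42, 12)], [(0, 10), (42, 12)]),
            # null rows dropped
            ([(0, 10), (42, np.nan), (84, 12)], [(0, 10), (84, 12)]),
            # same-time conflict: first occurrence wins
            ([(0, 10), (0, 11), (42, 12)], [(0, 10), (42, 12)]),
        ],
    )
    def test_cleaning_rules(self, pairs, expected):
        out = clean(record(pairs))
        assert list(zip(out.time_days, out.ld_mm)) == expected

    def test_times_strictly_increasing_after_clean(self):
        out = clean(record([(42, 12), (0, 10), (84, 9)]))
        assert np.all(np.diff(out.time_days) > 0)

    def test_empty_result_allowed(self):
        assert len(clean(record([(0, np.nan)]))) == 0

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5).map(float),
                st.one_of(st.just(np.nan), st.floats(1, 100)),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_clean_is_idempotent(self, pairs):
        once = clean(record(pairs))
        twice = clean(once)
        assert np.array_equal(once.time_days, twice.time_days)
        assert np.array_equal(once.ld_mm, twice.ld_mm)


class TestFilterCohort:
    def make_cohort(self, sizes):
        recs = [
            clean(record([(42 * j, 10.0) for j in range(n)], pid=f"P{i}"))
            for i, n in enumerate(sizes)
        ]
        return Cohort(records=recs)

    def test_six_points_excluded_seven_retained(self):
        kept = filter_cohort(self.make_cohort([6, 7]))
        assert [r.patient_id for r in kept] == ["P1"]

    def test_empty_cohort(self):
        assert len(filter_cohort(Cohort(records=[]))) == 0

    def test_threshold_monotone(self):
        cohort = self.make_cohort([3, 5, 7, 9, 11])
        for k in range(2, 12):
            tighter = {r.patient_id for r in filter_cohort(cohort, k)}
            looser = {r.patient_id for r in filter_cohort(cohort, k - 1)}
            assert tighter <= looser


class TestLdToCells:
    def test_zero_diameter(self):
        assert ld_to_cells(0.0, SCALES) == 0.0

    def test_ten_millimeter_lesion(self):
        # 0.75 * (pi/6) * 1000 mm^3 / 8e-6 mm^3/cell
        assert ld_to_cells(10.0, SCALES) == pytest.approx(4.9087e7, rel=1e-4)

    @given(st.floats(0.1, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_exactly_cubic(self, ld):
        assert ld_to_cells(2 * ld, SCALES) == pytest.approx(8 * ld_to_cells(ld, SCALES))

    def test_strictly_increasing(self):
        grid = np.linspace(0.1, 100, 200)
        assert np.all(np.diff(ld_to_cells(grid, SCALES)) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ld_to_cells(-1.0, SCALES)

    @given(st.floats(0.5, 150.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_roundtrip(self, ld):
        assert cells_to_ld(ld_to_cells(ld, SCALES), SCALES) == pytest.approx(ld)


class TestNormalize:
    def test_twenty_millimeter_lesion_normalizes(self):
        rec = normalize(clean(record([(0, 20.0), (42, 20.0)])), SCALES)
        assert rec.y[0] == pytest.approx(0.3927, rel=1e-3)

    def test_pretreatment_scan_has_negative_tau(self):
        rec = normalize(clean(record([(-7, 10.0), (0, 10.0)])), SCALES)
        assert rec.tau[0] == pytest.approx(-0.07)

    def test_tau_scales_linearly_with_time_scale(self):
        doubled = ScaleConstants(time_scale=0.02)
        r1 = normalize(clean(record([(0, 10.0), (42, 11.0)])), SCALES)
        r2 = normalize(clean(record([(0, 10.0), (42, 11.0)])), doubled)
        assert np.allclose(r2.tau, 2 * r1.tau)

    def test_requires_cleaning_first(self):
        with pytest.raises(ValueError, match="clean"):
            normalize(record([(0, 10.0)]), SCALES)


def test_write_read_roundtrip(tmp_path):
    recs = [
        clean(record([(0, 10.0), (42, 12.5), (84, 15.0)], pid="A")),
        clean(record([(0, 30.0), (42, 28.0)], pid="B")),
    ]
    cohort = Cohort(records=recs)
    path = tmp_path / "out.csv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    for orig in recs:
        got = back.get(orig.patient_id)
        assert np.allclose(got.time_days, orig.time_days)
        assert np.allclose(got.ld_mm, orig.ld_mm)


def test_truncate_keeps_leading_measurements():
    rec = normalize(clean(record([(42 * j, 10.0 + j) for j in range(9)])), SCALES)
    head = truncate(rec, 7)
    assert len(head) == 7
    assert np.array_equal(head.y, rec.y[:7])
    with pytest.raises(ValueError):
        truncate(rec, 0)
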