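import numpy as np
import pytest

from cgmficc.ingest_qc import (
    SLOTS_PER_DAY,
    GlucoseReading,
    QCRules,
    apply_qc,
    fill_small_gaps,
    grid_cohort,
    grid_day,
    read_cgm_long,
    readings_to_frame,
)

from conftest import make_curve


def write_csv(tmp_path, rows, name="cgm.csv"):
    path = tmp_path / name
    path.write_text("subject_id,timestamp_min,glucose_mgdl\n" + "\n".join(rows) + "\n")
    return path


class TestReadCgmLong:
    def test_well_formed_rows_in_order(self, tmp_path):
        path = write_csv(tmp_path, ["A,10,100", "A,5,90", "B,0,110"])
        readings = read_cgm_long(path)
        assert [(r.subject_id, r.timestamp, r.glucose) for r in readings] == [
            ("A", 5, 90.0),
            ("A", 10, 100.0),
            ("B", 0, 110.0),
        ]

    def test_out_of_range_clamped_with_warning(self, tmp_path, caplog):
        path = write_csv(tmp_path, ["A,0,420", "A,5,100"])
        with caplog.at_level("WARNING"):
            readings = read_cgm_long(path, clamp=True)
        assert readings[0].glucose == 400.0
        assert "1 reading" in caplog.text

    def test_out_of_range_dropped_when_clamp_off(self, tmp_path):
        path = write_csv(tmp_path, ["A,0,30", "A,5,100"])
        readings = read_cgm_long(path, clamp=False)
        assert len(readings) == 1 and readings[0].glucose == 100.0

    def test_duplicate_timestamp_rejected(self, tmp_path):
        path = write_csv(tmp_path, ["A,0,100", "A,0,105"])
        with pytest.raises(ValueError, match="duplicate"):
            read_cgm_long(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = write_csv(tmp_path, ["A,0,100", "A,5,oops"])
        with pytest.raises(ValueError, match="line 3"):
            read_cgm_long(path)


class TestGridDay:
    def test_on_grid_identity(self):
        readings = [GlucoseReading("A", 5 * s, 100.0 + s) for s in range(SLOTS_PER_DAY)]
        curve = grid_day(readings)
        assert curve.observed_mask.all()
        assert np.array_equal(curve.values, 100.0 + np.arange(SLOTS_PER_DAY))

    def test_colliding_readings_averaged(self):
        curve = grid_day([GlucoseReading("A", 0, 100.0), GlucoseReading("A", 3, 110.0)])
        assert curve.values[0] == 105.0
        assert curve.observed_mask[0] and curve.observed_mask.sum() == 1

    def test_empty_input_all_missing(self):
        curve = grid_day([], subject_id="A", calendar_day=2)
        assert not curve.observed_mask.any() and curve.calendar_day == 2

    def test_mixed_subject_days_rejected(self):
        with pytest.raises(ValueError):
            grid_day([GlucoseReading("A", 0, 100.0), GlucoseReading("B", 5, 100.0)])

    def test_grid_cohort_matches_grid_day(self, rng):
        # off-grid timestamps and collisions, two subjects, two days
        readings = []
        for sid in ("A", "B"):
            for day in range(2):
                ts = np.sort(rng.choice(1440, size=200, replace=False)) + day * 1440
                for t in ts:
                    readings.append(GlucoseReading(sid, int(t), float(rng.uniform(60, 200))))
        by_subject = grid_cohort(readings_to_frame(readings))
        for sid in ("A", "B"):
            for day in range(2):
                subset = [r for r in readings if r.subject_id == sid and r.calendar_day == day]
                direct = grid_day(subset)
                fast = next(c for c in by_subject[sid] if c.calendar_day == day)
                assert np.array_equal(direct.observed_mask, fast.observed_mask)
                assert np.allclose(direct.values[direct.observed_mask], fast.values[fast.observed_mask])


class TestFillSmallGaps:
    def test_interior_gap_linear(self):
        curve = make_curve("A", 1, values={0: 100.0, 3: 130.0})
        filled = fill_small_gaps(curve)
        assert filled.values[1] == 110.0 and filled.values[2] == 120.0
        assert filled.observed_mask.all()
        assert filled.n_imputed == SLOTS_PER_DAY - 2

    def test_complete_curve_unchanged(self):
        curve = make_curve("A", 1, fill_value=123.0)
        filled = fill_small_gaps(curve)
        assert filled.equals(curve)

    def test_leading_gap_nearest_value(self):
        layout = {s: 90.0 if s == 3 else 100.0 for s in range(3, SLOTS_PER_DAY)}
        curve = make_curve("A", 1, values=layout)
        filled = fill_small_gaps(curve)
        assert np.array_equal(filled.values[:3], [90.0, 90.0, 90.0])

    def test_all_missing_rejected(self):
        curve = make_curve("A", 1, values={})
        with pytest.raises(ValueError):
            fill_small_gaps(curve)

    def test_preserves_observed_and_bounds(self, rng):
        for _ in range(20):
            mask = rng.random(SLOTS_PER_DAY) > 0.1
            mask[rng.integers(SLOTS_PER_DAY)] = True
            vals = rng.uniform(60, 250, SLOTS_PER_DAY)
            curve = make_curve("A", 1, values=vals, observed=mask)
            filled = fill_small_gaps(curve)
            assert np.array_equal(filled.values[mask], vals[mask])
            obs = vals[mask]
            assert filled.values.min() >= obs.min() - 1e-12
            assert filled.values.max() <= obs.max() + 1e-12


def gap_curve(sid, day, n_missing, sticks=3):
    mask = np.ones(SLOTS_PER_DAY, bool)
    if n_missing:
        mask[10 : 10 + n_missing] = False
    vals = np.where(mask, 100.0, np.nan)
    return make_curve(sid, day, values=vals, observed=mask, n_fingersticks=sticks)


class TestApplyQC:
    def test_first_day_dropped(self):
        curves = {"A": [gap_curve("A", d, 0) for d in range(6)]}
        series, report = apply_qc(curves, None)
        assert series[0].n_days == 5
        assert report.days_dropped_day1 == 1
        assert all(c.calendar_day != 0 for c in series[0].day_curves)

    def test_two_hour_boundary(self):
        # 25 missing slots (125 min) dropped, 24 (120 min) retained
        curves = {"A": [gap_curve("A", 1, 25), gap_curve("A", 2, 24), gap_curve("A", 3, 0)]}
        series, report = apply_qc(curves, None)
        assert report.days_dropped_gap == 1
        assert {c.calendar_day for c in series[0].day_curves} == {2, 3}

    def test_calibration_rule(self):
        curves = {"A": [gap_curve("A", 1, 0, sticks=2), gap_curve("A", 2, 0), gap_curve("A", 3, 0)]}
        series, report = apply_qc(curves, None)
        assert report.days_dropped_calibration == 1
        assert series[0].n_days == 2

    def test_subject_with_one_day_excluded(self):
        curves = {"A": [gap_curve("A", 1, 0), gap_curve("A", 2, 0)], "B": [gap_curve("B", 1, 0)]}
        series, report = apply_qc(curves, None)
        assert [s.subject_id for s in series] == ["A"]
        assert report.subjects_dropped == ["B"]

    def test_day_conservation(self, rng):
        curves = {}
        for i in range(10):
            sid = f"S{i}"
            curves[sid] = [
                gap_curve(sid, d, int(rng.integers(0, 40)), sticks=int(rng.integers(1, 5)))
                for d in range(int(rng.integers(1, 7)))
            ]
        _, rep = apply_qc(curves, None)
        assert rep.days_in == (
            rep.days_retained
            + rep.days_dropped_day1
            + rep.days_dropped_gap
            + rep.days_dropped_calibration
        )
        for tally in rep.per_subject.values():
            assert tally["days_in"] == (
                tally["retained"] + tally["day1"] + tally["gap"] + tally["calibration"]
            )

    def test_idempotent_on_own_output(self):
        curves = {"A": [gap_curve("A", d, m) for d, m in [(0, 0), (1, 10), (2, 30), (3, 0)]]}
        series, _ = apply_qc(curves, None)
        again, rep2 = apply_qc({s.subject_id: s.day_curves for s in series}, None)
        assert rep2.days_in == rep2.days_retained
        assert len(again) == len(series)
        for s1, s2 in zip(series, again):
            assert all(c1.equals(c2) for c1, c2 in zip(s1.day_curves, s2.day_curves))

    def test_fingerstick_counting(self):
        from cgmficc.ingest_qc import FingerstickReading

        curves = {"A": [gap_curve("A", 1, 0), gap_curve("A", 2, 0)]}
        sticks = [FingerstickReading("A", 1 * 1440 + t, 95.0) for t in (450, 810, 1230)]
        sticks += [FingerstickReading("A", 2 * 1440 + 450, 95.0)]  # day 2: only 1
        series, report = apply_qc(curves, sticks, QCRules(min_days_per_subject=1))
        assert report.days_dropped_calibration == 1
        assert series[0].day_curves[0].n_fingersticks == 3
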