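import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpipd.curve_inputs import (AtRiskTable, CurveInputError, DigitizedCurve,
                                TickSet, compute_cif_increments,
                                compute_decrements, enforce_monotone,
                                load_curve, merge_cif_curves, prepare)


class TestLoadCurve:
    def test_valid_passthrough(self):
        c = load_curve([(1, 0.75), (2, 0.375), (3, 0.0)])
        assert c.times.tolist() == [1, 2, 3]
        assert c.values.tolist() == [0.75, 0.375, 0.0]

    def test_sorts_by_time(self):
        c = load_curve([(2, 0.5), (1, 0.8)])
        assert c.times.tolist() == [1, 2]
        assert c.values.tolist() == [0.8, 0.5]

    def test_clips_small_excursions_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            c = load_curve([(1, 1.004)])
        assert c.values.tolist() == [1.0]

    def test_rejects_large_excursions(self):
        with pytest.raises(CurveInputError):
            load_curve([(1, 1.02)])

    def test_rejects_empty_and_non_numeric(self):
        with pytest.raises(CurveInputError):
            load_curve(io.StringIO("time,value\n"))
        with pytest.raises(CurveInputError):
            load_curve(io.StringIO("time,value\n1,abc\n"))

    def test_reads_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("time,value\n1,0.9\n2,0.5\n")
        c = load_curve(p)
        assert c.values.tolist() == [0.9, 0.5]

    def test_collapses_exact_duplicates(self):
        c = load_curve([(1, 0.9), (1, 0.9), (2, 0.5)])
        assert c.times.tolist() == [1, 2]


class TestEnforceMonotone:
    def test_km_clip_and_drop(self):
        c = DigitizedCurve(times=[1, 2, 3], values=[0.8, 0.81, 0.6])
        out = enforce_monotone(c)
        assert out.times.tolist() == [1, 3]
        assert out.values.tolist() == [0.8, 0.6]

    def test_monotone_input_unchanged(self):
        c = DigitizedCurve(times=[1, 2], values=[0.8, 0.6])
        out = enforce_monotone(c)
        assert out.values.tolist() == [0.8, 0.6]

    def test_cif_clip(self):
        c = DigitizedCurve(times=[1, 2, 3], values=np.array([[0.1], [0.09], [0.3]]),
                           mode="cif")
        out = enforce_monotone(c)
        assert out.times.tolist() == [1, 3]
        assert out.values[:, 0].tolist() == [0.1, 0.3]

    def test_keep_times_preserved(self):
        c = DigitizedCurve(times=[1, 2, 3], values=[0.8, 0.8, 0.6])
        out = enforce_monotone(c, keep_times=[2])
        assert out.times.tolist() == [1, 2, 3]


class TestDecrements:
    @pytest.mark.parametrize("values,expected", [
        ([0.75, 0.375, 0.0], [0.25, 0.5, 1.0]),
        ([0.9, 0.9], [0.1, 0.0]),
        ([1.0], [0.0]),
    ])
    def test_km_examples(self, values, expected):
        assert compute_decrements(values) == pytest.approx(expected)

    def test_rise_after_zero_rejected(self):
        with pytest.raises(CurveInputError):
            compute_decrements([0.5, 0.0, 0.2])

    def test_nelson_aalen_uses_hazard_increments(self):
        assert compute_decrements([0.1, 0.3, 0.9], mode="nelson-aalen") == \
            pytest.approx([0.1, 0.2, 0.6])

    def test_cif_two_cause_example(self):
        f = np.array([[1 / 3, 0.0], [1 / 3, 1 / 3]])
        o = compute_cif_increments(f)
        assert o == pytest.approx(np.array([[1 / 3, 0.0], [0.0, 0.5]]))

    def test_constant_rows_zero_increments(self):
        f = np.array([[0.2, 0.1], [0.2, 0.1]])
        assert compute_cif_increments(f)[1] == pytest.approx([0.0, 0.0])

    @given(st.lists(st.floats(0.01, 0.98), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_single_cause_cif_equals_km_decrements(self, fvals):
        f = np.minimum.accumulate(1 - np.sort(np.asarray(fvals))[::-1])  # 1-f nonincr
        f = 1 - f
        o_cif = compute_cif_increments(f.reshape(-1, 1))[:, 0]
        o_km = compute_decrements(1 - f)
        assert o_cif == pytest.approx(o_km, abs=1e-12)


class TestAtRiskValidation:
    def test_requires_time_zero(self):
        with pytest.raises(CurveInputError):
            AtRiskTable(times=[1, 2], counts=[5, 3])

    def test_rejects_increasing_counts(self):
        with pytest.raises(CurveInputError):
            AtRiskTable(times=[0, 1], counts=[5, 6])

    def test_rejects_non_integer(self):
        with pytest.raises(CurveInputError):
            AtRiskTable(times=[0, 1], counts=[5.0, 2.5])


class TestPrepare:
    def test_grid_and_sets_hand_example(self):
        curve = DigitizedCurve(times=[1, 2, 3], values=[0.8, 0.5, 0.2])
        prob = prepare(curve, at_risk=AtRiskTable(times=[0, 2.5], counts=[10, 4]),
                       ticks=TickSet(times=[1.5]))
        assert prob.times.tolist() == [1, 1.5, 2, 2.5, 3]
        # C_1 = {1, 1.5, 2} (half-open [0, 2.5)); 2.5 and 3 fall in the tail
        assert prob.period.tolist() == [0, 0, 0, -1, -1]
        assert prob.c_star.tolist() == [False, True, False, False, False]
        # inserted times carry values forward: zero decrement there
        assert prob.o[[1, 3]] == pytest.approx([0.0, 0.0])

    def test_no_channels_grid_is_curve(self):
        curve = DigitizedCurve(times=[1, 2], values=[0.8, 0.6])
        prob = prepare(curve, n_total=10)
        assert prob.times.tolist() == [1, 2]
        assert not prob.ticks_available and not prob.at_risk_available

    def test_tick_at_event_time_keeps_both_variables(self):
        curve = DigitizedCurve(times=[1, 2], values=[0.8, 0.6])
        prob = prepare(curve, n_total=10, ticks=TickSet(times=[2.0]))
        i = np.where(prob.times == 2.0)[0][0]
        assert prob.o[i] > 0 and prob.tick_mask[i]
        assert not prob.c_star[i] and not prob.s_star[i]

    def test_periods_partition_grid(self):
        curve = DigitizedCurve(times=np.arange(1, 9) / 2.0,
                               values=np.linspace(0.9, 0.2, 8))
        prob = prepare(curve, at_risk=AtRiskTable(times=[0, 1, 2, 3],
                                                  counts=[20, 15, 10, 6]))
        n_in_periods = sum((prob.period == j).sum() for j in range(prob.leaving.size))
        assert n_in_periods + (prob.period == -1).sum() == prob.times.size

    def test_idempotent_on_own_grid(self):
        curve = DigitizedCurve(times=[1, 2, 3], values=[0.8, 0.5, 0.2])
        ar = AtRiskTable(times=[0, 2.5], counts=[10, 4])
        prob = prepare(curve, at_risk=ar, ticks=TickSet(times=[1.5]))
        again = prepare(DigitizedCurve(times=prob.times, values=prob.values),
                        at_risk=ar, ticks=TickSet(times=[1.5]))
        assert np.array_equal(again.times, prob.times)
        assert again.o == pytest.approx(prob.o)
        assert np.array_equal(again.period, prob.period)

    def test_conflicting_n(self):
        curve = DigitizedCurve(times=[1], values=[0.5])
        with pytest.raises(CurveInputError, match="conflicts"):
            prepare(curve, at_risk=AtRiskTable(times=[0], counts=[10]), n_total=8)

    def test_n_below_event_lower_bound(self):
        curve = DigitizedCurve(times=[1, 2, 3], values=[0.7, 0.4, 0.1])
        with pytest.raises(CurveInputError, match="below"):
            prepare(curve, n_total=2)

    def test_unit_mismatch_report_times(self):
        curve = DigitizedCurve(times=[0.1, 0.2], values=[0.8, 0.6])
        with pytest.raises(CurveInputError, match="units"):
            prepare(curve, at_risk=AtRiskTable(times=[0, 12, 24], counts=[10, 8, 5]))


def test_merge_cif_curves_carries_forward():
    c1 = DigitizedCurve(times=[1, 3], values=np.array([[0.1], [0.3]]), mode="cif",
                        cause_labels=("a",))
    c2 = DigitizedCurve(times=[2], values=np.array([[0.2]]), mode="cif",
                        cause_labels=("b",))
    merged = merge_cif_curves([c1, c2])
    assert merged.times.tolist() == [1, 2, 3]
    assert merged.values[:, 0].tolist() == [0.1, 0.1, 0.3]
    assert merged.values[:, 1].tolist() == [0.0, 0.2, 0.2]
    with pytest.raises(CurveInputError, match="duplicate"):
        merge_cif_curves([c1, c1])
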