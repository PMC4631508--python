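"""Shoulder detection, cohort averaging, and genotype statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from cytomorph import (
    AlignmentSpec,
    align_and_average,
    compare_groups,
    detect_cytokinesis_onset,
    detect_shoulder,
    mutant_timecourse,
    peak_rate,
    percent_change,
    simulate_trace_cohort,
    timecourse_trace,
    wildtype_timecourse,
    window_slope,
)
from cytomorph.trace import TRACE_COLUMNS, GeometryTrace

MUTANT_SPEC = AlignmentSpec(slope_ratio_threshold=0.60)


def make_trace(values, dt=60.0, cell_id=1, column="aspect_ratio"):
    n = len(values)
    df = pd.DataFrame({c: np.ones(n) for c in TRACE_COLUMNS})
    df["frame"] = np.arange(n)
    df["cell_id"] = cell_id
    df[column] = np.asarray(values, dtype=float)
    return GeometryTrace(cell_id, np.arange(n) * dt, df)


class TestWindowSlope:
    def test_constant_series_zero(self):
        tr = make_trace(np.full(30, 2.0))
        assert window_slope(tr.values("aspect_ratio"), tr.times, 15,
                            "forward", 600) == 0.0

    def test_linear_series_recovers_slope_both_directions(self):
        tr = make_trace(1.0 + 0.25 * np.arange(30))  # 0.25 per minute
        for d in ("forward", "backward"):
            assert window_slope(tr.values("aspect_ratio"), tr.times, 15, d,
                                600) == pytest.approx(0.25)

    def test_piecewise_elbow_exact_slopes(self):
        k, m1, m2 = 20, 0.1, 0.7
        x = np.arange(40)
        v = np.where(x <= k, m1 * x, m1 * k + m2 * (x - k))
        tr = make_trace(v)
        assert window_slope(v, tr.times, k, "backward",
                            600) == pytest.approx(m1)
        assert window_slope(v, tr.times, k, "forward",
                            600) == pytest.approx(m2)

    def test_out_of_bounds_window_rejected(self):
        tr = make_trace(np.arange(30.0))
        with pytest.raises(ValueError, match="bounds"):
            window_slope(tr.values("aspect_ratio"), tr.times, 2, "backward",
                         600)


def brute_force_shoulder(trace, spec):
    """Independent exhaustive evaluation of the shoulder criterion."""
    v = trace.values(spec.signal)
    n = len(v)
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    for i in range(n):
        lo = trace.times[i] - spec.window
        hi = trace.times[i] + spec.window
        # the peak forward slope is taken over every index whose forward
        # window fits, even where the backward window does not
        if hi <= trace.times[-1] + 1e-9:
            sel = (trace.times >= trace.times[i]) & (trace.times <= hi + 1e-9)
            fwd[i] = np.polyfit(trace.times[sel] / 60.0, v[sel], 1)[0]
        if lo >= trace.times[0] - 1e-9:
            sel = (trace.times >= lo - 1e-9) & (trace.times <= trace.times[i])
            bwd[i] = np.polyfit(trace.times[sel] / 60.0, v[sel], 1)[0]
    eps = 1e-6 * max(v.max() - v.min(), 1e-300)
    if np.all(np.isnan(fwd)) or not (np.nanmax(fwd) > 0):
        return None
    peak = np.nanmax(fwd)
    for i in range(n):
        if np.isnan(fwd[i]) or np.isnan(bwd[i]):
            continue
        if (fwd[i] > 0
                and fwd[i] >= (1 + spec.slope_ratio_threshold)
                * max(bwd[i], eps)
                and fwd[i] >= spec.peak_fraction * peak):
            return i
    return None


class TestDetectShoulder:
    def test_flat_then_rise_calls_junction(self):
        v = np.concatenate([np.ones(16), 1 + 0.05 * np.arange(1, 25)])
        i0 = detect_shoulder(make_trace(v))
        assert abs(i0 - 15) <= 1

    def test_strictly_linear_trace_is_no_call(self):
        assert detect_shoulder(make_trace(1 + 0.05 * np.arange(40))) is None
        assert detect_shoulder(make_trace(np.ones(40))) is None

    def test_wildtype_scene_onset_recovered(self):
        tc = wildtype_timecourse(onset_frame=12)
        i0 = detect_shoulder(timecourse_trace(tc))
        assert i0 in (11, 12, 13)

    def test_matches_brute_force_oracle_on_synthetic_traces(self):
        rng = np.random.default_rng(0)
        spec = AlignmentSpec()
        traces = [timecourse_trace(wildtype_timecourse(onset_frame=o))
                  for o in (10, 12, 14)]
        traces += [timecourse_trace(mutant_timecourse(onset_frame=11))]
        traces += simulate_trace_cohort(6, "wildtype", seed=3)
        traces += [make_trace(1 + 0.02 * rng.standard_normal(40))
                   for _ in range(4)]
        for tr in traces:
            assert detect_shoulder(tr, spec) == brute_force_shoulder(tr, spec)

    def test_time_offset_equivariance(self):
        tr = timecourse_trace(wildtype_timecourse())
        i0 = detect_shoulder(tr)
        shifted = GeometryTrace(tr.cell_id, tr.times + 300.0, tr.data)
        i1 = detect_shoulder(shifted)
        assert shifted.times[i1] - tr.times[i0] == pytest.approx(300.0)

    def test_onset_recovery_median_error_at_most_one_frame(self):
        errs = []
        for tr in simulate_trace_cohort(20, "wildtype", noise_cv=0.01,
                                        seed=11):
            i0 = detect_shoulder(tr)
            assert i0 is not None
            errs.append(abs(i0 - tr.data.attrs["onset_frame"]))
        assert np.median(errs) <= 1


class TestCytokinesisOnset:
    def test_wildtype_onset_within_two_frames_of_neck_shrink(self):
        tc = wildtype_timecourse()
        i = detect_cytokinesis_onset(timecourse_trace(tc))
        assert abs(i - tc.cytokinesis_onset_frame) <= 2

    def test_mutant_flat_chvr_is_no_call(self):
        tr = timecourse_trace(mutant_timecourse())
        assert detect_cytokinesis_onset(tr) is None

    def test_onset_lag_recovers_programmed_value(self):
        """Elongation-to-furrow lag: detected within 2 frames of the
        programmed 7-min lag (chosen inside the observed 6.6±1.1 min)."""
        tc = wildtype_timecourse(cytokinesis_lag_frames=7)
        tr = timecourse_trace(tc)
        lag = detect_cytokinesis_onset(tr) - detect_shoulder(tr)
        assert abs(lag - 7) <= 2


class TestAlignAndAverage:
    def test_identical_staggered_traces_collapse_with_zero_sem(self):
        base = wildtype_timecourse(onset_frame=10)
        late = wildtype_timecourse(onset_frame=14, n_frames=44)
        g = align_and_average([timecourse_trace(base),
                               timecourse_trace(late)])
        s = g.summary
        assert (s["surface_area_sem"] < 1e-6 * s["surface_area_mean"]).all()

    def test_mean_curve_within_sem_band_of_truth(self):
        traces = simulate_trace_cohort(8, "wildtype", seed=21)
        g = align_and_average(traces)
        truth = timecourse_trace(wildtype_timecourse(onset_frame=10))
        t0 = truth.times[detect_shoulder(truth)]
        truth = truth.shifted(t0)
        s = g.summary
        hits = 0
        total = 0
        for _, row in s.iterrows():
            j = np.flatnonzero(np.isclose(truth.times, row["time_s"]))
            if not len(j):
                continue
            total += 1
            tv = truth.values("surface_area")[j[0]]
            if abs(row["surface_area_mean"] - tv) <= 2 * row["surface_area_sem"] \
                    + 0.01 * tv:
                hits += 1
        assert total > 20 and hits / total >= 0.9

    def test_mutant_group_aspect_ratio_rises_then_declines(self):
        g = align_and_average(simulate_trace_cohort(6, "mutant_arrest",
                                                    seed=2),
                              MUTANT_SPEC)
        m = g.summary["aspect_ratio_mean"].to_numpy()
        ipeak = int(np.argmax(m))
        assert 0 < ipeak < len(m) - 1
        assert m[ipeak] > m[0] + 0.1 and m[ipeak] > m[-1] + 0.1

    def test_fewer_than_two_callable_traces_rejected(self):
        flat = make_trace(np.ones(40))
        ok = timecourse_trace(wildtype_timecourse())
        with pytest.raises(ValueError, match=">= 2"):
            align_and_average([flat, flat, ok])


class TestStatistics:
    def test_percent_change_constant_descriptor_is_zero(self):
        g = align_and_average([timecourse_trace(wildtype_timecourse()),
                               timecourse_trace(
                                   wildtype_timecourse(onset_frame=11,
                                                       n_frames=41))])
        pc = percent_change(g, "volume")
        assert pc.attrs["mean"] == pytest.approx(0.0, abs=0.5)

    def test_idealized_division_surface_area_plus_26_percent(self):
        """Noise-free division trace: surface area +26%, volume conserved."""
        g = align_and_average(
            [timecourse_trace(wildtype_timecourse(onset_frame=o,
                                                  n_frames=40 + o - 10))
             for o in (10, 11)])
        pc = percent_change(g, "surface_area")
        assert pc.attrs["mean"] == pytest.approx(100 * (2 ** (1 / 3) - 1),
                                                 abs=2.0)
        assert abs(percent_change(g, "volume").attrs["mean"]) < 0.5

    def test_peak_rate_linear_and_constant(self):
        n = 40
        df_rows = []
        for cid, offset in ((1, 0.0), (2, 1.0)):
            tr = make_trace(offset + 10.0 * np.arange(n),
                            column="surface_um2", cell_id=cid)
            tr.data["aspect_ratio"] = np.concatenate(
                [np.ones(15), 1 + 0.05 * np.arange(1, n - 14)])
            df_rows.append(tr)
        g = align_and_average(df_rows)
        assert peak_rate(g) == pytest.approx(10.0, rel=0.01)

    def test_peak_rate_recovers_programmed_rate(self):
        """Cohort with a programmed 50 µm²/min ramp: recovered within 10%.

        The ramp plateau (15 min) is wide relative to the 5-point
        derivative smoothing, so the group estimate must land on the
        programmed rate despite 1% descriptor noise and staggered onsets.
        """
        rate = 50.0  # µm²/min
        rng = np.random.default_rng(31)
        traces = []
        for cid in range(8):
            onset = 12 + int(rng.integers(-2, 3))
            n = 45
            f = np.arange(n)
            ramp = np.clip(f - onset, 0, 15)
            sa = 450.0 + rate * ramp
            sa = sa * (1 + 0.01 * rng.standard_normal(n))
            tr = make_trace(np.where(f < onset, 1.0,
                                     1 + 0.04 * np.clip(f - onset, 0, 15)),
                            cell_id=cid + 1)
            tr.data["surface_um2"] = sa
            traces.append(tr)
        g = align_and_average(traces)
        assert peak_rate(g) == pytest.approx(rate, rel=0.10)

    def test_identical_groups_p_one(self):
        t, p = compare_groups(np.array([1.0, 2.0, 3.0]),
                              np.array([1.0, 2.0, 3.0]))
        assert p == pytest.approx(1.0)
        assert compare_groups(np.array([2.0, 2.0]),
                              np.array([2.0, 2.0])) == (0.0, 1.0)

    def test_pooled_t_hand_computed_case(self):
        t, p = compare_groups(np.array([1.0, 2.0, 3.0]),
                              np.array([4.0, 5.0, 6.0]))
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_type_one_error_rate_calibrated(self):
        """Null rejection rate at alpha=0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.standard_normal(10)
            b = rng.standard_normal(10)
            _, p = compare_groups(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_wildtype_vs_arrest_discrimination(self):
        """Default synthetic cohorts (n=8) separate at p < 0.01 on
        surface-area percent change."""
        wt = align_and_average(simulate_trace_cohort(8, "wildtype", seed=41))
        mut = align_and_average(simulate_trace_cohort(8, "mutant_arrest",
                                                      seed=42), MUTANT_SPEC)
        _, p = compare_groups(wt, mut, "surface_area")
        assert p < 0.01
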