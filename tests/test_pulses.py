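"""Time-series pipeline: cleaning, rates, detrending, pulses, ratcheting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseratchet.pulses import (
    NoEventsError,
    NotEnoughPulsesError,
    TooShortError,
    UntrackedAtEvalError,
    categorize_cell,
    constriction_rate,
    detrend_area,
    exclude_short_tracks,
    find_local_extrema,
    find_rate_peaks,
    interpolate_gaps,
    mean_peak_rate,
    peak_triggered_average,
    per_embryo_average,
    ratchet_amplitude,
    smooth_moving_mean,
)
from pulseratchet.synthetic import PulseTraceParams, gen_pulse_trace
from pulseratchet.traces import CellTrace, EmptyTraceError


def make_trace(area, times=None, dt=1.0, **kw):
    area = np.asarray(area, dtype=float)
    if times is None:
        times = np.arange(area.size) * dt
    return CellTrace("e1", "c1", np.asarray(times, float), area, **kw)


# ---------------------------------------------------------------------------
# gap interpolation


class TestInterpolateGaps:
    def test_single_gap_linear_midpoint(self):
        out = interpolate_gaps(make_trace([4, np.nan, 2]))
        np.testing.assert_allclose(out.area_um2, [4, 3, 2])

    def test_run_of_three_left_missing(self):
        out = interpolate_gaps(make_trace([4, np.nan, np.nan, np.nan, 2]))
        assert np.isnan(out.area_um2[1:4]).all()

    def test_run_of_two_interpolated(self):
        out = interpolate_gaps(make_trace([3, np.nan, np.nan, 6]))
        np.testing.assert_allclose(out.area_um2, [3, 4, 5, 6])

    def test_leading_and_trailing_missing_trimmed(self):
        out = interpolate_gaps(make_trace([np.nan, 5, 6, np.nan]))
        np.testing.assert_allclose(out.area_um2, [5, 6])
        np.testing.assert_allclose(out.times_s, [1, 2])

    def test_all_missing_raises(self):
        with pytest.raises(EmptyTraceError):
            interpolate_gaps(make_trace([np.nan, np.nan, np.nan]))


# ---------------------------------------------------------------------------
# smoothing


def brute_force_moving_mean(x, window):
    """Independent oracle: symmetric truncated centered mean."""
    x = np.asarray(x, float)
    n = x.size
    kl, kr = (window - 1) // 2, window // 2
    out = np.empty(n)
    for i in range(n):
        if i - kl < 0 or i + kr > n - 1:
            k = min(i, n - 1 - i)
            lo, hi = i - k, i + k + 1
        else:
            lo, hi = i - kl, i + kr + 1
        out[i] = x[lo:hi].mean()
    return out


class TestSmoothing:
    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(smooth_moving_mean(x, 1), x)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_moving_mean(np.full(9, 3.5), 3), 3.5)

    @pytest.mark.parametrize("window", [2, 3, 5, 10])
    def test_matches_brute_force_oracle(self, window, rng):
        x = rng.normal(size=47)
        np.testing.assert_allclose(
            smooth_moving_mean(x, window), brute_force_moving_mean(x, window)
        )

    def test_empty_raises(self):
        with pytest.raises(EmptyTraceError):
            smooth_moving_mean(np.array([]), 3)


# ---------------------------------------------------------------------------
# rate


class TestConstrictionRate:
    def test_linear_fall_gives_constant_positive_rate(self):
        # area falls at 10 μm²/min on a 6 s grid
        t = np.arange(20) * 6.0
        trace = make_trace(100 - 10.0 / 60.0 * t, times=t)
        rate = constriction_rate(trace, smooth_window=1)
        np.testing.assert_allclose(rate.rate_um2_per_min, 10.0)
        # midpoint timestamps
        np.testing.assert_allclose(rate.times_s, t[:-1] + 3.0)

    def test_constant_area_zero_rate(self):
        rate = constriction_rate(make_trace(np.full(10, 30.0)), smooth_window=1)
        np.testing.assert_allclose(rate.rate_um2_per_min, 0.0)

    def test_linear_rise_gives_negative_rate(self):
        t = np.arange(15) * 6.0
        rate = constriction_rate(
            make_trace(50 + 5.0 / 60.0 * t, times=t), smooth_window=1
        )
        np.testing.assert_allclose(rate.rate_um2_per_min, -5.0)

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            constriction_rate(make_trace([5.0]))


# ---------------------------------------------------------------------------
# detrending


class TestDetrend:
    def test_exact_cubic_leaves_zero_residual(self):
        t = np.linspace(0, 100, 40)
        area = 50 - 0.1 * t + 1e-3 * t**2 - 1e-6 * t**3
        det = detrend_area(make_trace(area, times=t))
        np.testing.assert_allclose(det.residual_um2, 0.0, atol=1e-9)

    def test_reconstruction_identity(self, rng):
        t = np.arange(60) * 3.8
        area = 40 + rng.normal(0, 2, size=60) + 5 * np.sin(t / 20)
        area = np.abs(area) + 1
        trace = make_trace(area, times=t)
        det = detrend_area(trace)
        np.testing.assert_allclose(det.reconstruct(), area, rtol=1e-9)

    def test_cubic_plus_sine_residual_matches_lstsq_oracle(self, rng):
        t = np.arange(80) * 2.0
        sine = 3 * np.sin(2 * np.pi * t / 70)
        area = 60 - 0.05 * t + sine
        det = detrend_area(make_trace(area, times=t))
        # independent oracle: residual of the sine against its own cubic fit
        design = np.vander(t, 4)
        beta, *_ = np.linalg.lstsq(design, sine, rcond=None)
        expected = sine - design @ beta
        np.testing.assert_allclose(det.residual_um2, expected, atol=1e-8)

    def test_too_few_samples_raises(self):
        with pytest.raises(TooShortError):
            detrend_area(make_trace([1, 2, 3, 4.0]))


# ---------------------------------------------------------------------------
# extrema


def brute_force_extrema(x, kind):
    """Exhaustive neighbor scan with first-of-plateau rule."""
    x = np.asarray(x, float)
    if kind == "minima":
        x = -x
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if x[i - 1] < x[i] and j + 1 < n and x[j + 1] < x[i]:
            out.append(i)
        i = j + 1
    return out


class TestExtrema:
    def test_simple_peak(self):
        ev = find_local_extrema([1, 3, 1], "maxima")
        assert ev.indices.tolist() == [1]
        assert ev.values.tolist() == [3]

    def test_monotone_has_none(self):
        assert len(find_local_extrema(np.arange(10.0), "maxima")) == 0
        assert len(find_local_extrema(np.arange(10.0), "minima")) == 0

    def test_plateau_reports_first_sample(self):
        ev = find_local_extrema([0, 2, 2, 2, 1], "maxima")
        assert ev.indices.tolist() == [1]

    def test_endpoints_never_extrema(self):
        assert len(find_local_extrema([5, 1, 0], "maxima")) == 0

    def test_short_input_empty(self):
        assert len(find_local_extrema([1, 2], "maxima")) == 0

    @pytest.mark.parametrize("kind", ["maxima", "minima"])
    def test_matches_exhaustive_scan_on_random_sequences(self, kind):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            # small integer alphabet provokes plenty of ties and plateaus
            x = rng.integers(0, 5, size=n).astype(float)
            ev = find_local_extrema(x, kind)
            assert ev.indices.tolist() == brute_force_extrema(x, kind), x

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=3, max_size=25))
    def test_property_agrees_with_oracle(self, values):
        x = np.array(values, dtype=float)
        ev = find_local_extrema(x, "maxima")
        assert ev.indices.tolist() == brute_force_extrema(x, "maxima")


# ---------------------------------------------------------------------------
# ratchet statistic


class TestRatchet:
    def test_staircase_with_two_percent_drops(self):
        # zig-zag whose successive raw-area maxima fall by 2% of initial
        initial = 100.0
        area = []
        for k in range(6):
            peak = initial * (1 - 0.02 * k)
            area += [peak, peak - 6.0]
        trace = make_trace(np.array(area), dt=5.0)
        res = ratchet_amplitude(trace)
        assert res.mean_interpeak_diff == pytest.approx(-2.0, abs=0.05)

    def test_pure_sinusoid_is_flat(self):
        t = np.arange(0, 300, 2.0)
        area = 50 + 4 * np.sin(2 * np.pi * t / 60)
        res = ratchet_amplitude(make_trace(area, times=t))
        assert abs(res.mean_interpeak_diff) < 0.1

    def test_generator_full_vs_no_ratchet(self):
        def cohort_mean(e):
            vals = []
            for seed in range(8):
                p = PulseTraceParams(
                    duration_s=500,
                    initial_area_um2=60,
                    pulse_amplitude_um2=3.0,
                    ratchet_efficiency=e,
                    seed=seed,
                    trend_coeffs=(0, 0, 0, 0),
                )
                trace, _ = gen_pulse_trace(p)
                vals.append(ratchet_amplitude(trace).mean_interpeak_diff)
            return np.mean(vals)

        full = cohort_mean(1.0)
        none = cohort_mean(0.0)
        assert full < -1.0
        assert abs(none) < 0.3
        # monotone in efficiency
        means = [cohort_mean(e) for e in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_insufficient_extrema_raises(self):
        t = np.arange(10) * 3.0
        with pytest.raises(NotEnoughPulsesError):
            ratchet_amplitude(make_trace(50 - 0.1 * t, times=t))


# ---------------------------------------------------------------------------
# rate peaks


class TestRatePeaks:
    def _rate_trace(self, rates_per_min, dt=60.0):
        # build areas whose finite-difference rates equal the given sequence
        area = [100.0]
        for r in rates_per_min:
            area.append(area[-1] - r * dt / 60.0)
        return make_trace(np.array(area), dt=dt)

    def test_single_constriction_peak(self):
        trace = self._rate_trace([-1, 2, -1])
        rate = constriction_rate(trace, smooth_window=1)
        ev = find_rate_peaks(rate, "constriction")
        assert ev.values.tolist() == [pytest.approx(2.0)]

    def test_all_negative_rate_yields_no_peaks(self):
        trace = self._rate_trace([-1, -0.2, -1])
        rate = constriction_rate(trace, smooth_window=1)
        assert len(find_rate_peaks(rate, "constriction")) == 0

    def test_polarity_symmetry(self, rng):
        from pulseratchet.pulses import RateSeries

        r = rng.normal(size=50)
        t = np.arange(50, dtype=float)
        fwd = RateSeries(t, r, smoothed=False, window_points=1)
        rev = RateSeries(t, -r, smoothed=False, window_points=1)
        a = find_rate_peaks(fwd, "constriction")
        b = find_rate_peaks(rev, "expansion")
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_allclose(a.values, b.values)

    def test_mean_peak_rate_averages_peaks(self):
        trace = self._rate_trace([-1, 8, -1, 12, -1])
        assert mean_peak_rate(trace, "constriction") == pytest.approx(10.0)

    def test_mean_peak_rate_single_peak(self):
        trace = self._rate_trace([-1, 7.5, -1])
        assert mean_peak_rate(trace, "constriction") == pytest.approx(7.5)

    def test_no_peaks_raises(self):
        trace = self._rate_trace([-1, -2, -1])
        with pytest.raises(NoEventsError):
            mean_peak_rate(trace, "constriction")


# ---------------------------------------------------------------------------
# categorization


def step_trace(final_ratio, initial=100.0, dt=10.0, duration=600.0):
    """Area constant at `initial`, stepping to final_ratio·initial at 100 s."""
    t = np.arange(0, duration + dt, dt)
    area = np.where(t < 100, initial, final_ratio * initial)
    return make_trace(area, times=t)


class TestCategorize:
    @pytest.mark.parametrize(
        "ratio,label",
        [
            (0.4, "constricted"),
            (0.7, "impaired"),
            (1.2, "expanded"),
            (0.5, "impaired"),
            (1.0, "impaired"),
        ],
    )
    def test_boundaries(self, ratio, label):
        cat = categorize_cell(step_trace(ratio))
        assert cat.label == label
        assert cat.area_ratio_at_eval == pytest.approx(ratio)

    def test_untracked_at_eval_raises(self):
        with pytest.raises(UntrackedAtEvalError):
            categorize_cell(step_trace(0.4, duration=300.0))


# ---------------------------------------------------------------------------
# exclusion rule


class TestExcludeShortTracks:
    def test_equal_durations_nothing_excluded(self):
        cells = [make_trace(np.full(31, 20.0), dt=10.0) for _ in range(5)]
        kept, report = exclude_short_tracks(cells)
        assert len(kept) == 5
        assert not any(r["excluded"] for r in report.values())

    def test_single_short_track_excluded(self):
        long_cells = [
            CellTrace("e1", f"c{i}", np.arange(0, 301, 3.0), np.full(101, 20.0))
            for i in range(100)
        ]
        short = CellTrace("e1", "short", np.arange(0, 11, 5.0), np.full(3, 20.0))
        kept, report = exclude_short_tracks(long_cells + [short])
        assert report["short"]["excluded"]
        assert len(kept) == 100
        # oracle: cutoff = median - 1 SD of the durations
        durations = np.array([300.0] * 100 + [10.0])
        cutoff = np.median(durations) - np.std(durations, ddof=1)
        assert 10.0 < cutoff <= 300.0

    def test_empty_cohort(self):
        kept, report = exclude_short_tracks([])
        assert kept == [] and report == {}


# ---------------------------------------------------------------------------
# peak-triggered averaging


class TestTriggeredAverage:
    def _trace_with_peak(self):
        p = PulseTraceParams(
            duration_s=400,
            initial_area_um2=60,
            pulse_period_s=120.0,
            pulse_amplitude_um2=4.0,
            ratchet_efficiency=0.5,
            first_pulse_s=100.0,
            trend_coeffs=(0, 0, 0, 0),
        )
        trace, _ = gen_pulse_trace(p)
        rate = constriction_rate(trace, smooth_window=1)
        events = find_rate_peaks(rate, "constriction")
        return trace, events

    def test_single_peak_mean_is_window_and_sd_zero(self):
        trace, events = self._trace_with_peak()
        # keep only the first peak to guarantee a single isolated event
        first = events.__class__(
            events.kind, events.indices[:1], events.times_s[:1], events.values[:1]
        )
        avg = peak_triggered_average([trace], [first])
        assert avg.n_peaks == 1
        np.testing.assert_allclose(avg.sd["area"], 0.0)
        assert avg.lag_grid_s[0] == -avg.lag_grid_s[-1]
        # mean at lag 0 equals the rate at the peak
        i0 = np.argmin(np.abs(avg.lag_grid_s))
        assert avg.mean["rate"][i0] == pytest.approx(first.values[0], rel=1e-6)

    def test_two_identical_traces_sd_zero(self):
        trace, events = self._trace_with_peak()
        first = events.__class__(
            events.kind, events.indices[:1], events.times_s[:1], events.values[:1]
        )
        avg = peak_triggered_average([trace, trace], [first, first])
        assert avg.n_peaks == 2
        np.testing.assert_allclose(avg.sd["area"], 0.0, atol=1e-12)

    def test_reporter_rises_across_constriction_peaks(self, control_cohort):
        traces, _ = control_cohort
        traces = traces[:10]
        events = [
            find_rate_peaks(constriction_rate(t, smooth_window=1), "constriction")
            for t in traces
        ]
        avg = peak_triggered_average(traces, events)
        assert avg.mean["intensity"][-1] >= avg.mean["intensity"][0]

    def test_no_isolated_peaks_raises(self):
        trace, _ = self._trace_with_peak()
        empty = find_rate_peaks(
            constriction_rate(make_trace(np.full(30, 50.0)), smooth_window=1),
            "constriction",
        )
        with pytest.raises(NoEventsError):
            peak_triggered_average([trace], [empty])


# ---------------------------------------------------------------------------
# two-stage averaging


class TestPerEmbryoAverage:
    def test_one_embryo_two_cells(self):
        t = np.arange(5, dtype=float)
        cells = [
            CellTrace("e1", "a", t, np.full(5, 2.0)),
            CellTrace("e1", "b", t, np.full(5, 4.0)),
        ]
        times, per_embryo, grand, sd = per_embryo_average(cells)
        np.testing.assert_allclose(per_embryo["e1"], 3.0)
        np.testing.assert_allclose(grand, 3.0)
        np.testing.assert_allclose(sd, 0.0)

    def test_two_embryos_constant_means(self):
        t = np.arange(4, dtype=float)
        cells = [
            CellTrace("e1", "a", t, np.full(4, 3.0)),
            CellTrace("e2", "b", t, np.full(4, 5.0)),
        ]
        _, _, grand, sd = per_embryo_average(cells)
        np.testing.assert_allclose(grand, 4.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_matches_brute_force_oracle(self, rng):
        t = np.arange(6, dtype=float)
        cells = []
        values = {}
        for e in range(3):
            for c in range(4):
                a = np.abs(rng.normal(30, 5, size=6)) + 1
                cells.append(CellTrace(f"e{e}", f"e{e}c{c}", t, a))
                values.setdefault(e, []).append(a)
        _, per_embryo, grand, sd = per_embryo_average(cells)
        embryo_means = np.array([np.mean(values[e], axis=0) for e in range(3)])
        for e in range(3):
            np.testing.assert_allclose(per_embryo[f"e{e}"], embryo_means[e])
        np.testing.assert_allclose(grand, embryo_means.mean(axis=0))
        np.testing.assert_allclose(sd, embryo_means.std(axis=0, ddof=1))
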