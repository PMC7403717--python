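"""Per-cell pulsation analysis for apical-constriction time series.

The operations here reproduce, step by step, the standard analysis chain for
pulsatile apical constriction during ventral furrow formation:

* gap interpolation of short segmentation dropouts,
* centered moving-mean smoothing,
* constriction rate as a finite-difference quotient (positive = constricting,
  μm²/min),
* cubic-polynomial detrending of the area signal,
* strict local-extrema (pulse) detection with a deterministic plateau rule,
* the ratchet statistic: mean difference in area between consecutive
  pulsation peaks, as a percentage of the initial area (negative values mean
  the surface shrinks incrementally — a ratchet; values near zero mean the
  surface relaxes back — no ratchet),
* rate-peak detection (constriction and expansion polarity) with the rule
  that only positive peaks count,
* cell categorization by the area ratio 7 min after onset
  (< 0.5 constricted; 0.5–1 impaired; > 1 expanded),
* a tracked-duration exclusion rule, peak-triggered averaging in ±25 s
  windows, and two-stage (cell → embryo) averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .traces import CellTrace, EmptyTraceError

__all__ = [
    "RateSeries",
    "DetrendedTrace",
    "PulseEvents",
    "RatchetResult",
    "CellCategory",
    "TriggeredAverage",
    "TooShortError",
    "NotEnoughPulsesError",
    "UntrackedAtEvalError",
    "NoEventsError",
    "interpolate_gaps",
    "smooth_moving_mean",
    "constriction_rate",
    "detrend_area",
    "find_local_extrema",
    "ratchet_amplitude",
    "find_rate_peaks",
    "mean_peak_rate",
    "categorize_cell",
    "exclude_short_tracks",
    "peak_triggered_average",
    "per_embryo_average",
]


class TooShortError(ValueError):
    """Trace has too few measured samples for the requested operation."""


class NotEnoughPulsesError(ValueError):
    """Fewer than two same-kind extrema: the ratchet statistic is undefined."""


class UntrackedAtEvalError(ValueError):
    """Trace does not cover the categorization evaluation time."""


class NoEventsError(ValueError):
    """No (isolated) peaks available for the requested statistic."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class RateSeries:
    """Finite-difference constriction rate at interval midpoints.

    ``rate_um2_per_min`` is positive while the cell constricts (area falls)
    and negative while it expands — the field's sign convention.
    """

    times_s: np.ndarray
    rate_um2_per_min: np.ndarray
    smoothed: bool
    window_points: int

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class DetrendedTrace:
    """Residual area after removing a least-squares cubic trend."""

    times_s: np.ndarray
    residual_um2: np.ndarray
    trend_coeffs: np.ndarray  # highest power first, np.polyval convention

    def trend(self) -> np.ndarray:
        return np.polyval(self.trend_coeffs, self.times_s)

    def reconstruct(self) -> np.ndarray:
        return self.residual_um2 + self.trend()


EventKind = Literal[
    "area_max", "area_min", "rate_constriction_peak", "rate_expansion_peak"
]


@dataclass
class PulseEvents:
    """Detected pulsation events: strict local extrema of a source signal."""

    kind: EventKind
    indices: np.ndarray
    times_s: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class RatchetResult:
    """Ratchet statistic for one cell (% of initial area per pulse interval)."""

    cell_id: str
    mean_interpeak_diff: float
    n_maxima: int
    n_minima: int


@dataclass
class CellCategory:
    label: Literal["constricted", "impaired", "expanded"]
    area_ratio_at_eval: float


@dataclass
class TriggeredAverage:
    """Peak-aligned mean ± SD of area, rate and reporter intensity."""

    lag_grid_s: np.ndarray
    mean: dict
    sd: dict
    n_peaks: int


# ---------------------------------------------------------------------------
# cleaning and smoothing


def interpolate_gaps(trace: CellTrace, max_gap: int = 2) -> CellTrace:
    """Fill short segmentation dropouts by linear interpolation.

    Interior runs of at most ``max_gap`` missing frames (default 2: gaps
    *smaller than three* time points) are linearly interpolated between the
    flanking measured values; longer runs are left missing. Leading and
    trailing missing frames have no anchor on one side and are trimmed.
    """
    present = trace.present
    idx = np.flatnonzero(present)
    if idx.size == 0:
        raise EmptyTraceError("trace has no measured area values")
    trace = trace.take(np.arange(idx[0], idx[-1] + 1))
    present = trace.present
    area = trace.area_um2.copy()

    missing = ~present
    if missing.any():
        # run-length encode the missing stretches (all interior after trim)
        edges = np.diff(missing.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1  # exclusive
        for s, e in zip(starts, ends):
            if e - s <= max_gap:
                t0, t1 = trace.times_s[s - 1], trace.times_s[e]
                a0, a1 = area[s - 1], area[e]
                area[s:e] = a0 + (a1 - a0) * (trace.times_s[s:e] - t0) / (t1 - t0)
    return trace.with_area(area)


def smooth_moving_mean(series: Sequence[float], window_points: int) -> np.ndarray:
    """Centered moving mean with symmetric truncation at the boundaries.

    For an odd window ``2k+1`` the output at index ``i`` averages indices
    ``i±min(k, i, n-1-i)``; an even window ``w`` uses half-widths
    ``(w-1)//2`` left and ``w//2`` right, truncated the same way. Output
    length equals input length. NaNs are ignored inside the window but
    preserved at their own positions.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise EmptyTraceError("cannot smooth an empty series")
    if window_points < 1 or window_points > x.size:
        raise ValueError("window_points must be in [1, len(series)]")
    if window_points == 1:
        return x.copy()
    kl = (window_points - 1) // 2
    kr = window_points // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        k_left = min(kl, i)
        k_right = min(kr, n - 1 - i)
        k = min(k_left, k_right) if k_left != kl or k_right != kr else None
        if k is None:
            lo, hi = i - kl, i + kr + 1
        else:
            lo, hi = i - k, i + k + 1
        window = x[lo:hi]
        finite = window[np.isfinite(window)]
        out[i] = finite.mean() if finite.size else np.nan
    out[~np.isfinite(x)] = np.nan
    return out


# ---------------------------------------------------------------------------
# rates and detrending


def constriction_rate(trace: CellTrace, smooth_window: int = 10) -> RateSeries:
    """Constriction rate in μm²/min at interval midpoints.

    ``rate_i = -(A_{i+1} - A_i) / (t_{i+1} - t_i) * 60``, so a shrinking
    area gives positive values. ``smooth_window`` applies a centered moving
    mean to the rate (window of 10 points for presentation; pass 1 for the
    unsmoothed rate used in peak detection).
    """
    if trace.n_present < 2:
        raise TooShortError("need at least 2 measured samples for a rate")
    dt = np.diff(trace.times_s)
    if dt.max() / dt.min() >= 2:
        raise ValueError("sampling too irregular (max/min interval ratio >= 2)")
    da = np.diff(trace.area_um2)
    rate = -(da / dt) * 60.0
    mid = trace.times_s[:-1] + dt / 2.0
    window = min(smooth_window, rate.size)
    if window > 1:
        rate = smooth_moving_mean(rate, window)
    return RateSeries(
        times_s=mid,
        rate_um2_per_min=rate,
        smoothed=window > 1,
        window_points=window,
    )


def detrend_area(trace: CellTrace) -> DetrendedTrace:
    """Remove a least-squares cubic trend from the area signal.

    The trend is fit on the measured samples only; the residual is
    ``area - trend`` (NaN where area is missing).
    """
    present = trace.present
    if present.sum() < 5:
        raise TooShortError("need at least 5 measured samples to detrend")
    coeffs = np.polyfit(trace.times_s[present], trace.area_um2[present], 3)
    residual = trace.area_um2 - np.polyval(coeffs, trace.times_s)
    return DetrendedTrace(
        times_s=trace.times_s.copy(), residual_um2=residual, trend_coeffs=coeffs
    )


# ---------------------------------------------------------------------------
# extrema and pulses


def _strict_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima with a first-of-plateau rule.

    A flat-topped run strictly above both flanks reports its first sample;
    endpoints are never maxima.
    """
    n = x.size
    if n < 3:
        return np.empty(0, dtype=int)
    out = []
    i = 1
    while i < n - 1:
        if not np.isfinite(x[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        # plateau (possibly length 1) runs from i to j inclusive
        left_ok = np.isfinite(x[i - 1]) and x[i - 1] < x[i]
        right_ok = j + 1 < n and np.isfinite(x[j + 1]) and x[j + 1] < x[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return np.asarray(out, dtype=int)


def find_local_extrema(
    series: Sequence[float],
    kind: Literal["maxima", "minima"],
    times_s: Optional[np.ndarray] = None,
    event_kind: Optional[EventKind] = None,
) -> PulseEvents:
    """Strict local maxima or minima of a 1-D signal.

    Minima are found by negating the series. Sequences shorter than 3
    return an empty event set.
    """
    x = np.asarray(series, dtype=float)
    if kind not in ("maxima", "minima"):
        raise ValueError("kind must be 'maxima' or 'minima'")
    sig = x if kind == "maxima" else -x
    idx = _strict_maxima(sig)
    if times_s is None:
        times_s = np.arange(x.size, dtype=float)
    if event_kind is None:
        event_kind = "area_max" if kind == "maxima" else "area_min"
    return PulseEvents(
        kind=event_kind,
        indices=idx,
        times_s=np.asarray(times_s, dtype=float)[idx],
        values=x[idx],
    )


def ratchet_amplitude(trace: CellTrace, diff_on_raw: bool = True) -> RatchetResult:
    """Mean area difference between consecutive pulsation peaks.

    Pipeline: cubic detrend → strict local maxima and minima of the
    residual → for each extremum kind, mean of consecutive differences
    evaluated on the raw area at the extremum indices (``diff_on_raw=False``
    evaluates them on the residual instead) → average of the per-kind means,
    expressed as % of the initial area. Negative values indicate ratcheting;
    values near zero indicate that pulses relax back.
    """
    det = detrend_area(trace)
    source = trace.area_um2 if diff_on_raw else det.residual_um2
    kind_means = []
    n_by_kind = {}
    for kind in ("maxima", "minima"):
        events = find_local_extrema(det.residual_um2, kind, times_s=trace.times_s)
        n_by_kind[kind] = len(events)
        if len(events) >= 2:
            vals = source[events.indices]
            kind_means.append(np.mean(np.diff(vals)))
    if not kind_means:
        raise NotEnoughPulsesError(
            "need >= 2 maxima or >= 2 minima on the detrended signal"
        )
    mean_diff = float(np.mean(kind_means)) / trace.initial_area_um2 * 100.0
    return RatchetResult(
        cell_id=trace.cell_id,
        mean_interpeak_diff=mean_diff,
        n_maxima=n_by_kind["maxima"],
        n_minima=n_by_kind["minima"],
    )


def find_rate_peaks(
    rate: RateSeries, polarity: Literal["constriction", "expansion"]
) -> PulseEvents:
    """Positive pulsation peaks of the (unsmoothed) constriction rate.

    Expansion is analyzed by negating the rate. Local maxima with
    non-positive values are discarded.
    """
    if polarity not in ("constriction", "expansion"):
        raise ValueError("polarity must be 'constriction' or 'expansion'")
    signal = rate.rate_um2_per_min if polarity == "constriction" else -rate.rate_um2_per_min
    events = find_local_extrema(
        signal,
        "maxima",
        times_s=rate.times_s,
        event_kind=(
            "rate_constriction_peak"
            if polarity == "constriction"
            else "rate_expansion_peak"
        ),
    )
    keep = events.values > 0
    return PulseEvents(
        kind=events.kind,
        indices=events.indices[keep],
        times_s=events.times_s[keep],
        values=events.values[keep],
    )


def mean_peak_rate(
    trace: CellTrace, polarity: Literal["constriction", "expansion"]
) -> float:
    """Per-cell mean of positive rate-peak values (μm²/min).

    Peaks are detected on the unsmoothed finite-difference rate. A cell
    without any peak of the requested polarity raises :class:`NoEventsError`
    and is excluded from that group statistic.
    """
    rate = constriction_rate(trace, smooth_window=1)
    peaks = find_rate_peaks(rate, polarity)
    if len(peaks) == 0:
        raise NoEventsError(f"no {polarity} peaks in cell {trace.cell_id}")
    return float(np.mean(peaks.values))


# ---------------------------------------------------------------------------
# categorization and cohort-level helpers


def categorize_cell(
    trace: CellTrace, eval_time_s: float = 420.0, smooth_window: int = 3
) -> CellCategory:
    """Classify a cell by its area ratio 7 min after onset.

    The ratio is the 3-point-smoothed area at the sample nearest
    ``eval_time_s`` divided by the smoothed initial area. Boundaries follow
    the interval notation (< 0.5; 0.5 < 1; > 1): exactly 0.5 and exactly
    1.0 are 'impaired'.
    """
    present_idx = np.flatnonzero(trace.present)
    if present_idx.size == 0:
        raise EmptyTraceError("trace has no measured area values")
    t0 = trace.times_s[present_idx[0]]
    if trace.times_s[present_idx[-1]] - t0 < eval_time_s:
        raise UntrackedAtEvalError(
            f"cell {trace.cell_id} not tracked through {eval_time_s} s"
        )
    smoothed = smooth_moving_mean(trace.area_um2, min(smooth_window, len(trace)))
    target = t0 + eval_time_s
    i_eval = int(np.argmin(np.abs(trace.times_s - target)))
    ratio = float(smoothed[i_eval] / smoothed[present_idx[0]])
    if ratio < 0.5:
        label = "constricted"
    elif ratio <= 1.0:
        label = "impaired"
    else:
        label = "expanded"
    return CellCategory(label=label, area_ratio_at_eval=ratio)


def exclude_short_tracks(cohort: Iterable[CellTrace]):
    """Drop cells tracked for less than (median − 1 SD) of the durations.

    Returns ``(kept, report)`` where ``report`` maps each cell id to its
    tracked duration and whether it was excluded. SD uses the n−1
    denominator; with fewer than 2 cells nothing is excluded.
    """
    cells = list(cohort)
    durations = np.array([c.duration_s for c in cells])
    if len(cells) < 2:
        cutoff = -np.inf
    else:
        cutoff = float(np.median(durations) - np.std(durations, ddof=1))
    kept = [c for c, d in zip(cells, durations) if d >= cutoff]
    report = {
        c.cell_id: {"duration_s": float(d), "excluded": bool(d < cutoff)}
        for c, d in zip(cells, durations)
    }
    return kept, report


def _isolated(events: PulseEvents, half_window_s: float) -> np.ndarray:
    """Mask of peaks with no same-polarity peak within the half window."""
    t = events.times_s
    ok = np.ones(t.size, dtype=bool)
    for i in range(t.size):
        others = np.delete(t, i)
        if others.size and np.min(np.abs(others - t[i])) <= half_window_s:
            ok[i] = False
    return ok


def peak_triggered_average(
    traces: Sequence[CellTrace],
    events_per_trace: Sequence[PulseEvents],
    half_window_s: float = 25.0,
    lag_step_s: Optional[float] = None,
) -> TriggeredAverage:
    """Event-aligned averaging of area, rate and reporter intensity.

    For every *isolated* peak (no same-polarity peak within
    ``half_window_s``), the raw area, unsmoothed rate and intensity are
    sampled on a common lag grid centered at the peak (linear interpolation
    in time); windows that would extend past the trace are dropped. Returns
    the per-lag mean and SD over all collected windows.
    """
    if len(traces) != len(events_per_trace):
        raise ValueError("need one PulseEvents per trace")
    if lag_step_s is None:
        dts = np.diff(traces[0].times_s)
        lag_step_s = float(np.median(dts))
    n_half = int(round(half_window_s / lag_step_s))
    lags = np.arange(-n_half, n_half + 1) * lag_step_s

    windows: dict[str, list[np.ndarray]] = {"area": [], "rate": [], "intensity": []}
    n_peaks = 0
    for trace, events in zip(traces, events_per_trace):
        if len(events) == 0:
            continue
        rate = constriction_rate(trace, smooth_window=1)
        keep = _isolated(events, half_window_s)
        for t_peak in events.times_s[keep]:
            grid = t_peak + lags
            if grid[0] < trace.times_s[0] or grid[-1] > trace.times_s[-1]:
                continue
            if grid[0] < rate.times_s[0] or grid[-1] > rate.times_s[-1]:
                continue
            windows["area"].append(np.interp(grid, trace.times_s, trace.area_um2))
            windows["rate"].append(np.interp(grid, rate.times_s, rate.rate_um2_per_min))
            if trace.intensity is not None:
                windows["intensity"].append(
                    np.interp(grid, trace.times_s, trace.intensity)
                )
            n_peaks += 1
    if n_peaks == 0:
        raise NoEventsError("no isolated peaks with complete windows")
    mean = {}
    sd = {}
    for name, stack in windows.items():
        if not stack:
            continue
        arr = np.vstack(stack)
        mean[name] = arr.mean(axis=0)
        sd[name] = arr.std(axis=0, ddof=0)
    return TriggeredAverage(lag_grid_s=lags, mean=mean, sd=sd, n_peaks=n_peaks)


def per_embryo_average(cohort: Sequence[CellTrace], signal: str = "area_um2"):
    """Two-stage averaging: cells within embryo, then across embryos.

    All traces must share a common time base (samples are matched by time
    value). Returns ``(times, per_embryo_means, grand_mean, sd)`` where
    ``per_embryo_means`` maps embryo id → mean series and the SD (n−1) is
    computed across embryo means at each time point.
    """
    cells = list(cohort)
    if not cells:
        raise EmptyTraceError("empty cohort")
    all_times = np.unique(np.concatenate([c.times_s for c in cells]))
    embryos = sorted({c.embryo_id for c in cells})
    per_embryo = {}
    for emb in embryos:
        rows = []
        for c in cells:
            if c.embryo_id != emb:
                continue
            values = getattr(c, signal) if signal != "area_um2" else c.area_um2
            row = np.full(all_times.size, np.nan)
            pos = np.searchsorted(all_times, c.times_s)
            row[pos] = values
            rows.append(row)
        with np.errstate(invalid="ignore"):
            per_embryo[emb] = np.nanmean(np.vstack(rows), axis=0)
    stack = np.vstack([per_embryo[e] for e in embryos])
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(stack, axis=0)
        if len(embryos) >= 2:
            sd = np.nanstd(stack, axis=0, ddof=1)
        else:
            sd = np.zeros_like(grand)
    return all_times, per_embryo, grand, sd
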