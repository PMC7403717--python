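"""Synthetic data with known ground truth for the analysis pipeline.

No imaging data from the original study are publicly available, so every
stage of the pipeline is exercised on synthetic inputs that emulate the
measurements:

* **Pulse traces** — per-cell apical-area time series built from a smooth
  pulse waveform: a raised-cosine constriction of amplitude ``A`` followed
  by a raised-cosine relaxation that returns ``(1 - e)·A`` of the lost
  area, where ``e`` is the *ratchet efficiency*. ``e = 1`` produces a
  strictly non-increasing staircase (full ratchet); ``e = 0`` returns the
  surface to its pre-pulse level (no ratchet). A polynomial baseline drift
  and Gaussian measurement noise can be added on top. A reporter-intensity
  channel rises in proportion to instantaneous constriction and is flat
  otherwise.
* **Cell cohorts** — mixtures of behavioral classes (constricted /
  impaired / expanded) whose per-class peak constriction and expansion
  rates are drawn from configurable normal distributions. Defaults encode
  the study conditions: control-like cells peaking at 9.9 ± 1.1 μm²/min
  constriction and 3.2 ± 0.8 μm²/min expansion, knockdown-like deficient
  cells at 7.5 ± 1.2 and 5.1 ± 1.4 μm²/min, sampling interval 3.8 s, pulse
  periods of 60–90 s, and class mixes assigned exactly by largest-remainder
  rounding.
* **Surface phantoms** — 3-D stacks containing a bright band centered on a
  known height map (flat, tilted plane, sinusoid or paraboloid), for
  validating the surface-projection algorithm.
* **Labeled movies** — 2-D integer label movies plus matched intensity
  movies with prescribed per-cell areas and intensities, for validating
  per-cell intensity quantification.

Each generator is deterministic for a fixed seed; per-cell random streams
are derived by stable hashing of (seed, embryo index, cell index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .traces import CellTrace

__all__ = [
    "InvalidParametersError",
    "LayoutInfeasibleError",
    "PulseTraceParams",
    "PulseTraceTruth",
    "ClassRateSpec",
    "CohortParams",
    "CohortTruth",
    "SurfacePhantomParams",
    "LabeledMovieParams",
    "gen_pulse_trace",
    "gen_cohort",
    "gen_surface_phantom",
    "gen_labeled_movie",
    "largest_remainder_counts",
    "control_cohort_params",
    "knockdown_cohort_params",
    "CONTROL_CLASS_SPECS",
    "KNOCKDOWN_CLASS_SPECS",
]


class InvalidParametersError(ValueError):
    """Parameter set is internally inconsistent or drives the area ≤ 0."""


class LayoutInfeasibleError(ValueError):
    """Requested cell layout cannot be placed without label overlap."""


# ---------------------------------------------------------------------------
# pulse waveform


def _pulse_delta(
    t: np.ndarray,
    start_s: float,
    amplitude: float,
    efficiency: float,
    t_constrict: float,
    t_relax: float,
) -> np.ndarray:
    """Area change contributed by one pulse at times ``t`` (≤ 0 everywhere).

    Raised-cosine drop of ``amplitude`` over ``t_constrict`` seconds, then a
    raised-cosine recovery of ``(1 - efficiency)·amplitude`` over
    ``t_relax`` seconds, then a permanent plateau at
    ``-efficiency·amplitude``.
    """
    u = t - start_s
    out = np.zeros_like(t, dtype=float)
    c = (u >= 0) & (u < t_constrict)
    out[c] = -amplitude * 0.5 * (1.0 - np.cos(np.pi * u[c] / t_constrict))
    if t_relax > 0 and efficiency < 1.0:
        r = (u >= t_constrict) & (u < t_constrict + t_relax)
        phase = (u[r] - t_constrict) / t_relax
        out[r] = -amplitude + (1.0 - efficiency) * amplitude * 0.5 * (
            1.0 - np.cos(np.pi * phase)
        )
        done = u >= t_constrict + t_relax
    else:
        done = u >= t_constrict
    out[done] = -efficiency * amplitude
    return out


_ATTEN_CACHE: dict = {}


def _atten_curve(dt_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated sampled peak rate of a unit raised-cosine ramp vs duration.

    For each ramp duration T the curve holds the expected (over a uniform
    sampling phase) maximum finite-difference quotient of a unit-amplitude
    raised-cosine transition sampled every ``dt_s`` seconds, ×60 (min⁻¹).
    The curve is strictly decreasing in T.
    """
    key = round(dt_s, 9)
    if key in _ATTEN_CACHE:
        return _ATTEN_CACHE[key]
    t_grid = np.geomspace(0.4 * dt_s, 400.0, 200)
    phases = np.linspace(0.0, dt_s, 64, endpoint=False)
    rates = np.empty(t_grid.size)
    for i, big_t in enumerate(t_grid):
        k = np.arange(-1, int(math.ceil(big_t / dt_s)) + 2)
        t = phases[:, None] + k[None, :] * dt_s
        y = 0.5 * (1.0 - np.cos(np.pi * np.clip(t / big_t, 0.0, 1.0)))
        rates[i] = (np.diff(y, axis=1) / dt_s).max(axis=1).mean() * 60.0
    result = (t_grid, rates)
    _ATTEN_CACHE[key] = result
    return result


def expected_discrete_peak_rate(ramp_duration_s: float, dt_s: float) -> float:
    """Expected sampled peak rate of a unit raised-cosine ramp, in min⁻¹.

    This is the conversion factor the cohort generator uses to translate a
    target *measured* peak rate into a waveform amplitude, accounting for
    the loss incurred by finite-difference sampling at interval ``dt_s``.
    """
    t_grid, rates = _atten_curve(dt_s)
    return float(np.interp(ramp_duration_s, t_grid, rates))


def _ramp_duration_for_rate(unit_rate: float, dt_s: float) -> float:
    """Invert :func:`expected_discrete_peak_rate` (clamped to the table)."""
    t_grid, rates = _atten_curve(dt_s)
    return float(np.interp(unit_rate, rates[::-1], t_grid[::-1]))


# ---------------------------------------------------------------------------
# single-trace generator


@dataclass
class PulseTraceParams:
    """Parameters of one synthetic pulsatile area trace."""

    duration_s: float = 600.0
    dt_s: float = 3.8
    initial_area_um2: float = 36.0
    pulse_period_s: float = 75.0
    pulse_amplitude_um2: float = 2.5
    ratchet_efficiency: float = 0.75
    trend_coeffs: Sequence[float] = (0.0, 0.0, 0.0, 0.0)  # polyval, μm² vs s
    noise_sd_um2: float = 0.0
    reporter_gain: float = 1.0  # a.u. per μm² of constriction
    seed: int = 0
    # waveform timing (defaults derived from the period when None)
    constriction_duration_s: Optional[float] = None
    relaxation_duration_s: Optional[float] = None
    first_pulse_s: Optional[float] = None
    baseline_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise InvalidParametersError("dt_s must be positive")
        if self.duration_s < 10 * self.dt_s:
            raise InvalidParametersError("duration_s must be at least 10 dt_s")
        if not 0.0 <= self.ratchet_efficiency <= 1.0:
            raise InvalidParametersError("ratchet_efficiency must be in [0, 1]")
        if self.pulse_period_s <= 0 or self.pulse_amplitude_um2 < 0:
            raise InvalidParametersError("period and amplitude must be positive")


@dataclass
class PulseTraceTruth:
    """Ground truth accompanying a generated trace."""

    pulse_start_s: np.ndarray
    constriction_peak_s: np.ndarray  # time of maximal constriction rate
    area_min_s: np.ndarray  # end of each constriction phase
    retained_um2_per_pulse: float
    amplitude_um2: float
    constriction_duration_s: float
    relaxation_duration_s: float


def gen_pulse_trace(
    params: PulseTraceParams,
    embryo_id: str = "e1",
    cell_id: str = "c1",
    rng: Optional[np.random.Generator] = None,
) -> tuple[CellTrace, PulseTraceTruth]:
    """Generate one pulsatile area trace plus its ground truth.

    Only pulses whose constriction *and* relaxation phases complete within
    the trace are emitted, so closed-form bookkeeping (total retained loss
    = n_pulses · efficiency · amplitude at the final plateau) holds exactly
    for noise-free parameter sets.
    """
    p = params
    if rng is None:
        rng = np.random.default_rng(p.seed)
    t_con = (
        p.constriction_duration_s
        if p.constriction_duration_s is not None
        else 0.35 * p.pulse_period_s
    )
    t_rel = (
        p.relaxation_duration_s
        if p.relaxation_duration_s is not None
        else (0.35 * p.pulse_period_s if p.ratchet_efficiency < 1.0 else 0.0)
    )
    if t_con + t_rel > p.pulse_period_s:
        raise InvalidParametersError(
            "constriction plus relaxation must fit within one period"
        )
    t0 = (
        p.first_pulse_s
        if p.first_pulse_s is not None
        else float(rng.uniform(5.0, p.pulse_period_s))
    )

    n = int(math.floor(p.duration_s / p.dt_s)) + 1
    times = np.arange(n) * p.dt_s

    starts = []
    s = t0
    while s + t_con + t_rel <= p.duration_s:
        starts.append(s)
        s += p.pulse_period_s
    starts = np.asarray(starts)

    clean = p.initial_area_um2 + np.polyval(np.asarray(p.trend_coeffs, float), times)
    for s in starts:
        clean = clean + _pulse_delta(
            times, s, p.pulse_amplitude_um2, p.ratchet_efficiency, t_con, t_rel
        )
    if clean.min() <= 0:
        raise InvalidParametersError("parameters drive the area to zero or below")

    # reporter: integrates instantaneous constriction, flat during expansion
    loss_steps = np.maximum(0.0, -np.diff(clean))
    intensity = p.baseline_intensity + p.reporter_gain * np.concatenate(
        ([0.0], np.cumsum(loss_steps))
    )

    area = clean.copy()
    if p.noise_sd_um2 > 0:
        area = area + rng.normal(0.0, p.noise_sd_um2, size=n)
        if area.min() <= 0:
            raise InvalidParametersError("noise drives the area to zero or below")

    trace = CellTrace(
        embryo_id=embryo_id,
        cell_id=cell_id,
        times_s=times,
        area_um2=area,
        intensity=intensity,
        meta={"seed": p.seed},
    )
    truth = PulseTraceTruth(
        pulse_start_s=starts,
        constriction_peak_s=starts + t_con / 2.0,
        area_min_s=starts + t_con,
        retained_um2_per_pulse=p.ratchet_efficiency * p.pulse_amplitude_um2,
        amplitude_um2=p.pulse_amplitude_um2,
        constriction_duration_s=t_con,
        relaxation_duration_s=t_rel,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class ClassRateSpec:
    """Target peak-rate statistics and dynamics of one behavioral class."""

    constriction_rate_mean: float  # μm²/min
    constriction_rate_sd: float
    expansion_rate_mean: float
    expansion_rate_sd: float
    ratchet_efficiency: float
    area_ratio_band: tuple[float, float]  # area fraction at the 7-min mark
    period_range_s: tuple[float, float] = (60.0, 90.0)


#: Control embryos: cells constrict in a ratcheted manner; 9.9 ± 1.1 μm²/min
#: peak constriction, 3.2 ± 0.8 μm²/min peak expansion.
CONTROL_CLASS_SPECS: dict[str, ClassRateSpec] = {
    "constricted": ClassRateSpec(9.9, 1.1, 3.2, 0.8, 0.75, (0.32, 0.46)),
    "impaired": ClassRateSpec(7.5, 1.2, 5.1, 1.4, 0.15, (0.56, 0.94)),
    "expanded": ClassRateSpec(7.5, 1.2, 5.1, 1.4, 0.0, (1.03, 1.18)),
}

#: Knockdown embryos: cells that still constrict behave like control cells;
#: deficient cells (impaired + expanded) pulse at 7.5 ± 1.2 μm²/min
#: constriction and 5.1 ± 1.4 μm²/min expansion without ratcheting.
KNOCKDOWN_CLASS_SPECS = CONTROL_CLASS_SPECS


@dataclass
class CohortParams:
    """A mixture cohort of synthetic cells across several embryos."""

    n_cells: int = 200
    class_mix: dict = field(
        default_factory=lambda: {"constricted": 1.0, "impaired": 0.0, "expanded": 0.0}
    )
    class_specs: dict = field(default_factory=lambda: dict(CONTROL_CLASS_SPECS))
    n_embryos: int = 5
    duration_s: float = 480.0
    dt_s: float = 3.8
    eval_time_s: float = 420.0
    initial_area_mean_um2: float = 36.0
    initial_area_sd_um2: float = 3.0
    noise_sd_um2: float = 0.0
    reporter_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise InvalidParametersError("class_mix must sum to 1")
        if self.n_cells < 0 or self.n_embryos < 1:
            raise InvalidParametersError("counts must be non-negative")
        for spec in self.class_specs.values():
            if spec.constriction_rate_sd < 0 or spec.expansion_rate_sd < 0:
                raise InvalidParametersError("rate SDs must be non-negative")


@dataclass
class CohortTruth:
    """Per-cell ground truth for a generated cohort."""

    class_labels: dict  # cell_id -> class name
    drawn_constriction_rates: dict  # cell_id -> μm²/min target
    drawn_expansion_rates: dict
    area_ratio_targets: dict
    trend_slopes_um2_per_min: dict
    pulse_truths: dict  # cell_id -> PulseTraceTruth


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer counts summing to ``n`` via largest-remainder rounding."""
    f = np.asarray(fractions, dtype=float)
    raw = f * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


# Quadratic trend coefficient giving the baseline constriction rate a slight
# strictly positive drift (1e-4 μm²/min per s). Between pulses the sampled
# rate is then strictly monotone instead of constant-to-rounding, so pulse
# detection on noise-free traces sees exactly one positive peak per cycle
# rather than a fringe of rounding-level extrema. The induced rate drift over
# a 10-min trace (0.06 μm²/min) is far below the cell-to-cell rate SD.
_TREND_QUAD_COEFF = -1e-4 / 120.0


def _solve_cell_dynamics(
    spec: ClassRateSpec,
    r_con: float,
    r_exp: float,
    ratio_target: float,
    initial_area: float,
    period: float,
    t0: float,
    duration_s: float,
    dt_s: float,
    eval_time_s: float,
) -> tuple[float, float, float, float]:
    """Solve (amplitude, relax duration, trend slope, effective period).

    Fixed point: the waveform amplitude reproduces the drawn *measured*
    constriction-peak rate after discrete sampling and after the trend's
    constant rate contribution; the relaxation duration reproduces the
    drawn expansion-peak rate; the linear trend slope places the noise-free
    area at ``eval_time_s`` exactly at ``ratio_target`` of the initial
    area.
    """
    e = spec.ratchet_efficiency
    t_con = 0.35 * period
    g_con = expected_discrete_peak_rate(t_con, dt_s)
    slope = 0.0  # constriction-positive trend rate, μm²/min
    amp = r_con / g_con
    t_rel = 0.35 * period
    p_eff = period
    for _ in range(10):
        amp = max(r_con - slope, 0.5) / g_con
        if e < 1.0:
            target_e = max(r_exp + slope, 0.5)
            t_rel = _ramp_duration_for_rate(target_e / ((1.0 - e) * amp), dt_s)
            t_rel = min(t_rel, 4.0 * period)
        else:
            t_rel = 0.0
        p_eff = max(period, t_con + t_rel + dt_s)
        # noise-free pulse contribution at the evaluation time
        starts = []
        s = t0
        while s + t_con + t_rel <= duration_s:
            starts.append(s)
            s += p_eff
        t_eval = np.asarray([eval_time_s])
        pulse_loss = 0.0
        for s in starts:
            pulse_loss -= _pulse_delta(t_eval, s, amp, e, t_con, t_rel)[0]
        quad_drop = -_TREND_QUAD_COEFF * eval_time_s**2
        slope = (
            initial_area * (1.0 - ratio_target) - pulse_loss - quad_drop
        ) / (eval_time_s / 60.0)
    return amp, t_rel, slope, p_eff


def gen_cohort(params: CohortParams) -> tuple[list[CellTrace], CohortTruth]:
    """Generate a mixture cohort with exact class counts and embryo ids.

    Class counts follow largest-remainder rounding of ``class_mix``; cells
    are distributed round-robin over ``n_embryos`` embryos. Per-cell
    waveform parameters are calibrated so that, at zero noise, the analysis
    pipeline recovers the drawn peak rates (in expectation over pulse
    phase) and the exact class mix at the 7-min categorization.
    """
    p = params
    names = list(p.class_mix.keys())
    counts = largest_remainder_counts(p.n_cells, [p.class_mix[k] for k in names])
    labels = [name for name, c in zip(names, counts) for _ in range(c)]

    traces: list[CellTrace] = []
    truth = CohortTruth({}, {}, {}, {}, {}, {})
    for i, label in enumerate(labels):
        emb_idx = i % p.n_embryos
        embryo_id = f"e{emb_idx + 1}"
        cell_id = f"c{i + 1:04d}"
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, emb_idx, i]))
        spec = p.class_specs[label]

        r_con = max(2.0, float(rng.normal(spec.constriction_rate_mean, spec.constriction_rate_sd)))
        r_exp = max(0.8, float(rng.normal(spec.expansion_rate_mean, spec.expansion_rate_sd)))
        ratio_target = float(rng.uniform(*spec.area_ratio_band))
        initial = max(20.0, float(rng.normal(p.initial_area_mean_um2, p.initial_area_sd_um2)))
        period = float(rng.uniform(*spec.period_range_s))
        t0 = float(rng.uniform(5.0, period))

        amp, t_rel, slope, p_eff = _solve_cell_dynamics(
            spec, r_con, r_exp, ratio_target, initial, period, t0,
            p.duration_s, p.dt_s, p.eval_time_s,
        )
        trace_params = PulseTraceParams(
            duration_s=p.duration_s,
            dt_s=p.dt_s,
            initial_area_um2=initial,
            pulse_period_s=p_eff,
            pulse_amplitude_um2=amp,
            ratchet_efficiency=spec.ratchet_efficiency,
            trend_coeffs=(0.0, _TREND_QUAD_COEFF, -slope / 60.0, 0.0),
            noise_sd_um2=p.noise_sd_um2,
            reporter_gain=p.reporter_gain,
            seed=p.seed,
            constriction_duration_s=0.35 * period,
            relaxation_duration_s=t_rel,
            first_pulse_s=t0,
        )
        trace, pulse_truth = gen_pulse_trace(trace_params, embryo_id, cell_id, rng=rng)
        trace.meta.update({"class": label, "ratio_target": ratio_target})
        traces.append(trace)
        truth.class_labels[cell_id] = label
        truth.drawn_constriction_rates[cell_id] = r_con
        truth.drawn_expansion_rates[cell_id] = r_exp
        truth.area_ratio_targets[cell_id] = ratio_target
        truth.trend_slopes_um2_per_min[cell_id] = slope
        truth.pulse_truths[cell_id] = pulse_truth
    return traces, truth


def control_cohort_params(n_cells: int = 200, seed: int = 0, **kw) -> CohortParams:
    """Study-condition control cohort: every cell ratchets and constricts."""
    return CohortParams(
        n_cells=n_cells,
        class_mix={"constricted": 1.0, "impaired": 0.0, "expanded": 0.0},
        class_specs=dict(CONTROL_CLASS_SPECS),
        seed=seed,
        **kw,
    )


def knockdown_cohort_params(n_cells: int = 200, seed: int = 0, **kw) -> CohortParams:
    """Study-condition knockdown cohort: 50/44/6% constricted/impaired/expanded."""
    return CohortParams(
        n_cells=n_cells,
        class_mix={"constricted": 0.50, "impaired": 0.44, "expanded": 0.06},
        class_specs=dict(KNOCKDOWN_CLASS_SPECS),
        seed=seed,
        **kw,
    )


# ---------------------------------------------------------------------------
# surface phantoms


@dataclass
class SurfacePhantomParams:
    """A 3-D stack containing a bright band centered on a known surface."""

    shape_zyx: tuple[int, int, int] = (16, 64, 64)
    pixel_size_um: float = 0.21
    z_step_um: float = 0.5
    height_function: str = "flat"  # flat | tilted_plane | sinusoid | paraboloid
    height_params: dict = field(default_factory=lambda: {"z0": 8.0})
    surface_intensity: float = 1000.0
    surface_thickness_slices: int = 3
    background_level: float = 10.0
    noise_sd: float = 0.0
    blur_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surface_intensity <= self.background_level:
            raise InvalidParametersError(
                "surface_intensity must exceed background_level"
            )


def _height_field(params: SurfacePhantomParams) -> np.ndarray:
    nz, ny, nx = params.shape_zyx
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    hp = params.height_params
    kind = params.height_function
    if kind == "flat":
        h = np.full((ny, nx), float(hp.get("z0", nz / 2)))
    elif kind == "tilted_plane":
        h = hp.get("z0", 2.0) + hp.get("slope_x", 0.05) * xx + hp.get("slope_y", 0.0) * yy
    elif kind == "sinusoid":
        h = hp.get("z0", nz / 2) + hp.get("amplitude", 2.0) * np.sin(
            2 * np.pi * xx / hp.get("period_x_px", nx / 2.0)
        ) * np.cos(2 * np.pi * yy / hp.get("period_y_px", 1e12))
    elif kind == "paraboloid":
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        h = hp.get("z0", 2.0) + hp.get("curvature", 0.002) * (
            (xx - cx) ** 2 + (yy - cy) ** 2
        )
    else:
        raise InvalidParametersError(f"unknown height function '{kind}'")
    if h.min() < 0 or h.max() > nz - 1:
        raise InvalidParametersError("height function leaves the z-range")
    return h


def gen_surface_phantom(params: SurfacePhantomParams):
    """Build a surface phantom stack and its true per-pixel height map.

    The bright band spans ``surface_thickness_slices`` around the height,
    with fractional-overlap weights at the band edges and a slight (1%)
    apodization toward the band center so that the per-column brightest
    slice is always the slice nearest the true height (no argmax ties).

    Returns ``(ImageStack, true_height_px)`` where ``true_height_px`` is a
    (ny, nx) float array of z-positions in slice units. Use
    :func:`true_heights_on_grid` to compare against a gridded height map.
    """
    from .imaging import ImageStack  # local import to avoid a cycle

    p = params
    nz, ny, nx = p.shape_zyx
    h = _height_field(p)
    z = np.arange(nz, dtype=float)
    half = p.surface_thickness_slices / 2.0
    # fractional overlap of slice interval [z-1/2, z+1/2] with the band
    lo = np.maximum(z[:, None, None] - 0.5, h[None] - half)
    hi = np.minimum(z[:, None, None] + 0.5, h[None] + half)
    w = np.clip(hi - lo, 0.0, 1.0)
    w *= 1.0 - 0.01 * np.abs(z[:, None, None] - h[None]) / max(half, 0.5)
    vol = p.background_level + (p.surface_intensity - p.background_level) * w
    if p.blur_sigma_px > 0:
        vol = ndimage.gaussian_filter(vol, sigma=(0, p.blur_sigma_px, p.blur_sigma_px))
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        vol = vol + rng.normal(0.0, p.noise_sd, size=vol.shape)
    stack = ImageStack(
        voxels=vol, pixel_size_um=p.pixel_size_um, z_step_um=p.z_step_um
    )
    return stack, h


def true_heights_on_grid(true_height_px: np.ndarray, grid_size_px: int) -> np.ndarray:
    """Average a per-pixel height map over the projection grid units."""
    ny, nx = true_height_px.shape
    gy = math.ceil(ny / grid_size_px)
    gx = math.ceil(nx / grid_size_px)
    out = np.empty((gy, gx))
    for iy in range(gy):
        for ix in range(gx):
            block = true_height_px[
                iy * grid_size_px : (iy + 1) * grid_size_px,
                ix * grid_size_px : (ix + 1) * grid_size_px,
            ]
            out[iy, ix] = block.mean()
    return out


# ---------------------------------------------------------------------------
# labeled movies


@dataclass
class LabeledMovieParams:
    """Label + intensity movie with prescribed per-cell areas/intensities."""

    n_cells: int = 4
    frame_shape: tuple[int, int] = (64, 64)
    n_frames: int = 10
    area_px: Optional[np.ndarray] = None  # (n_cells, n_frames) pixel counts
    intensities: Optional[np.ndarray] = None  # (n_cells, n_frames) a.u.
    noise_sd: float = 0.0
    seed: int = 0


def gen_labeled_movie(params: LabeledMovieParams):
    """Generate matched label and intensity movies with exact pixel areas.

    Cells are laid out on a regular grid of bounding boxes; each cell's
    region fills exactly its prescribed pixel count row-major within its
    box (areas are exact; the region outline is quantized at one pixel
    row). Raises :class:`LayoutInfeasibleError` if the boxes cannot hold
    the largest requested cell.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    if p.area_px is None:
        base = rng.integers(60, 120, size=p.n_cells)
        decline = np.linspace(1.0, 0.6, p.n_frames)
        area_px = np.round(base[:, None] * decline[None, :]).astype(int)
    else:
        area_px = np.asarray(p.area_px, dtype=int)
    if p.intensities is None:
        intensities = rng.uniform(50, 200, size=(p.n_cells, 1)) * np.ones(
            (1, p.n_frames)
        )
    else:
        intensities = np.asarray(p.intensities, dtype=float)
        if intensities.ndim == 1:
            intensities = np.repeat(intensities[:, None], p.n_frames, axis=1)

    ny, nx = p.frame_shape
    n_side = math.ceil(math.sqrt(p.n_cells))
    box_y, box_x = ny // n_side, nx // n_side
    if box_y * box_x < area_px.max() or box_y < 1 or box_x < 1:
        raise LayoutInfeasibleError(
            "frame too small for the requested cell count and areas"
        )
    labels = np.zeros((p.n_frames, ny, nx), dtype=np.int32)
    movie = np.zeros((p.n_frames, ny, nx), dtype=float)
    for c in range(p.n_cells):
        gy, gx = divmod(c, n_side)
        y0, x0 = gy * box_y, gx * box_x
        for f in range(p.n_frames):
            k = int(area_px[c, f])
            flat = np.zeros(box_y * box_x, dtype=bool)
            flat[:k] = True
            region = flat.reshape(box_y, box_x)
            labels[f, y0 : y0 + box_y, x0 : x0 + box_x][region] = c + 1
            movie[f, y0 : y0 + box_y, x0 : x0 + box_x][region] = intensities[c, f]
    if p.noise_sd > 0:
        movie = movie + rng.normal(0.0, p.noise_sd, size=movie.shape)
    true_traces = {"area_px": area_px, "intensity": intensities}
    return labels, movie, true_traces
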