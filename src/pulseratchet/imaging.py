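"""Image-side quantification: surface projection, backgrounds, intensities.

The central piece is a grid-based surface projection for confocal stacks of
a curved epithelium: the stack is tiled into x/y grid units, the z-intensity
profile of each unit locates the surface peak, the resulting height map is
Gaussian-smoothed, and the slices around the (fractional) height are
mean-projected with proportional slice weights. To suppress grid-edge
artifacts the whole procedure is repeated on a stack padded by half a grid
unit (padding filled with the mean of the outer margin of each slice, which
offsets the grid by half a unit) and the two projections are averaged.

Also here: the two background-estimation rules (mean of the lowest focal
plane; mean of the stack minus one SD), clamped background subtraction,
apical mean projection over ~4 μm, whole-stack intensity time courses as
fold changes, per-cell mean intensity within label images, cell geometry
(area and A-P/D-V anisotropy from second moments), and Pearson
colocalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageStack",
    "HeightMap",
    "IntensityTimecourse",
    "EmptyInputError",
    "OutOfRangeError",
    "TooSmallError",
    "DegenerateNormalizationError",
    "UndefinedCorrelationError",
    "background_lowest_plane",
    "background_mean_minus_sd",
    "subtract_background",
    "mean_project_apical",
    "intensity_timecourse",
    "surface_project",
    "per_cell_mean_intensity",
    "cell_geometry",
    "pearson_colocalization",
]


class EmptyInputError(ValueError):
    pass


class OutOfRangeError(ValueError):
    pass


class TooSmallError(ValueError):
    pass


class DegenerateNormalizationError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class ImageStack:
    """A calibrated z/y/x intensity volume. z index 0 is the most apical plane."""

    voxels: np.ndarray
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0
    time_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D (z, y, x) array")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibrations must be positive")

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]


@dataclass
class HeightMap:
    """Per-grid-unit z-position of the detected surface (fractional slices)."""

    heights: np.ndarray  # (gy, gx)
    grid_size_px: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.heights.shape


@dataclass
class IntensityTimecourse:
    """Fold-change intensity time course, per embryo and pooled."""

    times_s: np.ndarray
    per_embryo: dict  # embryo id -> fold-change series on times_s
    mean: np.ndarray
    sd: np.ndarray


# ---------------------------------------------------------------------------
# backgrounds and simple projections


def background_lowest_plane(stack: ImageStack) -> float:
    """Mean intensity of the lowest focal plane (z index 0).

    Plane 0 is the first plane of the acquired stack, which by the stack
    convention used throughout this package carries no surface signal and
    serves as the background estimate.
    """
    if stack.voxels.size == 0:
        raise EmptyInputError("empty stack")
    return float(stack.voxels[0].mean())


def background_mean_minus_sd(stack: ImageStack) -> float:
    """Mean of all voxels minus one (population) standard deviation."""
    if stack.voxels.size == 0:
        raise EmptyInputError("empty stack")
    v = stack.voxels
    return float(v.mean() - v.std(ddof=0))


def subtract_background(image: np.ndarray, bg: float) -> np.ndarray:
    """Subtract a scalar background, clamping at zero (intensities are non-negative)."""
    if not np.isfinite(bg):
        raise ValueError("background must be finite")
    return np.maximum(np.asarray(image, dtype=float) - bg, 0.0)


def mean_project_apical(stack: ImageStack, depth_um: float = 4.0) -> np.ndarray:
    """Mean projection over the most apical ``round(depth_um / z_step)`` slices."""
    n = int(round(depth_um / stack.z_step_um))
    n = max(n, 1)
    if n > stack.n_z:
        raise OutOfRangeError("requested depth exceeds the stack")
    return stack.voxels[:n].mean(axis=0)


# ---------------------------------------------------------------------------
# intensity time course


def intensity_timecourse(
    stacks_per_embryo: dict,
    bg_rule: Literal["lowest_plane", "mean_minus_sd"] = "lowest_plane",
    n_grid: Optional[int] = None,
) -> IntensityTimecourse:
    """Whole-stack mean intensity over time as a fold change per embryo.

    ``stacks_per_embryo`` maps embryo id → time-ordered list of
    :class:`ImageStack` with ``time_s`` set. Per time point the
    background-corrected mean intensity is divided by its value at the
    first time point; because acquisition time grids differ slightly
    between embryos, each series is linearly interpolated onto a common
    grid before the across-embryo mean and SD are computed.
    """
    bg_fn = {
        "lowest_plane": background_lowest_plane,
        "mean_minus_sd": background_mean_minus_sd,
    }[bg_rule]
    series = {}
    for emb, stacks in stacks_per_embryo.items():
        if len(stacks) < 2:
            raise EmptyInputError(f"embryo {emb}: need at least 2 time points")
        times = np.array([s.time_s for s in stacks], dtype=float)
        vals = np.array([s.voxels.mean() - bg_fn(s) for s in stacks])
        if vals[0] <= 0:
            raise DegenerateNormalizationError(
                f"embryo {emb}: non-positive initial intensity"
            )
        series[emb] = (times, vals / vals[0])
    t_lo = max(t[0] for t, _ in series.values())
    t_hi = min(t[-1] for t, _ in series.values())
    if n_grid is None:
        n_grid = int(np.median([t.size for t, _ in series.values()]))
    grid = np.linspace(t_lo, t_hi, n_grid)
    per_embryo = {
        emb: np.interp(grid, t, f) for emb, (t, f) in series.items()
    }
    stack = np.vstack(list(per_embryo.values()))
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] >= 2 else np.zeros(grid.size)
    return IntensityTimecourse(
        times_s=grid, per_embryo=per_embryo, mean=stack.mean(axis=0), sd=sd
    )


# ---------------------------------------------------------------------------
# surface projection


def _unit_slices(n: int, grid: int) -> list[slice]:
    return [slice(i, min(i + grid, n)) for i in range(0, n, grid)]


def _grid_heights(vol: np.ndarray, grid: int) -> np.ndarray:
    """Per-unit argmax z of the summed z-intensity profile (ties → lowest z)."""
    ys = _unit_slices(vol.shape[1], grid)
    xs = _unit_slices(vol.shape[2], grid)
    heights = np.empty((len(ys), len(xs)))
    for iy, sy in enumerate(ys):
        for ix, sx in enumerate(xs):
            profile = vol[:, sy, sx].sum(axis=(1, 2))
            heights[iy, ix] = int(np.argmax(profile))
    return heights


def _project_at_heights(
    vol: np.ndarray, heights: np.ndarray, grid: int, thickness_slices: float
) -> np.ndarray:
    """Mean-project slices overlapping ±thickness/2 around each unit's height.

    Slice weights are proportional to the overlap of the slice interval
    [j−½, j+½] with the band around the (fractional) height, i.e. partial
    slices contribute proportionally.
    """
    nz = vol.shape[0]
    ys = _unit_slices(vol.shape[1], grid)
    xs = _unit_slices(vol.shape[2], grid)
    out = np.empty(vol.shape[1:])
    half = thickness_slices / 2.0
    z = np.arange(nz, dtype=float)
    for iy, sy in enumerate(ys):
        for ix, sx in enumerate(xs):
            h = float(np.clip(heights[iy, ix], 0, nz - 1))
            lo = np.maximum(z - 0.5, h - half)
            hi = np.minimum(z + 0.5, h + half)
            w = np.clip(hi - lo, 0.0, None)
            w_sum = w.sum()
            if w_sum <= 0:
                w = np.zeros(nz)
                w[int(round(h))] = 1.0
                w_sum = 1.0
            out[sy, sx] = np.tensordot(w / w_sum, vol[:, sy, sx], axes=(0, 0))
    return out


def _pad_with_margin_mean(vol: np.ndarray, pad: int) -> np.ndarray:
    """Expand each slice by ``pad`` pixels, filled with its outer-margin mean."""
    nz, ny, nx = vol.shape
    out = np.empty((nz, ny + 2 * pad, nx + 2 * pad))
    for j in range(nz):
        plane = vol[j]
        interior = plane[pad : ny - pad, pad : nx - pad] if min(ny, nx) > 2 * pad else None
        total = plane.sum()
        if interior is not None and interior.size:
            margin_mean = (total - interior.sum()) / (plane.size - interior.size)
        else:
            margin_mean = plane.mean()
        out[j] = margin_mean
        out[j, pad : pad + ny, pad : pad + nx] = plane
    return out


def surface_project(
    stack: ImageStack,
    grid_size_px: int = 16,
    gauss_sigma_units: float = 1.0,
    thickness_slices: float = 3.0,
) -> tuple[np.ndarray, HeightMap]:
    """Surface projection of a curved bright sheet inside a confocal stack.

    Algorithm: (1) tile x/y into ``grid_size_px`` units and take, per unit,
    the argmax z of the summed z-intensity profile (ties resolve to the
    most apical slice); (2) smooth the height map with a Gaussian of
    ``gauss_sigma_units`` grid units; (3) per unit, mean-project the slices
    within ±``thickness_slices``/2 of the filtered height with
    proportional (fractional-overlap) weights; (4) repeat on a copy padded
    by half a grid unit per side — padding filled with the mean of each
    slice's outer margin — which shifts the grid by half a unit; (5) return
    the pixelwise mean of both projections (pad cropped) plus the original
    grid's height map.
    """
    if grid_size_px < 2:
        raise ValueError("grid_size_px must be at least 2")
    vol = stack.voxels
    if stack.n_z < 2:
        raise TooSmallError("need at least 2 z-slices")
    if vol.shape[1] < grid_size_px or vol.shape[2] < grid_size_px:
        raise TooSmallError("stack smaller than one grid unit")

    heights_raw = _grid_heights(vol, grid_size_px)
    heights = ndimage.gaussian_filter(heights_raw, gauss_sigma_units, mode="nearest")
    proj_a = _project_at_heights(vol, heights, grid_size_px, thickness_slices)

    pad = grid_size_px // 2
    vol_b = _pad_with_margin_mean(vol, pad)
    heights_b = ndimage.gaussian_filter(
        _grid_heights(vol_b, grid_size_px), gauss_sigma_units, mode="nearest"
    )
    proj_b = _project_at_heights(vol_b, heights_b, grid_size_px, thickness_slices)
    proj_b = proj_b[pad : pad + vol.shape[1], pad : pad + vol.shape[2]]

    projection = 0.5 * (proj_a + proj_b)
    return projection, HeightMap(heights=heights, grid_size_px=grid_size_px)


# ---------------------------------------------------------------------------
# per-cell measurements


def per_cell_mean_intensity(projection: np.ndarray, labels: np.ndarray) -> dict:
    """Mean projected intensity within each nonzero label."""
    projection = np.asarray(projection, dtype=float)
    labels = np.asarray(labels)
    if projection.shape != labels.shape:
        raise ValueError("projection and label image shapes differ")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return {}
    means = ndimage.mean(projection, labels=labels, index=ids)
    return {int(i): float(m) for i, m in zip(ids, means)}


def cell_geometry(
    labels: np.ndarray, pixel_size_um: float, ap_axis: int = 1
) -> dict:
    """Area (μm²) and A-P/D-V anisotropy per labeled cell.

    Anisotropy is the ratio of the second-moment ellipse axis length along
    the anteroposterior image axis (``ap_axis``) to the orthogonal
    (dorsoventral) axis; pixel variances carry the +1/12 unit-square
    correction so a w×h rectangle gives exactly w/h. Values > 1 mean the
    cell is elongated along A-P.
    """
    labels = np.asarray(labels)
    if ap_axis not in (0, 1):
        raise ValueError("ap_axis must be 0 or 1")
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        coords = np.argwhere(labels == lab).astype(float)
        var = coords.var(axis=0, ddof=0) + 1.0 / 12.0
        aniso = math.sqrt(var[ap_axis] / var[1 - ap_axis])
        out[int(lab)] = {
            "area_um2": float(coords.shape[0] * pixel_size_um**2),
            "anisotropy": float(aniso),
        }
    return out


def pearson_colocalization(
    img_a: np.ndarray, img_b: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Pearson correlation of two channels over (masked) pixels."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the images")
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("need ≥2 pixels with variance in both channels")
    return float(np.corrcoef(a, b)[0, 1])
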