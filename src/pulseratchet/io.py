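"""File formats: trace tables (CSV), TIFF stacks with JSON sidecars, results.

The trace table is the interchange format for EDGE-style per-cell feature
exports: one row per (embryo, cell, frame) with columns ``embryo_id``,
``cell_id``, ``time_s``, ``area_um2`` and optional ``intensity`` /
``anisotropy``; empty fields mark missing values. All writes are atomic
(write to a temporary file in the destination directory, then rename), so
an interrupted run never leaves a half-written file.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .traces import CellTrace

__all__ = [
    "MissingColumnError",
    "NonMonotoneTimesError",
    "DuplicateKeyError",
    "read_trace_table",
    "write_trace_table",
    "traces_to_dataframe",
    "atomic_write_bytes",
    "atomic_write_text",
    "write_json",
    "read_stack_tiff",
    "write_stack_tiff",
    "results_bundle",
]

REQUIRED_COLUMNS = ("embryo_id", "cell_id", "time_s", "area_um2")
OPTIONAL_COLUMNS = ("intensity", "anisotropy")


class MissingColumnError(ValueError):
    pass


class NonMonotoneTimesError(ValueError):
    pass


class DuplicateKeyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# atomic writes


def atomic_write_bytes(path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


def write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# trace tables


def traces_to_dataframe(traces: Iterable[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        frame = {
            "embryo_id": tr.embryo_id,
            "cell_id": tr.cell_id,
            "time_s": tr.times_s,
            "area_um2": tr.area_um2,
        }
        if tr.intensity is not None:
            frame["intensity"] = tr.intensity
        if tr.anisotropy is not None:
            frame["anisotropy"] = tr.anisotropy
        rows.append(pd.DataFrame(frame))
    if not rows:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.concat(rows, ignore_index=True)


def write_trace_table(traces: Iterable[CellTrace], path) -> None:
    """Write a cohort as a comma-separated trace table (atomic)."""
    df = traces_to_dataframe(traces)
    atomic_write_text(path, df.to_csv(index=False))


def read_trace_table(path) -> list[CellTrace]:
    """Read a trace table back into :class:`CellTrace` objects.

    Raises :class:`MissingColumnError`, :class:`DuplicateKeyError` or
    :class:`NonMonotoneTimesError` on malformed input.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"trace table lacks columns: {missing}")
    if df.duplicated(subset=["embryo_id", "cell_id", "time_s"]).any():
        raise DuplicateKeyError("duplicate (embryo_id, cell_id, time_s) rows")
    traces = []
    for (emb, cell), sub in df.groupby(["embryo_id", "cell_id"], sort=True):
        times = sub["time_s"].to_numpy(dtype=float)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise NonMonotoneTimesError(
                f"times not strictly increasing for cell {cell} (embryo {emb})"
            )
        traces.append(
            CellTrace(
                embryo_id=str(emb),
                cell_id=str(cell),
                times_s=times,
                area_um2=sub["area_um2"].to_numpy(dtype=float),
                intensity=(
                    sub["intensity"].to_numpy(dtype=float)
                    if "intensity" in sub.columns
                    else None
                ),
                anisotropy=(
                    sub["anisotropy"].to_numpy(dtype=float)
                    if "anisotropy" in sub.columns
                    else None
                ),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# image stacks


def write_stack_tiff(path, voxels: np.ndarray, sidecar: Optional[dict] = None) -> None:
    """Write a (multi-page) TIFF atomically, plus an optional JSON sidecar."""
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, np.asarray(voxels), photometric="minisblack")
    atomic_write_bytes(path, buf.getvalue())
    if sidecar is not None:
        write_json(str(path) + ".json", sidecar)


def read_stack_tiff(path):
    """Read a TIFF volume and its JSON sidecar (None if absent)."""
    voxels = tifffile.imread(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    return voxels, sidecar


# ---------------------------------------------------------------------------
# results bundle


def results_bundle(config: dict, seed: Optional[int], results: dict) -> dict:
    """Self-describing JSON document holding a run's configuration and results."""
    return {
        "software": "pulseratchet",
        "version": __version__,
        "seed": seed,
        "config": config,
        "units": {
            "time": "s",
            "area": "um^2",
            "rate": "um^2/min",
            "ratchet_statistic": "% of initial area per pulse interval",
        },
        "results": results,
    }
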