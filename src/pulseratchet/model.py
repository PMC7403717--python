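"""Model/Results front end tying the per-cell pipeline to group statistics.

`ConstrictionDynamicsModel` is built from a cohort of per-cell traces (plus
an embryo→group assignment) and `fit()` runs the full analysis chain on
every cell — gap interpolation, tracked-duration exclusion, categorization
at 7 min, the ratchet statistic, and per-cell mean peak constriction and
expansion rates. The returned `ConstrictionDynamicsResults` carries a
per-cell table and provides the group-level layer: mean ± SD rate tables,
fold changes relative to a control group, the maximal-SD Cohen's d with the
|d| < 0.5 non-significance rule, t-tests, one-way ANOVA + Tukey, category
fractions and a text `summary()`.

Typical use::

    model = ConstrictionDynamicsModel.from_trace_table("traces.csv",
                                                       groups=group_map)
    res = model.fit()
    print(res.summary())
    res.compare_rates("control", "knockdown")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import pulses, stats
from .pulses import NoEventsError, NotEnoughPulsesError, UntrackedAtEvalError
from .traces import CellTrace

__all__ = ["ConstrictionDynamicsModel", "ConstrictionDynamicsResults"]


class ConstrictionDynamicsModel:
    """Per-cell pulsation analysis over a cohort of traces.

    Parameters
    ----------
    traces
        The cohort of :class:`CellTrace` objects.
    groups
        Either a mapping from embryo id to group name, a callable
        ``trace -> group``, or None (every cell in group ``"all"``).
    eval_time_s
        Categorization time after onset (default 420 s = 7 min).
    max_gap
        Longest missing run (in frames) interpolated before analysis.
    diff_on_raw
        Evaluate the ratchet statistic's inter-peak differences on the raw
        area (default) or on the detrended residual.
    apply_exclusion
        Drop cells tracked for less than (median − 1 SD) of the cohort's
        tracked durations before cohort-level statistics.
    """

    def __init__(
        self,
        traces: Sequence[CellTrace],
        groups: Union[dict, Callable, None] = None,
        eval_time_s: float = 420.0,
        max_gap: int = 2,
        diff_on_raw: bool = True,
        apply_exclusion: bool = True,
    ) -> None:
        self.traces = list(traces)
        if not self.traces:
            raise ValueError("need at least one trace")
        self.eval_time_s = eval_time_s
        self.max_gap = max_gap
        self.diff_on_raw = diff_on_raw
        self.apply_exclusion = apply_exclusion
        if groups is None:
            self._group_of = lambda tr: tr.meta.get("group", "all")
        elif callable(groups):
            self._group_of = groups
        else:
            self._group_of = lambda tr: groups.get(tr.embryo_id, "all")

    @classmethod
    def from_trace_table(cls, path, **kwargs) -> "ConstrictionDynamicsModel":
        from .io import read_trace_table

        return cls(read_trace_table(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ConstrictionDynamicsModel":
        """Build from a long-format frame with the trace-table columns."""
        import io as _io

        from .io import read_trace_table

        buf = _io.StringIO(df.to_csv(index=False))
        return cls(read_trace_table(buf), **kwargs)

    def fit(self) -> "ConstrictionDynamicsResults":
        """Run the per-cell pipeline and assemble the results table."""
        clean = [pulses.interpolate_gaps(tr, self.max_gap) for tr in self.traces]
        if self.apply_exclusion:
            kept, report = pulses.exclude_short_tracks(clean)
            excluded_ids = {cid for cid, r in report.items() if r["excluded"]}
        else:
            kept, excluded_ids = clean, set()

        rows = []
        for tr in clean:
            row = {
                "embryo_id": tr.embryo_id,
                "cell_id": tr.cell_id,
                "group": self._group_of(tr),
                "duration_s": tr.duration_s,
                "excluded": tr.cell_id in excluded_ids,
                "category": None,
                "area_ratio": np.nan,
                "ratchet_pct": np.nan,
                "n_maxima": 0,
                "n_minima": 0,
                "peak_constriction_rate": np.nan,
                "peak_expansion_rate": np.nan,
            }
            try:
                cat = pulses.categorize_cell(tr, self.eval_time_s)
                row["category"] = cat.label
                row["area_ratio"] = cat.area_ratio_at_eval
            except UntrackedAtEvalError:
                pass
            try:
                rr = pulses.ratchet_amplitude(tr, diff_on_raw=self.diff_on_raw)
                row["ratchet_pct"] = rr.mean_interpeak_diff
                row["n_maxima"] = rr.n_maxima
                row["n_minima"] = rr.n_minima
            except (NotEnoughPulsesError, pulses.TooShortError):
                pass
            for polarity, col in (
                ("constriction", "peak_constriction_rate"),
                ("expansion", "peak_expansion_rate"),
            ):
                try:
                    row[col] = pulses.mean_peak_rate(tr, polarity)
                except (NoEventsError, pulses.TooShortError):
                    pass
            rows.append(row)
        per_cell = pd.DataFrame(rows)
        return ConstrictionDynamicsResults(
            model=self, per_cell=per_cell, traces=clean
        )


@dataclass
class ConstrictionDynamicsResults:
    """Fitted per-cell statistics plus group-level comparisons."""

    model: ConstrictionDynamicsModel
    per_cell: pd.DataFrame
    traces: list = field(repr=False, default_factory=list)

    # -- selection --------------------------------------------------------

    @property
    def kept(self) -> pd.DataFrame:
        """Per-cell table restricted to non-excluded cells."""
        return self.per_cell[~self.per_cell["excluded"]]

    def _rates(self, group: str, polarity: str) -> np.ndarray:
        col = f"peak_{polarity}_rate"
        vals = self.kept.loc[self.kept["group"] == group, col].dropna()
        return vals.to_numpy()

    # -- group statistics -------------------------------------------------

    def group_rate_table(self) -> pd.DataFrame:
        """Mean ± SD of per-cell mean peak rates, by group and polarity."""
        recs = []
        for group in sorted(self.kept["group"].unique()):
            for polarity in ("constriction", "expansion"):
                vals = self._rates(group, polarity)
                recs.append(
                    {
                        "group": group,
                        "polarity": polarity,
                        "mean_um2_per_min": vals.mean() if vals.size else np.nan,
                        "sd_um2_per_min": (
                            vals.std(ddof=1) if vals.size > 1 else np.nan
                        ),
                        "n_cells": vals.size,
                    }
                )
        return pd.DataFrame(recs)

    def compare_rates(self, control: str, test: str) -> dict:
        """Fold changes, effect sizes and t-tests of test vs control rates."""
        out = {}
        for polarity in ("constriction", "expansion"):
            c = self._rates(control, polarity)
            t = self._rates(test, polarity)
            fc = stats.fold_change_rates(c.mean(), t.mean())
            es = stats.cohens_d(c, t)
            t_stat, p = stats.two_sample_ttest(c, t)
            out[polarity] = {
                "control_mean": float(c.mean()),
                "test_mean": float(t.mean()),
                "fold": fc.fold,
                "percent_change": fc.percent_change,
                "cohens_d": es.d,
                "significant": es.significant,
                "t": t_stat,
                "p": p,
            }
        out["ratio_of_changes"] = stats.ratio_of_changes(
            out["expansion"]["percent_change"],
            out["constriction"]["percent_change"],
        )
        return out

    def category_table(self, group: Optional[str] = None) -> dict:
        """Constricted/impaired/expanded fractions (optionally one group)."""
        sub = self.kept if group is None else self.kept[self.kept["group"] == group]
        cats = sub["category"].dropna().tolist()
        return stats.category_fractions(cats)

    def ratchet_by_category(self, group: Optional[str] = None) -> pd.DataFrame:
        """Ratchet statistic (mean ± SD, % initial area) per category."""
        sub = self.kept if group is None else self.kept[self.kept["group"] == group]
        recs = []
        for cat, vals in sub.groupby("category")["ratchet_pct"]:
            v = vals.dropna().to_numpy()
            recs.append(
                {
                    "category": cat,
                    "mean_pct": v.mean() if v.size else np.nan,
                    "sd_pct": v.std(ddof=1) if v.size > 1 else np.nan,
                    "n_cells": v.size,
                }
            )
        return pd.DataFrame(recs)

    def anova(self, column: str, by: str = "group") -> stats.AnovaResult:
        """One-way ANOVA of a per-cell column across groups or categories."""
        sub = self.kept[[by, column]].dropna()
        labels = sorted(sub[by].unique())
        groups = [sub.loc[sub[by] == lab, column].to_numpy() for lab in labels]
        return stats.anova_oneway(groups, labels=[str(x) for x in labels])

    def heatmap_matrix(self, group: Optional[str] = None) -> pd.DataFrame:
        """Cells × time matrix of area normalized to each cell's initial value."""
        traces = [
            tr
            for tr in self.traces
            if (group is None or self.model._group_of(tr) == group)
            and not self.per_cell.set_index("cell_id")["excluded"].get(tr.cell_id, False)
        ]
        times = np.unique(np.concatenate([tr.times_s for tr in traces]))
        mat = np.full((len(traces), times.size), np.nan)
        ids = []
        for i, tr in enumerate(traces):
            pos = np.searchsorted(times, tr.times_s)
            smoothed = pulses.smooth_moving_mean(tr.area_um2, min(3, len(tr)))
            mat[i, pos] = smoothed / tr.initial_area_um2
            ids.append(tr.cell_id)
        return pd.DataFrame(mat, index=ids, columns=times)

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        """Readable multi-section summary of the fitted cohort."""
        lines = ["Constriction dynamics summary", "=" * 64]
        n_total = len(self.per_cell)
        n_excl = int(self.per_cell["excluded"].sum())
        lines.append(f"cells: {n_total} ({n_excl} excluded by tracked-duration rule)")
        lines.append("")
        lines.append("Peak pulsation rates (μm²/min, per-cell means):")
        lines.append(self.group_rate_table().to_string(index=False, float_format="%.2f"))
        lines.append("")
        for group in sorted(self.kept["group"].unique()):
            try:
                table = self.category_table(group)
            except ValueError:
                continue
            frac = table["fractions"]
            lines.append(
                f"categories [{group}] (n={table['n']}): "
                + ", ".join(f"{k} {100 * frac[k]:.0f}%" for k in frac)
            )
        lines.append("")
        lines.append("Ratchet statistic (% initial area per pulse interval):")
        lines.append(
            self.ratchet_by_category().to_string(index=False, float_format="%.2f")
        )
        return "\n".join(lines)

    def plot_heatmap(self, group: Optional[str] = None, ax=None):
        """Heat map of normalized area over time, one row per cell."""
        import matplotlib.pyplot as plt

        mat = self.heatmap_matrix(group)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            mat.to_numpy(),
            aspect="auto",
            cmap="viridis_r",
            vmin=0.2,
            vmax=1.2,
            extent=(mat.columns[0], mat.columns[-1], mat.shape[0], 0),
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("cell")
        plt.colorbar(im, ax=ax, label="area / initial area")
        return ax
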