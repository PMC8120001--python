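"""Summary report: grouped scatter plots, distance traces and a stats table.

Column scatters follow the small-dot-per-cell / large-dot-per-fish-mean
convention, annotated with n.s. / * / ** / *** / **** significance labels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import aggregate_per_fish, compare_groups, significance_label

_MEASUREMENTS = {
    "mean_speed_um_min": "mean speed (μm/min)",
    "directionality_ratio": "directionality ratio",
}


def build_report(out_dir: str | Path, metrics: pd.DataFrame | None = None,
                 distances: pd.DataFrame | None = None,
                 groups: pd.DataFrame | None = None,
                 frame_interval: float = 2.0) -> dict[str, Path]:
    """Write report files; tolerates empty/missing inputs ("no data").

    ``metrics`` is a per-track metrics table (with a ``fish`` column);
    ``groups`` maps ``fish`` to ``group`` for between-group statistics;
    ``distances`` is the per-frame distance table for traces.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stats_rows = []

    if metrics is not None and len(metrics) and groups is not None and len(groups):
        merged = metrics.merge(groups[["fish", "group"]], on="fish", how="inner")
        for column, label in _MEASUREMENTS.items():
            if column not in merged.columns:
                continue
            cells = merged.dropna(subset=[column]).rename(columns={column: "value"})
            if not len(cells):
                continue
            per_fish = aggregate_per_fish(cells[["group", "fish", "value"]])
            result = None
            by_group = {g: sub["value"].to_numpy() for g, sub in per_fish.groupby("group")}
            if len(by_group) >= 2 and all(len(v) >= 3 for v in by_group.values()):
                result = compare_groups(by_group)
                stats_rows.append({
                    "measurement": column, "test": result.test_name,
                    "route": result.route, "statistic": result.statistic,
                    "p_value": result.p_value,
                    "significance": significance_label(result.p_value),
                })
            written[f"scatter_{column}"] = _column_scatter(
                cells, per_fish, label, result, out_dir / f"scatter_{column}.png")

    if distances is not None and len(distances):
        written["distance_traces"] = _distance_traces(
            distances, frame_interval, out_dir / "distance_traces.png")

    stats_df = pd.DataFrame(stats_rows) if stats_rows else pd.DataFrame(
        [{"measurement": "no data", "test": "", "route": "", "statistic": np.nan,
          "p_value": np.nan, "significance": "n.a."}])
    stats_path = out_dir / "report_stats.csv"
    stats_df.to_csv(stats_path, index=False)
    written["stats"] = stats_path
    return written


def _column_scatter(cells: pd.DataFrame, per_fish: pd.DataFrame, ylabel: str,
                    result, path: Path) -> Path:
    rng = np.random.default_rng(0)  # reproducible jitter
    groups = sorted(cells["group"].unique())
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.6))
    for gi, g in enumerate(groups):
        cv = cells.loc[cells["group"] == g, "value"].to_numpy()
        ax.scatter(gi + rng.uniform(-0.18, 0.18, len(cv)), cv, s=8, alpha=0.4,
                   color="C0", zorder=2)
        fv = per_fish.loc[per_fish["group"] == g, "value"].to_numpy()
        ax.scatter(gi + rng.uniform(-0.10, 0.10, len(fv)), fv, s=60,
                   edgecolor="k", color="C1", zorder=3)
        if len(fv):
            ax.hlines(fv.mean(), gi - 0.28, gi + 0.28, color="k", zorder=4)
            if len(fv) > 1:
                sem = fv.std(ddof=1) / np.sqrt(len(fv))
                ax.errorbar(gi, fv.mean(), yerr=sem, fmt="none", ecolor="k",
                            capsize=4, zorder=4)
    if result is not None and len(groups) == 2:
        top = cells["value"].max()
        ax.plot([0, 1], [top * 1.06] * 2, color="k", lw=1)
        ax.text(0.5, top * 1.08, significance_label(result.p_value),
                ha="center", va="bottom")
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _distance_traces(distances: pd.DataFrame, frame_interval: float, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for (fish, track, lesion), sub in distances.groupby(["fish", "track_id", "lesion_id"]):
        sub = sub.sort_values("frame")
        ax.plot(sub["frame"] * frame_interval, sub["distance_um"], lw=0.8, alpha=0.7)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("surface distance (μm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
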