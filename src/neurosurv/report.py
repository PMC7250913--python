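"""Figures summarising a pipeline run, drawn purely from stage CSVs.

Nothing here recomputes statistics: the step plots, trajectory panel and
forest plot display exactly the numbers written by the analyze stage.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import read_table

__all__ = ["ReportError", "render_report"]


class ReportError(FileNotFoundError):
    """A required analysis output is missing."""


def _step_na(ax, na, group):
    g = na[na["group"] == group].sort_values("time")
    t = np.concatenate([[0.0], g["time"].to_numpy()])
    h = np.concatenate([[0.0], g["H"].to_numpy()])
    if np.any(np.diff(h) < 0):
        raise AssertionError("cumulative hazard must be non-decreasing")
    ax.step(t, h, where="post", label=str(group))
    ax.fill_between(np.concatenate([[0.0], g["time"].to_numpy()]),
                    np.concatenate([[0.0], g["ci_lo"].to_numpy()]),
                    np.concatenate([[0.0], g["ci_hi"].to_numpy()]),
                    step="post", alpha=0.15)


def render_report(out_dir: str | Path) -> list[Path]:
    """Write na_curves.png, trajectories.png and quartile_forest.png
    (each skipped with a warning when its input is absent or empty)."""
    out = Path(out_dir)
    na_path = out / "na_curves.csv"
    if not na_path.exists():
        raise ReportError(f"missing analysis output: {na_path}")
    figures: list[Path] = []

    na = read_table(na_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    for group in na["group"].unique():
        _step_na(ax, na, group)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative hazard")
    ax.legend(title="group")
    fig.tight_layout()
    p = out / "na_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    figures.append(p)

    tracks_path = out / "tracks.csv"
    if tracks_path.exists():
        tr = read_table(tracks_path)
        tr = tr[tr["present"].astype(bool)]
        fig, ax = plt.subplots(figsize=(5, 4))
        for _, g in tr.groupby("track_id"):
            ax.plot(g["time_h"], g["mean_green"], color="seagreen", alpha=0.25, lw=0.8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("reporter level (background-subtracted)")
        fig.tight_layout()
        p = out / "trajectories.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figures.append(p)
    else:
        warnings.warn("tracks.csv absent; trajectory panel skipped", stacklevel=2)

    q_paths = sorted(out.glob("quartile_model_*.csv"))
    rows = []
    for qp in q_paths:
        q = read_table(qp)
        q = q[q["term"].str.startswith("quartile")]
        if len(q):
            t0 = qp.stem.split("_")[-1]
            for _, r in q.iterrows():
                rows.append((f"{t0}h {r['term']}", r["hr"], r["ci_lo"], r["ci_hi"]))
    if rows:
        fig, ax = plt.subplots(figsize=(5, 0.5 + 0.35 * len(rows)))
        ys = np.arange(len(rows))[::-1]
        for y, (label, hr, lo, hi) in zip(ys, rows):
            if np.isfinite(lo) and np.isfinite(hi):
                ax.plot([lo, hi], [y, y], color="k", lw=1)
            ax.plot(hr, y, "s", color="firebrick")
        ax.axvline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_yticks(ys)
        ax.set_yticklabels([r[0] for r in rows])
        ax.set_xlabel("hazard ratio (vs Q1)")
        fig.tight_layout()
        p = out / "quartile_forest.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figures.append(p)
    elif q_paths:
        warnings.warn("quartile tables empty; forest plot skipped", stacklevel=2)
    return figures
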