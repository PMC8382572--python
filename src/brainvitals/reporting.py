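"""Descriptive tables and figures: violins, radar profiles, grand averages.

Figures are views only: every numeric series a figure shows is also written
as CSV next to it, so re-running reporting on identical inputs reproduces the
record byte-for-byte regardless of rendering details.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .measures import MEASURES, UNITS
from .pipeline import AverageWaveform
from .scoring import StandardizedProfile


def descriptive_table(measurements: pd.DataFrame,
                      grouping: list[str] = ["group", "session"]) -> pd.DataFrame:
    """Per group/session/measure: n, mean, SD, median, IQR, range, min, max.

    SD uses denominator n-1; the IQR is the 75th minus 25th percentile with
    linear-interpolation quantiles. Empty cells are omitted.
    """
    rows = []
    for keys, sub in measurements.groupby(grouping + ["measure"]):
        vals = sub["value"].dropna().to_numpy(float)
        if len(vals) == 0:
            continue
        q25, q75 = np.percentile(vals, [25, 75])
        row = dict(zip(grouping + ["measure"], keys))
        row.update(n=len(vals), mean=vals.mean(),
                   sd=vals.std(ddof=1) if len(vals) > 1 else np.nan,
                   median=float(np.median(vals)), iqr=q75 - q25,
                   range=vals.max() - vals.min(), min=vals.min(), max=vals.max())
        rows.append(row)
    return pd.DataFrame(rows)


def radar_polygon(profile: StandardizedProfile) -> tuple[np.ndarray, np.ndarray]:
    """(angles, scores) of the closed radar polygon; NaN marks missing axes."""
    angles = np.linspace(0, 2 * np.pi, len(MEASURES), endpoint=False)
    scores = np.array([np.nan if profile.scores[m] is None else profile.scores[m]
                       for m in MEASURES], dtype=float)
    return np.append(angles, angles[0]), np.append(scores, scores[0])


def render_radar(profiles: dict[str, StandardizedProfile], out: str | Path,
                 ) -> "plt.Figure":
    """Overlayed radar plot of one or more standardized profiles.

    Writes the figure to ``out`` and its scores to ``out`` with a ``.csv``
    suffix; returns the figure so tests can inspect the plotted polygons.
    """
    fig, ax = plt.subplots(subplot_kw=dict(polar=True), figsize=(5, 5))
    axis_angles = np.linspace(0, 2 * np.pi, len(MEASURES), endpoint=False)
    records = []
    for label, prof in profiles.items():
        angles, scores = radar_polygon(prof)
        ax.plot(angles, scores, label=label)
        ax.fill(angles, np.nan_to_num(scores), alpha=0.15)
        for m in MEASURES:
            records.append(dict(profile=label, measure=m, score=prof.scores[m]))
    ax.set_xticks(axis_angles)
    ax.set_xticklabels([m.replace("_", "\n") for m in MEASURES], fontsize=7)
    ax.set_ylim(0, 100)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    pd.DataFrame(records).to_csv(out.with_suffix(out.suffix + ".csv"), index=False)
    return fig


def render_violin(measurements: pd.DataFrame, out: str | Path,
                  grouping: list[str] = ["group", "session"]) -> "plt.Figure":
    """Violin plot per measure and group/session, with mean/min/max hashes."""
    fig, axes = plt.subplots(3, 2, figsize=(9, 9))
    records = []
    for ax, m in zip(axes.ravel(), MEASURES):
        sub = measurements[measurements["measure"] == m]
        labels, datasets = [], []
        for keys, cell in sub.groupby(grouping):
            vals = cell["value"].dropna().to_numpy(float)
            if len(vals) == 0:
                continue
            label = "-".join(str(k) for k in (keys if isinstance(keys, tuple) else (keys,)))
            labels.append(label)
            datasets.append(vals)
            records.extend(dict(measure=m, cell=label, value=v) for v in vals)
        if datasets:
            parts = ax.violinplot(datasets, showmeans=True, showextrema=True)
        ax.set_title(f"{m} ({UNITS[m]})", fontsize=8)
        ax.set_xticks(range(1, len(labels) + 1))
        ax.set_xticklabels(labels, fontsize=7)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    pd.DataFrame(records).to_csv(out.with_suffix(out.suffix + ".csv"), index=False)
    return fig


def render_waveforms(waveforms: list[AverageWaveform], out: str | Path) -> "plt.Figure":
    """Condition-average ERP overlays with a stimulus-onset marker."""
    if not waveforms:
        raise ValueError("no waveforms to plot")
    fig, ax = plt.subplots(figsize=(7, 4))
    records = []
    for wf in waveforms:
        label = f"{wf.condition}@{wf.electrode} (n={wf.n_epochs_included})"
        ax.plot(wf.times_ms, wf.samples, label=label)
        records.extend(dict(condition=wf.condition, electrode=wf.electrode,
                            time_ms=t, uv=v) for t, v in zip(wf.times_ms, wf.samples))
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.legend(fontsize=7)
    out = Path(out)
    fig.savefig(out, dpi=120)
    pd.DataFrame(records).to_csv(out.with_suffix(out.suffix + ".csv"), index=False)
    return fig


def grand_average(waveforms: list[AverageWaveform]) -> AverageWaveform:
    """Participant-mean of same-condition, same-electrode averages."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    conds = {(w.condition, w.electrode) for w in waveforms}
    if len(conds) != 1:
        raise ValueError("waveforms must share condition and electrode")
    stack = np.stack([w.samples for w in waveforms])
    (cond, el), = conds
    return AverageWaveform(cond, el, waveforms[0].times_ms.copy(), stack.mean(axis=0),
                           len(waveforms))
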