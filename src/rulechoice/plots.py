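"""Optional figures mirroring the standard choice-analysis panels:
per-period allocation curves for training and pooled bar panels for the
choice test."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import analysis  # noqa: E402
from .events import EventLog  # noqa: E402


def plot_training(log: EventLog, path: str | Path) -> Path:
    """Percentage of responses to the instructed/VI alternative across
    successive observation periods, one trace per component."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for label, marker, fill in (("Rich", "o", "none"), ("Lean", "o", "full")):
        series = analysis.percent_instructed_series(log, label)
        ax.plot(series.index, series.values, marker=marker,
                fillstyle=fill, lw=1, label=label)
    ax.set_xlabel("Observation period")
    ax.set_ylabel("% responses to instructed alternative")
    ax.set_ylim(-5, 105)
    ax.axhline(50, color="0.7", lw=0.8, ls="--")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_choice_test(log: EventLog, path: str | Path) -> Path:
    """Pooled per-alternative percentages for the four test components."""
    report = analysis.choice_test_report(log)
    fig, axes = plt.subplots(1, 4, figsize=(9, 2.8), sharey=True)
    for ax, (_, row) in zip(axes, report.iterrows()):
        ax.bar([0, 1], [row["pct_1"], row["pct_2"]], color=["0.3", "0.7"])
        ax.set_xticks([0, 1])
        ax.set_xticklabels([row["alternative_1"], row["alternative_2"]],
                           rotation=45, ha="right", fontsize=8)
        ax.set_title(row["component"])
        ax.set_ylim(0, 105)
    axes[0].set_ylabel("% responses")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
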