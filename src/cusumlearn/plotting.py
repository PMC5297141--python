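"""CUSUM chart export: value vs. attempt, decision gridlines, signals."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import StateSegment
from .cusum import ScoreConstants, Trajectory


def plot_trajectory(
    trajectory: Trajectory,
    constants: ScoreConstants,
    segments: Optional[Sequence[StateSegment]] = None,
    title: str = "CUSUM learning curve",
    path=None,
):
    """Plot one CUSUM chart.

    Horizontal gridlines are drawn every ``H0`` chart units (``H0 == H1``
    for a symmetric design); signal attempts, if segments are given, are
    marked with their declared state.
    """
    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = np.arange(len(trajectory.values))
    ax.step(x, trajectory.values, where="post", lw=1.2, color="black")

    lo = min(trajectory.values.min(), -constants.H0)
    hi = max(trajectory.values.max(), constants.H1)
    levels = np.arange(
        np.floor(lo / constants.H0) * constants.H0,
        np.ceil(hi / constants.H1) * constants.H1 + 1e-9,
        constants.H0,
    )
    for lev in levels:
        ax.axhline(lev, color="grey", lw=0.5, ls="--", zorder=0)

    if segments:
        colors = {"proficient": "tab:green", "nonproficient": "tab:red"}
        for seg in segments:
            if seg.signal_attempt is not None:
                ax.plot(
                    seg.signal_attempt,
                    trajectory.values[seg.signal_attempt],
                    "o",
                    color=colors.get(seg.state, "tab:blue"),
                    label=f"{seg.state} (attempt {seg.signal_attempt})",
                )
        if ax.get_legend_handles_labels()[0]:
            ax.legend(loc="best", fontsize=8)

    ax.set_xlabel("sampling attempt")
    ax.set_ylabel("CUSUM value")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
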