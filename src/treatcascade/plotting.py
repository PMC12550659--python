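"""Cumulative-response figures for cascade results."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cascade import CascadeResult, cumulative_response_curve

__all__ = ["plot_cumulative_response"]


def plot_cumulative_response(
    results: Sequence[CascadeResult],
    output_path: str | Path,
    labels: Sequence[str] | None = None,
) -> Path:
    """Write a panel-per-scenario cumulative response chart.

    Each panel shows percent of the cohort responded (y) against treatment
    step (x), with a horizontal guide at the coverage target.  One panel
    per result; ``labels`` title the panels.  Returns the written path.
    """
    results = list(results)
    if not results:
        raise ValueError("at least one cascade result is required")
    if labels is not None and len(labels) != len(results):
        raise ValueError("labels must match results one-to-one")

    fig, axes = plt.subplots(
        1, len(results), figsize=(4.2 * len(results), 3.6), sharey=True, squeeze=False
    )
    for i, (ax, res) in enumerate(zip(axes[0], results)):
        curve = cumulative_response_curve(res)
        steps = [k for k, _ in curve]
        pct = [v for _, v in curve]
        ax.step(steps, pct, where="post", color="C0")
        ax.plot(steps, pct, "o", color="C0", ms=3)
        ax.axhline(
            100.0 * res.config.coverage_target, color="grey", ls="--", lw=0.8,
            label=f"{100 * res.config.coverage_target:g}% target",
        )
        ax.set_xlabel("treatment step")
        if i == 0:
            ax.set_ylabel("% of cohort responded")
        if labels is not None:
            ax.set_title(labels[i])
        ax.set_ylim(0, 102)
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    output_path = Path(output_path)
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path
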