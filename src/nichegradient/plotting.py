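"""Optional per-combination diagnostic plots (histogram, CIs, curve, HPI)."""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .pipeline import CombinationResult


def plot_combination(result: CombinationResult, path: str | Path) -> None:
    """Proportions with CIs, the fitted curve, and the shaded HPI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.binned is None:
        raise ValueError("nothing to plot for an excluded combination")
    b = result.binned
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        b.midpoints,
        b.proportions,
        yerr=[b.proportions - b.ci_lower, b.ci_upper - b.proportions],
        fmt="ko",
        capsize=2,
        label="bin proportions (CI)",
    )
    if result.marked is not None:
        idx = list(result.marked.indices)
        ax.plot(
            b.midpoints[idx], b.proportions[idx], "o", mfc="none", mec="red",
            ms=12, label="marked points",
        )
    if result.fitted is not None:
        xs = np.linspace(result.fitted.xmin, result.fitted.xmax, 400)
        ax.plot(xs, result.fitted(xs), "b-", label="logistic polynomial")
        if result.hpi is not None:
            band = (xs >= result.hpi.xL) & (xs <= result.hpi.xU)
            ax.fill_between(xs[band], 0, result.fitted(xs)[band], alpha=0.3,
                            color="gray", label="highest-probability interval")
    ax.set_xlabel(result.variable)
    ax.set_ylabel("occurrence proportion")
    ax.set_title(f"{result.species} / {result.variable}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
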