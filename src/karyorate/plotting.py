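"""Optional density plots of the DeltaR posteriors with HPD bars."""

from __future__ import annotations

from typing import Mapping, Optional, Tuple

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.stats import gaussian_kde  # noqa: E402


def plot_delta_r_densities(
    samples: Mapping[str, np.ndarray],
    intervals: Optional[Mapping[str, Tuple[float, float]]] = None,
    path=None,
    title: str = "DeltaR posterior (holocentric - monocentric, per Myr)",
):
    """Kernel-density curves of DeltaR per mechanism, with the 95% HPD drawn
    as a horizontal bar below each curve and a reference line at zero."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, (mech, vals) in enumerate(samples.items()):
        vals = np.asarray(vals, dtype=float)
        if np.ptp(vals) > 0:
            kde = gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 256)
            ax.plot(grid, kde(grid), label=mech)
        else:
            ax.axvline(vals[0], label=mech)
        if intervals and mech in intervals:
            low, high = intervals[mech]
            ax.plot([low, high], [-(k + 1) * 0.03, -(k + 1) * 0.03], lw=3)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("DeltaR (events / Myr)")
    ax.set_ylabel("posterior density")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
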