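"""Static report figures: Bland-Altman and correlation plots."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .agreement import bland_altman


def _get_ax(ax):
    if ax is not None:
        return ax, None
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    return ax, fig


def bland_altman_plot(
    device: Sequence[float],
    reference: Sequence[float],
    label: str = "SpO2 (%)",
    path: Optional[Union[str, Path]] = None,
    ax=None,
):
    """Scatter of pair means vs differences with bias and 1.96-SD limits."""
    d = np.asarray(device, float)
    r = np.asarray(reference, float)
    bias, sd, loa = bland_altman(d, r)
    ax, fig = _get_ax(ax)
    ax.scatter((d + r) / 2.0, d - r, s=12, alpha=0.6)
    ax.axhline(bias, color="k", lw=1)
    for y in loa:
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean of device and reference {label}")
    ax.set_ylabel(f"device - reference {label}")
    if fig is not None and path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax


def correlation_plot(
    device: Sequence[float],
    reference: Sequence[float],
    label: str = "SpO2 (%)",
    path: Optional[Union[str, Path]] = None,
    ax=None,
):
    """Device vs reference scatter with the identity line."""
    d = np.asarray(device, float)
    r = np.asarray(reference, float)
    ax, fig = _get_ax(ax)
    ax.scatter(r, d, s=12, alpha=0.6)
    lo, hi = min(r.min(), d.min()), max(r.max(), d.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel(f"device {label}")
    if fig is not None and path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax
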