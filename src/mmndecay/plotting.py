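"""Diagnostic figures: difference waves and decay-vs-cognition scatter."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .erp import ErpWave


def plot_difference_waves(
    waves: Mapping[str, ErpWave],
    ax=None,
    title: Optional[str] = None,
):
    """Overlay fronto-central difference waves (one line per condition)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, wave in waves.items():
        ax.plot(wave.times_ms, wave.values[0], label=label)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.invert_yaxis()  # negativity up, ERP convention
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_delta_vs_composite(delta_uv: Sequence[float], composite: Sequence[float], ax=None):
    """Scatter of the ΔMMN decay score against a composite, with the least
    squares line and Pearson r annotated."""
    import matplotlib.pyplot as plt

    from .stats import pearson_r

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(delta_uv, dtype=float)
    y = np.asarray(composite, dtype=float)
    ax.scatter(x, y, s=18, alpha=0.8)
    b, a = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, a + b * xs, color="C3")
    ax.set_xlabel("ΔMMN (uV)")
    ax.set_ylabel("composite score")
    ax.annotate(f"r = {pearson_r(x, y):.2f}", xy=(0.05, 0.92), xycoords="axes fraction")
    return ax
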