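"""Small plotting helpers for concentration-time profiles."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .convolve import ConcentrationProfile


def plot_profiles(
    profiles: Sequence[ConcentrationProfile],
    labels: Sequence[str] | None = None,
    *,
    observations=None,
    logy: bool = False,
    title: str = "",
    path=None,
):
    """Overlay concentration-time profiles (optionally with observed points).

    ``observations`` is an optional iterable of (times, conc) pairs drawn as
    dots, in the style of observed-vs-predicted overlays.
    """
    fig, ax = plt.subplots(figsize=(8, 5))
    labels = labels or [p.metadata.get("model", f"profile {i}") for i, p in enumerate(profiles)]
    for prof, lab in zip(profiles, labels):
        ax.plot(prof.times, prof.conc, label=str(lab))
    if observations is not None:
        for t, c in observations:
            ax.plot(t, c, "o", ms=4, alpha=0.6)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    if logy:
        ax.set_yscale("log")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
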