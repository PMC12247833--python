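"""Profile figures: mean intensity vs signed distance with SEM bands and a
secondary per-bin cell-count axis."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profile import BinProfile

__all__ = ["plot_profile"]


def plot_profile(
    prof: BinProfile,
    path: str | Path | None = None,
    ax: plt.Axes | None = None,
    color: str = "black",
) -> plt.Axes:
    """Line plot of per-bin mean intensity with an SEM band, plus per-bin
    cell counts on a secondary axis. Negative distances are inside the
    stroma; the dashed line marks the stromal border."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = prof.bin_centers_um
    ok = prof.n > 0
    ax.plot(x[ok], prof.mean_intensity[ok], "o-", color=color, ms=4, lw=1)
    sem = np.where(np.isnan(prof.sem), 0.0, prof.sem)
    ax.fill_between(
        x[ok],
        (prof.mean_intensity - sem)[ok],
        (prof.mean_intensity + sem)[ok],
        color="grey",
        alpha=0.4,
        lw=0,
    )
    ax.axvline(0.0, ls="--", color="tab:red", lw=1)
    ax.set_xlabel("signed distance to stromal border (µm)")
    ax.set_ylabel(f"mean intensity  {prof.population_label}".strip())
    ax2 = ax.twinx()
    ax2.bar(x, prof.n, width=prof.bin_width_um * 0.9, alpha=0.2, color="tab:blue")
    ax2.set_ylabel("cells per bin")
    if path is not None:
        ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
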