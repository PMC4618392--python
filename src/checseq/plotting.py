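"""Minimal figure export: profile line charts and a kinetics heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import TimeCourseMatrix
from .profiles import CleavageProfile


def plot_profile(profile: CleavageProfile, path, title: str = "") -> None:
    """Line chart of a cleavage (or average-signal) profile, CI band if present."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.offsets, profile.mean, lw=1.2, color="tab:blue")
    if profile.lo is not None:
        ax.fill_between(profile.offsets, profile.lo, profile.hi,
                        alpha=0.3, color="tab:blue", lw=0)
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("offset from match center (bp)")
    ax.set_ylabel(f"mean signal ({profile.units})")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_time_matrix(matrix: TimeCourseMatrix, path, order: np.ndarray | None = None) -> None:
    """Plain heatmap of the (Z-scored) peaks x time matrix."""
    values = matrix.values if order is None else matrix.values[order]
    fig, ax = plt.subplots(figsize=(3, 6))
    im = ax.imshow(values, aspect="auto", interpolation="nearest", cmap="RdBu_r",
                   vmin=-2, vmax=2)
    ax.set_xticks(range(len(matrix.times)))
    ax.set_xticklabels([f"{t:g}" for t in matrix.times], fontsize=7, rotation=45)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("peaks")
    fig.colorbar(im, ax=ax, shrink=0.5, label="row Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
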