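"""Minimal matplotlib figures: metagene profile and consensus logo."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .models import REGIONS
from .motif import ConsensusMatrix
from .regions import MetageneProfile

BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}


def metagene_plot(
    profile: MetageneProfile, path: str | Path, title: str = ""
) -> None:
    fig, ax = plt.subplots(figsize=(7, 3))
    x = range(3 * profile.n_bins)
    ax.plot(x, profile.flat, lw=1.5, color="#333333")
    for i, region in enumerate(REGIONS):
        ax.axvspan(
            i * profile.n_bins,
            (i + 1) * profile.n_bins,
            alpha=0.08,
            color=["#1f77b4", "#2ca02c", "#d62728"][i],
        )
        ax.text(
            (i + 0.5) * profile.n_bins,
            ax.get_ylim()[1] * 0.95,
            region.value.upper(),
            ha="center",
            va="top",
            fontsize=9,
        )
    ax.set_xlabel("metagene position (5'UTR | CDS | 3'UTR)")
    ax.set_ylabel("site density")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def logo_plot(matrix: ConsensusMatrix, path: str | Path, title: str = "") -> None:
    """Sequence logo as stacked scaled letters from the frequency matrix."""
    freq = matrix.frequencies
    fig, ax = plt.subplots(figsize=(0.5 * freq.shape[0] + 1, 2.5))
    for col in range(freq.shape[0]):
        bottom = 0.0
        order = freq[col].argsort()
        for bi in order:
            f = freq[col, bi]
            if f <= 0:
                continue
            base = "ACGU"[bi]
            ax.text(
                col,
                bottom + f / 2,
                base,
                ha="center",
                va="center",
                fontsize=6 + 22 * f,
                fontweight="bold",
                color=BASE_COLORS[base],
            )
            bottom += f
    ax.set_xlim(-0.6, freq.shape[0] - 0.4)
    ax.set_ylim(0, 1.02)
    ax.set_xticks(range(freq.shape[0]))
    ax.set_xticklabels(
        [str(o) for o in range(-matrix.flank, 5 + matrix.flank)], fontsize=7
    )
    ax.set_xlabel("offset from k-mer start (nt)")
    ax.set_ylabel("base frequency")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
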