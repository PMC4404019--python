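"""Heat-map rendering of ratio maps and codon-pair residual matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .context import PairContextTable, DifferentialMap
from .genetic_code import CODONS
from .rscu import RatioMap


def save_ratio_heatmap(rmap: RatioMap, path: "Path | str") -> None:
    """One-row map of RSCU ratios; similar codons (0.9-1.1) in blue."""
    values = rmap.ratio.to_numpy()[None, :]
    colors = np.where(rmap.similar.to_numpy()[None, :], 1.0, 0.0)
    fig, ax = plt.subplots(figsize=(16, 1.6))
    ax.imshow(colors, aspect="auto", cmap="Blues", vmin=0, vmax=1.3)
    ax.set_xticks(range(64))
    ax.set_xticklabels(CODONS, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_title(f"RSCU ratio {rmap.numerator_label} / {rmap.denominator_label}",
                 fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    del values


def _codon_axes(ax) -> None:
    ax.set_xticks(range(64))
    ax.set_xticklabels(CODONS, rotation=90, fontsize=4)
    ax.set_yticks(range(64))
    ax.set_yticklabels(CODONS, fontsize=4)


def save_residual_heatmap(table: PairContextTable, path: "Path | str",
                          clip: float = 10.0) -> None:
    """64x64 adjusted-residual map; positive = good 3' context."""
    fig, ax = plt.subplots(figsize=(10, 10))
    im = ax.imshow(np.clip(table.residual, -clip, clip), cmap="RdBu_r",
                   vmin=-clip, vmax=clip)
    _codon_axes(ax)
    ax.set_xlabel("3' codon")
    ax.set_ylabel("5' codon")
    ax.set_title(f"3' codon context, group {table.group_label}", fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.6, label="adjusted residual")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_differential_heatmap(dmap: DifferentialMap, path: "Path | str") -> None:
    """Similarity map between two groups: similar cells black, different blue."""
    img = np.where(np.isnan(dmap.delta), 0.5, np.where(dmap.similar, 0.0, 1.0))
    fig, ax = plt.subplots(figsize=(10, 10))
    ax.imshow(img, cmap="Blues", vmin=0, vmax=1)
    _codon_axes(ax)
    ax.set_xlabel("3' codon")
    ax.set_ylabel("5' codon")
    ax.set_title(f"context difference {dmap.label_a} vs {dmap.label_b}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
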