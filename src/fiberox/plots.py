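"""Diagnostic figures: damage vs disease stage and vs ABI."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_LABELS = {"carbonyl": "Carbonyl content (gsu)", "hne": "HNE content (gsu)"}
_COLS = {"carbonyl": "mean_carbonyl_gsu", "hne": "mean_hne_gsu"}


def plot_damage_vs_stage(pad_summaries: pd.DataFrame, path: str | Path) -> Path:
    """Scatter of specimen mean damage against Fontaine stage, both markers."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharex=True)
    for ax, marker in zip(axes, ("carbonyl", "hne")):
        ax.scatter(pad_summaries["fontaine_stage"], pad_summaries[_COLS[marker]],
                   s=18, alpha=0.8)
        ax.set_xlabel("Fontaine stage")
        ax.set_ylabel(_LABELS[marker])
        ax.set_xticks([2, 3, 4])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_damage_vs_abi(pad_summaries: pd.DataFrame, path: str | Path) -> Path:
    """Scatter of specimen mean damage against ankle-brachial index."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharex=True)
    for ax, marker in zip(axes, ("carbonyl", "hne")):
        ax.scatter(pad_summaries["abi"], pad_summaries[_COLS[marker]],
                   s=18, alpha=0.8)
        ax.set_xlabel("ABI")
        ax.set_ylabel(_LABELS[marker])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
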