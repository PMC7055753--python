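"""Basic agreement plots: Bland-Altman and device-vs-reference scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import BlandAltman
from .vitals import UNITS, Vital


def bland_altman_plot(ba: BlandAltman, vital: Vital, device: str, path: str | Path) -> Path:
    """Signed difference vs pair mean, with bias and 1.96-SD limit lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=14, alpha=0.6, edgecolors="none")
    ax.axhline(ba.mean_signed_diff, linestyle=":", color="k", label="mean difference")
    if ba.loa_low is not None:
        ax.axhline(ba.loa_low, linestyle="--", color="k")
        ax.axhline(ba.loa_high, linestyle="--", color="k")
    unit = UNITS[Vital(vital)]
    ax.set_xlabel(f"mean of pair ({unit})")
    ax.set_ylabel(f"device - reference ({unit})")
    ax.set_title(f"{device}: {Vital(vital).value}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def scatter_plot(
    investigational,
    reference,
    vital: Vital,
    device: str,
    path: str | Path,
    cutoff: float | None = None,
) -> Path:
    """Device vs reference with identity line and optional clinical cutoff."""
    inv = np.asarray(investigational, float)
    ref = np.asarray(reference, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ref, inv, s=14, alpha=0.6, edgecolors="none")
    lo = min(ref.min(), inv.min())
    hi = max(ref.max(), inv.max())
    ax.plot([lo, hi], [lo, hi], color="k", linewidth=1, label="identity")
    if cutoff is not None:
        ax.axvline(cutoff, linestyle="--", color="grey")
        ax.axhline(cutoff, linestyle="--", color="grey")
    unit = UNITS[Vital(vital)]
    ax.set_xlabel(f"reference ({unit})")
    ax.set_ylabel(f"device ({unit})")
    ax.set_title(f"{device}: {Vital(vital).value}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
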