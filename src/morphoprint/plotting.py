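"""Heatmaps and line plots for fingerprints and biosimilarity matrices.

Rendering mirrors the field's reporting style: fingerprint heatmaps with
a diverging blue/white/red map (decreased features blue, increased red)
and a reference-first row ordering; cross-biosimilarity heatmaps with
banded shading; per-feature line plots for a single fingerprint.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .containers import Fingerprint


def fingerprint_heatmap(
    fps: Sequence[Fingerprint],
    reference_first: bool = True,
    vmax: float = 10.0,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Stacked fingerprint heatmap, reference (first entry) on top."""
    fps = list(fps)
    if not reference_first:
        fps = sorted(fps, key=lambda fp: -fp.induction)
    data = pd.DataFrame({fp.label: fp.z for fp in fps}).T
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.5 * len(fps) + 1.5))
    sns.heatmap(
        data, cmap="RdBu_r", center=0.0, vmin=-vmax, vmax=vmax, ax=ax,
        xticklabels=False, cbar_kws={"label": "z-score"},
    )
    ax.set_xlabel("feature")
    return ax


def biosimilarity_heatmap(
    matrix: pd.DataFrame, ax: plt.Axes | None = None
) -> plt.Axes:
    """Cross-biosimilarity heatmap with percent annotations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix),) * 2)
    sns.heatmap(
        matrix, cmap="Blues", vmin=0, vmax=100, annot=True, fmt=".0f", ax=ax,
        cbar_kws={"label": "biosimilarity (%)"},
    )
    return ax


def fingerprint_lineplot(fp: Fingerprint, ax: plt.Axes | None = None) -> plt.Axes:
    """Per-feature z line plot with region boundaries marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    z = fp.z.to_numpy(dtype=float)
    ax.plot(np.arange(1, z.size + 1), z, lw=0.8)
    ax.axhline(0, color="grey", lw=0.5)
    for name, (lo, hi) in fp.regions.items():
        ax.axvline(hi + 0.5, color="k", lw=0.5, ls=":")
        ax.text((lo + hi) / 2, ax.get_ylim()[1], name, ha="center", va="top", fontsize=8)
    ax.set_xlabel("feature position")
    ax.set_ylabel("z-score")
    ax.set_title(fp.label)
    return ax
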