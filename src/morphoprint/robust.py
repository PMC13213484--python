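"""Robust-feature selection from two biological repeats.

High-content features vary widely in reproducibility. Following the
standard procedure, two biological repeats of one reference plate are
profiled; for every feature the vector of its well-level values across
the whole plate is formed for each repeat, and the feature is kept when
the two vectors agree with similarity >= 0.8. "Similarity" is the same
1 - Pearson-correlation-distance measure (clipped at 0) used for
biosimilarity, so a single similarity notion runs through the package.
Selection happens once per screen, on raw well medians, before any
Z-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ScreenError, feature_columns

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelection:
    """Selected feature subset with per-feature replicate similarity."""

    features: list[str]
    similarity: pd.Series  # per feature, NaN where undefined (constant vector)
    threshold: float

    def __post_init__(self) -> None:
        valid = self.similarity.dropna()
        if len(valid) and not ((valid >= 0) & (valid <= 1)).all():
            raise ScreenError("similarities must lie in [0, 1] after clipping")

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_index": np.arange(1, len(self.similarity) + 1),
                "feature_name": self.similarity.index,
                "similarity": self.similarity.to_numpy(),
                "selected": [f in set(self.features) for f in self.similarity.index],
            }
        )


def select_robust_features(
    repeat_1: pd.DataFrame,
    repeat_2: pd.DataFrame,
    min_similarity: float = 0.8,
) -> FeatureSelection:
    """Keep features whose whole-plate profiles agree across two repeats.

    Both frames are well-level profiles of the same reference plate
    (matched by compound when layouts differ, otherwise by well). For each
    feature the across-well value vectors of the two repeats are compared
    with similarity = max(0, Pearson r); features reaching
    ``min_similarity`` are retained in their original column order.
    Features that are constant in either repeat have undefined similarity
    and are rejected with a log message.
    """
    feats = feature_columns(repeat_1)
    if feats != feature_columns(repeat_2):
        raise ScreenError("repeats carry different feature sets")

    r1, r2 = _match_rows(repeat_1, repeat_2)
    if len(r1) < 3:
        raise ScreenError("need >= 3 matched wells to assess reproducibility")

    a = r1[feats].to_numpy(dtype=float)
    b = r2[feats].to_numpy(dtype=float)
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    denom = np.sqrt((a_c**2).sum(axis=0) * (b_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a_c * b_c).sum(axis=0) / denom
    # ptp == 0 catches constant columns exactly, immune to mean round-off
    constant = (np.ptp(a, axis=0) == 0) | (np.ptp(b, axis=0) == 0) | (denom == 0)
    r[constant] = np.nan

    n_constant = int(np.isnan(r).sum())
    if n_constant:
        logger.warning(
            "%d features constant in a repeat: similarity undefined, rejected",
            n_constant,
        )
    sim = pd.Series(np.clip(r, 0.0, 1.0), index=feats, name="similarity")
    selected = [f for f in feats if sim[f] >= min_similarity]
    return FeatureSelection(features=selected, similarity=sim, threshold=min_similarity)


def _match_rows(r1: pd.DataFrame, r2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align the two repeats by compound label if present, else by index."""
    if "compound" in r1.columns and "compound" in r2.columns:
        key = ["compound"]
        if "concentration_uM" in r1.columns and "concentration_uM" in r2.columns:
            key.append("concentration_uM")
        a = r1.reset_index().set_index(key).sort_index()
        b = r2.reset_index().set_index(key).sort_index()
        common = a.index.intersection(b.index)
        if a.index.has_duplicates or b.index.has_duplicates:
            # fall back to positional matching within duplicated labels
            a = a.loc[common].groupby(level=list(range(len(key)))).median(numeric_only=True)
            b = b.loc[common].groupby(level=list(range(len(key)))).median(numeric_only=True)
            return a, b
        return a.loc[common], b.loc[common]
    common = r1.index.intersection(r2.index)
    return r1.loc[common], r2.loc[common]


def apply_selection(profiles: pd.DataFrame, selection: FeatureSelection) -> pd.DataFrame:
    """Restrict a profile frame to the selected features.

    Metadata columns are preserved. An empty selection is an error — the
    downstream analysis is meaningless on a zero-length fingerprint.
    """
    if len(selection) == 0:
        raise ScreenError("empty feature selection")
    missing = [f for f in selection.features if f not in profiles.columns]
    if missing:
        raise ScreenError(f"selection names unknown features: {missing[:5]}")
    meta = [c for c in profiles.columns if c not in feature_columns(profiles)]
    return profiles[meta + list(selection.features)]
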