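"""Fingerprint metrics: induction, biosimilarity, regions, top features.

Biosimilarity between two fingerprints is defined from the Pearson
correlation distance CD = 1 - r:

    biosimilarity = 100 x max(0, 1 - CD) = 100 x max(0, r)

so anti-correlated profiles clip to 0% rather than going negative. The
induction value of a fingerprint is the percentage of selected features
whose |z| reaches the significance threshold (default 3 robust-SD units);
a compound is called biologically active when its induction exceeds 5%.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import correlation as _correlation_distance

from .containers import Fingerprint, ScreenError

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = 5.0  # induction % above which a compound is active


def induction(z: np.ndarray | pd.Series, change_threshold: float = 3.0) -> float:
    """Percent of features significantly changed: 100 * |{|z| >= t}| / n."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ScreenError("induction undefined for an empty feature set")
    if not np.all(np.isfinite(z)):
        raise ScreenError("induction requires finite z-scores")
    return 100.0 * float(np.count_nonzero(np.abs(z) >= change_threshold)) / z.size


def is_active(induction_pct: float, threshold: float = ACTIVITY_THRESHOLD) -> bool:
    """Biological activity call: strictly greater than the 5% cutoff."""
    if not 0.0 <= induction_pct <= 100.0:
        raise ScreenError("induction must lie in [0, 100]")
    return induction_pct > threshold


def biosimilarity(
    z_a: np.ndarray | pd.Series, z_b: np.ndarray | pd.Series
) -> float:
    """Biosimilarity percent between two profiles; NaN for constant input.

    Computed as 100 * max(0, 1 - CD) with CD the Pearson correlation
    distance. Constant vectors have no defined correlation and yield NaN
    with a warning, never 0 or 100.
    """
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.shape != b.shape:
        raise ScreenError("profiles must have equal length")
    if a.size < 3:
        raise ScreenError("biosimilarity needs >= 3 features")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant profile: biosimilarity undefined, reporting NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cd = _correlation_distance(a, b)
    return 100.0 * max(0.0, 1.0 - float(cd))


def cross_biosimilarity(
    fingerprints: Sequence[Fingerprint], min_induction: float = 30.0
) -> pd.DataFrame:
    """Pairwise biosimilarity matrix among sufficiently active fingerprints.

    Fingerprints at or below ``min_induction`` percent are filtered out
    first (the reporting convention restricts cross-comparison to profiles
    with induction > 30%). The result is symmetric with a 100% diagonal,
    labelled ``compound@concentration``.
    """
    survivors = [fp for fp in fingerprints if fp.induction > min_induction]
    if len(survivors) < 2:
        raise ScreenError(
            f"fewer than 2 fingerprints exceed the induction > {min_induction}% filter"
        )
    labels = [fp.label for fp in survivors]
    n = len(survivors)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = biosimilarity(survivors[i].z, survivors[j].z)
            mat[i, j] = mat[j, i] = s
    return pd.DataFrame(mat, index=labels, columns=labels)


def region_summary(fp: Fingerprint, change_threshold: float = 3.0) -> pd.DataFrame:
    """Per-compartment mean |z| and count of significantly changed features.

    Supports observations of the form "more dramatically changed in the
    cytoplasm parameters than the nuclei parameters".
    """
    if not fp.regions:
        raise ScreenError("fingerprint carries no region partition")
    rows = {}
    for region in fp.regions:
        z = fp.region_values(region).to_numpy(dtype=float)
        rows[region] = {
            "n_features": z.size,
            "mean_abs_z": float(np.mean(np.abs(z))) if z.size else 0.0,
            "n_changed": int(np.count_nonzero(np.abs(z) >= change_threshold)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def top_changed(fp: Fingerprint, min_abs: float = 10.0) -> pd.DataFrame:
    """Features with |z| >= ``min_abs``, strongest first.

    Ties in |z| are broken by feature position ascending. Returns a frame
    with columns ``feature``, ``position`` (1-based) and ``z``; may be
    empty.
    """
    z = fp.z.to_numpy(dtype=float)
    idx = np.flatnonzero(np.abs(z) >= min_abs)
    # stable sort on -|z| keeps ascending positions among ties
    order = idx[np.argsort(-np.abs(z[idx]), kind="stable")]
    return pd.DataFrame(
        {
            "feature": fp.z.index[order],
            "position": order + 1,
            "z": z[order],
        }
    ).reset_index(drop=True)
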