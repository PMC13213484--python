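"""Aggregation and Z-score fingerprinting.

The workflow follows the standard cell-painting convention: per-site
feature values are aggregated as medians per well (9 sites -> 1 well),
then as medians over the replicate plates matched by compound identity
(layouts are shifted between replicates, so wells cannot be matched by
position). Z-scores are computed relative to the median of the DMSO
vehicle wells with a robust scale (1.4826 x MAD by default, plain SD
optionally), and the fingerprint of a compound is the vector of Z-scores
over the selected robust features.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .containers import (
    META_COLS,
    ROLE_VEHICLE,
    FeatureTable,
    Fingerprint,
    PlateLayout,
    ScreenError,
    feature_columns,
    region_partition,
)
from .metrics import induction as induction_value

logger = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor: MAD -> SD for a normal distribution

#: relative-cell-count class bands (percent of vehicle median)
CELL_COUNT_NORMAL = 80.0
CELL_COUNT_ARREST = 50.0


def aggregate_sites(table: FeatureTable, layout: PlateLayout) -> pd.DataFrame:
    """Collapse imaging sites to one profile per well (median per feature).

    Missing values are ignored within each per-feature median; a well whose
    feature is missing at every site stays NaN and is logged, never
    silently zeroed.

    Returns a frame indexed by well with metadata columns
    (``compound``, ``concentration_uM``, ``role``, ``cell_count``) followed
    by the feature columns.
    """
    value_cols = ["cell_count"] + table.feature_names
    med = table.data.groupby("well", sort=True)[value_cols].median()

    n_all_missing = int(med[table.feature_names].isna().to_numpy().sum())
    if n_all_missing:
        logger.warning(
            "plate %s: %d (well, feature) entries missing at every site",
            table.plate_id,
            n_all_missing,
        )

    ann = layout.data.set_index("well")[["compound", "concentration_uM", "role"]]
    unmatched = med.index.difference(ann.index)
    if len(unmatched):
        raise ScreenError(
            f"plate {table.plate_id!r}: wells missing from layout: "
            f"{list(unmatched)[:5]}"
        )
    out = ann.join(med, how="inner")
    out.index.name = "well"
    return out[["compound", "concentration_uM", "role", "cell_count"] + table.feature_names]


def aggregate_replicates(plates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Median across replicate plates, matched by (compound, concentration).

    Layout shifting between replicates is irrelevant here because matching
    is by compound label, not well position. A compound present on only a
    subset of plates is aggregated over the plates that carry it, with a
    warning.

    Returns a frame indexed by (compound, concentration_uM).
    """
    if not plates:
        raise ScreenError("no plates to aggregate")
    tagged = []
    for p, frame in enumerate(plates):
        f = frame.copy()
        f["_plate"] = p
        tagged.append(f)
    stacked = pd.concat(tagged, axis=0, ignore_index=False)
    value_cols = ["cell_count"] + feature_columns(stacked)
    grouped = stacked.groupby(["compound", "concentration_uM"], sort=True)

    plate_counts = grouped["_plate"].nunique()
    short = plate_counts[plate_counts < len(plates)]
    if len(short):
        logger.warning(
            "%d compound/concentration pairs present on only a subset of plates",
            len(short),
        )

    out = grouped[value_cols].median()
    role = grouped["role"].first()
    out.insert(0, "role", role)
    return out


def aggregate_vehicle_wells(plates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Replicate-aggregated vehicle wells, one profile per well position.

    Vehicle wells keep their positions when layouts are shifted, so they
    are matched by well across plates and medianed there. Unlike
    :func:`aggregate_replicates` they are *not* collapsed to one DMSO row:
    the spread across vehicle wells is what calibrates the Z-score scale.
    """
    vehicles = [p[p["role"] == ROLE_VEHICLE] for p in plates]
    if not vehicles or all(v.empty for v in vehicles):
        raise ScreenError("no vehicle wells on any plate")
    stacked = pd.concat(vehicles, axis=0)
    value_cols = ["cell_count"] + feature_columns(stacked)
    out = stacked.groupby(level=0, sort=True)[value_cols].median()
    out.insert(0, "role", ROLE_VEHICLE)
    out.insert(0, "concentration_uM", 0.0)
    out.insert(0, "compound", stacked["compound"].iloc[0])
    out.index.name = "well"
    return out


def dmso_reference(
    vehicle_profiles: pd.DataFrame, scale_method: Literal["mad", "sd"] = "mad"
) -> tuple[pd.Series, pd.Series]:
    """Per-feature location (median) and scale of the DMSO vehicle wells.

    The robust scale is ``1.4826 x MAD``; ``scale_method="sd"`` switches to
    the sample standard deviation.
    """
    feats = feature_columns(vehicle_profiles)
    if len(vehicle_profiles) < 3:
        raise ScreenError("need >= 3 vehicle profiles to estimate dispersion")
    values = vehicle_profiles[feats]
    center = values.median()
    if scale_method == "mad":
        scale = (values - center).abs().median() * MAD_TO_SD
    elif scale_method == "sd":
        scale = values.std(ddof=1)
    else:
        raise ValueError(f"unknown scale method {scale_method!r}")
    return center, scale


def zscore_profile(
    values: pd.Series,
    center: pd.Series,
    scale: pd.Series,
) -> pd.Series:
    """Robust Z-scores of one profile; zero/NaN-scale features are dropped."""
    usable = scale.index[(scale > 0) & np.isfinite(scale) & np.isfinite(center)]
    dropped = scale.index.difference(usable)
    if len(dropped):
        logger.warning(
            "%d features with zero or undefined DMSO dispersion excluded", len(dropped)
        )
    z = (values[usable] - center[usable]) / scale[usable]
    return z.dropna()


def fingerprint(
    profile: pd.Series,
    vehicle_profiles: pd.DataFrame,
    features: Sequence[str] | None = None,
    change_threshold: float = 3.0,
    scale_method: Literal["mad", "sd"] = "mad",
    compound: str | None = None,
    concentration: float | None = None,
    regions: dict[str, tuple[int, int]] | None = None,
) -> Fingerprint:
    """Z-score fingerprint of one compound profile versus the DMSO wells.

    Parameters
    ----------
    profile
        One row of a compound-level profile frame (metadata + features).
    vehicle_profiles
        Well- or compound-level profiles of the vehicle wells (>= 3 rows).
    features
        Selected robust feature subset; defaults to every feature present.
    change_threshold
        |z| at or above which a feature counts as significantly changed
        for the induction value.
    """
    if features is not None:
        if len(features) == 0:
            raise ScreenError("empty feature selection")
        vehicle_profiles = vehicle_profiles[
            [c for c in vehicle_profiles.columns if c in META_COLS]
            + list(features)
        ]
    feats = feature_columns(vehicle_profiles)
    center, scale = dmso_reference(vehicle_profiles, scale_method)
    z = zscore_profile(profile[feats].astype(float), center, scale)
    ind = induction_value(z.to_numpy(), change_threshold=change_threshold)

    rcc = None
    rcc_class = None
    if "cell_count" in profile.index and "cell_count" in vehicle_profiles.columns:
        rcc, rcc_class = relative_cell_count(
            float(profile["cell_count"]), vehicle_profiles["cell_count"]
        )

    return Fingerprint(
        compound=compound if compound is not None else str(profile.get("compound", "?")),
        concentration=(
            concentration
            if concentration is not None
            else float(profile.get("concentration_uM", np.nan))
        ),
        z=z,
        induction=ind,
        relative_cell_count=rcc,
        cell_count_class=rcc_class,
        regions=(
            regions
            if regions is not None
            else (region_partition(len(z)) if len(z) >= 3 else {})
        ),
    )


def fingerprint_screen(
    profiles: pd.DataFrame,
    vehicle_profiles: pd.DataFrame | None = None,
    features: Sequence[str] | None = None,
    change_threshold: float = 3.0,
    scale_method: Literal["mad", "sd"] = "mad",
) -> list[Fingerprint]:
    """Fingerprints for every non-vehicle entry of a compound-level frame.

    The frame must be indexed by (compound, concentration_uM) as produced
    by :func:`aggregate_replicates`. ``vehicle_profiles`` supplies the
    per-well DMSO null profiles (see :func:`aggregate_vehicle_wells`); if
    omitted, vehicle-role rows of ``profiles`` are used. Fingerprints are
    computed for all treatment and reference entries; activity (induction)
    is stored as metadata rather than used to suppress profiles.
    """
    vehicle = (
        vehicle_profiles
        if vehicle_profiles is not None
        else profiles[profiles["role"] == ROLE_VEHICLE]
    )
    if vehicle.empty:
        raise ScreenError("no vehicle profiles in screen")
    out = []
    for (cmpd, conc), row in profiles[profiles["role"] != ROLE_VEHICLE].iterrows():
        out.append(
            fingerprint(
                row,
                vehicle,
                features=features,
                change_threshold=change_threshold,
                scale_method=scale_method,
                compound=str(cmpd),
                concentration=float(conc),
            )
        )
    return out


def relative_cell_count(
    treated_count: float, vehicle_counts: Iterable[float]
) -> tuple[float, str]:
    """Treated cell count as percent of the vehicle median, with class.

    Classes follow the reporting bands: >= 80% ``normal`` (the 100 +/- 20%
    band), 50-80% ``reduced``, < 50% ``growth_arrest``.
    """
    vehicle_median = float(np.median(np.asarray(list(vehicle_counts), dtype=float)))
    if vehicle_median <= 0:
        raise ScreenError("vehicle median cell count must be positive")
    pct = 100.0 * float(treated_count) / vehicle_median
    if pct >= CELL_COUNT_NORMAL:
        cls = "normal"
    elif pct >= CELL_COUNT_ARREST:
        cls = "reduced"
    else:
        cls = "growth_arrest"
    return pct, cls
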