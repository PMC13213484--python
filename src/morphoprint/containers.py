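"""Core data containers for a cell-painting screen.

A screen is organised as plates -> wells -> imaging sites. The feature
extractor emits one row per (well, site) with a cell count and ~1716
morphological feature values; the plate layout maps wells to compound,
concentration and role (vehicle / treatment / reference).

Well- and compound-level profiles are plain :class:`pandas.DataFrame`
objects: metadata columns (``compound``, ``concentration_uM``, ``role``,
``cell_count``) followed by one column per feature. Helper accessors below
split the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: metadata columns of a well/compound profile frame; everything else is a feature
META_COLS = ("compound", "concentration_uM", "role", "cell_count")

ROLE_VEHICLE = "vehicle"
ROLE_TREATMENT = "treatment"
ROLE_REFERENCE = "reference"

#: canonical compartment partition of the robust feature set, 1-based
#: inclusive positions: cell 1-229, cytoplasm 230-461, nuclei 462-579
CANONICAL_REGIONS: dict[str, tuple[int, int]] = {
    "cell": (1, 229),
    "cytoplasm": (230, 461),
    "nuclei": (462, 579),
}


class ScreenError(ValueError):
    """Raised for malformed screen inputs (layouts, tables, selections)."""


def feature_columns(frame: pd.DataFrame) -> list[str]:
    """Feature columns of a profile frame, in stored order."""
    return [c for c in frame.columns if c not in META_COLS]


def well_names(n_wells: int) -> list[str]:
    """Row-major letter-number well IDs (A01..P24 for a 384-well plate)."""
    n_cols = 24 if n_wells > 96 else 12 if n_wells > 24 else 6
    n_rows = int(np.ceil(n_wells / n_cols))
    if n_rows > 26:
        raise ScreenError(f"cannot lay out {n_wells} wells")
    names = [
        f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)
    ]
    return names[:n_wells]


def region_partition(
    n_features: int, template: Mapping[str, tuple[int, int]] = CANONICAL_REGIONS
) -> dict[str, tuple[int, int]]:
    """Partition ``n_features`` positions into compartment blocks.

    For the canonical 579-feature set this returns the published split
    exactly; for other sizes the blocks are scaled proportionally so that
    region summaries remain meaningful on simulated screens.
    """
    total = max(end for _, end in template.values())
    if n_features == total:
        return dict(template)
    items = list(template.items())
    if n_features < len(items):
        raise ScreenError(
            f"cannot partition {n_features} features into {len(items)} regions"
        )
    sizes = np.array([hi - lo + 1 for _, (lo, hi) in items], dtype=float)
    cum = np.round(np.cumsum(sizes) / sizes.sum() * n_features).astype(int)
    cum[-1] = n_features
    # enforce strictly increasing block ends so every region is non-empty
    for i in range(len(cum) - 2, -1, -1):
        cum[i] = min(cum[i], cum[i + 1] - 1)
    for i in range(1, len(cum)):
        cum[i] = max(cum[i], cum[i - 1] + 1)
    bounds: dict[str, tuple[int, int]] = {}
    start = 1
    for (name, _), end in zip(items, cum):
        bounds[name] = (start, int(end))
        start = int(end) + 1
    return bounds


@dataclass
class FeatureTable:
    """Per-site feature measurements for one plate.

    ``data`` columns: ``well``, ``site``, ``cell_count``, then feature
    columns. Each (well, site) pair must be unique.
    """

    plate_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "site", "cell_count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ScreenError(f"feature table missing columns: {sorted(missing)}")
        if self.data.duplicated(["well", "site"]).any():
            raise ScreenError("duplicate (well, site) rows in feature table")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("well", "site", "cell_count")]

    @property
    def wells(self) -> list[str]:
        return list(pd.unique(self.data["well"]))


@dataclass
class PlateLayout:
    """Well annotations for one plate: compound, concentration, role."""

    plate_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "compound", "concentration_uM", "role"}
        missing = required - set(self.data.columns)
        if missing:
            raise ScreenError(f"plate layout missing columns: {sorted(missing)}")
        if not (self.data["role"] == ROLE_VEHICLE).any():
            raise ScreenError(f"plate {self.plate_id!r} has no vehicle wells")
        if self.data["well"].duplicated().any():
            raise ScreenError("duplicate wells in plate layout")

    def vehicle_wells(self) -> list[str]:
        return list(self.data.loc[self.data["role"] == ROLE_VEHICLE, "well"])


@dataclass
class Fingerprint:
    """Phenotypic profile of one compound at one concentration.

    ``z`` holds the robust Z-scores over the selected feature set;
    ``induction`` is the percentage of features significantly changed
    versus vehicle; ``relative_cell_count`` is the treated median cell
    count as a percentage of the vehicle median. ``regions`` maps each
    compartment to its 1-based inclusive position range within ``z``.
    """

    compound: str
    concentration: float
    z: pd.Series
    induction: float
    relative_cell_count: float | None = None
    cell_count_class: str | None = None
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z.to_numpy(dtype=float))):
            raise ScreenError("fingerprint z-scores must be finite")
        if not 0.0 <= self.induction <= 100.0:
            raise ScreenError("induction must lie in [0, 100]")
        if self.regions:
            covered: list[int] = []
            for lo, hi in self.regions.values():
                covered.extend(range(lo, hi + 1))
            if sorted(covered) != list(range(1, len(self.z) + 1)):
                raise ScreenError("regions must partition the feature positions")

    @property
    def label(self) -> str:
        return f"{self.compound}@{self.concentration:g}"

    def region_values(self, region: str) -> pd.Series:
        lo, hi = self.regions[region]
        return self.z.iloc[lo - 1 : hi]


def profile_labels(profiles: Sequence[Fingerprint]) -> list[str]:
    return [fp.label for fp in profiles]
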