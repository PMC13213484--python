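"""End-to-end orchestration: simulate -> select -> fingerprint -> metrics.

`run_screen` chains the full analysis on a simulated screen and returns
every intermediate product; the CLI's ``run-all`` command is a thin
wrapper that writes these to disk. Robust-feature selection uses the
first two replicate plates as the two biological repeats of the
reference plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .containers import Fingerprint, ScreenError
from .metrics import cross_biosimilarity, is_active
from .profiles import (
    aggregate_replicates,
    aggregate_sites,
    aggregate_vehicle_wells,
    fingerprint_screen,
)
from .robust import FeatureSelection, apply_selection, select_robust_features
from .simulate import (
    CompoundSpec,
    PhenotypeSignature,
    SimulationConfig,
    simulate_screen,
)
from .subprofile import match_clusters, synthetic_cluster_library


@dataclass
class ScreenResult:
    """Everything computed for one screen."""

    config: SimulationConfig
    well_profiles: list[pd.DataFrame]
    compound_profiles: pd.DataFrame
    selection: FeatureSelection
    fingerprints: list[Fingerprint]
    activity: pd.DataFrame
    cross_biosim: pd.DataFrame | None
    cluster_report: pd.DataFrame | None = None
    ground_truth: Any = None


def run_screen(
    config: SimulationConfig,
    min_similarity: float = 0.8,
    change_threshold: float = 3.0,
    scale_method: str = "mad",
    cross_min_induction: float = 30.0,
    match_library: bool = False,
    assign_threshold: float = 85.0,
) -> ScreenResult:
    """Simulate a screen and run the full analysis chain on it."""
    tables, layouts, truth = simulate_screen(config)
    well_profiles = [aggregate_sites(t, l) for t, l in zip(tables, layouts)]

    if len(well_profiles) >= 2:
        selection = select_robust_features(
            well_profiles[0], well_profiles[1], min_similarity=min_similarity
        )
    else:
        selection = select_robust_features(
            well_profiles[0], well_profiles[0], min_similarity=min_similarity
        )
    if len(selection) == 0:
        raise ScreenError("no robust features survived selection")

    compound_profiles = aggregate_replicates(well_profiles)
    vehicle_profiles = aggregate_vehicle_wells(well_profiles)
    restricted = apply_selection(compound_profiles, selection)
    restricted_vehicle = apply_selection(vehicle_profiles, selection)
    fingerprints = fingerprint_screen(
        restricted,
        vehicle_profiles=restricted_vehicle,
        change_threshold=change_threshold,
        scale_method=scale_method,
    )

    activity = pd.DataFrame(
        {
            "compound": [fp.compound for fp in fingerprints],
            "concentration_uM": [fp.concentration for fp in fingerprints],
            "induction": [fp.induction for fp in fingerprints],
            "active": [is_active(fp.induction) for fp in fingerprints],
            "relative_cell_count": [fp.relative_cell_count for fp in fingerprints],
            "cell_count_class": [fp.cell_count_class for fp in fingerprints],
        }
    )

    try:
        cross = cross_biosimilarity(fingerprints, min_induction=cross_min_induction)
    except ScreenError:
        cross = None

    report = None
    if match_library:
        library = synthetic_cluster_library(
            list(fingerprints[0].z.index) if fingerprints else [],
            seed=config.seed,
        )
        frames = []
        for fp in fingerprints:
            r = match_clusters(fp, library, assign_threshold=assign_threshold)
            r.insert(0, "fingerprint", fp.label)
            frames.append(r.reset_index())
        report = pd.concat(frames, ignore_index=True) if frames else None

    return ScreenResult(
        config=config,
        well_profiles=well_profiles,
        compound_profiles=compound_profiles,
        selection=selection,
        fingerprints=fingerprints,
        activity=activity,
        cross_biosim=cross,
        cluster_report=report,
        ground_truth=truth,
    )


# -- structured-text config --------------------------------------------------

def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    signatures = [
        PhenotypeSignature(
            name=s["name"],
            affected_features=np.asarray(s["affected_features"], dtype=int),
            effect_sizes=np.asarray(s["effect_sizes"], dtype=float),
            concentration_scaling={
                float(k): float(v) for k, v in s.get("concentration_scaling", {}).items()
            },
        )
        for s in d.pop("signatures", [])
    ]
    compounds = d.pop("compounds", None)
    if compounds is not None:
        compounds = [CompoundSpec(**c) for c in compounds]
    return SimulationConfig(signatures=signatures, compounds=compounds, **d)


def load_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_resolved_config(config: SimulationConfig, path: str) -> None:
    """Write the fully resolved config next to the outputs (reproducibility)."""
    d = {
        k: v
        for k, v in vars(config).items()
        if k not in ("signatures", "compounds")
    }
    d["signatures"] = [
        {
            "name": s.name,
            "affected_features": [int(i) for i in s.affected_features],
            "effect_sizes": [float(e) for e in s.effect_sizes],
            "concentration_scaling": {
                float(k): float(v) for k, v in s.concentration_scaling.items()
            },
        }
        for s in config.signatures
    ]
    if config.compounds is not None:
        d["compounds"] = [vars(c) for c in config.compounds]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def write_screen_outputs(result: ScreenResult, outdir: str) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_selection(result.selection, out / "feature_selection.csv")
    mio.write_fingerprints(result.fingerprints, out / "fingerprints.csv")
    result.activity.to_csv(out / "activity.csv", index=False, float_format="%.6g")
    if result.cross_biosim is not None:
        mio.write_matrix(result.cross_biosim, out / "cross_biosimilarity.csv")
    if result.cluster_report is not None:
        result.cluster_report.to_csv(
            out / "cluster_match.csv", index=False, float_format="%.6g"
        )
    dump_resolved_config(result.config, str(out / "resolved_config.yaml"))
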