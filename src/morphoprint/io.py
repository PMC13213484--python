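"""Delimited-text I/O for every artifact of the pipeline.

All files are plain CSV with a header row; sidecar metadata (region
partitions, cluster library manifests, run configs) is YAML. Formats:

- feature table:  ``plate,well,site,cell_count,<feature...>``
- plate layout:   ``plate,well,compound,concentration_uM,role``
- fingerprints:   one row per (compound, concentration): metadata columns
  then the selected features; regions in a ``.regions.yaml`` sidecar
- feature selection: ``feature_index,feature_name,similarity,selected``
- cluster library: a directory with ``library.yaml`` plus one member
  z-table and dominant-feature list per cluster
- qPCR table:     ``sample,group,gene,replicate,ct``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import Fingerprint, FeatureTable, PlateLayout, ScreenError
from .robust import FeatureSelection
from .subprofile import Cluster, ClusterLibrary


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message formatting
        raise ScreenError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenError(f"{path}: line 1: missing columns {missing}")
    return df


# -- feature tables / layouts -------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.insert(0, "plate", table.plate_id)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[FeatureTable]:
    """Read per-site feature tables; one FeatureTable per plate in the file."""
    df = _read_csv(path, ["plate", "well", "site", "cell_count"])
    return [
        FeatureTable(plate_id=str(pid), data=sub.drop(columns="plate").reset_index(drop=True))
        for pid, sub in df.groupby("plate", sort=True)
    ]


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    df = layout.data.copy()
    df.insert(0, "plate", layout.plate_id)
    df.to_csv(path, index=False)


def read_layout(path: str | Path) -> list[PlateLayout]:
    df = _read_csv(path, ["plate", "well", "compound", "concentration_uM", "role"])
    return [
        PlateLayout(plate_id=str(pid), data=sub.drop(columns="plate").reset_index(drop=True))
        for pid, sub in df.groupby("plate", sort=True)
    ]


# -- fingerprints -------------------------------------------------------------

def write_fingerprints(fps: Sequence[Fingerprint], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for fp in fps:
        row = {
            "compound": fp.compound,
            "concentration_uM": fp.concentration,
            "induction": fp.induction,
            "relative_cell_count": fp.relative_cell_count,
            "cell_count_class": fp.cell_count_class,
        }
        row.update(fp.z.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if fps and fps[0].regions:
        sidecar = path.with_suffix(path.suffix + ".regions.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {k: [int(a), int(b)] for k, (a, b) in fps[0].regions.items()}, fh
            )


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    path = Path(path)
    meta_cols = [
        "compound",
        "concentration_uM",
        "induction",
        "relative_cell_count",
        "cell_count_class",
    ]
    df = _read_csv(path, ["compound", "concentration_uM", "induction"])
    feats = [c for c in df.columns if c not in meta_cols]
    regions: dict[str, tuple[int, int]] = {}
    sidecar = path.with_suffix(path.suffix + ".regions.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            regions = {k: tuple(v) for k, v in yaml.safe_load(fh).items()}
    out = []
    for _, row in df.iterrows():
        rcc = row.get("relative_cell_count")
        out.append(
            Fingerprint(
                compound=str(row["compound"]),
                concentration=float(row["concentration_uM"]),
                z=pd.Series(row[feats].to_numpy(dtype=float), index=feats),
                induction=float(row["induction"]),
                relative_cell_count=None if pd.isna(rcc) else float(rcc),
                cell_count_class=(
                    None if pd.isna(row.get("cell_count_class")) else str(row["cell_count_class"])
                ),
                regions=regions,
            )
        )
    return out


# -- feature selection --------------------------------------------------------

def write_selection(selection: FeatureSelection, path: str | Path) -> None:
    selection.to_frame().to_csv(path, index=False)


def read_selection(path: str | Path, threshold: float | None = None) -> FeatureSelection:
    df = _read_csv(path, ["feature_index", "feature_name", "similarity", "selected"])
    sim = pd.Series(
        df["similarity"].to_numpy(dtype=float), index=df["feature_name"], name="similarity"
    )
    feats = list(df.loc[df["selected"].astype(bool), "feature_name"])
    return FeatureSelection(
        features=feats,
        similarity=sim,
        threshold=float(threshold) if threshold is not None else float("nan"),
    )


# -- cluster libraries --------------------------------------------------------

def write_cluster_library(library: ClusterLibrary, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"metadata": library.metadata, "clusters": {}}
    for name, cluster in library.clusters.items():
        member_file = f"{name}.members.csv"
        cluster.members.rename_axis("member").to_csv(directory / member_file)
        manifest["clusters"][name] = {
            "members": member_file,
            "dominant_features": list(cluster.dominant_features),
        }
    with open(directory / "library.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_cluster_library(directory: str | Path) -> ClusterLibrary:
    directory = Path(directory)
    manifest_path = directory / "library.yaml"
    if not manifest_path.exists():
        raise ScreenError(f"{manifest_path}: not found")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    clusters = {}
    for name, entry in manifest["clusters"].items():
        members = pd.read_csv(directory / entry["members"], index_col="member")
        clusters[name] = Cluster(
            name=name,
            members=members,
            dominant_features=list(entry["dominant_features"]),
        )
    return ClusterLibrary(clusters=clusters, metadata=manifest.get("metadata", {}))


# -- qPCR ---------------------------------------------------------------------

def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["sample", "group", "gene", "replicate", "ct"])
    if not np.isfinite(df["ct"].to_numpy(dtype=float)).all():
        raise ScreenError(f"{path}: non-finite Ct values")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("label").to_csv(path, float_format="%.6g")
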