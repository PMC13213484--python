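"""Subprofile analysis: matching fingerprints to bioactivity clusters.

An established bioactivity cluster is a set of reference-compound
fingerprints sharing a mode of action, together with the subset of
"dominant" features that characterise the cluster. The cluster
subprofile is the elementwise median of the member z-vectors restricted
to the dominant features; a test fingerprint is compared to each cluster
by biosimilarity on that restricted feature set. A similarity above 85%
to a cluster (or to a single reference compound) supports assigning the
mode of action; a compound below threshold everywhere is the "unknown
cluster" outcome.

The dominant-feature sets are library content consumed as data — how
they were derived for the published clusters is outside this package.
A synthetic 13-cluster library generator is provided for testing; it
carries the canonical cluster names but makes no claim of equivalence
to the real clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Fingerprint, ScreenError, region_partition
from .metrics import biosimilarity

#: the 13 established bioactivity cluster names used by the synthetic library
CLUSTER_NAMES = (
    "AKT_PI3K_MTOR",
    "aurora_kinase",
    "BET",
    "DNA_synthesis",
    "HDAC",
    "HSP90",
    "LCH",
    "mitochondrial_stress",
    "Na_K_ATPase",
    "protein_synthesis",
    "pyrimidine_synthesis",
    "tubulin",
    "uncoupler",
)


@dataclass
class Cluster:
    """One bioactivity cluster: member z-profiles plus dominant features."""

    name: str
    members: pd.DataFrame  # rows = member compounds, columns = features (z)
    dominant_features: list[str]

    def __post_init__(self) -> None:
        if self.members.empty:
            raise ScreenError(f"cluster {self.name!r} has no members")
        unknown = [f for f in self.dominant_features if f not in self.members.columns]
        if unknown:
            raise ScreenError(
                f"cluster {self.name!r}: dominant features not in member profiles: "
                f"{unknown[:5]}"
            )


@dataclass
class ClusterLibrary:
    """Named bioactivity clusters sharing one selected feature space."""

    clusters: dict[str, Cluster]
    metadata: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        first = next(iter(self.clusters.values()))
        return list(first.members.columns)


def build_cluster_subprofile(
    members: pd.DataFrame | Sequence[Fingerprint],
    dominant_features: Sequence[str],
) -> pd.Series:
    """Elementwise median of member z-vectors on the dominant features."""
    if len(dominant_features) == 0:
        raise ScreenError("dominant feature set must be non-empty")
    if not isinstance(members, pd.DataFrame):
        members = pd.DataFrame([fp.z for fp in members])
    if members.empty:
        raise ScreenError("cluster must have >= 1 member")
    return members[list(dominant_features)].median(axis=0)


def match_clusters(
    fp: Fingerprint,
    library: ClusterLibrary,
    assign_threshold: float = 85.0,
) -> pd.DataFrame:
    """Compare one fingerprint against every cluster of a library.

    For each cluster, the fingerprint is restricted to the cluster's
    dominant features and compared by biosimilarity to the cluster
    subprofile; the assignment flag is true when similarity strictly
    exceeds ``assign_threshold`` percent. The nearest reference compound
    by full-profile biosimilarity is reported alongside.

    Returns a frame indexed by cluster name with columns
    ``subprofile_biosimilarity``, ``assigned``, ``best_reference`` and
    ``best_reference_biosimilarity``.
    """
    lib_features = library.feature_names
    missing = [f for f in lib_features if f not in fp.z.index]
    if missing:
        raise ScreenError(
            f"fingerprint lacks library features (feature-space mismatch): "
            f"{missing[:5]}"
        )
    rows = {}
    for name, cluster in library.clusters.items():
        sub = build_cluster_subprofile(cluster.members, cluster.dominant_features)
        sim = biosimilarity(
            fp.z[cluster.dominant_features].to_numpy(), sub.to_numpy()
        )
        best_ref, best_sim = None, -np.inf
        for ref_name, ref_z in cluster.members.iterrows():
            s = biosimilarity(fp.z[lib_features].to_numpy(), ref_z.to_numpy())
            if np.isfinite(s) and s > best_sim:
                best_ref, best_sim = ref_name, s
        rows[name] = {
            "subprofile_biosimilarity": sim,
            "assigned": bool(np.isfinite(sim) and sim > assign_threshold),
            "best_reference": best_ref,
            "best_reference_biosimilarity": (
                best_sim if np.isfinite(best_sim) else np.nan
            ),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cluster"
    return out


def synthetic_cluster_library(
    feature_names: Sequence[str],
    n_members: int = 3,
    n_dominant: int = 40,
    signal_sd: float = 5.0,
    member_noise_sd: float = 0.5,
    seed: int = 0,
) -> ClusterLibrary:
    """Synthetic 13-cluster library for testing the matcher.

    Each cluster receives a random archetype z-profile concentrated on its
    own dominant-feature block; members are noisy copies of the archetype.
    Purely synthetic — named after the canonical clusters only so that
    reports read naturally.
    """
    feature_names = list(feature_names)
    rng = np.random.default_rng(seed)
    nf = len(feature_names)
    if n_dominant * len(CLUSTER_NAMES) > nf:
        n_dominant = max(3, nf // len(CLUSTER_NAMES))
    clusters = {}
    for k, name in enumerate(CLUSTER_NAMES):
        dom_idx = np.arange(k * n_dominant, (k + 1) * n_dominant) % nf
        archetype = np.zeros(nf)
        archetype[dom_idx] = rng.normal(0.0, signal_sd, size=len(dom_idx))
        members = {}
        for m in range(1, n_members + 1):
            noise = rng.normal(0.0, member_noise_sd, size=nf)
            members[f"{name}_ref{m}"] = archetype + noise
        clusters[name] = Cluster(
            name=name,
            members=pd.DataFrame.from_dict(
                members, orient="index", columns=feature_names
            ),
            dominant_features=[feature_names[i] for i in dom_idx],
        )
    return ClusterLibrary(
        clusters=clusters,
        metadata={"synthetic": True, "seed": seed, "n_dominant": n_dominant},
    )


def noisy_copy_fingerprint(
    library: ClusterLibrary,
    cluster_name: str,
    noise_ratio: float = 0.2,
    seed: int = 0,
    induction: float = 50.0,
) -> Fingerprint:
    """Fingerprint built as a noisy copy of one cluster's subprofile.

    Noise SD is ``noise_ratio`` times the subprofile's own SD. Used to
    validate that the matcher recovers a programmed cluster membership.
    """
    rng = np.random.default_rng(seed)
    cluster = library.clusters[cluster_name]
    feats = library.feature_names
    full = cluster.members.median(axis=0)
    sd = float(full.std(ddof=0))
    z = full + rng.normal(0.0, noise_ratio * sd, size=len(feats))
    return Fingerprint(
        compound=f"{cluster_name}_probe",
        concentration=10.0,
        z=pd.Series(z.to_numpy(), index=feats),
        induction=induction,
        regions=region_partition(len(feats)),
    )
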