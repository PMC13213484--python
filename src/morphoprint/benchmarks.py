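"""Repeated-seed validation studies of the pipeline on simulated screens.

Each study simulates screens with known ground truth, runs the full
analysis chain, and reports how well the pipeline recovers what was
programmed: null calibration of the induction statistic, recovery of
shared/disjoint phenotype signatures, robust-feature retention rates,
cluster-assignment reliability, and qPCR fold-change recovery. Screen
geometries are scaled below the full 384-well x 1716-feature assay where
many seeds are replicated; the defaults below are the package's standard
study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import biosimilarity, is_active
from .pipeline import run_screen
from .qpcr import relative_expression, summarize_expression
from .robust import select_robust_features
from .simulate import (
    CompoundSpec,
    PhenotypeSignature,
    SimulationConfig,
    simulate_qpcr,
    simulate_replicate_pair,
)
from .subprofile import (
    CLUSTER_NAMES,
    match_clusters,
    noisy_copy_fingerprint,
    synthetic_cluster_library,
)


def _subseed(base_seed: int, i: int) -> int:
    return (base_seed * 10_007 + i) % (2**31 - 1)


def null_calibration_study(
    n_screens: int = 50,
    base_seed: int = 0,
    n_features: int = 300,
    n_wells: int = 384,
) -> pd.DataFrame:
    """Screens with zero programmed effects: induction should stay null.

    Returns one row per screen with the median and maximum compound
    induction and whether any compound crossed the 5% activity call.
    """
    rows = []
    for i in range(n_screens):
        cfg = SimulationConfig(
            n_features=n_features,
            n_wells=n_wells,
            seed=_subseed(base_seed, i),
        )
        res = run_screen(cfg)
        inductions = np.array(
            [fp.induction for fp in res.fingerprints if fp.compound.startswith("inert")]
        )
        rows.append(
            {
                "seed": cfg.seed,
                "median_induction": float(np.median(inductions)),
                "max_induction": float(inductions.max()),
                "any_active": bool(np.any([is_active(v) for v in inductions])),
            }
        )
    return pd.DataFrame(rows)


def signature_recovery_study(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_features: int = 250,
    n_wells: int = 192,
    effect_size: float = 5.0,
    affected_fraction: float = 0.2,
) -> pd.DataFrame:
    """Compounds sharing a signature vs compounds with disjoint signatures.

    Two compounds carry signature A (``effect_size`` per-site robust-SD
    units on ``affected_fraction`` of the features) and one carries a
    disjoint signature B. Per seed, reports the within-pair and
    between-pair biosimilarity and the induction of an A compound (the
    pipeline's estimate of the programmed active-feature fraction).
    """
    naff = round(affected_fraction * n_features)
    rows = []
    for i in range(n_seeds):
        sig_a = PhenotypeSignature(
            "sigA", np.arange(naff), np.full(naff, effect_size)
        )
        sig_b = PhenotypeSignature(
            "sigB", np.arange(naff, 2 * naff), np.full(naff, effect_size)
        )
        cfg = SimulationConfig(
            n_features=n_features,
            n_wells=n_wells,
            seed=_subseed(base_seed, i),
            signatures=[sig_a, sig_b],
            compounds=[
                CompoundSpec("A1", "sigA"),
                CompoundSpec("A2", "sigA"),
                CompoundSpec("B1", "sigB"),
            ],
        )
        res = run_screen(cfg)
        fp = {f.compound: f for f in res.fingerprints}
        rows.append(
            {
                "seed": cfg.seed,
                "shared_biosimilarity": biosimilarity(fp["A1"].z, fp["A2"].z),
                "disjoint_biosimilarity": biosimilarity(fp["A1"].z, fp["B1"].z),
                "estimated_active_fraction": fp["A1"].induction,
            }
        )
    return pd.DataFrame(rows)


def robust_selection_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_wells: int = 96,
    n_features_per_class: int = 100,
    high_correlation: float = 0.95,
    low_correlation: float = 0.0,
    min_similarity: float = 0.8,
) -> pd.DataFrame:
    """Retention rates for features with programmed replicate correlation.

    Half of the features are given a high across-repeat correlation (they
    should be retained at the 0.8 threshold) and half are uncorrelated
    (they should be rejected). Returns per-seed retention rates per class.
    """
    rho = np.concatenate(
        [
            np.full(n_features_per_class, high_correlation),
            np.full(n_features_per_class, low_correlation),
        ]
    )
    rows = []
    for i in range(n_seeds):
        r1, r2 = simulate_replicate_pair(n_wells, rho, seed=_subseed(base_seed, i))
        sel = select_robust_features(r1, r2, min_similarity=min_similarity)
        chosen = set(sel.features)
        hi = [f"f_{j + 1:04d}" for j in range(n_features_per_class)]
        lo = [f"f_{j + 1:04d}" for j in range(n_features_per_class, 2 * n_features_per_class)]
        rows.append(
            {
                "seed": _subseed(base_seed, i),
                "high_retained": np.mean([f in chosen for f in hi]),
                "low_retained": np.mean([f in chosen for f in lo]),
            }
        )
    return pd.DataFrame(rows)


def cluster_assignment_study(
    n_trials: int = 100,
    base_seed: int = 0,
    n_features: int = 579,
    noise_ratio: float = 0.2,
    assign_threshold: float = 85.0,
) -> pd.DataFrame:
    """Matcher reliability on noisy copies and on orthogonal fingerprints.

    Per trial: one fingerprint built as a noisy copy of a randomly chosen
    cluster subprofile (should be assigned to that cluster) and one
    orthogonal random fingerprint (should never be assigned anywhere).
    """
    feature_names = [f"f_{i + 1:04d}" for i in range(n_features)]
    rows = []
    for i in range(n_trials):
        seed = _subseed(base_seed, i)
        # distinct sub-streams: a probe drawn from the same PCG stream as
        # the library would alias the archetype draws, not be independent
        lib_seed, pick_seed, copy_seed, ortho_seed = (
            np.random.SeedSequence(seed).generate_state(4) >> 1
        )
        rng = np.random.default_rng(int(pick_seed))
        library = synthetic_cluster_library(feature_names, seed=int(lib_seed))
        target = CLUSTER_NAMES[int(rng.integers(len(CLUSTER_NAMES)))]
        probe = noisy_copy_fingerprint(
            library, target, noise_ratio=noise_ratio, seed=int(copy_seed)
        )
        report = match_clusters(probe, library, assign_threshold=assign_threshold)
        correct = bool(report.loc[target, "assigned"])

        from .containers import Fingerprint, region_partition

        ortho = Fingerprint(
            compound="random_probe",
            concentration=10.0,
            z=pd.Series(
                np.random.default_rng(int(ortho_seed)).standard_normal(n_features),
                index=feature_names,
            ),
            induction=50.0,
            regions=region_partition(n_features),
        )
        ortho_report = match_clusters(ortho, library, assign_threshold=assign_threshold)
        rows.append(
            {
                "seed": seed,
                "target_cluster": target,
                "assigned_to_target": correct,
                "orthogonal_assigned_anywhere": bool(ortho_report["assigned"].any()),
                "target_similarity": float(
                    report.loc[target, "subprofile_biosimilarity"]
                ),
            }
        )
    return pd.DataFrame(rows)


def qpcr_recovery_study(
    n_seeds: int = 200,
    base_seed: int = 0,
    true_fold_change: float = 0.75,
    ct_noise_sd: float = 0.2,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Geometric-mean fold-change estimates over many noisy experiments.

    Under Gaussian Ct noise the per-sample fold change is lognormal with
    median equal to the true fold change, so the geometric mean is the
    natural unbiased summary (in log space).
    """
    rows = []
    for i in range(n_seeds):
        seed = _subseed(base_seed, i)
        table = simulate_qpcr(
            n_replicates=n_replicates,
            true_fold_change=true_fold_change,
            ct_noise_sd=ct_noise_sd,
            seed=seed,
        )
        rel = relative_expression(table, "NRAS", ["GAPDH", "ACTB"])
        treat = rel.loc[rel["group"] == "treatment", "fold_change"]
        s = summarize_expression(treat)
        rows.append({"seed": seed, "geometric_mean": s.geometric_mean})
    return pd.DataFrame(rows)
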