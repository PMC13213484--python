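"""Synthetic cell-painting screens and qPCR tables with known ground truth.

No raw image data is publicly deposited for screens of this kind, so
every downstream stage is exercised on simulated plates instead. The
generator emulates the assay design: a 384-well plate, 9 imaging sites
per well, triplicate plates with cyclically shifted compound layouts (to
reduce plate effects), DMSO vehicle wells defining the null phenotype,
and 1716 features with heterogeneous per-feature location and scale.

The null model is independent Gaussian per feature with feature-specific
location and scale drawn once per screen; plate effects are additive per
(plate, feature). A treated well is shifted on its signature's affected
features by ``effect_size x concentration multiplier`` in units of the
feature's base scale. Cell counts are simulated as a separate
non-negative integer column with an optional per-compound toxicity
effect. A configurable fraction of features can be made irreproducible
(per-plate, per-well noise dominating any compound effect) to exercise
robust-feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ROLE_REFERENCE,
    ROLE_TREATMENT,
    ROLE_VEHICLE,
    FeatureTable,
    PlateLayout,
    ScreenError,
    well_names,
)

VEHICLE_COMPOUND = "DMSO"


@dataclass
class PhenotypeSignature:
    """Ground-truth phenotype: which features a mechanism perturbs, and how much.

    ``effect_sizes`` are expressed in units of each feature's base scale
    (the SD of the per-site noise when ``site_noise_sd`` is 1).
    ``concentration_scaling`` maps concentration (uM) to a multiplier;
    unlisted concentrations default to 1.0.
    """

    name: str
    affected_features: np.ndarray  # 0-based feature positions
    effect_sizes: np.ndarray
    concentration_scaling: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affected_features = np.asarray(self.affected_features, dtype=int)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.affected_features.shape != self.effect_sizes.shape:
            raise ScreenError("affected_features and effect_sizes must align")
        if not np.all(np.isfinite(self.effect_sizes)):
            raise ScreenError("effect sizes must be finite")

    def multiplier(self, concentration: float) -> float:
        return float(self.concentration_scaling.get(concentration, 1.0))


@dataclass
class CompoundSpec:
    """One simulated compound: signature (or inert), concentration, toxicity."""

    name: str
    signature: str | None = None
    concentration_uM: float = 10.0
    toxicity: float = 0.0  # fractional reduction of cell count, 0..1
    role: str = ROLE_TREATMENT


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated screen.

    Defaults mirror the real assay: 384 wells, 9 sites per well, triplicate
    plates with shifted layouts, 1716 extracted features.
    """

    n_features: int = 1716
    n_wells: int = 384
    sites_per_well: int = 9
    n_replicate_plates: int = 3
    vehicle_fraction: float = 0.1
    signatures: list[PhenotypeSignature] = field(default_factory=list)
    compounds: list[CompoundSpec] | None = None
    site_noise_sd: float = 1.0
    plate_offset_sd: float = 0.5
    n_reference_compounds: int = 32
    reference_coverage: float = 0.4  # fraction of features each reference perturbs
    reference_effect_sd: float = 6.0  # in base-scale units
    irreproducible_fraction: float = 0.0
    irreproducible_noise_sd: float = 5.0
    layout_shift: bool = True
    base_cell_count: float = 180.0  # cells per imaging site
    cell_count_noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ScreenError("n_features must be >= 1")
        if self.sites_per_well < 1:
            raise ScreenError("sites_per_well must be >= 1")
        if not 0.0 < self.vehicle_fraction < 1.0:
            raise ScreenError("vehicle_fraction must be in (0, 1)")
        for sd in (
            self.site_noise_sd,
            self.plate_offset_sd,
            self.irreproducible_noise_sd,
            self.cell_count_noise_sd,
        ):
            if sd < 0:
                raise ScreenError("noise SDs must be >= 0")
        for sig in self.signatures:
            if sig.affected_features.size and (
                sig.affected_features.min() < 0
                or sig.affected_features.max() >= self.n_features
            ):
                raise ScreenError(
                    f"signature {sig.name!r} references feature index outside "
                    f"0..{self.n_features - 1}"
                )


@dataclass
class GroundTruth:
    """Programmed truth of a simulated screen, for validating the pipeline."""

    compound_signature: dict[str, str | None]
    active_fraction: dict[str, float]  # programmed fraction of affected features
    expected_effect: dict[str, np.ndarray]  # per-feature shift in base-scale units
    feature_class: pd.Series  # "stable" or "noisy" per feature
    feature_scale: np.ndarray
    feature_location: np.ndarray


def _default_compounds(config: SimulationConfig) -> list[CompoundSpec]:
    out = [
        CompoundSpec(name=f"{sig.name}_cmpd", signature=sig.name)
        for sig in config.signatures
    ]
    return out


def _build_layouts(
    config: SimulationConfig, compounds: list[CompoundSpec]
) -> list[PlateLayout]:
    wells = well_names(config.n_wells)
    n_vehicle = max(1, round(config.vehicle_fraction * config.n_wells))
    # spread vehicle wells evenly across the plate
    vehicle_pos = set(np.linspace(0, config.n_wells - 1, n_vehicle, dtype=int))
    treatment_wells = [w for i, w in enumerate(wells) if i not in vehicle_pos]

    specs = list(compounds)
    for i in range(len(specs), len(treatment_wells)):
        specs.append(CompoundSpec(name=f"inert_{i + 1:03d}"))
    specs = specs[: len(treatment_wells)]

    layouts = []
    for p in range(config.n_replicate_plates):
        shift = p if config.layout_shift else 0
        rotated = specs[shift:] + specs[:shift]  # cyclic permutation of positions
        rows = []
        it = iter(rotated)
        for i, w in enumerate(wells):
            if i in vehicle_pos:
                rows.append((w, VEHICLE_COMPOUND, 0.0, ROLE_VEHICLE))
            else:
                c = next(it)
                rows.append((w, c.name, c.concentration_uM, c.role))
        layouts.append(
            PlateLayout(
                plate_id=f"plate_{p + 1}",
                data=pd.DataFrame(
                    rows, columns=["well", "compound", "concentration_uM", "role"]
                ),
            )
        )
    return layouts


def simulate_screen(
    config: SimulationConfig,
) -> tuple[list[FeatureTable], list[PlateLayout], GroundTruth]:
    """Generate one replicated screen: feature tables, layouts, ground truth.

    Deterministic for a fixed ``config.seed``. Vehicle wells are drawn from
    the null model only; treated wells add their signature's effects times
    the concentration multiplier.
    """
    rng = np.random.default_rng(config.seed)
    nf = config.n_features
    feature_names = [f"f_{i + 1:04d}" for i in range(nf)]

    # per-feature baseline drawn once per screen: heterogeneous loc/scale
    loc = rng.normal(10.0, 3.0, size=nf)
    scale = rng.lognormal(mean=0.0, sigma=0.4, size=nf)

    n_noisy = round(config.irreproducible_fraction * nf)
    noisy_idx = rng.choice(nf, size=n_noisy, replace=False) if n_noisy else np.array([], int)
    feature_class = pd.Series("stable", index=feature_names, name="class")
    feature_class.iloc[noisy_idx] = "noisy"

    # reference compounds: strong, diverse phenotypes drawn once per screen.
    # they give per-feature well profiles genuine structure, which is what
    # replicate-based robust-feature selection measures.
    ref_signatures = []
    ref_compounds = []
    n_ref_features = max(1, round(config.reference_coverage * nf))
    for i in range(config.n_reference_compounds):
        idx = np.sort(rng.choice(nf, size=n_ref_features, replace=False))
        eff = rng.normal(0.0, config.reference_effect_sd, size=n_ref_features)
        sig = PhenotypeSignature(f"_reference_{i + 1}", idx, eff)
        ref_signatures.append(sig)
        ref_compounds.append(
            CompoundSpec(name=f"REF_{i + 1:02d}", signature=sig.name, role=ROLE_REFERENCE)
        )

    compounds = (
        list(config.compounds) if config.compounds is not None else _default_compounds(config)
    )
    compounds = ref_compounds + compounds
    layouts = _build_layouts(config, compounds)
    sig_by_name = {s.name: s for s in [*config.signatures, *ref_signatures]}
    spec_by_name = {c.name: c for c in compounds}
    for c in compounds:
        if c.signature is not None and c.signature not in sig_by_name:
            raise ScreenError(f"compound {c.name!r} references unknown signature")

    tables = []
    for layout in layouts:
        plate_offset = rng.normal(0.0, config.plate_offset_sd, size=nf) * scale
        frames = []
        for _, wrow in layout.data.iterrows():
            well, cmpd = wrow["well"], wrow["compound"]
            mean = loc + plate_offset
            toxicity = 0.0
            if wrow["role"] != ROLE_VEHICLE:
                cspec = spec_by_name.get(cmpd)
                if cspec is not None:
                    toxicity = cspec.toxicity
                    if cspec.signature is not None:
                        sig = sig_by_name[cspec.signature]
                        delta = np.zeros(nf)
                        delta[sig.affected_features] = (
                            sig.effect_sizes * sig.multiplier(wrow["concentration_uM"])
                        )
                        mean = mean + delta * scale
            if n_noisy:
                # irreproducible features: a fresh large offset per (plate, well)
                mean = mean.copy()
                mean[noisy_idx] += rng.normal(
                    0.0, config.irreproducible_noise_sd, size=n_noisy
                ) * scale[noisy_idx]
            sites = rng.normal(
                mean,
                config.site_noise_sd * scale,
                size=(config.sites_per_well, nf),
            )
            counts = np.clip(
                np.round(
                    rng.normal(
                        config.base_cell_count * (1.0 - toxicity),
                        config.cell_count_noise_sd,
                        size=config.sites_per_well,
                    )
                ),
                0,
                None,
            ).astype(int)
            df = pd.DataFrame(sites, columns=feature_names)
            df.insert(0, "cell_count", counts)
            df.insert(0, "site", np.arange(1, config.sites_per_well + 1))
            df.insert(0, "well", well)
            frames.append(df)
        tables.append(
            FeatureTable(
                plate_id=layout.plate_id,
                data=pd.concat(frames, ignore_index=True),
            )
        )

    expected_effect = {}
    active_fraction = {}
    compound_signature = {}
    for c in compounds:
        delta = np.zeros(nf)
        if c.signature is not None:
            sig = sig_by_name[c.signature]
            delta[sig.affected_features] = sig.effect_sizes * sig.multiplier(
                c.concentration_uM
            )
        expected_effect[c.name] = delta
        active_fraction[c.name] = float(np.count_nonzero(delta)) / nf
        compound_signature[c.name] = c.signature
    # inert filler compounds added by the layout builder
    for layout in layouts:
        for cmpd in layout.data.loc[
            layout.data["role"] != ROLE_VEHICLE, "compound"
        ]:
            if cmpd not in expected_effect:
                expected_effect[cmpd] = np.zeros(nf)
                active_fraction[cmpd] = 0.0
                compound_signature[cmpd] = None

    truth = GroundTruth(
        compound_signature=compound_signature,
        active_fraction=active_fraction,
        expected_effect=expected_effect,
        feature_class=feature_class,
        feature_scale=scale,
        feature_location=loc,
    )
    return tables, layouts, truth


def simulate_replicate_pair(
    n_wells: int,
    correlations: Sequence[float] | np.ndarray,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two matched well-profile frames with programmed per-feature correlation.

    Feature ``i`` of the two repeats is drawn from a bivariate normal with
    correlation ``correlations[i]`` across wells — a direct harness for
    robust-feature selection. Returns frames indexed by well with a
    ``compound`` column (one mock compound per well) and one column per
    feature.
    """
    rho = np.asarray(correlations, dtype=float)
    if np.any((rho < -1) | (rho > 1)):
        raise ScreenError("correlations must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    nf = rho.size
    z1 = rng.standard_normal((n_wells, nf))
    z2 = rng.standard_normal((n_wells, nf))
    x1 = z1
    x2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    names = [f"f_{i + 1:04d}" for i in range(nf)]
    if n_wells <= 384:
        wells = well_names(n_wells)
    else:
        wells = [f"W{i + 1:05d}" for i in range(n_wells)]
    cols = {"compound": [f"ref_{i + 1:03d}" for i in range(n_wells)]}
    a = pd.DataFrame(x1, index=wells, columns=names)
    b = pd.DataFrame(x2, index=wells, columns=names)
    a = pd.concat([pd.DataFrame(cols, index=wells), a], axis=1)
    b = pd.concat([pd.DataFrame(cols, index=wells), b], axis=1)
    a.index.name = b.index.name = "well"
    return a, b


def simulate_qpcr(
    n_replicates: int,
    true_fold_change: float,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "NRAS",
    reference_genes: Sequence[str] = ("GAPDH", "ACTB"),
    base_ct: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Ct table for a treatment/control qPCR experiment with known fold change.

    The treatment group's target Ct is shifted by ``-log2(true_fold_change)``
    cycles relative to control so that the expected ``2^-ddCt`` equals
    ``true_fold_change`` exactly; Gaussian noise of SD ``ct_noise_sd``
    cycles is added to every measurement. Columns:
    ``sample, group, gene, replicate, ct``.
    """
    if n_replicates < 1:
        raise ScreenError("n_replicates must be >= 1")
    if true_fold_change <= 0:
        raise ScreenError("fold change must be positive")
    if ct_noise_sd < 0:
        raise ScreenError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = {target_gene: 24.0}
    for i, g in enumerate(reference_genes):
        base[g] = 20.0 - i
    if base_ct:
        base.update(base_ct)

    shift = -np.log2(true_fold_change)
    rows = []
    for group in ("control", "treatment"):
        for r in range(1, n_replicates + 1):
            sample = f"{group}_{r}"
            for gene in (target_gene, *reference_genes):
                ct = base[gene]
                if group == "treatment" and gene == target_gene:
                    ct += shift
                ct += rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append((sample, group, gene, r, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
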