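"""Relative gene expression from qPCR Ct values (2^-ddCt method).

For each sample, dCt is the target gene's Ct minus the arithmetic mean
Ct of the reference genes (e.g. GAPDH and beta-actin). ddCt subtracts
the mean dCt of the vehicle-control group, and relative expression is
2^-ddCt, so one extra cycle of target amplification halves the reported
expression. Group summaries use the geometric mean and geometric SD,
matching the lognormal character of 2^-ddCt; hypothesis testing runs on
the dCt values (one-way ANOVA followed by Dunnett's many-to-one
comparison against the control group).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ScreenError

QPCR_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


def delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
) -> pd.DataFrame:
    """dCt per (sample, replicate): target Ct minus mean reference-gene Ct.

    Returns a frame with columns ``sample``, ``group``, ``replicate``,
    ``delta_ct``. Every sample/replicate must carry the target and all
    reference genes.
    """
    missing_cols = set(QPCR_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ScreenError(f"qPCR table missing columns: {sorted(missing_cols)}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise ScreenError("Ct values must be finite")

    wide = table.pivot_table(
        index=["sample", "group", "replicate"], columns="gene", values="ct"
    )
    needed = [target_gene, *reference_genes]
    absent = [g for g in needed if g not in wide.columns]
    if absent:
        raise ScreenError(f"genes absent from table: {absent}")
    if wide[needed].isna().any().any():
        bad = wide[wide[needed].isna().any(axis=1)].index.tolist()
        raise ScreenError(f"missing gene measurements for: {bad[:5]}")

    dct = wide[target_gene] - wide[list(reference_genes)].mean(axis=1)
    out = dct.rename("delta_ct").reset_index()
    return out


def rel_expression(delta_ct_value: float, delta_ct_control: float) -> float:
    """Fold change 2^-(dCt_treatment - dCt_control)."""
    ddct = float(delta_ct_value) - float(delta_ct_control)
    return float(2.0 ** (-ddct))


def relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-sample relative expression normalised to the control-group mean dCt.

    The ddCt reference is the arithmetic mean dCt over all control-group
    measurements, so the control group's fold changes center on 1 (their
    geometric mean is exactly 1 when noise-free).
    """
    dct = delta_ct(table, target_gene, reference_genes)
    control = dct.loc[dct["group"] == control_group, "delta_ct"]
    if control.empty:
        raise ScreenError(f"no rows in control group {control_group!r}")
    ref = float(control.mean())
    dct["fold_change"] = [rel_expression(v, ref) for v in dct["delta_ct"]]
    return dct


@dataclass
class ExpressionSummary:
    geometric_mean: float
    geometric_sd: float
    n: int


def summarize_expression(fold_changes: Sequence[float]) -> ExpressionSummary:
    """Geometric mean and geometric SD of positive fold changes.

    gmean = exp(mean(log x)); gSD = exp(sd(log x), ddof=1). With a single
    value the geometric SD is reported as 1.
    """
    x = np.asarray(list(fold_changes), dtype=float)
    if x.size == 0:
        raise ScreenError("no fold changes to summarize")
    if np.any(x <= 0):
        raise ScreenError("fold changes must be positive")
    logs = np.log(x)
    gsd = float(np.exp(np.std(logs, ddof=1))) if x.size > 1 else 1.0
    return ExpressionSummary(
        geometric_mean=float(np.exp(logs.mean())), geometric_sd=gsd, n=int(x.size)
    )


def test_vs_control(
    delta_ct_by_group: dict[str, Sequence[float]] | pd.DataFrame,
    control_group: str = "control",
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett many-to-one tests on dCt values.

    ``delta_ct_by_group`` maps group name to its dCt replicates (or is the
    frame returned by :func:`delta_ct`). Each treatment group is compared
    against the control with Dunnett's procedure (multivariate-t adjusted
    two-sided p-values). Returns one row per treatment group with columns
    ``anova_F``, ``anova_p``, ``p_adjusted``.
    """
    if isinstance(delta_ct_by_group, pd.DataFrame):
        groups = {
            g: sub["delta_ct"].to_numpy(dtype=float)
            for g, sub in delta_ct_by_group.groupby("group")
        }
    else:
        groups = {g: np.asarray(v, dtype=float) for g, v in delta_ct_by_group.items()}
    if control_group not in groups:
        raise ScreenError(f"control group {control_group!r} not present")
    if len(groups) < 2:
        raise ScreenError("need >= 2 groups including control")
    for g, v in groups.items():
        if v.size < 2:
            raise ScreenError(f"group {g!r} has fewer than 2 replicates")

    control = groups[control_group]
    treatment_names = [g for g in groups if g != control_group]
    samples = [groups[g] for g in treatment_names]

    pooled_var = float(np.sum([np.var(v, ddof=1) * (v.size - 1) for v in groups.values()]))
    if pooled_var == 0.0:
        # degenerate: no within-group variability at all
        means_equal = len({float(np.mean(v)) for v in groups.values()}) == 1
        stat = np.zeros(len(samples)) if means_equal else np.full(len(samples), np.inf)
        pval = np.ones(len(samples)) if means_equal else np.zeros(len(samples))
        f_stat, f_p = (0.0, 1.0) if means_equal else (np.inf, 0.0)
    else:
        f_stat, f_p = stats.f_oneway(control, *samples)
        dunnett = stats.dunnett(*samples, control=control, alternative="two-sided")
        stat, pval = dunnett.statistic, dunnett.pvalue
    out = pd.DataFrame(
        {
            "group": treatment_names,
            "mean_delta_ct": [float(np.mean(groups[g])) for g in treatment_names],
            "statistic": stat,
            "p_adjusted": pval,
        }
    ).set_index("group")
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    out["anova_F"] = float(f_stat)
    out["anova_p"] = float(f_p)
    return out
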