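"""Relative expression fold changes for the inflammation gene panel.

Quantification uses the standard 2^-ddCt method with amplification
efficiency fixed at 2: per sample dCt = Ct_target - Ct_reference (the
reference gene is rps11), ddCt = dCt_sample - mean(dCt_baseline), and
FC = 2^-ddCt, so the mean dCt of the baseline group maps to FC = 1.
Group-level fold change is the mean over biological replicate pools.
Treatment groups are tested against the reference group (spike + DMSO)
with the two-sided Mann-Whitney U test and the usual significance stars.

Note on gene naming: the inflammasome target amplified by the ptgs2a
primer pair is referred to as "ptg" in places; both names denote the
same assay here.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .screen_stats import mann_whitney_u

DEFAULT_REFERENCE_GENE = "rps11"


def significance_stars(p: float) -> str:
    """Stars at p < 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _delta_ct(
    table: pd.DataFrame, target_gene: str, reference_gene: str
) -> pd.DataFrame:
    """Per-sample dCt = Ct_target - Ct_reference for one target gene.

    Samples without a reference-gene Ct are dropped with a warning.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    ref = (
        table[table["gene"] == reference_gene]
        .set_index("sample_id")["ct"]
        .rename("ct_ref")
    )
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    tgt = table[table["gene"] == target_gene].copy()
    if tgt.empty:
        raise ValueError(f"target gene {target_gene!r} absent from table")
    tgt = tgt.join(ref, on="sample_id")
    dropped = tgt["ct_ref"].isna()
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} sample(s) lack a {reference_gene} Ct and "
            "were dropped",
            stacklevel=3,
        )
        tgt = tgt[~dropped]
    tgt["delta_ct"] = tgt["ct"] - tgt["ct_ref"]
    return tgt[["sample_id", "group", "gene", "ct", "ct_ref", "delta_ct"]]


def fold_change_ddct(
    table: pd.DataFrame,
    target_gene: str,
    baseline_group: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> pd.DataFrame:
    """Per-sample ddCt fold changes of one gene relative to a baseline group.

    Returns one row per sample with delta_ct, ddct and fold_change
    columns; every group in the table is included (the baseline group's
    mean dCt gives FC = 1 by construction).
    """
    per_sample = _delta_ct(table, target_gene, reference_gene)
    base = per_sample[per_sample["group"] == baseline_group]["delta_ct"]
    if base.empty:
        raise ValueError(f"baseline group {baseline_group!r} has no samples")
    base_mean = float(base.mean())
    out = per_sample.copy()
    out["ddct"] = out["delta_ct"] - base_mean
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def fold_change_table(
    table: pd.DataFrame,
    baseline_group: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold changes for every target gene in the panel.

    Returns ``(per_sample, per_group)``: per-sample rows for all genes,
    and group means/SDs (the quantity shown in fold-change heatmaps).
    """
    if genes is None:
        genes = [g for g in table["gene"].unique() if g != reference_gene]
    per_sample = pd.concat(
        [
            fold_change_ddct(table, g, baseline_group, reference_gene)
            for g in genes
        ],
        ignore_index=True,
    )
    per_group = (
        per_sample.groupby(["gene", "group"], sort=True)["fold_change"]
        .agg(mean_fold_change="mean", sd_fold_change="std", n="count")
        .reset_index()
    )
    return per_sample, per_group


def compare_vs_reference(
    per_sample: pd.DataFrame,
    reference_group: str,
) -> pd.DataFrame:
    """Mann-Whitney U of every (gene, group) against the reference group.

    Returns (gene, group, p_value, stars); empty groups are skipped with
    a warning rather than failing the panel.
    """
    rows = []
    for gene, sub in per_sample.groupby("gene", sort=True):
        ref = sub[sub["group"] == reference_group]["fold_change"].to_numpy()
        if ref.size == 0:
            warnings.warn(
                f"reference group {reference_group!r} empty for gene {gene!r}; "
                "skipped",
                stacklevel=2,
            )
            continue
        for group, gsub in sub.groupby("group", sort=True):
            if group == reference_group:
                continue
            vals = gsub["fold_change"].to_numpy()
            if vals.size == 0:
                warnings.warn(f"group {group!r} empty for gene {gene!r}; skipped",
                              stacklevel=2)
                continue
            _, p = mann_whitney_u(vals, ref)
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "p_value": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def analyze_qpcr(
    table: pd.DataFrame,
    baseline_group: str,
    reference_group: str | None = None,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> pd.DataFrame:
    """Full qPCR stage: fold changes plus significance vs the reference.

    ``baseline_group`` anchors FC = 1 (vehicle without spike);
    ``reference_group`` (default: the baseline) is the comparator for
    the Mann-Whitney tests (spike + vehicle in the inflammation panel).
    """
    per_sample, per_group = fold_change_table(table, baseline_group, reference_gene)
    tests = compare_vs_reference(
        per_sample, reference_group if reference_group is not None else baseline_group
    )
    out = per_group.merge(tests, on=["gene", "group"], how="left")
    out["stars"] = out["stars"].fillna("")
    return out
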