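"""Statistics layer of the phenotypic screen.

Each treatment group is compared to the vehicle (DMSO) controls of the
plates on which it was tested, using the two-sided Mann-Whitney U test.
Three complementary quantities describe an effect:

* Hedges g — standardized mean difference with the small-sample bias
  correction J = 1 - 3/(4N - 9);
* relative median difference — (median_t - median_c)/median_c;
* fold change / percentage effect — FC = median_t/median_c and
  (FC - 1) x 100.

Plate-to-plate drift is removed by median-shift batch correction: each
experiment's values are shifted by (global control median - that
experiment's control median), which leaves within-plate differences
untouched and aligns every control median with the global one.

The composite effect score for a (treatment, metric) pair is

    score = -log10(p) * |g| * |relΔ| * sign(relΔ)

reported only when p < alpha (otherwise masked — the grey cells of the
screen heatmap); positive scores mean an increase over control, negative
a decrease.  Compounds are then allocated to ΔHeart, ΔBody length,
ΔVasculature, ΔActivity or "No significant effect" by the family of
their largest-magnitude significant score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_CONTROL_LABEL = "DMSO"
DEFAULT_ALPHA = 0.05

#: Largest per-group size for which the exact (permutation) Mann-Whitney
#: null distribution is used on tie-free data.
EXACT_MWU_MAX_N = 8

GROUP_HEART = "ΔHeart"
GROUP_BODY = "ΔBody length"
GROUP_VASC = "ΔVasculature"
GROUP_ACTIVITY = "ΔActivity"
GROUP_NONE = "No significant effect"

#: metric -> phenotype family used for compound grouping
METRIC_FAMILIES: dict[str, str] = {
    "heart_rate_bpm": GROUP_HEART,
    "ejection_fraction_pct": GROUP_HEART,
    "body_length_um": GROUP_BODY,
    "isv_count": GROUP_VASC,
    "isv_median_area_px2": GROUP_VASC,
    "velocity_dark": GROUP_ACTIVITY,
    "velocity_bright": GROUP_ACTIVITY,
    "accommodation_activity": GROUP_ACTIVITY,
    "log_bright_dark_ratio": GROUP_ACTIVITY,
}

#: tie-break order between families with equal |score|
FAMILY_ORDER = (GROUP_HEART, GROUP_BODY, GROUP_VASC, GROUP_ACTIVITY)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, used for every reported percentage."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EffectResult:
    """One (treatment, metric) comparison against its plate controls."""

    treatment: str
    metric: str
    n_treat: int
    n_ctrl: int
    u_stat: float
    p_value: float
    hedges_g: float
    rel_median_diff: float
    fold_change: float
    percent_effect: float
    score: float | None          # None = masked (not significant)
    significant: bool

    def as_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "metric": self.metric,
            "n_treat": self.n_treat,
            "n_ctrl": self.n_ctrl,
            "u_stat": self.u_stat,
            "p_value": self.p_value,
            "hedges_g": self.hedges_g,
            "rel_median_diff": self.rel_median_diff,
            "fold_change": self.fold_change,
            "percent_effect": self.percent_effect,
            "score": self.score,
            "significant": self.significant,
        }


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    For tie-free samples with at most 8 per group the exact permutation
    null distribution of U is used; larger or tied samples use the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and max(a.size, b.size) <= EXACT_MWU_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hedges_g(a: Sequence[float], b: Sequence[float]) -> float:
    """Bias-corrected standardized mean difference (a minus b).

    g = (mean_a - mean_b) / s_pooled * J with J = 1 - 3/(4N - 9);
    antisymmetric under group swap.  A zero pooled spread is an error —
    the caller flags the metric instead of reporting infinity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na + nb < 3 or min(na, nb) < 1:
        raise ValueError("need at least 3 values overall and both groups non-empty")
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled spread: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float((a.mean() - b.mean()) / pooled * j)


def relative_median_diff(treat: Sequence[float], ctrl: Sequence[float]) -> float:
    """(median_t - median_c) / median_c; zero control median is an error."""
    mt = float(np.median(np.asarray(treat, dtype=float)))
    mc = float(np.median(np.asarray(ctrl, dtype=float)))
    if mc == 0:
        raise ValueError("control median is zero: relative difference undefined")
    return (mt - mc) / mc


def percentage_effect(treat: Sequence[float], ctrl: Sequence[float]) -> tuple[float, float]:
    """Fold change of medians and the derived percentage effect.

    FC = median_t / median_c, percent effect = (FC - 1) x 100.
    """
    mt = float(np.median(np.asarray(treat, dtype=float)))
    mc = float(np.median(np.asarray(ctrl, dtype=float)))
    if mc == 0:
        raise ValueError("control median is zero: fold change undefined")
    fc = mt / mc
    return fc, (fc - 1.0) * 100.0


def effect_score(
    p: float,
    g: float,
    rel_diff: float,
    alpha: float | None = None,
) -> float | None:
    """Composite score -log10(p) * |g| * |relΔ| * sign(relΔ).

    With ``alpha`` given, the score is masked (None) when p >= alpha,
    matching the grey no-significance cells of the screen heatmap.  The
    sign follows the direction of the median shift so that increases are
    positive and decreases negative regardless of the signs of g and of
    the raw triple product.
    """
    if not (0 < p <= 1):
        raise ValueError("p-value must lie in (0, 1]")
    if alpha is not None and p >= alpha:
        return None
    magnitude = -math.log10(p) * abs(g) * abs(rel_diff)
    return math.copysign(magnitude, rel_diff) if rel_diff != 0 else 0.0


# --------------------------------------------------------------------------
# batch correction
# --------------------------------------------------------------------------


def batch_correct(
    records: pd.DataFrame,
    metric: str,
    control_label: str = DEFAULT_CONTROL_LABEL,
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    """Median-shift batch correction of one metric across experiments.

    shift(experiment) = global control median - experiment control
    median; every measurement of the experiment is moved by its shift.
    After correction every experiment's control median equals the global
    control median, and all within-experiment differences are unchanged.
    """
    if metric not in records.columns:
        raise ValueError(f"metric {metric!r} not in records")
    ctrl = records[records["treatment"] == control_label]
    global_median = ctrl[metric].median()
    if not np.isfinite(global_median):
        raise ValueError(f"no finite control values for metric {metric!r}")
    out = records.copy()
    out[metric] = out[metric].astype(float)
    for exp, sub in records.groupby(experiment_col):
        exp_ctrl = sub[sub["treatment"] == control_label][metric]
        exp_median = exp_ctrl.median()
        if not np.isfinite(exp_median):
            raise ValueError(
                f"experiment {exp!r} has no finite control values for {metric!r}"
            )
        shift = global_median - exp_median
        out.loc[sub.index, metric] = sub[metric] + shift
    return out


def batch_correct_all(
    records: pd.DataFrame,
    metrics: Iterable[str],
    control_label: str = DEFAULT_CONTROL_LABEL,
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    out = records
    for m in metrics:
        out = batch_correct(out, m, control_label, experiment_col)
    return out


# --------------------------------------------------------------------------
# screen-level comparisons
# --------------------------------------------------------------------------


def _metric_values(records: pd.DataFrame, metric: str) -> pd.Series:
    alive = records["alive"] if "alive" in records.columns else True
    vals = records.loc[alive, metric] if not isinstance(alive, bool) else records[metric]
    return vals.dropna()


def compare_treatment(
    records: pd.DataFrame,
    treatment: str,
    metric: str,
    control_label: str = DEFAULT_CONTROL_LABEL,
    alpha: float = DEFAULT_ALPHA,
) -> EffectResult:
    """One treatment vs the controls of the plates it was tested on.

    Dead larvae never enter metric comparisons; degenerate inputs (zero
    spread, zero control median) are flagged as NaN effect fields rather
    than aborting the whole screen.
    """
    sub_t = records[records["treatment"] == treatment]
    plates = sub_t["experiment_id"].unique()
    sub_c = records[
        (records["treatment"] == control_label)
        & (records["experiment_id"].isin(plates))
    ]
    t = _metric_values(sub_t, metric).to_numpy()
    c = _metric_values(sub_c, metric).to_numpy()
    if t.size == 0 or c.size == 0:
        raise ValueError(
            f"no usable values for {treatment!r}/{metric!r} (treat {t.size}, "
            f"ctrl {c.size})"
        )
    u, p = mann_whitney_u(t, c)
    try:
        g = hedges_g(t, c)
    except ValueError:
        g = math.nan
    try:
        rel = relative_median_diff(t, c)
        fc, pct = percentage_effect(t, c)
    except ValueError:
        rel = fc = pct = math.nan
    significant = p < alpha
    if math.isnan(g) or math.isnan(rel):
        score = None
    else:
        score = effect_score(p, g, rel, alpha=alpha)
    return EffectResult(
        treatment=treatment,
        metric=metric,
        n_treat=int(t.size),
        n_ctrl=int(c.size),
        u_stat=u,
        p_value=p,
        hedges_g=g,
        rel_median_diff=rel,
        fold_change=fc,
        percent_effect=pct,
        score=score,
        significant=significant,
    )


def run_screen(
    records: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    batch_corrected: bool = True,
    control_label: str = DEFAULT_CONTROL_LABEL,
) -> pd.DataFrame:
    """All (treatment, metric) comparisons; one tidy row each."""
    if metrics is None:
        metrics = [m for m in METRIC_FAMILIES if m in records.columns]
    data = (
        batch_correct_all(records, metrics, control_label)
        if batch_corrected
        else records
    )
    treatments = [
        tr for tr in data["treatment"].unique() if tr != control_label
    ]
    rows = []
    for tr in sorted(treatments):
        for metric in metrics:
            rows.append(
                compare_treatment(data, tr, metric, control_label, alpha).as_dict()
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mortality, effusion, grouping and the screen summary
# --------------------------------------------------------------------------


def mortality_and_effusion_rates(
    records: pd.DataFrame,
    control_label: str | None = None,
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Per-treatment mortality rate and pericardial-effusion percentage.

    The mortality rate is the mean over replicates of the percentage of
    larvae dead before imaging; the effusion percentage is computed
    among surviving larvae scored for effusion.
    """
    rows = []
    for treatment, sub in records.groupby("treatment", sort=True):
        if control_label is not None and treatment == control_label:
            continue
        per_rep = [
            (~rep["alive"]).mean() * 100.0
            for _, rep in sub.groupby(replicate_col)
        ]
        mr = float(np.mean(per_rep)) if per_rep else 0.0
        scored = sub[sub["alive"] & sub["effusion"].notna()]
        eff = float(scored["effusion"].mean() * 100.0) if len(scored) else math.nan
        rows.append(
            {
                "treatment": treatment,
                "mortality_rate_pct": mr,
                "effusion_pct": eff,
                "n_total": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def classify_compound(results: pd.DataFrame) -> str:
    """Allocate a compound to a phenotype group from its effect results.

    "No significant effect" iff no metric is significant; otherwise the
    family of the metric with the largest |score|, ties broken by the
    fixed family order Heart, Body length, Vasculature, Activity.
    """
    sig = results[results["significant"] & results["score"].notna()]
    if len(sig) == 0:
        return GROUP_NONE
    best: tuple[float, int] | None = None
    best_family = GROUP_NONE
    for _, row in sig.iterrows():
        family = METRIC_FAMILIES.get(row["metric"])
        if family is None:
            continue
        key = (abs(row["score"]), -FAMILY_ORDER.index(family))
        if best is None or key > best:
            best = key
            best_family = family
    return best_family


def classify_all(results: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {
            tr: classify_compound(sub)
            for tr, sub in results.groupby("treatment", sort=True)
        },
        name="group",
    )


def summarize_screen(
    results: pd.DataFrame,
    records: pd.DataFrame,
    mr_threshold: float = 10.0,
    effusion_threshold: float = 25.0,
    control_label: str = DEFAULT_CONTROL_LABEL,
) -> dict:
    """Screen-level counts and percentages of compounds per criterion.

    Percentages are count/total x 100 rounded half-up to one decimal.
    """
    rates = mortality_and_effusion_rates(records, control_label=control_label)
    compounds = sorted(results["treatment"].unique())
    total = len(compounds)

    def pct(count: int) -> float:
        return round_half_up(100.0 * count / total, 1) if total else 0.0

    mr_flagged = rates[rates["mortality_rate_pct"] > mr_threshold]["treatment"]
    eff_flagged = rates[rates["effusion_pct"] >= effusion_threshold]["treatment"]
    summary: dict = {
        "n_compounds": total,
        "mortality_over_threshold": {
            "threshold_pct": mr_threshold,
            "count": int(len(mr_flagged)),
            "pct_of_compounds": pct(len(mr_flagged)),
            "treatments": sorted(mr_flagged),
        },
        "effusion_over_threshold": {
            "threshold_pct": effusion_threshold,
            "count": int(len(eff_flagged)),
            "pct_of_compounds": pct(len(eff_flagged)),
            "treatments": sorted(eff_flagged),
        },
        "significant_per_metric": {},
        "significant_per_family": {},
        "groups": classify_all(results).to_dict(),
    }
    for metric, sub in results.groupby("metric"):
        n = int(sub["significant"].sum())
        summary["significant_per_metric"][metric] = {
            "count": n,
            "pct_of_compounds": pct(n),
        }
    for family in FAMILY_ORDER:
        metrics = [m for m, f in METRIC_FAMILIES.items() if f == family]
        sub = results[results["metric"].isin(metrics)]
        n = int(sub[sub["significant"]]["treatment"].nunique())
        summary["significant_per_family"][family] = {
            "count": n,
            "pct_of_compounds": pct(n),
        }
    return summary
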