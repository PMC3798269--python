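"""Gene-set definitions and cross-condition enrichment statistics.

Summaries follow the boxplot convention: median, quartiles by linear
interpolation, whiskers at the most extreme datum within 1.5x IQR of the
quartiles.  Set comparisons use a Welch two-sample two-sided t-test by
default; p-values below 2.2e-16 are displayed as "< 2.2e-16" (the exact
value is kept internally).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSet, ValidationError

P_DISPLAY_FLOOR = 2.2e-16


def fold_change(log2_enrichment: float) -> float:
    """Linear fold enrichment from a log2 enrichment value (2**x)."""
    return float(2.0 ** log2_enrichment)


def format_p(p: float) -> str:
    if np.isnan(p):
        return "."
    return "< 2.2e-16" if p < P_DISPLAY_FLOOR else f"{p:.3g}"


@dataclass
class SetSummary:
    """Boxplot-style summary of one gene set's TSS enrichment distribution."""

    name: str
    condition: str
    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    median_fold: float
    p_vs_reference: float  # NaN when undefined
    reference: str = ""

    @property
    def p_display(self) -> str:
        return format_p(self.p_vs_reference)


@dataclass
class ConditionRatio:
    """Linear fold ratio of set medians between two conditions, with the
    per-gene log2 differences that rank genes by ratio."""

    name: str
    condition_a: str
    condition_b: str
    ratio: float
    log2_diff: pd.Series  # per-gene score_A - score_B, jointly defined genes only


def define_set_by_fold_change(
    folds: Mapping[str, float] | pd.Series,
    threshold: float = 4.0,
    direction: str = "down",
    name: str | None = None,
) -> GeneSet:
    """Genes changed more than ``threshold``-fold: linear fold-change
    < 1/threshold (down) or > threshold (up)."""
    if threshold <= 1:
        raise ValidationError("fold-change threshold must exceed 1")
    if direction not in ("down", "up"):
        raise ValidationError(f"direction must be 'down' or 'up', got {direction!r}")
    s = pd.Series(folds, dtype=float)
    if (s <= 0).any():
        raise ValidationError("fold-changes must be positive")
    hit = s < 1.0 / threshold if direction == "down" else s > threshold
    return GeneSet.from_ids(name or f"{direction}_{threshold:g}x", s.index[hit])


def define_ubiquitous_set(
    presence: pd.DataFrame, required: int | None = None, name: str = "ubiquitous"
) -> GeneSet:
    """Genes with a present call in every tissue column (or in at least
    ``required`` tissues when given)."""
    if presence.shape[1] < 1:
        raise ValidationError("need at least one tissue column")
    calls = presence.astype(bool).sum(axis=1)
    need = presence.shape[1] if required is None else required
    return GeneSet.from_ids(name, presence.index[calls >= need])


def _set_scores(table: pd.DataFrame, gene_set: GeneSet, condition: str) -> np.ndarray:
    if condition not in table.columns:
        raise ValidationError(f"condition {condition!r} not in table")
    idx = table.index.intersection(sorted(gene_set.members))
    vals = table.loc[idx, condition].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def summarize_set(
    table: pd.DataFrame,
    gene_set: GeneSet,
    condition: str,
    reference: GeneSet | None = None,
    equal_var: bool = False,
) -> SetSummary:
    """Summarize a set's enrichment distribution in one condition and test
    it against a reference set's scores (Welch t-test unless equal_var)."""
    vals = _set_scores(table, gene_set, condition)
    if len(vals) == 0:
        raise ValidationError(f"no defined scores for set {gene_set.name!r} in {condition!r}")
    q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    in_fence = vals[(vals >= q25 - 1.5 * iqr) & (vals <= q75 + 1.5 * iqr)]
    p = np.nan
    ref_name = ""
    if reference is not None:
        ref_name = reference.name
        ref_vals = _set_scores(table, reference, condition)
        if len(vals) >= 2 and len(ref_vals) >= 2:
            if vals.std() == 0 and ref_vals.std() == 0:
                # degenerate: no within-group variance, decide by the means
                p = 1.0 if vals.mean() == ref_vals.mean() else 0.0
            else:
                p = stats.ttest_ind(vals, ref_vals, equal_var=equal_var).pvalue
    return SetSummary(
        name=gene_set.name,
        condition=condition,
        n=len(vals),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(in_fence.min()),
        whisker_high=float(in_fence.max()),
        median_fold=fold_change(med),
        p_vs_reference=float(p) if p == p else np.nan,
        reference=ref_name,
    )


def summaries_to_frame(summaries: list[SetSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "set": s.name, "condition": s.condition, "n": s.n,
                "median": s.median, "q25": s.q25, "q75": s.q75,
                "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                "median_fold": s.median_fold, "reference": s.reference,
                "p_vs_reference": s.p_display,
            }
        )
    return pd.DataFrame(rows)


def condition_ratio(
    table: pd.DataFrame, gene_set: GeneSet, condition_a: str, condition_b: str
) -> ConditionRatio:
    """Fold ratio of set medians between two conditions,
    ``2**(median_A - median_B)`` over genes defined in both."""
    for c in (condition_a, condition_b):
        if c not in table.columns:
            raise ValidationError(f"condition {c!r} not in table")
    idx = table.index.intersection(sorted(gene_set.members))
    sub = table.loc[idx, [condition_a, condition_b]].dropna()
    if len(sub) == 0:
        raise ValidationError("no genes defined in both conditions")
    med_a = float(sub[condition_a].median())
    med_b = float(sub[condition_b].median())
    diff = (sub[condition_a] - sub[condition_b]).rename("log2_diff")
    return ConditionRatio(
        gene_set.name, condition_a, condition_b, fold_change(med_a - med_b), diff
    )


def top_k_by_ratio(ratio: ConditionRatio, k: int = 200) -> GeneSet:
    """The k genes with the largest per-gene log2 condition differences;
    ties broken by gene_id for determinism."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(ratio.log2_diff):
        raise ValidationError(f"k={k} exceeds {len(ratio.log2_diff)} defined genes")
    order = ratio.log2_diff.sort_index().sort_values(ascending=False, kind="mergesort")
    return GeneSet.from_ids(
        f"top{k}_{ratio.condition_a}_vs_{ratio.condition_b}", order.index[:k]
    )


def score_correlation(x: pd.Series, y: pd.Series) -> float:
    """Pearson correlation over jointly defined genes (NaN if degenerate)."""
    joint = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joint) < 3:
        raise ValidationError("need at least 3 jointly defined genes")
    a = joint.iloc[:, 0].to_numpy(dtype=float)
    b = joint.iloc[:, 1].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
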