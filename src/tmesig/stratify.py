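"""Immune-content normalization, median stratification, and rank tests.

Samples are first split at the median neutrophil score, then each
neutrophil stratum is split at its own median TGFβ score, giving four
groups.  Before stratification the expression matrix can be normalized
for total immune content by residualizing every gene against PTPRC
(CD45), the pan-leukocyte marker: this removes the linear dependence of
each gene on overall infiltration while preserving each gene's mean, so
downstream scores remain in log2 expression units.  All group
comparisons use the Mann–Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_LABELS = ("Ne_hi/TGFB_hi", "Ne_hi/TGFB_lo", "Ne_lo/TGFB_hi", "Ne_lo/TGFB_lo")


class DegenerateSplitError(ValueError):
    """Raised when all scores are identical and no median split exists."""


@dataclass
class GroupComparison:
    """One pairwise Mann–Whitney comparison.

    ``u`` is the rank-sum statistic counting pairs where the first
    group's value exceeds the second's (ties counted half).  ``method``
    is ``"exact"`` (full enumeration of rank assignments) or
    ``"normal_approx"`` (tie- and continuity-corrected).
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u: float
    p_value: float
    method: str


@dataclass
class StratifiedGroups:
    """Four-group assignment from sequential median splits."""

    labels: pd.Series  # sample_id -> group label
    neutrophil_median: float
    tgfb_medians: dict[str, float]  # per neutrophil stratum (or {"global": m})

    def counts(self) -> dict[str, int]:
        return {g: int((self.labels == g).sum()) for g in GROUP_LABELS}

    def samples(self, label: str) -> list:
        return self.labels.index[self.labels == label].tolist()


def normalize_immune_content(
    matrix: pd.DataFrame, ptprc_symbol: str = "PTPRC"
) -> pd.DataFrame:
    """Residualize every gene against PTPRC, preserving gene means.

    Each gene row (except PTPRC itself) is replaced by the residual of
    its OLS regression on the centered PTPRC row, plus the gene's
    original mean; the PTPRC row becomes its own mean.  Output rows are
    therefore uncorrelated with PTPRC and the transform is idempotent.
    A constant PTPRC row carries no immune-content information, so the
    matrix is returned unchanged with a warning.
    """
    ptprc_symbol = ptprc_symbol.strip().upper()
    if ptprc_symbol not in matrix.index:
        raise KeyError(f"{ptprc_symbol!r} not present in expression matrix")
    p = matrix.loc[ptprc_symbol].to_numpy(dtype=float)
    if np.ptp(p) == 0:  # constant row; centering alone is not ulp-safe
        warnings.warn(
            f"{ptprc_symbol} is constant across samples; "
            "immune-content normalization is the identity",
            stacklevel=2,
        )
        return matrix.copy()
    p_centered = p - p.mean()
    denom = (p_centered**2).sum()

    values = matrix.to_numpy(dtype=float)
    slopes = values @ p_centered / denom  # per-gene OLS slope on centered PTPRC
    out = values - np.outer(slopes, p_centered)
    result = pd.DataFrame(out, index=matrix.index.copy(), columns=matrix.columns.copy())
    result.loc[ptprc_symbol] = p.mean()
    return result


def median_split(scores: pd.Series) -> tuple[pd.Index, pd.Index, float]:
    """Split samples at the median score (high strictly above the median).

    Samples exactly at the median fall in the low stratum, so the high
    stratum matches the strict "> median" definition.  Identical scores
    admit no split and raise :class:`DegenerateSplitError`.
    """
    if len(scores) == 0:
        raise ValueError("cannot split an empty sample set")
    if scores.nunique() == 1:
        raise DegenerateSplitError("all scores identical; degenerate split")
    median = float(scores.median())
    high = scores.index[scores > median]
    low = scores.index[scores <= median]
    return high, low, median


def double_stratify(
    scores: pd.DataFrame, within_stratum_tgfb: bool = True
) -> StratifiedGroups:
    """Assign each sample to one of four neutrophil × TGFβ groups.

    The first split is at the median neutrophil score over all samples;
    each neutrophil stratum is then split at the median TGFβ score
    computed within that stratum (default) or at the global TGFβ median.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to form four groups")
    ne_high, ne_low, ne_median = median_split(scores["neutrophil"])

    labels = pd.Series(index=scores.index, dtype=object, name="group")
    tgfb_medians: dict[str, float] = {}
    if within_stratum_tgfb:
        strata = {"Ne_hi": ne_high, "Ne_lo": ne_low}
        for stratum, idx in strata.items():
            hi, lo, m = median_split(scores.loc[idx, "tgfb"])
            tgfb_medians[stratum] = m
            labels.loc[hi] = f"{stratum}/TGFB_hi"
            labels.loc[lo] = f"{stratum}/TGFB_lo"
    else:
        hi_all, lo_all, m = median_split(scores["tgfb"])
        tgfb_medians["global"] = m
        labels.loc[ne_high.intersection(hi_all)] = "Ne_hi/TGFB_hi"
        labels.loc[ne_high.intersection(lo_all)] = "Ne_hi/TGFB_lo"
        labels.loc[ne_low.intersection(hi_all)] = "Ne_lo/TGFB_hi"
        labels.loc[ne_low.intersection(lo_all)] = "Ne_lo/TGFB_lo"
    return StratifiedGroups(
        labels=labels, neutrophil_median=ne_median, tgfb_medians=tgfb_medians
    )


def mann_whitney(
    values_a,
    values_b,
    exact_limit: int = 8,
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    The p-value comes from exact enumeration of the U null distribution
    when ``min(n_a, n_b) <= exact_limit`` and the pooled values are
    tie-free, otherwise from the normal approximation with tie and
    continuity correction.  The two-sided p-value is twice the smaller
    tail, capped at 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    use_exact = min(a.size, b.size) <= exact_limit and not ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "normal_approx",
    )


@dataclass
class FourGroupComparison:
    """All pairwise T-cell-score comparisons between the four groups."""

    comparisons: list[GroupComparison]
    medians: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def compare_four_groups(
    tcell_scores: pd.Series,
    groups: StratifiedGroups,
    exact_limit: int = 8,
    adjust: bool = False,
) -> FourGroupComparison:
    """Pairwise Mann–Whitney comparisons of T-cell scores across groups.

    All six pairwise comparisons are run in the fixed label order; empty
    groups are skipped with a warning.  No multiplicity correction is
    applied by default; ``adjust=True`` appends BH-adjusted p-values.
    """
    group_values = {
        g: tcell_scores.loc[tcell_scores.index.intersection(groups.samples(g))]
        for g in GROUP_LABELS
    }
    medians = {
        g: float(v.median()) if len(v) else float("nan")
        for g, v in group_values.items()
    }
    comparisons: list[GroupComparison] = []
    for ga, gb in combinations(GROUP_LABELS, 2):
        if len(group_values[ga]) == 0 or len(group_values[gb]) == 0:
            warnings.warn(f"skipping comparison {ga} vs {gb}: empty group", stacklevel=2)
            continue
        comparisons.append(
            mann_whitney(
                group_values[ga],
                group_values[gb],
                exact_limit=exact_limit,
                group_a=ga,
                group_b=gb,
            )
        )
    result = FourGroupComparison(comparisons=comparisons, medians=medians)
    if adjust and comparisons:
        adj = multipletests([c.p_value for c in comparisons], method="fdr_bh")[1]
        frame = result.to_frame()
        frame["adj_p"] = adj
        result.frame_adjusted = frame  # type: ignore[attr-defined]
    return result


@dataclass
class SubtypeComparison:
    """Pairwise score comparisons and boxplot summaries across subtypes."""

    comparisons: list[GroupComparison]
    summary: pd.DataFrame  # per subtype: n, min, q1, median, q3, max


def compare_across_subtypes(
    scores: pd.DataFrame,
    annotation: pd.Series,
    axis: str = "neutrophil",
    exact_limit: int = 8,
) -> SubtypeComparison:
    """Pairwise Mann–Whitney tests of one axis score between CMS subtypes.

    Subtypes with fewer than two scored samples are excluded with a
    warning; at least two eligible subtypes are required.
    """
    common = scores.index.intersection(annotation.index)
    values = scores.loc[common, axis]
    labels = annotation.loc[common]
    subtype_values: dict[str, pd.Series] = {}
    for subtype in sorted(labels.unique()):
        if subtype == "unlabeled":
            continue
        v = values[labels == subtype]
        if len(v) < 2:
            warnings.warn(
                f"excluding subtype {subtype}: fewer than 2 samples", stacklevel=2
            )
            continue
        subtype_values[subtype] = v
    if len(subtype_values) < 2:
        raise ValueError("need at least two subtypes with >= 2 samples each")

    summary = pd.DataFrame(
        {
            "subtype": list(subtype_values),
            "n": [len(v) for v in subtype_values.values()],
            "min": [float(v.min()) for v in subtype_values.values()],
            "q1": [float(v.quantile(0.25)) for v in subtype_values.values()],
            "median": [float(v.median()) for v in subtype_values.values()],
            "q3": [float(v.quantile(0.75)) for v in subtype_values.values()],
            "max": [float(v.max()) for v in subtype_values.values()],
        }
    )
    comparisons = [
        mann_whitney(
            subtype_values[sa],
            subtype_values[sb],
            exact_limit=exact_limit,
            group_a=sa,
            group_b=sb,
        )
        for sa, sb in combinations(subtype_values, 2)
    ]
    return SubtypeComparison(comparisons=comparisons, summary=summary)
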