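"""Differential presence of cytokines on antibody arrays.

A cytokine is *differentially present* between two co-culture conditions
when its between-condition log2 fold change falls strictly outside the
asymmetric window (fc_down, fc_up) = (−0.4, +0.6).  The fold-change flag
is reported independently of the test: a moderated two-sample t-test
(per-cytokine pooled variances shrunk toward their across-cytokine
median with a fixed prior df) with Benjamini–Hochberg adjustment
quantifies evidence separately.  Rows can be z-scored for heatmap export.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tmesig.io import AnalysisConfig


class ConstantRowError(ValueError):
    """Raised when a row to be z-scored has no variance."""


def _condition_columns(conditions: pd.Series, cond: str) -> list:
    cols = conditions.index[conditions == cond].tolist()
    if not cols:
        raise ValueError(f"no samples labeled with condition {cond!r}")
    return cols


def diff_presence(
    array: pd.DataFrame,
    conditions: pd.Series,
    cond_a: str,
    cond_b: str,
    config: AnalysisConfig | None = None,
    moderation: bool = True,
) -> pd.DataFrame:
    """Flag and test cytokines differing between two conditions.

    Parameters
    ----------
    array:
        Cytokines × samples matrix of log2 intensities.
    conditions:
        Sample → condition label mapping covering the array's columns.
    cond_a, cond_b:
        Conditions to compare; log2FC is mean(cond_a) − mean(cond_b).
    moderation:
        Shrink per-cytokine pooled variances toward their across-cytokine
        median with prior df ``config.prior_df`` (total df = prior +
        residual).  ``False`` uses Welch's t-test instead.

    Returns one row per cytokine with ``log2fc``, ``t``, ``p_value``,
    ``adj_p`` (BH across all cytokines), and ``flagged`` (the fold-change
    window, strict inequalities, independent of the p-value).  With a
    single sample in either condition the fold change and flag are still
    computed but the test columns are NaN, with a warning.
    """
    config = config or AnalysisConfig()
    cols_a = _condition_columns(conditions, cond_a)
    cols_b = _condition_columns(conditions, cond_b)
    A = array[cols_a].to_numpy(dtype=float)
    B = array[cols_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]

    log2fc = A.mean(axis=1) - B.mean(axis=1)
    flagged = (log2fc > config.fc_up) | (log2fc < config.fc_down)
    result = pd.DataFrame(
        {"log2fc": log2fc, "flagged": flagged}, index=array.index.copy()
    )
    result.index.name = "cytokine"

    if na < 2 or nb < 2:
        warnings.warn(
            "a condition has a single sample; fold-change flags computed "
            "but no test performed",
            stacklevel=2,
        )
        result["t"] = np.nan
        result["p_value"] = np.nan
        result["adj_p"] = np.nan
        return result[["log2fc", "t", "p_value", "adj_p", "flagged"]]

    if moderation:
        df_resid = na + nb - 2
        var_a = A.var(axis=1, ddof=1)
        var_b = B.var(axis=1, ddof=1)
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid
        prior_var = float(np.median(pooled))
        d0 = config.prior_df
        shrunk = (d0 * prior_var + df_resid * pooled) / (d0 + df_resid)
        se = np.sqrt(shrunk * (1.0 / na + 1.0 / nb))
        df_total = d0 + df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = log2fc / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_total)
        pvals = np.where(np.isnan(tvals), 1.0, pvals)
        tvals = np.where(np.isnan(tvals), 0.0, tvals)
    else:
        tvals, pvals = stats.ttest_ind(A, B, axis=1, equal_var=False)
        pvals = np.where(np.isnan(tvals), 1.0, pvals)
        tvals = np.where(np.isnan(tvals), 0.0, tvals)

    result["t"] = tvals
    result["p_value"] = np.clip(pvals, 0.0, 1.0)
    result["adj_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result[["log2fc", "t", "p_value", "adj_p", "flagged"]]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0 and sample standard deviation 1 (ddof=1)."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        constant = matrix.index[sd == 0].tolist()
        raise ConstantRowError(f"constant rows cannot be z-scored: {constant}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=matrix.index.copy(), columns=matrix.columns.copy())
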