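"""Prototype scoring, data-driven signature expansion, and signature scoring.

A *prototype score* is the per-sample mean log2 expression of a curated
marker panel for one axis (neutrophils, T cells, or TGFβ activity).  The
panel is *expanded* by regressing every gene in the matrix on all three
prototype scores simultaneously (ordinary least squares with intercept)
and collecting genes whose coefficient on one axis is large and whose
BH-adjusted p-value on that axis is small.  The final signature score is
again a plain per-sample mean over the expanded gene list, so all score
properties (linearity, permutation invariance) are inherited from the
arithmetic mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tmesig.io import AnalysisConfig, GeneSetCollection

logger = logging.getLogger(__name__)

#: Axis order used everywhere (scores, fits, signatures).
AXES = ("neutrophil", "tcell", "tgfb")


class MissingGeneError(ValueError):
    """Raised when no panel gene of an axis is present in the matrix."""


class CollinearityError(ValueError):
    """Raised when the prototype-score design matrix is rank-deficient."""


@dataclass(frozen=True)
class PrototypePanel:
    """Curated marker genes defining the three prototype scores."""

    neutrophil: tuple[str, ...] = (
        "CXCR1", "CXCR2", "S100A8", "S100A9", "CSFR3", "MMP9", "MMP25", "FCGR3B",
    )
    tcell: tuple[str, ...] = (
        "CD8A", "CD3D", "CD3E", "CD3G", "IRF1", "GZMB", "IL27", "GNLY", "PRF1",
        "CCL5", "STAT1", "IL12RB1", "CD28", "CCR5", "IL12RB2", "CD38", "CXCR6",
        "TBX21",
    )
    tgfb: tuple[str, ...] = ("DCN", "COL1A1", "SPARC", "ACTA2")

    def __post_init__(self):
        for axis in AXES:
            genes = tuple(g.strip().upper() for g in getattr(self, axis))
            object.__setattr__(self, axis, genes)
            if not genes:
                raise ValueError(f"empty prototype list for axis {axis!r}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes in {axis!r} prototype list")

    def genes(self, axis: str) -> tuple[str, ...]:
        return getattr(self, axis)

    def all_genes(self) -> set[str]:
        return set().union(*(self.genes(axis) for axis in AXES))

    def axis_of(self, gene: str) -> str | None:
        for axis in AXES:
            if gene in self.genes(axis):
                return axis
        return None


DEFAULT_PANEL = PrototypePanel()


@dataclass
class SignatureSet:
    """Per-axis signature gene lists with per-gene provenance.

    ``genes`` has one row per selected gene with columns ``gene``,
    ``axis``, ``provenance`` ("prototype" or "expanded"),
    ``coefficient`` and ``adj_p`` (NaN for prototype-only derivations).
    """

    genes: pd.DataFrame
    expanded: bool = False

    def axis_genes(self, axis: str) -> list[str]:
        return self.genes.loc[self.genes["axis"] == axis, "gene"].tolist()

    def to_gene_sets(self) -> GeneSetCollection:
        collection = GeneSetCollection()
        for axis in AXES:
            kind = "expanded" if self.expanded else "prototype"
            collection.add(axis, self.axis_genes(axis), f"{kind} {axis} signature")
        return collection


def _present_panel_genes(
    matrix: pd.DataFrame, panel: PrototypePanel, axis: str
) -> list[str]:
    present = [g for g in panel.genes(axis) if g in matrix.index]
    missing = [g for g in panel.genes(axis) if g not in matrix.index]
    if not present:
        raise MissingGeneError(
            f"no {axis} prototype gene present in matrix; missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"{axis} prototype genes absent from matrix: {missing}", stacklevel=3
        )
    return present


def _mean_scores(matrix: pd.DataFrame, axis_genes: dict[str, list[str]]) -> pd.DataFrame:
    scores = pd.DataFrame(
        {axis: matrix.loc[genes].mean(axis=0) for axis, genes in axis_genes.items()}
    )
    scores.index.name = "sample_id"
    return scores[list(AXES)]


def compute_prototype_scores(
    matrix: pd.DataFrame, panel: PrototypePanel = DEFAULT_PANEL
) -> pd.DataFrame:
    """Average log2 expression of each axis's present panel genes per sample.

    Returns a samples × (neutrophil, tcell, tgfb) frame.  Panel genes
    absent from the matrix are dropped with a warning; an axis with no
    present gene raises :class:`MissingGeneError`.
    """
    axis_genes = {axis: _present_panel_genes(matrix, panel, axis) for axis in AXES}
    scores = _mean_scores(matrix, axis_genes)
    scores.attrs["computed_from"] = "prototype"
    return scores


def fit_gene_models(
    matrix: pd.DataFrame,
    prototype_scores: pd.DataFrame,
    panel: PrototypePanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Per-gene OLS of expression on the three prototype scores.

    Each gene's log2 expression is regressed on an intercept plus the
    neutrophil, T-cell, and TGFβ prototype scores simultaneously.
    Returns one row per gene with, for each axis, the coefficient
    (``coef_<axis>``, log2 units per unit prototype score), the two-sided
    t-test p-value (``p_<axis>``), and the BH-adjusted p-value
    (``adjp_<axis>``, adjusted across all tested genes within the axis),
    plus ``prototype_axis`` ("" for non-panel genes).

    Zero-variance genes receive coefficient 0 and p-value 1 by
    convention.  Requires at least 6 samples (residual df >= 2) and a
    full-rank design; identical prototype scores raise
    :class:`CollinearityError` naming the collinear axes.
    """
    samples = matrix.columns
    n = len(samples)
    if n < 6:
        raise ValueError(f"need >= 6 samples to fit gene models, got {n}")
    scores = prototype_scores.loc[samples, list(AXES)]

    X = np.column_stack([np.ones(n), scores.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(scores.to_numpy().T)
        pairs = [
            (AXES[i], AXES[j])
            for i in range(3)
            for j in range(i + 1, 3)
            if abs(corr[i, j]) > 1 - 1e-12 or not np.isfinite(corr[i, j])
        ]
        raise CollinearityError(
            f"rank-deficient design; collinear or degenerate axes: {pairs or AXES}"
        )

    Y = matrix.to_numpy()  # genes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T  # 4 x n
    beta = Y @ hat.T  # genes x 4
    resid = Y - beta @ X.T
    df_resid = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / df_resid
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    # perfect fits: zero residual variance with a nonzero coefficient
    pvals = np.where(np.isnan(tvals) & (beta != 0), 0.0, pvals)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    flat = matrix.var(axis=1, ddof=0).to_numpy() == 0
    beta[flat, 1:] = 0.0
    tvals[flat, :] = 0.0
    pvals[flat, :] = 1.0

    fit = pd.DataFrame(index=matrix.index.copy())
    fit.index.name = "gene"
    for j, axis in enumerate(AXES, start=1):
        fit[f"coef_{axis}"] = beta[:, j]
        fit[f"t_{axis}"] = tvals[:, j]
        fit[f"p_{axis}"] = np.clip(pvals[:, j], 0.0, 1.0)
        fit[f"adjp_{axis}"] = multipletests(fit[f"p_{axis}"], method="fdr_bh")[1]
    fit["prototype_axis"] = [panel.axis_of(g) or "" for g in fit.index]
    return fit


def select_signature_genes(
    fit: pd.DataFrame,
    panel: PrototypePanel = DEFAULT_PANEL,
    config: AnalysisConfig | None = None,
) -> SignatureSet:
    """Select expanded signatures from per-gene fits.

    A non-panel gene qualifies for an axis when its BH-adjusted p-value
    on that axis is below ``alpha_select`` and its coefficient exceeds
    ``min_coef`` (signed by default: co-expressed genes only).  A gene
    qualifying on several axes is assigned to the axis with the smallest
    adjusted p-value (tie: larger coefficient; then axis order).  Each
    axis list starts with the panel genes present in the fit, followed by
    candidates in ascending adjusted-p order (tie: descending
    coefficient, then gene name), truncated at ``max_genes`` total.
    """
    config = config or AnalysisConfig()
    rows: list[dict] = []
    candidates: dict[str, list[tuple]] = {axis: [] for axis in AXES}
    panel_genes = panel.all_genes()

    for gene in fit.index:
        if gene in panel_genes:
            continue
        quals = []
        for axis in AXES:
            coef = fit.at[gene, f"coef_{axis}"]
            adjp = fit.at[gene, f"adjp_{axis}"]
            value = abs(coef) if config.absolute_coef else coef
            if adjp < config.alpha_select and value > config.min_coef:
                quals.append((adjp, -coef, AXES.index(axis), axis, coef))
        if quals:
            adjp, _, _, axis, coef = min(quals)
            candidates[axis].append((adjp, -coef, gene))

    for axis in AXES:
        proto_present = [g for g in panel.genes(axis) if g in fit.index]
        for gene in proto_present:
            rows.append(
                {
                    "gene": gene,
                    "axis": axis,
                    "provenance": "prototype",
                    "coefficient": fit.at[gene, f"coef_{axis}"],
                    "adj_p": fit.at[gene, f"adjp_{axis}"],
                }
            )
        if not candidates[axis]:
            warnings.warn(
                f"no genes qualified for the {axis} signature; "
                "falling back to the prototype list",
                stacklevel=2,
            )
        room = max(config.max_genes - len(proto_present), 0)
        for adjp, neg_coef, gene in sorted(candidates[axis])[:room]:
            rows.append(
                {
                    "gene": gene,
                    "axis": axis,
                    "provenance": "expanded",
                    "coefficient": -neg_coef,
                    "adj_p": adjp,
                }
            )

    genes = pd.DataFrame(
        rows, columns=["gene", "axis", "provenance", "coefficient", "adj_p"]
    )
    return SignatureSet(genes=genes, expanded=True)


def prototype_signature_set(
    matrix: pd.DataFrame, panel: PrototypePanel = DEFAULT_PANEL
) -> SignatureSet:
    """Prototype-only signatures restricted to genes present in the matrix."""
    rows = [
        {
            "gene": g,
            "axis": axis,
            "provenance": "prototype",
            "coefficient": np.nan,
            "adj_p": np.nan,
        }
        for axis in AXES
        for g in _present_panel_genes(matrix, panel, axis)
    ]
    return SignatureSet(genes=pd.DataFrame(rows), expanded=False)


def compute_signature_scores(
    matrix: pd.DataFrame, signatures: SignatureSet
) -> pd.DataFrame:
    """Average log2 expression of each axis's signature genes per sample."""
    axis_genes: dict[str, list[str]] = {}
    for axis in AXES:
        genes = [g for g in signatures.axis_genes(axis) if g in matrix.index]
        missing = [g for g in signatures.axis_genes(axis) if g not in matrix.index]
        if not genes:
            raise MissingGeneError(
                f"no {axis} signature gene present in matrix; missing: {missing}"
            )
        if missing:
            warnings.warn(
                f"{axis} signature genes absent from matrix: {missing}",
                stacklevel=2,
            )
        axis_genes[axis] = genes
    scores = _mean_scores(matrix, axis_genes)
    scores.attrs["computed_from"] = "expanded" if signatures.expanded else "prototype"
    return scores


def derive_signatures(
    matrix: pd.DataFrame,
    panel: PrototypePanel = DEFAULT_PANEL,
    config: AnalysisConfig | None = None,
) -> tuple[SignatureSet, pd.DataFrame]:
    """Full derivation: prototype scores, expansion (if warranted), rescoring.

    Expansion is skipped — prototype signatures and scores are returned —
    when ``config.expand_signatures`` is false or the cohort has fewer
    than ``config.min_samples_expand`` samples, mirroring prototype-only
    scoring of small adenoma series.
    """
    config = config or AnalysisConfig()
    prototype_scores = compute_prototype_scores(matrix, panel)
    n = matrix.shape[1]
    if not config.expand_signatures or n < config.min_samples_expand:
        if config.expand_signatures:
            logger.info(
                "cohort of %d samples below expansion minimum (%d); "
                "using prototype signatures",
                n,
                config.min_samples_expand,
            )
        return prototype_signature_set(matrix, panel), prototype_scores
    fit = fit_gene_models(matrix, prototype_scores, panel)
    signatures = select_signature_genes(fit, panel, config)
    scores = compute_signature_scores(matrix, signatures)
    return signatures, scores
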