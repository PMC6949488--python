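"""Seeded synthetic cohorts and antibody arrays with known ground truth.

The cohort generator emulates the structure the signature analysis
assumes: each sample carries latent abundances of neutrophils (N),
T cells (T), TGFβ-active stroma (F), and monocytes (M), drawn log-normal
so they are positive and right-skewed like cell fractions.  Gene rows are
``baseline + loading · latent + Gaussian log2 noise``: prototype marker
genes and planted co-expressed genes load on their axis latent, PTPRC
loads on total immune content I = N + T + M, and background genes carry
no signal.  A negative coupling ``beta_int`` feeds the standardized N·F
interaction into T, encoding T-cell suppression where neutrophils meet
TGFβ activity.  CMS-like labels assign CMS4 to the top TGFβ quartile.

Marker genes load at a fixed 0.75 while planted co-expressed genes load
uniformly in [0.8, 1.2]: relative to the prototype score (whose slope on
the latent equals the mean marker loading) the planted genes then have
expected regression coefficients of roughly 1.07–1.6 log2 units per unit
score, i.e. they are planted to satisfy the coefficient-above-1
definition of a co-expressed signature gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tmesig.signatures import AXES, DEFAULT_PANEL, PrototypePanel

CMS_POOL = ("CMS1", "CMS2", "CMS3")


@dataclass
class CohortConfig:
    """Parameters of the synthetic bulk-expression cohort.

    Defaults give a 200-sample, 1,000-gene cohort with 30 planted
    co-expressed genes per axis, log2 noise sd 0.5, and interaction
    coupling −1 (strong suppression of T where N and F are jointly high).
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_planted_per_axis: int = 30
    planted_loading_range: tuple[float, float] = (0.8, 1.2)
    marker_loading: float = 0.75
    ptprc_loading: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    beta_int: float = -1.0
    interaction_noise_sd: float = 0.25
    tgfb_neutrophil_coupling: float = 0.0
    panel: PrototypePanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        if self.beta_int > 0:
            raise ValueError("beta_int must be <= 0 (suppressive coupling)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted_per_axis < 0:
            raise ValueError("n_planted_per_axis must be >= 0")
        lo, hi = self.planted_loading_range
        if not 0 < lo <= hi:
            raise ValueError("planted_loading_range must be 0 < lo <= hi")
        n_markers = sum(len(self.panel.genes(axis)) for axis in AXES)
        n_structured = n_markers + 3 * self.n_planted_per_axis + 1  # + PTPRC
        if self.n_genes < n_structured:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than structured gene count "
                f"{n_structured}"
            )
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort.

    ``latents`` is samples × (N, T, F, M, I); ``genes`` has one row per
    gene with its axis membership (neutrophil / tcell / tgfb / ptprc /
    background), loading, and whether it was planted as expandable.
    """

    latents: pd.DataFrame
    genes: pd.DataFrame

    def planted(self, axis: str) -> list[str]:
        sel = (self.genes["axis"] == axis) & self.genes["planted"]
        return self.genes.loc[sel, "gene"].tolist()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


_AXIS_PREFIX = {"neutrophil": "NEUP", "tcell": "TCEP", "tgfb": "TGFP"}


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate (expression matrix, CMS-like annotation, ground truth).

    Deterministic given ``(config, seed)``; independent random streams
    are spawned from the single seed for latents, loadings/baselines,
    noise, and labels.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    rng_latent, rng_gene, rng_noise, rng_label = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = config.n_samples

    N = rng_latent.lognormal(0.0, 1.0, n)
    T0 = rng_latent.lognormal(0.0, 1.0, n)
    F = rng_latent.lognormal(0.0, 1.0, n)
    M = rng_latent.lognormal(0.0, 1.0, n)
    if config.tgfb_neutrophil_coupling:
        N = N + config.tgfb_neutrophil_coupling * _standardize(F)
    T = (
        T0
        + config.beta_int * _standardize(N * F)
        + rng_latent.normal(0.0, config.interaction_noise_sd, n)
    )
    I = N + T + M

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    latents = pd.DataFrame(
        {"N": N, "T": T, "F": F, "M": M, "I": I}, index=sample_ids
    )
    latents.index.name = "sample_id"
    axis_latent = {"neutrophil": N, "tcell": T, "tgfb": F, "ptprc": I}

    genes: list[str] = []
    memberships: list[str] = []
    loadings: list[float] = []
    planted_flags: list[bool] = []

    for axis in AXES:
        for g in config.panel.genes(axis):
            genes.append(g)
            memberships.append(axis)
            loadings.append(config.marker_loading)
            planted_flags.append(False)
    lo, hi = config.planted_loading_range
    for axis in AXES:
        for i in range(config.n_planted_per_axis):
            genes.append(f"{_AXIS_PREFIX[axis]}{i + 1:03d}")
            memberships.append(axis)
            loadings.append(float(rng_gene.uniform(lo, hi)))
            planted_flags.append(True)
    genes.append("PTPRC")
    memberships.append("ptprc")
    loadings.append(config.ptprc_loading)
    planted_flags.append(False)
    for i in range(config.n_genes - len(genes)):
        genes.append(f"BG{i + 1:04d}")
        memberships.append("background")
        loadings.append(0.0)
        planted_flags.append(False)

    baselines = rng_gene.normal(config.baseline_mean, config.baseline_sd, len(genes))
    latent_rows = np.array(
        [axis_latent.get(m, np.zeros(n)) for m in memberships]
    )
    values = (
        baselines[:, None]
        + np.asarray(loadings)[:, None] * latent_rows
        + rng_noise.normal(0.0, config.noise_sd, (len(genes), n))
    )
    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    matrix.index.name = "gene"

    labels = pd.Series(
        rng_label.choice(CMS_POOL, size=n), index=sample_ids, name="cms"
    )
    n_cms4 = n // 4
    top_f = latents["F"].nlargest(n_cms4).index
    labels.loc[top_f] = "CMS4"

    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "axis": memberships,
            "loading": loadings,
            "planted": planted_flags,
        }
    )
    return matrix, labels, SyntheticTruth(latents=latents, genes=truth_genes)


@dataclass
class ArrayConfig:
    """Parameters of the synthetic cytokine array.

    Defaults mirror the co-culture design: three supernatant replicates
    with neutrophils (T+Ne), three with monocytes (T+Mo), two T-cell-only
    controls; two cytokines shifted by +1.5 log2 units in the T+Ne
    condition over a noise sd of 0.3.
    """

    n_cytokines: int = 300
    samples_per_condition: dict[str, int] = field(
        default_factory=lambda: {"T+Ne": 3, "T+Mo": 3, "T_only": 2}
    )
    n_planted: int = 2
    delta: float = 1.5
    shifted_condition: str = "T+Ne"
    noise_sd: float = 0.3
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted > self.n_cytokines:
            raise ValueError("cannot plant more cytokines than exist")
        if self.shifted_condition not in self.samples_per_condition:
            raise ValueError(
                f"shifted condition {self.shifted_condition!r} not among conditions"
            )
        if any(k < 1 for k in self.samples_per_condition.values()):
            raise ValueError("every condition needs at least one sample")


def generate_array(
    config: ArrayConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Generate (intensity matrix, condition labels, planted-truth flags).

    Background cytokines are Normal(baseline, sd) in every condition;
    planted cytokines gain ``delta`` in the shifted condition only.
    Deterministic given ``(config, seed)``.
    """
    config = config or ArrayConfig()
    ss = np.random.SeedSequence(seed)
    rng_base, rng_noise, rng_plant = (np.random.default_rng(s) for s in ss.spawn(3))

    cytokines = [f"CYT{i + 1:04d}" for i in range(config.n_cytokines)]
    planted_idx = rng_plant.choice(
        config.n_cytokines, size=config.n_planted, replace=False
    )
    planted = pd.Series(False, index=cytokines, name="planted")
    planted.iloc[np.sort(planted_idx)] = True

    sample_ids: list[str] = []
    condition_list: list[str] = []
    for cond, k in config.samples_per_condition.items():
        for i in range(k):
            sample_ids.append(f"{cond}_{i + 1}")
            condition_list.append(cond)
    conditions = pd.Series(condition_list, index=sample_ids, name="condition")

    baselines = rng_base.normal(
        config.baseline_mean, config.baseline_sd, config.n_cytokines
    )
    values = baselines[:, None] + rng_noise.normal(
        0.0, config.noise_sd, (config.n_cytokines, len(sample_ids))
    )
    shifted_cols = conditions == config.shifted_condition
    values[np.ix_(planted.to_numpy(), shifted_cols.to_numpy())] += config.delta

    matrix = pd.DataFrame(values, index=cytokines, columns=sample_ids)
    matrix.index.name = "cytokine"
    return matrix, conditions, planted
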