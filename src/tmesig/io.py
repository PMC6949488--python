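"""Readers, writers, and run configuration.

Expression matrices are carried as :class:`pandas.DataFrame` objects with
uppercase gene symbols in the row index and sample identifiers in the
columns; values are log2-scale expression.  Gene sets use the GMT dialect
(one set per line: name, description, genes, tab-separated).  Tables are
plain CSV with a header row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CMS_LABELS = ("CMS1", "CMS2", "CMS3", "CMS4", "unlabeled")


class MatrixFormatError(ValueError):
    """Raised when a delimited expression/array file cannot be validated."""


class GmtFormatError(ValueError):
    """Raised when a GMT line does not have the required fields."""


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions.

    Genes are stored uppercase and must be unique within a set; set names
    must be unique (enforced by the dict container).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        genes = [str(g).strip().upper() for g in genes]
        if len(set(genes)) != len(genes):
            dups = sorted({g for g in genes if genes.count(g) > 1})
            raise GmtFormatError(f"duplicate genes in set {name!r}: {dups}")
        self.sets[name] = genes
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions


@dataclass
class AnalysisConfig:
    """Tunable parameters of the signature/stratification analysis.

    Parameters
    ----------
    alpha_select:
        BH-adjusted p-value threshold below which a gene qualifies for a
        signature (deliberately permissive default, 0.5).
    min_coef:
        Minimum regression coefficient (log2 units per unit prototype
        score) a gene must exceed to qualify; positive-only by default
        since signatures collect co-expressed genes.
    max_genes:
        Cap on signature size, prototype genes included.
    fc_up, fc_down:
        Bounds of the cytokine-array log2 fold-change window; a cytokine
        is differentially present when its log2FC falls strictly outside
        (fc_down, fc_up).
    ptprc_symbol:
        Gene used as the proxy for total immune content.
    expand_signatures:
        When false, prototype gene lists are used as-is (small cohorts).
    min_samples_expand:
        Cohorts smaller than this are scored with prototypes only.
    absolute_coef:
        Select on |coefficient| rather than the signed coefficient.
    prior_df:
        Prior degrees of freedom for the array-test variance moderation.
    exact_limit:
        Largest min(n_a, n_b) for which the Mann-Whitney p-value is
        computed by exact enumeration (tie-free inputs only).
    within_stratum_tgfb:
        Split on the TGFβ median computed inside each neutrophil stratum
        (default) rather than the global TGFβ median.
    rng_seed:
        Seed for any simulation performed in a run.
    """

    alpha_select: float = 0.5
    min_coef: float = 1.0
    max_genes: int = 50
    fc_up: float = 0.6
    fc_down: float = -0.4
    ptprc_symbol: str = "PTPRC"
    expand_signatures: bool = True
    min_samples_expand: int = 30
    absolute_coef: bool = False
    prior_df: float = 4.0
    exact_limit: int = 8
    within_stratum_tgfb: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_select <= 1:
            raise ValueError("alpha_select must be in (0, 1]")
        if self.min_coef < 0:
            raise ValueError("min_coef must be >= 0")
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")
        if not self.fc_down < 0 < self.fc_up:
            raise ValueError("fold-change window must satisfy fc_down < 0 < fc_up")
        self.ptprc_symbol = self.ptprc_symbol.strip().upper()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _infer_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in (".tsv", ".txt", ".tab"):
        return "\t"
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check finiteness and identifier uniqueness of a genes × samples frame."""
    if matrix.index.duplicated().any():
        dups = sorted(set(matrix.index[matrix.index.duplicated()]))
        raise MatrixFormatError(f"duplicate gene identifiers: {dups}")
    if matrix.columns.duplicated().any():
        dups = sorted(set(matrix.columns[matrix.columns.duplicated()]))
        raise MatrixFormatError(f"duplicate sample identifiers: {dups}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise MatrixFormatError("matrix contains non-numeric values")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise MatrixFormatError(
            "non-finite value at gene "
            f"{matrix.index[bad[0]]!r}, sample {matrix.columns[bad[1]]!r}"
        )
    return matrix


def read_expression_matrix(
    path: str | Path, transform: str = "none"
) -> pd.DataFrame:
    """Read a delimited gene-by-sample expression matrix.

    The first column holds gene symbols (case-normalized to uppercase),
    the header row holds sample identifiers.  Duplicate gene rows are
    collapsed by their mean with a warning; duplicate sample identifiers
    are an error.  ``transform="log2_plus1"`` applies log2(x + 1)
    elementwise for raw-scale inputs; the default assumes values are
    already log2.
    """
    path = Path(path)
    if transform not in ("none", "log2_plus1"):
        raise ValueError(f"unknown transform {transform!r}")
    sep = _infer_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = [h.strip() for h in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise MatrixFormatError(f"duplicate sample identifiers: {dups}")

    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.columns = sample_ids
    raw.index = raw.index.astype(str).str.strip().str.upper()

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric value {raw.iat[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixFormatError(
            f"missing value at gene {numeric.index[g]!r}, "
            f"sample {numeric.columns[s]!r}; missing values are not imputed"
        )
    matrix = numeric.astype(float)

    if matrix.index.duplicated().any():
        dups = sorted(set(matrix.index[matrix.index.duplicated()]))
        warnings.warn(
            f"collapsing duplicate gene rows by mean: {dups}", stacklevel=2
        )
        matrix = matrix.groupby(level=0, sort=False).mean()

    if transform == "log2_plus1":
        if (matrix.to_numpy() <= -1).any():
            raise MatrixFormatError("log2_plus1 transform requires values > -1")
        matrix = np.log2(matrix + 1.0)

    return validate_expression_matrix(matrix)


def read_annotation(path: str | Path) -> pd.Series:
    """Read a sample annotation CSV with columns ``sample_id`` and ``cms``.

    Missing or empty labels become ``"unlabeled"``.
    """
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "cms" not in cols:
        raise MatrixFormatError("annotation needs columns 'sample_id' and 'cms'")
    samples = df[cols["sample_id"]].str.strip()
    if samples.duplicated().any():
        dups = sorted(set(samples[samples.duplicated()]))
        raise MatrixFormatError(f"duplicate annotated samples: {dups}")
    labels = df[cols["cms"]].fillna("unlabeled").str.strip().str.upper()
    labels = labels.replace({"": "unlabeled", "UNLABELED": "unlabeled", "NA": "unlabeled"})
    bad = sorted(set(labels) - set(CMS_LABELS))
    if bad:
        raise MatrixFormatError(f"unknown subtype labels: {bad}")
    return pd.Series(labels.to_numpy(), index=samples.to_numpy(), name="cms")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes, tab-separated)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtFormatError(
                    f"line {lineno}: expected at least 3 tab-separated fields "
                    f"(name, description, genes), got {len(parts)}"
                )
            name, description = parts[0], parts[1]
            if name in collection.sets:
                raise GmtFormatError(f"line {lineno}: duplicate set name {name!r}")
            collection.add(name, [g for g in parts[2:] if g.strip()], description)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            description = collection.descriptions.get(name, "")
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_table(
    rows: pd.DataFrame | Iterable[Mapping], path: str | Path
) -> None:
    """Write homogeneous records as a header-ed CSV with stable column order."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        columns = list(rows[0].keys()) if rows else None
        df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
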