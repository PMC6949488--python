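"""Closed-form study metrics: tumor size and T-cell proliferation index."""

from __future__ import annotations

from typing import Iterable

import pandas as pd


def tumor_volume(diameter: float) -> float:
    """Tumor volume from its diameter: diameter**3 / 2 (units cubed)."""
    if diameter < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter}")
    return diameter**3 / 2.0


def tumor_burden(diameters: Iterable[float]) -> float:
    """Total tumor burden per animal: sum of per-tumor volumes."""
    return float(sum(tumor_volume(d) for d in diameters))


def proliferation_index(
    n_proliferated_condition: float, n_proliferated_alone: float
) -> float:
    """Proliferated T cells under a co-culture condition relative to T cells alone."""
    if n_proliferated_alone <= 0:
        raise ValueError("reference count of proliferated T cells must be positive")
    return n_proliferated_condition / n_proliferated_alone


def burden_summary(diameters_by_mouse: dict[str, Iterable[float]]) -> pd.DataFrame:
    """Per-mouse burden, tumor count, and average tumor size table."""
    rows = []
    for mouse, diameters in diameters_by_mouse.items():
        diameters = list(diameters)
        volumes = [tumor_volume(d) for d in diameters]
        rows.append(
            {
                "mouse": mouse,
                "tumor_count": len(diameters),
                "tumor_burden": float(sum(volumes)),
                "average_tumor_size": float(sum(volumes) / len(volumes))
                if volumes
                else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["mouse", "tumor_count", "tumor_burden", "average_tumor_size"])
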