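"""Filtering, log transform, within-sample centering, and batch correction.

The normalization pipeline for LC-MS relative peak areas is: drop any
metabolite with a missing value in any sample; natural-log transform;
mean-center each sample (row) to absorb sample-to-sample loading
differences; then, per metabolite, regress out the LC-MS batch as a
categorical main effect and keep the residuals.  The residuals are the
normalized abundances used by every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = [
    "AbundanceTable",
    "QCReport",
    "filter_complete",
    "log_center",
    "batch_residualize",
    "technical_cv",
    "normalize",
]


@dataclass
class QCReport:
    """Per-metabolite coefficient of variation across technical replicates."""

    cv: pd.Series

    @property
    def mean_cv(self) -> float:
        return float(self.cv.mean())

    @property
    def cv_range(self) -> tuple[float, float]:
        return float(self.cv.min()), float(self.cv.max())


def filter_complete(table: AbundanceTable) -> AbundanceTable:
    """Drop every metabolite with a missing value in any sample.

    Column order of the survivors is preserved; all samples are kept.
    """
    if table.stage != "raw":
        raise ValueError(f"filter_complete expects a raw table, got stage {table.stage!r}")
    complete = table.values.columns[table.values.notna().all(axis=0)]
    if len(complete) == 0:
        raise ValueError("no metabolite has complete values across all samples")
    return replace(table, values=table.values[complete])


def log_center(table: AbundanceTable) -> AbundanceTable:
    """Natural-log transform, then mean-center each sample (row).

    Every row of the result has mean zero to within 1e-9.
    """
    if table.stage not in ("raw", "logged"):
        raise ValueError(f"log_center expects stage raw or logged, got {table.stage!r}")
    vals = table.values
    if table.stage == "raw":
        bad = vals <= 0
        if bad.to_numpy().any():
            cells = [
                f"({r}, {c})"
                for r, c in zip(*np.nonzero(bad.to_numpy()))
                for r, c in [(vals.index[r], vals.columns[c])]
            ]
            raise ValueError(
                "log transform requires strictly positive values; offending cells: "
                + ", ".join(cells[:20])
            )
        vals = np.log(vals)
    centered = vals.sub(vals.mean(axis=1), axis=0)
    out = replace(table, values=centered)
    out.stage = "centered"
    return out


def batch_residualize(table: AbundanceTable) -> AbundanceTable:
    """Residualize each metabolite on batch (categorical main effect).

    Least-squares residuals of ``value ~ batch`` reduce, for a purely
    categorical design, to subtracting the per-batch mean within each
    metabolite; per-metabolite per-batch means of the output are 0 within
    1e-9.  Singleton batches are refused because their residuals would be
    identically zero.
    """
    if table.stage != "centered":
        raise ValueError(f"batch_residualize expects stage centered, got {table.stage!r}")
    batches = table.metadata["batch"]
    sizes = batches.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(
            f"singleton batches {sorted(singletons.index.tolist())}: residualization "
            "would zero them degenerately; merge batches before normalizing"
        )
    residuals = table.values - table.values.groupby(batches).transform("mean")
    out = replace(table, values=residuals)
    out.stage = "normalized"
    return out


def normalize(table: AbundanceTable) -> AbundanceTable:
    """Full pipeline: filter_complete -> log_center -> batch_residualize."""
    return batch_residualize(log_center(filter_complete(table)))


def technical_cv(replicate_table: AbundanceTable) -> QCReport:
    """Per-metabolite CV = sample SD / mean across technical replicate rows."""
    if replicate_table.n_samples < 2:
        raise ValueError("technical_cv requires at least 2 technical replicate rows")
    vals = replicate_table.values
    means = vals.mean(axis=0)
    if (means == 0).any():
        zero = means.index[means == 0].tolist()
        raise ValueError(f"zero mean for metabolites {zero[:10]}; CV undefined")
    cv = vals.std(axis=0, ddof=1) / means
    return QCReport(cv=cv.abs())
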