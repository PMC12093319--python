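"""Core sample-by-metabolite container and its TSV dialect.

The package moves a single object through the pipeline: an
:class:`AbundanceTable`, a samples x metabolites value matrix with linked
per-sample metadata (selection regime, selection history, replicate
population, age in days from egg, LC-MS batch, pool size).  The ``stage``
tag records how far the table has progressed through normalization and may
only advance in the order raw -> logged -> centered -> normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

#: Reserved metadata column names, in canonical order.
METADATA_COLUMNS = [
    "sample_id",
    "regime",
    "history",
    "replicate",
    "age_days",
    "batch",
    "n_pooled",
]

#: Legal stage tags, in pipeline order.
STAGES = ["raw", "logged", "centered", "normalized"]


@dataclass
class AbundanceTable:
    """Samples x metabolites abundance matrix with linked sample metadata.

    Parameters
    ----------
    values
        DataFrame of abundance values, one row per sample, one column per
        metabolite.  The index is the sample identifier.
    metadata
        DataFrame of per-sample metadata with the same index as ``values``
        and (at least) the columns in :data:`METADATA_COLUMNS`.
    stage
        One of ``raw``, ``logged``, ``centered``, ``normalized``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("values and metadata indexes do not match row-for-row")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def advance_stage(self, new_stage: str) -> None:
        """Validate that ``new_stage`` is a legal forward move and apply it."""
        if STAGES.index(new_stage) <= STAGES.index(self.stage):
            raise ValueError(
                f"stage may only advance ({self.stage!r} -> {new_stage!r} is not forward)"
            )
        self.stage = new_stage

    def subset(self, mask) -> "AbundanceTable":
        """Row-subset by a boolean mask or index list, keeping the stage tag."""
        return replace(self, values=self.values.loc[mask], metadata=self.metadata.loc[mask])

    def exclude(self, pairs: list[tuple[str, int]]) -> "AbundanceTable":
        """Drop samples matching any (regime, age_days) pair.

        The day-9 accelerated-regime samples are the canonical use: they sit
        in a distinct post-eclosion physiological state with no control-regime
        analog, so clock fitting and the trajectory models drop them.
        """
        keep = pd.Series(True, index=self.metadata.index)
        for regime, age in pairs:
            keep &= ~(
                (self.metadata["regime"] == regime) & (self.metadata["age_days"] == age)
            )
        return self.subset(keep)

    # -- TSV dialect -------------------------------------------------------

    def write(self, values_path: str | Path, metadata_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="sample_id")
        self.metadata.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read(
        cls,
        values_path: str | Path,
        metadata_path: str | Path,
        stage: str = "raw",
    ) -> "AbundanceTable":
        values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
        metadata = pd.read_csv(metadata_path, sep="\t")
        metadata = metadata.set_index("sample_id", drop=False)
        metadata.index.name = None
        return cls(values=values, metadata=metadata, stage=stage)


def make_metadata(records: list[dict]) -> pd.DataFrame:
    """Build a metadata frame indexed by sample_id from plain dicts."""
    meta = pd.DataFrame.from_records(records)
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    return meta[METADATA_COLUMNS + [c for c in meta.columns if c not in METADATA_COLUMNS]]
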