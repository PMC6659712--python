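"""Core data containers shared across the pipeline.

Event tables are plain :class:`pandas.DataFrame` objects following a fixed
column schema (:data:`EVENT_COLUMNS`); bead distributions and MFI matrices
get small dedicated containers because they carry assay metadata that a bare
array cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column schema of an event table: one row per detected bead.
EVENT_COLUMNS = [
    "event_id",
    "well_id",
    "sample_id",
    "experiment",
    "condition",
    "replicate",
    "region",
    "cl1",
    "cl2",
    "doublet_disc",
    "reporter",
]

#: Sentinel region value for events not (yet) assigned to a bead class.
UNCLASSIFIED = -1


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Check that *events* carries the event-table schema.

    Returns the frame unchanged; raises ``ValueError`` on a missing column or
    on physically impossible values (negative reporter or discriminator).
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if (events["reporter"] < 0).any():
        raise ValueError("reporter fluorescence must be >= 0")
    if (events["doublet_disc"] < 0).any():
        raise ValueError("doublet discriminator must be >= 0")
    return events


@dataclass
class BeadDistribution:
    """Reporter values for one interaction (``IP_Probe``) in one well.

    The reporter multiset is the unit of the nonparametric ANC tests; its
    median is the MFI entering network analysis.
    """

    interaction: str
    sample_id: str
    experiment: int | str
    condition: str
    replicate: int | str
    reporters: np.ndarray

    def __post_init__(self) -> None:
        self.reporters = np.asarray(self.reporters, dtype=float)

    def __len__(self) -> int:
        return self.reporters.size


@dataclass
class MFIMatrix:
    """Interactions x samples matrix of median fluorescence intensities.

    ``values`` holds the matrix (rows = interaction names, columns = sample
    ids); ``samples`` is a per-sample annotation frame indexed by sample id
    with at least ``condition`` and ``experiment`` columns (``replicate`` and
    ``detergent`` when applicable).  The same container carries the matrix
    through batch correction and the log2 transform; ``log2_scale`` records
    which scale the values are on.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate interaction names")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples missing annotations: {list(missing)}")
        # keep annotation rows aligned with matrix columns
        self.samples = self.samples.loc[self.values.columns]

    @property
    def interactions(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "MFIMatrix":
        return MFIMatrix(self.values.copy(), self.samples.copy(), self.log2_scale)


@dataclass
class SolubilityMeasurement:
    """Densitometry of one protein's band in lysate vs pellet."""

    protein: str
    lysate_density: float
    pellet_density: float

    def __post_init__(self) -> None:
        if self.lysate_density < 0 or self.pellet_density < 0:
            raise ValueError("band densities must be >= 0")
        if self.lysate_density == 0 and self.pellet_density == 0:
            raise ValueError("lysate and pellet densities cannot both be zero")
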