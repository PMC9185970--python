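"""Core in-memory containers shared across the pipeline.

The substrate of every analysis is a :class:`BetaMatrix` — a probes × samples
matrix of methylation beta values (fraction methylated, in [0, 1]) together
with a sample sheet describing which individual, sample type (e.g. PBMC or
monocyte) and collection day each column comes from.

Epigenetic ages are carried in a long-format :class:`pandas.DataFrame`
("age table") with one row per (sample, clock, normalization, correction)
combination; :data:`AGE_COLUMNS` fixes its schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, ReconciliationError

SAMPLE_SHEET_COLUMNS = ["sample_id", "individual", "sample_type", "day"]

AGE_COLUMNS = [
    "sample_id",
    "individual",
    "sample_type",
    "day",
    "clock_name",
    "normalization",
    "corrected",
    "epigenetic_age",
]

#: Columns that identify one longitudinal series in an age table.
SERIES_KEYS = ["individual", "sample_type", "clock_name", "normalization", "corrected"]


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise DataError(f"sample sheet missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicated sample ids in sample sheet: {dupes}")
    return samples.reset_index(drop=True)


@dataclass
class BetaMatrix:
    """Probes × samples methylation matrix with its sample sheet.

    Parameters
    ----------
    values:
        DataFrame indexed by probe id, one column per sample id, entries the
        beta values in [0, 1] (NaN allowed for missing measurements).
    samples:
        Sample sheet with columns ``sample_id, individual, sample_type, day``.
    normalization:
        Label of the normalization strategy that produced these values
        ("raw" for unnormalized data).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicated probe ids: {dupes[:10]}")
        sheet_ids = list(self.samples["sample_id"])
        matrix_ids = list(self.values.columns)
        if set(sheet_ids) != set(matrix_ids):
            only_sheet = sorted(set(sheet_ids) - set(matrix_ids))
            only_matrix = sorted(set(matrix_ids) - set(sheet_ids))
            raise ReconciliationError(
                "sample sheet and beta matrix disagree: "
                f"sheet-only={only_sheet[:5]}, matrix-only={only_matrix[:5]}"
            )
        # canonical column order follows the sheet
        self.values = self.values.loc[:, sheet_ids]
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((arr < 0.0) | (arr > 1.0))
            r, c = bad[0]
            raise DataError(
                f"beta value out of [0, 1]: probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}, value {arr[r, c]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, normalization: str | None = None) -> "BetaMatrix":
        """Return a copy carrying new values (and optionally a new label)."""
        return BetaMatrix(
            values=values,
            samples=self.samples.copy(),
            normalization=self.normalization if normalization is None else normalization,
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), self.samples.copy(), self.normalization)


def empty_age_table() -> pd.DataFrame:
    return pd.DataFrame(columns=AGE_COLUMNS)


def validate_age_table(ages: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in AGE_COLUMNS if c not in ages.columns]
    if missing:
        raise DataError(f"age table missing columns: {missing}")
    if not np.isfinite(ages["epigenetic_age"].to_numpy(dtype=float)).all():
        raise DataError("age table contains non-finite epigenetic ages")
    return ages
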