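"""Readers and writers for the pipeline's tabular artifacts.

Everything is plain CSV (gzip transparently supported via pandas): beta
matrices with a leading ``probe_id`` column, sample sheets, probe
annotations, phenotypes, cell-type references and gold standards. Reading
validates what writing guarantees, so write→read round trips are lossless
at full float precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SAMPLE_SHEET_COLUMNS, BetaMatrix, validate_sample_sheet
from .errors import DataError, FormatError

_FLOAT_FMT = "%.17g"


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "individual": str, "sample_type": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns: {missing}")
    return validate_sample_sheet(sheet[SAMPLE_SHEET_COLUMNS])


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


def read_beta_matrix(path, sample_sheet_path) -> BetaMatrix:
    """Read a probes × samples CSV (first column probe_id) plus its sample sheet."""
    values = pd.read_csv(path, index_col=0)
    if values.index.name != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id', got {values.index.name!r}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric beta values")
    samples = read_sample_sheet(sample_sheet_path)
    return BetaMatrix(values=values, samples=samples)  # range/reconciliation checks inside


def write_beta_matrix(matrix: BetaMatrix, path, sample_sheet_path=None) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, float_format=_FLOAT_FMT)
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype=str)
    required = ["probe_id", "design_type", "island_relation", "genic_category"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation table {path} missing columns: {missing}")
    if ann["probe_id"].duplicated().any():
        raise FormatError(f"annotation table {path} has duplicated probe ids")
    bad = set(ann["design_type"]) - {"I", "II"}
    if bad:
        raise DataError(f"unknown design types in {path}: {sorted(bad)}")
    return ann[required]


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in pheno.columns:
        raise FormatError(f"phenotype table {path} missing 'sample_id' column")
    if pheno["sample_id"].duplicated().any():
        raise FormatError(f"phenotype table {path} has duplicated sample ids")
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_references(path) -> pd.DataFrame:
    ref = pd.read_csv(path, index_col=0)
    if ref.index.name != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'")
    if ref.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 cell-type columns")
    return ref


def write_references(ref: pd.DataFrame, path) -> None:
    out = ref.copy()
    out.index.name = "probe_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_gold_standard(path) -> pd.Series:
    gold = pd.read_csv(path)
    if list(gold.columns[:2]) != ["probe_id", "beta"]:
        raise FormatError(f"{path}: expected columns probe_id, beta")
    return gold.set_index("probe_id")["beta"].astype(float)


def write_gold_standard(gold: pd.Series, path) -> None:
    gold.rename("beta").rename_axis("probe_id").reset_index().to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_age_table(path) -> pd.DataFrame:
    from .containers import validate_age_table

    return validate_age_table(pd.read_csv(path, dtype={"sample_id": str}))


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)
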