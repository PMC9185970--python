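"""Linear epigenetic clocks and the piecewise log-linear age calibration.

An epigenetic clock is a linear predictor over a fixed panel of CpGs:

    predictor(sample) = intercept + sum_i coef_i * beta_i

First-generation pan-tissue-style clocks are trained on a transformed age
scale that is logarithmic in childhood and linear in adulthood; reading an
age off such a clock requires inverting that calibration
(:func:`inverse_transform`).  Clocks trained directly in years (PhenoAge-style
models) use the identity transform.

Published coefficient files are user-supplied inputs; this module only
defines the representation, the age computation, and CSV round-tripping.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import AGE_COLUMNS, BetaMatrix
from .errors import (
    DataError,
    FormatError,
    InvalidArgumentError,
    MissingProbeError,
)

INTERCEPT_ROW = "(Intercept)"

TRANSFORMS = ("identity", "horvath")
MISSING_POLICIES = ("error", "mean_impute", "drop")


@dataclass(frozen=True)
class ClockDefinition:
    """A linear epigenetic clock.

    Parameters
    ----------
    name:
        Label used to tag rows of the age table.
    intercept:
        Intercept on the transformed-age scale.
    coefficients:
        Mapping CpG id -> coefficient (transformed-age units per beta unit).
    transform:
        ``"identity"`` (predictor already in years) or ``"horvath"``
        (piecewise log-linear calibration; ages obtained via its inverse).
    adult_age:
        Knot of the horvath calibration, in years. Ignored for identity.
    missing_policy:
        What to do when a clock CpG is absent or NaN in the data:
        ``"error"`` (default), ``"mean_impute"`` (fill NaN cells with the
        probe's within-dataset mean) or ``"drop"`` (absent probes contribute
        zero; a warning is emitted).
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    transform: str = "identity"
    adult_age: float = 20.0
    missing_policy: str = "error"

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise InvalidArgumentError("clock must have at least one coefficient")
        if self.transform not in TRANSFORMS:
            raise InvalidArgumentError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )
        if self.transform == "horvath" and not self.adult_age > 0:
            raise InvalidArgumentError("adult_age must be > 0 for the horvath transform")
        if self.missing_policy not in MISSING_POLICIES:
            raise InvalidArgumentError(
                f"unknown missing_policy {self.missing_policy!r}; expected one of {MISSING_POLICIES}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.coefficients)

    @property
    def n_cpgs(self) -> int:
        return len(self.coefficients)


def forward_transform(age, adult_age: float = 20.0):
    """Map age in years to the calibrated training scale.

    Logarithmic below the knot, linear above it::

        f(a) = log(a + 1) - log(adult_age + 1)   for a <= adult_age
        f(a) = (a - adult_age) / (adult_age + 1) for a >  adult_age

    Continuous and strictly increasing on (-1, inf); f(adult_age) = 0.
    """
    if not adult_age > 0:
        raise InvalidArgumentError("adult_age must be > 0")
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1.0):
        raise InvalidArgumentError("age must be > -1 for the log branch")
    out = np.where(
        a <= adult_age,
        np.log1p(a) - np.log1p(adult_age),
        (a - adult_age) / (adult_age + 1.0),
    )
    return out.item() if np.isscalar(age) or np.ndim(age) == 0 else out


def inverse_transform(x, adult_age: float = 20.0):
    """Exact inverse of :func:`forward_transform`, total on the reals."""
    if not adult_age > 0:
        raise InvalidArgumentError("adult_age must be > 0")
    v = np.asarray(x, dtype=float)
    out = np.where(
        v < 0.0,
        (adult_age + 1.0) * np.exp(v) - 1.0,
        (adult_age + 1.0) * v + adult_age,
    )
    return out.item() if np.isscalar(x) or np.ndim(x) == 0 else out


def _clock_betas(betas: BetaMatrix, clock: ClockDefinition) -> pd.DataFrame:
    """Resolve the clock CpG submatrix according to the missing policy."""
    present = [c for c in clock.cpg_ids if c in betas.values.index]
    absent = [c for c in clock.cpg_ids if c not in betas.values.index]
    if absent:
        if clock.missing_policy in ("error", "mean_impute"):
            # mean imputation needs within-dataset data, which an absent
            # probe does not have
            raise MissingProbeError(absent, context=f"clock {clock.name!r}")
        warnings.warn(
            f"clock {clock.name!r}: {len(absent)} CpG(s) absent from the beta "
            "matrix contribute 0 under missing_policy='drop'",
            stacklevel=3,
        )
    sub = betas.values.loc[present]
    if sub.isna().any().any():
        if clock.missing_policy == "mean_impute":
            row_means = sub.mean(axis=1)
            if row_means.isna().any():
                bad = row_means.index[row_means.isna()].tolist()
                raise DataError(f"clock CpGs with no data to impute from: {bad[:10]}")
            sub = sub.apply(lambda col: col.fillna(row_means))
        elif clock.missing_policy == "drop":
            sub = sub.fillna(0.0)  # NaN cells contribute 0, mirroring absent probes
        else:
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise DataError(
                f"non-finite beta at clock CpG(s) {bad[:10]} under missing_policy='error'"
            )
    return sub


def compute_epigenetic_age(
    betas: BetaMatrix,
    clock: ClockDefinition,
    normalization_label: str | None = None,
) -> pd.DataFrame:
    """Compute per-sample epigenetic ages, in years.

    Returns a long-format age table (see :data:`epifluct.containers.AGE_COLUMNS`)
    with one row per sample, tagged by clock name and normalization label.
    """
    label = betas.normalization if normalization_label is None else normalization_label
    sub = _clock_betas(betas, clock)
    coef = np.array([clock.coefficients[c] for c in sub.index], dtype=float)
    predictor = clock.intercept + coef @ sub.to_numpy(dtype=float)
    if clock.transform == "horvath":
        age_years = inverse_transform(predictor, clock.adult_age)
    else:
        age_years = predictor
    out = betas.samples.copy()
    out["clock_name"] = clock.name
    out["normalization"] = label
    out["corrected"] = False
    out["epigenetic_age"] = np.asarray(age_years, dtype=float)
    return out[AGE_COLUMNS]


def save_clock(clock: ClockDefinition, path) -> None:
    """Write a clock as CSV (cpg_id, coefficient) plus a YAML metadata sidecar.

    The intercept is stored as a reserved ``(Intercept)`` row; the sidecar at
    ``<path>.meta.yaml`` carries name, transform, adult_age and missing_policy.
    """
    lines = ["cpg_id,coefficient", f"{INTERCEPT_ROW},{clock.intercept!r}"]
    lines += [f"{cpg},{coef!r}" for cpg, coef in clock.coefficients.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    meta = {
        "name": clock.name,
        "transform": clock.transform,
        "adult_age": clock.adult_age,
        "missing_policy": clock.missing_policy,
    }
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_clock(path) -> ClockDefinition:
    """Read a clock written by :func:`save_clock`; exact round trip.

    Raises :class:`FormatError` with a line number on duplicate CpG ids,
    missing columns or unparseable coefficients. A missing sidecar falls back
    to an identity-transform clock named after the file.
    """
    import os

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError("empty clock file")
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != ["cpg_id", "coefficient"]:
        raise FormatError(
            f"expected header 'cpg_id,coefficient', got {lines[0]!r}", line=1
        )
    intercept = 0.0
    saw_intercept = False
    coefficients: dict[str, float] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise FormatError(f"expected 2 fields, got {len(parts)}", line=lineno)
        cpg, value = parts[0].strip(), parts[1].strip()
        try:
            coef = float(value)
        except ValueError:
            raise FormatError(f"unparseable coefficient {value!r}", line=lineno) from None
        if cpg == INTERCEPT_ROW:
            if saw_intercept:
                raise FormatError("duplicate (Intercept) row", line=lineno)
            intercept, saw_intercept = coef, True
        else:
            if cpg in coefficients:
                raise FormatError(f"duplicate cpg id {cpg!r}", line=lineno)
            coefficients[cpg] = coef
    meta_path = f"{path}.meta.yaml"
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    else:
        meta = {}
    stem = os.path.splitext(os.path.basename(str(path)))[0]
    return ClockDefinition(
        name=meta.get("name", stem),
        intercept=intercept,
        coefficients=coefficients,
        transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
        missing_policy=meta.get("missing_policy", "error"),
    )
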