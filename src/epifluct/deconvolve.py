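"""Reference-based cell-type deconvolution and composition-corrected ages.

Bulk methylation from a mixed cell population is, to first order, a convex
combination of the cell types' reference profiles; the mixing weights are
recovered per sample by constrained least squares (weights nonnegative,
summing to one) over a panel of discriminating probes.  Apparent epigenetic-
age changes driven purely by composition shifts can then be removed by
regressing each longitudinal age series on the estimated proportions and
keeping the residual (plus the series mean, so ages stay in years and the
series level is untouched).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import AGE_COLUMNS, SERIES_KEYS, BetaMatrix
from .errors import InsufficientDataError, InvalidArgumentError, PairingError
from .fluctuation import fluctuation_summary


def select_discriminating_probes(references: pd.DataFrame, n_probes: int = 100) -> list[str]:
    """Top-N probes by between-reference beta range (the default selection)."""
    spread = references.max(axis=1) - references.min(axis=1)
    return spread.sort_values(ascending=False, kind="stable").index[:n_probes].tolist()


def _simplex_lsq(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """argmin ||A w − y||² subject to w ≥ 0, Σw = 1."""
    k = A.shape[1]
    w0, _ = optimize.nnls(A, y)
    total = w0.sum()
    w0 = w0 / total if total > 0 else np.full(k, 1.0 / k)
    res = optimize.minimize(
        lambda w: 0.5 * np.sum((A @ w - y) ** 2),
        x0=w0,
        jac=lambda w: A.T @ (A @ w - y),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"ftol": 1e-12, "maxiter": 200},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def estimate_proportions(
    betas: BetaMatrix,
    references: pd.DataFrame,
    n_probes: int = 100,
    probe_ids=None,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions.

    Returns a samples × cell-types DataFrame of weights on the simplex.
    Probes are the explicit ``probe_ids`` if given, otherwise the
    ``n_probes`` with the largest between-reference range; they must be
    present in both the beta matrix and the references.
    """
    if references.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 cell types to deconvolve")
    if probe_ids is None:
        candidates = references.index.intersection(betas.values.index)
        probe_ids = select_discriminating_probes(references.loc[candidates], n_probes)
    else:
        probe_ids = list(probe_ids)
        absent = [p for p in probe_ids if p not in references.index or p not in betas.values.index]
        if absent:
            raise InvalidArgumentError(f"selected probes absent from data: {absent[:10]}")
    if len(probe_ids) < references.shape[1]:
        raise InsufficientDataError(
            f"only {len(probe_ids)} discriminating probes for {references.shape[1]} cell types"
        )
    A = references.loc[probe_ids].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < references.shape[1]:
        warnings.warn(
            "reference profiles are collinear on the selected probes; "
            "proportions may not be identifiable",
            stacklevel=2,
        )
    obs = betas.values.loc[probe_ids]
    weights = np.vstack([_simplex_lsq(A, obs[c].to_numpy(dtype=float)) for c in obs.columns])
    out = pd.DataFrame(weights, index=obs.columns, columns=references.columns)
    out.index.name = "sample_id"
    return out


def correct_age_for_composition(
    ages: pd.DataFrame,
    proportions: pd.DataFrame,
    min_extra_samples: int = 2,
) -> pd.DataFrame:
    """Residualize each age series on cell proportions, preserving its mean.

    Within every (individual, sample_type, clock, normalization) series the
    corrected age is the OLS residual of age on the proportions (most
    abundant cell type dropped as the simplex baseline; zero-variance
    regressors dropped) plus the series mean. Rows return with
    ``corrected=True``.
    """
    missing = [s for s in ages["sample_id"] if s not in proportions.index]
    if missing:
        raise PairingError(f"samples without estimated proportions: {missing[:10]}")
    n_cell = proportions.shape[1]
    # baseline: drop the most abundant cell type to break sum-to-one collinearity
    baseline = proportions.mean(axis=0).idxmax()
    predictors = proportions.drop(columns=baseline)

    out_groups = []
    for _, group in ages.groupby(SERIES_KEYS, sort=False, observed=True):
        g = group.sort_values("day")
        n = len(g)
        if n < n_cell + min_extra_samples:
            raise InsufficientDataError(
                f"series has {n} samples; need >= {n_cell + min_extra_samples} to correct"
            )
        y = g["epigenetic_age"].to_numpy(dtype=float)
        X = predictors.loc[g["sample_id"]].to_numpy(dtype=float)
        keep = X.std(axis=0) > 1e-12
        corrected = g.copy()
        if keep.any():
            Xk = X[:, keep]
            design = np.column_stack([np.ones(n), Xk])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            corrected["epigenetic_age"] = resid + y.mean()
        # no varying regressor -> composition cannot explain anything; unchanged
        corrected["corrected"] = True
        out_groups.append(corrected)
    return pd.concat(out_groups, ignore_index=True)[AGE_COLUMNS]


def compare_corrected_uncorrected(
    ages_uncorrected: pd.DataFrame,
    ages_corrected: pd.DataFrame,
) -> pd.DataFrame:
    """Side-by-side fluctuation indices for matched corrected/uncorrected series.

    Returns one row per series with uncorrected and corrected range, CV and
    max daily change, plus their deltas (corrected − uncorrected).
    """
    keys = [k for k in SERIES_KEYS if k != "corrected"]
    unc = fluctuation_summary(ages_uncorrected).summary.set_index(keys)
    cor = fluctuation_summary(ages_corrected).summary.set_index(keys)
    if set(unc.index) != set(cor.index):
        raise PairingError(
            f"series mismatch: only-uncorrected={sorted(set(unc.index) - set(cor.index))[:3]}, "
            f"only-corrected={sorted(set(cor.index) - set(unc.index))[:3]}"
        )
    cor = cor.loc[unc.index]
    out = pd.DataFrame(index=unc.index)
    for stat in ("range", "cv", "max_daily_change"):
        out[f"{stat}_uncorrected"] = unc[stat]
        out[f"{stat}_corrected"] = cor[stat]
        out[f"{stat}_delta"] = cor[stat] - unc[stat]
    return out.reset_index()
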