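"""Normalization strategies for Infinium-style beta matrices.

Three strategies are compared downstream:

``raw``
    Passthrough; values tagged "raw".
``bmiq``
    Beta-mixture quantile normalization. The two Infinium chemistries
    measure the same biology with different dynamic ranges: type II betas
    are compressed toward 0.5 relative to type I. Per sample, three-state
    beta mixtures (unmethylated / hemimethylated / methylated) are fitted
    separately to type I and type II probes; type II probes are then
    quantile-mapped state-by-state onto the type I distributions, leaving
    type I probes untouched.
``gold_standard``
    Per-sample monotone quantile mapping of each sample's betas onto a
    reference ("gold standard") distribution, calibrating a dataset toward
    a common target.

The EM fit maximizes the weighted beta log-likelihood exactly in the M-step
(bounded quasi-Newton on log shape parameters, candidate accepted only when
it improves the objective), so the log-likelihood trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import beta as beta_dist

from .containers import BetaMatrix
from .errors import (
    AnnotationError,
    CoverageError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
)

_CLAMP = 1e-6

STRATEGIES = ("raw", "bmiq", "gold_standard")


@dataclass
class BetaMixtureFit:
    """A fitted three-state beta mixture, states ordered by mean ascending."""

    weights: np.ndarray  # (3,) simplex
    a: np.ndarray  # (3,) shape parameters, > 0
    b: np.ndarray  # (3,)
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0

    @property
    def state_means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return sum(
            w * beta_dist.pdf(x, ai, bi) for w, ai, bi in zip(self.weights, self.a, self.b)
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dens = np.column_stack(
            [w * beta_dist.pdf(x, ai, bi) for w, ai, bi in zip(self.weights, self.a, self.b)]
        )
        dens = np.clip(dens, 1e-300, None)
        return dens / dens.sum(axis=1, keepdims=True)


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), _CLAMP, 1.0 - _CLAMP)


def _weighted_beta_mle(
    x: np.ndarray, r: np.ndarray, a0: float, b0: float
) -> tuple[float, float]:
    """Maximize sum(r * log Beta(x; a, b)) over a, b > 0, warm-started.

    Returns the previous parameters unless the candidate strictly improves
    the weighted objective (this keeps the EM ascent property airtight).
    """
    w = r.sum()
    if w <= 0:
        return a0, b0
    s_log_x = float(r @ np.log(x))
    s_log_1mx = float(r @ np.log1p(-x))

    def neg_obj(theta):
        a, b = np.exp(theta)
        from scipy.special import betaln

        return -((a - 1.0) * s_log_x + (b - 1.0) * s_log_1mx - w * betaln(a, b))

    res = optimize.minimize(
        neg_obj,
        x0=np.log([a0, b0]),
        method="L-BFGS-B",
        bounds=[(-10.0, 10.0)] * 2,
    )
    if res.fun < neg_obj(np.log([a0, b0])) - 1e-12:
        a, b = np.exp(res.x)
        return float(a), float(b)
    return a0, b0


def _moment_init(x: np.ndarray) -> tuple[float, float]:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-6)
    common = m * (1.0 - m) / v - 1.0
    common = max(common, 0.1)
    return max(m * common, 0.05), max((1.0 - m) * common, 0.05)


def _band_params(x: np.ndarray, edges: np.ndarray, n_states: int):
    a = np.empty(n_states)
    b = np.empty(n_states)
    for k in range(n_states):
        band = x[(x >= edges[k]) & (x <= edges[k + 1])]
        if band.size < 2:
            band = x
        a[k], b[k] = _moment_init(band)
    return a, b


def _em_run(x, a, b, weights, max_iter, tol) -> BetaMixtureFit:
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = np.column_stack(
            [w * beta_dist.pdf(x, ak, bk) for w, ak, bk in zip(weights, a, b)]
        )
        dens = np.clip(dens, 1e-300, None)
        total = dens.sum(axis=1)
        ll = float(np.log(total).sum())
        trace.append(ll)
        resp = dens / total[:, None]
        weights = resp.mean(axis=0)
        for k in range(len(a)):
            a[k], b[k] = _weighted_beta_mle(x, resp[:, k], a[k], b[k])
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * (abs(prev) + 1.0):
                converged = True
                break
    order = np.argsort(a / (a + b))
    return BetaMixtureFit(
        weights=weights[order],
        a=a[order],
        b=b[order],
        log_likelihood_trace=trace,
        converged=converged,
        n_iterations=it,
    )


def fit_beta_mixture(
    values,
    n_states: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 0,
) -> BetaMixtureFit:
    """Fit an ``n_states``-component beta mixture by EM.

    ``values`` must be at least 30 betas strictly inside (0, 1) after
    clamping. Two deterministic initializations are tried — conventional
    methylation bands (0.25 / 0.75 cutoffs) and empirical quantile bands —
    plus ``n_restarts`` seeded random ones; the fit with the highest final
    log-likelihood wins, which guards against the local optima either init
    alone can fall into. With ``n_restarts=0`` (default) the result is a
    deterministic function of the data.
    """
    x = _clamp(np.asarray(values, dtype=float))
    if x.size < 30:
        raise InsufficientDataError(f"need >= 30 values to fit a mixture, got {x.size}")
    if np.ptp(x) < 1e-12:
        raise DegenerateInputError("all values identical; beta mixture is undefined")
    if n_states < 1:
        raise InvalidArgumentError("n_states must be >= 1")

    inits = [np.quantile(x, np.linspace(0, 1, n_states + 1))]
    if n_states == 3:
        inits.insert(0, np.array([0.0, 0.25, 0.75, 1.0]))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        interior = np.sort(rng.uniform(x.min(), x.max(), n_states - 1))
        inits.append(np.concatenate([[0.0], interior, [1.0]]))

    best: BetaMixtureFit | None = None
    for edges in inits:
        a, b = _band_params(x, edges, n_states)
        fit = _em_run(x, a, b, np.full(n_states, 1.0 / n_states), max_iter, tol)
        if best is None or fit.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]:
            best = fit
    return best


def _mixture_cdf(fit: BetaMixtureFit, x: np.ndarray) -> np.ndarray:
    return sum(
        w * beta_dist.cdf(x, ai, bi) for w, ai, bi in zip(fit.weights, fit.a, fit.b)
    )


_GRID = np.linspace(_CLAMP, 1.0 - _CLAMP, 4001)


def _mixture_quantile_map(fit_from: BetaMixtureFit, fit_to: BetaMixtureFit,
                          x: np.ndarray) -> np.ndarray:
    """Monotone map sending the ``fit_from`` distribution onto ``fit_to``.

    ``x' = F_to^{-1}(F_from(x))`` with both CDFs the full fitted three-state
    mixtures; the inverse is evaluated by interpolation on a dense grid.
    Using the whole mixture rather than a state-by-state map keeps the
    transform well defined even when the likelihood splits one methylation
    mode across two states (the three-state fit is not identifiable on
    strongly bimodal samples, so state indices of two independent fits need
    not correspond).
    """
    q = _mixture_cdf(fit_from, x)
    cdf_to = _mixture_cdf(fit_to, _GRID)
    # enforce strict monotonicity for a well-defined interpolated inverse
    cdf_to = np.maximum.accumulate(cdf_to)
    return np.interp(q, cdf_to, _GRID)


def bmiq_normalize(
    sample_betas: pd.Series,
    design_types: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> pd.Series:
    """Normalize one sample's type II betas onto its type I distribution.

    Type I probes pass through unchanged. Three-state beta mixtures are
    fitted to each design type and type II betas are quantile-mapped through
    the fitted mixture CDFs (``x' = F_I^{-1}(F_II(x))``). The map is
    globally monotone, so the rank order of type II betas is preserved, and
    it is near-identity when the two distributions already agree.
    """
    design_types = design_types.reindex(sample_betas.index)
    if design_types.isna().any():
        missing = design_types.index[design_types.isna()].tolist()
        raise AnnotationError(f"probes without design-type labels: {missing[:10]}")
    mask_I = (design_types == "I").to_numpy()
    mask_II = (design_types == "II").to_numpy()
    if mask_I.sum() < 30 or mask_II.sum() < 30:
        raise InsufficientDataError(
            f"need >= 30 probes of each design type, got I={mask_I.sum()}, II={mask_II.sum()}"
        )

    x_I = _clamp(sample_betas.to_numpy(dtype=float)[mask_I])
    x_II = _clamp(sample_betas.to_numpy(dtype=float)[mask_II])
    fit_I = fit_beta_mixture(x_I, max_iter=max_iter, tol=tol, seed=seed)
    fit_II = fit_beta_mixture(x_II, max_iter=max_iter, tol=tol, seed=seed)

    out = _mixture_quantile_map(fit_II, fit_I, x_II)
    result = sample_betas.copy().astype(float)
    result.iloc[np.flatnonzero(mask_II)] = np.clip(out, 0.0, 1.0)
    return result


def calibrate_to_gold_standard(
    betas: BetaMatrix,
    gold_standard: pd.Series,
    max_missing_fraction: float = 0.05,
) -> BetaMatrix:
    """Quantile-map every sample onto the gold-standard beta distribution.

    Per sample, each beta is replaced by the gold-standard quantile at its
    own rank position ((r − 1)/(n − 1) plotting positions), a monotone map
    that is an exact fixed point when the sample already equals the
    reference. Probes absent from the gold standard (at most
    ``max_missing_fraction`` of the matrix) pass through unchanged.
    """
    covered = betas.values.index.intersection(gold_standard.index)
    missing_frac = 1.0 - len(covered) / max(betas.n_probes, 1)
    if missing_frac > max_missing_fraction:
        raise CoverageError(
            f"gold standard misses {missing_frac:.1%} of probes "
            f"(> {max_missing_fraction:.0%} allowed)"
        )
    gold_sorted = np.sort(gold_standard.to_numpy(dtype=float))
    n_gold = gold_sorted.size

    new_values = betas.values.copy().astype(float)
    sub = new_values.loc[covered]
    n = len(covered)
    for col in sub.columns:
        x = sub[col].to_numpy(dtype=float)
        ranks = stats.rankdata(x, method="average")
        p = (ranks - 1.0) / max(n - 1, 1)
        mapped = np.interp(p * (n_gold - 1), np.arange(n_gold), gold_sorted)
        new_values.loc[covered, col] = np.clip(mapped, 0.0, 1.0)
    return betas.with_values(new_values, normalization="gold_standard")


def normalize(
    betas: BetaMatrix,
    strategy: str,
    annotations: pd.DataFrame | None = None,
    gold_standard: pd.Series | None = None,
    **kwargs,
) -> BetaMatrix:
    """Dispatch to one of the normalization strategies.

    ``raw`` returns the matrix unchanged (label "raw"); ``bmiq`` requires
    ``annotations`` with a design_type column and is applied per sample;
    ``gold_standard`` requires a per-probe reference Series.
    """
    if strategy not in STRATEGIES:
        raise InvalidArgumentError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "raw":
        return betas.with_values(betas.values.copy(), normalization="raw")
    if strategy == "bmiq":
        if annotations is None:
            raise AnnotationError("bmiq requires a probe annotation table")
        design_types = annotations.set_index("probe_id")["design_type"]
        new_values = betas.values.copy().astype(float)
        for col in new_values.columns:
            new_values[col] = bmiq_normalize(new_values[col], design_types, **kwargs)
        return betas.with_values(new_values, normalization="bmiq")
    if gold_standard is None:
        raise InvalidArgumentError("gold_standard strategy requires a reference Series")
    return calibrate_to_gold_standard(betas, gold_standard, **kwargs)
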