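"""Characterization of clock CpGs: longitudinal SD, contribution, and tests.

Whether apparent age fluctuation is biology or noise can be probed through
the clock CpGs themselves.  Each CpG's longitudinal beta SD measures how much
it moves within a person; its *contribution* to age fluctuation is
|coefficient| × SD — a CpG only moves the age estimate insofar as the clock
weights it.  Quartile groups (variable/stable by SD, high/low by
contribution) are then compared on array annotations: CpG-island relation
and genic category via Pearson chi-squared on the 2 × k contingency table
(Bonferroni-adjusted threshold reported alongside), Infinium design type via
a two-sided Wilcoxon–Mann–Whitney test on the contributions, plus generic
hypergeometric set enrichment over user-supplied term maps.

A diagnostic Spearman correlation between |coefficient| and SD checks the
defensive pattern of published clocks: CpGs with large day-to-day SDs tend
to carry small coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clocks import ClockDefinition
from .containers import BetaMatrix
from .errors import (
    AnnotationError,
    DataError,
    InsufficientDataError,
    InvalidArgumentError,
)

ANNOTATION_AXES = ("island_relation", "genic_category")


def clock_cpg_sd(
    betas: BetaMatrix,
    clock: ClockDefinition,
    grouping: str = "mean",
) -> pd.Series:
    """Longitudinal SD of each clock CpG's beta values.

    The SD (sample formula, n−1) is computed across time points within each
    (individual, sample_type) series, then combined across series:
    ``grouping="mean"`` (default) averages them; ``"max"`` takes the largest;
    ``"pooled"`` computes one SD over all samples, ignoring series structure.
    """
    from .clocks import _clock_betas

    sub = _clock_betas(betas, clock)

    def _row_sd(frame: pd.DataFrame) -> pd.Series:
        x = frame.to_numpy(dtype=float)
        # anchor at the first column so constant rows give an exact 0
        x = x - x[:, :1]
        return pd.Series(x.std(axis=1, ddof=1), index=frame.index)

    if grouping == "pooled":
        return _row_sd(sub).rename("sd")
    sheet = betas.samples.set_index("sample_id")
    per_series = []
    for (_, _), cols in sheet.groupby(["individual", "sample_type"], observed=True):
        ids = [c for c in cols.index if c in sub.columns]
        if len(ids) < 2:
            raise InsufficientDataError("each series needs >= 2 time points for an SD")
        per_series.append(_row_sd(sub[ids]))
    stacked = pd.concat(per_series, axis=1)
    if grouping == "mean":
        return stacked.mean(axis=1).rename("sd")
    if grouping == "max":
        return stacked.max(axis=1).rename("sd")
    raise InvalidArgumentError(f"unknown grouping {grouping!r}")


def assign_quartile_groups(
    values: pd.Series,
    top_label: str = "top",
    bottom_label: str = "bottom",
    middle_label: str = "middle",
) -> pd.Series:
    """Label the top and bottom floor(n/4) entries of a per-CpG statistic.

    Ties are broken deterministically by a stable sort on (value, probe id),
    so group sizes are exactly floor(n/4) regardless of ties.
    """
    n = len(values)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 CpGs to form quartile groups, got {n}")
    k = n // 4
    ordered = values.to_frame("v").assign(pid=values.index.astype(str))
    ordered = ordered.sort_values(["v", "pid"], kind="stable")
    labels = pd.Series(middle_label, index=values.index, name="group")
    labels.loc[ordered.index[:k]] = bottom_label
    labels.loc[ordered.index[-k:]] = top_label
    return labels


def compute_contributions(clock: ClockDefinition, sds: pd.Series) -> pd.DataFrame:
    """Per-CpG contribution table: |coefficient| × SD with quartile labels.

    ``sd_group`` marks variable (top 25% by SD) vs stable (bottom 25%) CpGs;
    ``contribution_group`` marks high vs low contributions. The absolute
    coefficient is used: a CpG's influence on fluctuation is a magnitude.
    """
    missing = [c for c in clock.cpg_ids if c not in sds.index]
    if missing:
        raise DataError(f"no SD available for clock CpG(s): {missing[:10]}")
    coef = pd.Series(clock.coefficients)
    sd = sds.loc[coef.index].astype(float)
    if sd.isna().any():
        raise DataError(f"NaN SDs for: {sd.index[sd.isna()].tolist()[:10]}")
    table = pd.DataFrame(
        {
            "coefficient": coef,
            "sd": sd,
            "contribution": coef.abs() * sd,
        }
    )
    table.index.name = "probe_id"
    table["sd_group"] = assign_quartile_groups(table["sd"], "variable", "stable")
    table["contribution_group"] = assign_quartile_groups(table["contribution"], "high", "low")
    return table


def annotation_proportion_test(
    group_a,
    group_b,
    annotations: pd.DataFrame,
    axis: str,
    alpha: float = 0.05,
    n_tests: int = 6,
) -> dict:
    """Pearson chi-squared test of annotation proportions between CpG groups.

    Builds the 2 × k contingency table of ``axis`` categories for the two
    disjoint CpG sets and tests homogeneity without continuity correction.
    The Bonferroni-adjusted significance threshold ``alpha / n_tests`` is
    reported alongside (the study's design is 3 clocks × 2 sample types = 6
    tests, hence the default 0.05/6 ≈ 0.008). Any expected cell below 1
    attaches a low-count warning flag.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise InvalidArgumentError("both CpG groups must be non-empty")
    if group_a & group_b:
        raise InvalidArgumentError("CpG groups must be disjoint")
    if axis not in ANNOTATION_AXES:
        raise InvalidArgumentError(f"axis must be one of {ANNOTATION_AXES}")
    ann = annotations.set_index("probe_id")[axis]
    unannotated = (group_a | group_b) - set(ann.index)
    if unannotated:
        raise AnnotationError(f"unannotated CpGs: {sorted(unannotated)[:10]}")
    cats = sorted(set(ann.loc[list(group_a | group_b)]))
    counts = np.array(
        [
            [int((ann.loc[list(g)] == c).sum()) for c in cats]
            for g in (group_a, group_b)
        ],
        dtype=float,
    )
    # drop categories absent from both groups (degenerate columns)
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.shape[1] < 2:
        raise InsufficientDataError("need at least 2 annotation categories with members")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    return {
        "axis": axis,
        "chi2": float(chi2),
        "dof": int(dof),
        "p": float(p),
        "alpha": alpha,
        "n_tests": n_tests,
        "bonferroni_threshold": alpha / n_tests,
        "significant": bool(p < alpha / n_tests),
        "low_expected_count": bool((expected < 1).any()),
        "categories": [c for c, k in zip(cats, keep) if k],
        "counts": counts.astype(int).tolist(),
    }


def probe_type_contribution_test(
    contributions: pd.DataFrame,
    annotations: pd.DataFrame,
    exact_max_n: int = 20,
) -> dict:
    """Wilcoxon–Mann–Whitney test of contribution between Infinium I and II CpGs.

    Two-sided rank-sum test of the per-CpG contributions grouped by design
    type. The exact null distribution is used for combined n ≤ 20 without
    ties; otherwise the normal approximation with tie correction.
    """
    ann = annotations.set_index("probe_id")["design_type"].reindex(contributions.index)
    if ann.isna().any():
        raise AnnotationError(
            f"clock CpGs without design-type annotation: {ann.index[ann.isna()].tolist()[:10]}"
        )
    x = contributions.loc[ann == "I", "contribution"].to_numpy(dtype=float)
    y = contributions.loc[ann == "II", "contribution"].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError(
            f"both design types required among clock CpGs (I={x.size}, II={y.size})"
        )
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(combined) == 0.0:
        # complete tie: no evidence either way
        return {"U": float(x.size * y.size / 2.0), "p": 1.0, "n_I": x.size, "n_II": y.size,
                "method": "degenerate"}
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_I": int(x.size),
        "n_II": int(y.size),
        "method": method,
    }


def enrichment_test(
    target,
    background,
    term_map: dict,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric (upper-tail) set enrichment over supplied term maps.

    For each term, tests whether the overlap between the target CpG set and
    the term's probes exceeds expectation given the background universe:
    p = P[X ≥ overlap] with X hypergeometric(N, K, n). Terms are restricted
    to the background. ``correction`` is "bonferroni" or "bh".
    """
    target, background = set(target), set(background)
    if not target <= background:
        raise InvalidArgumentError("target must be a subset of the background")
    if correction not in ("bonferroni", "bh"):
        raise InvalidArgumentError("correction must be 'bonferroni' or 'bh'")
    N, n = len(background), len(target)
    rows = []
    for term, probes in term_map.items():
        in_bg = set(probes) & background
        K = len(in_bg)
        if K == 0:
            continue
        overlap = len(in_bg & target)
        expected = n * K / N
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append(
            {"term": term, "term_size": K, "overlap": overlap, "expected": expected, "p": p}
        )
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "expected", "p"])
    if len(out):
        method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        out["adjusted_p"] = multipletests(out["p"].to_numpy(), method=method)[1]
    else:
        out["adjusted_p"] = []
    return out


def coefficient_vs_sd_diagnostic(clock: ClockDefinition, sds: pd.Series) -> dict:
    """Spearman correlation between |coefficient| and longitudinal SD.

    Published clocks tend to assign small coefficients to CpGs with large
    within-person SDs; a clearly negative rho reproduces that pattern.
    Returns the scatter table alongside for plotting/export.
    """
    if clock.n_cpgs < 5:
        raise InsufficientDataError("need >= 5 CpGs for the diagnostic")
    coef = pd.Series(clock.coefficients)
    missing = coef.index.difference(sds.index)
    if len(missing):
        raise DataError(f"no SD for clock CpG(s): {missing.tolist()[:10]}")
    sd = sds.loc[coef.index].astype(float)
    scatter = pd.DataFrame({"abs_coefficient": coef.abs(), "sd": sd})
    scatter.index.name = "probe_id"
    if np.ptp(sd.to_numpy()) == 0.0 or np.ptp(coef.abs().to_numpy()) == 0.0:
        return {"rho": np.nan, "p": np.nan, "undefined": True, "scatter": scatter}
    rho, p = stats.spearmanr(coef.abs(), sd)
    return {"rho": float(rho), "p": float(p), "undefined": False, "scatter": scatter}
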