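"""Association between epigenetic ages and per-sample phenotypes.

Each (clock, sample type, normalization, correction) age series is regressed
on each blood-test item by ordinary least squares (age ~ phenotype), with a
two-sided t-test on the slope and multiple-testing correction across all
tests in the run.  The series are short autocorrelated within-person time
series, so the p-values are descriptive rather than confirmatory; the output
flags this via the ``model`` metadata column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError

ASSOC_KEYS = ["clock_name", "sample_type", "normalization", "corrected"]


def associate(
    ages: pd.DataFrame,
    phenotypes: pd.DataFrame,
    correction: str = "bonferroni",
    min_samples: int = 5,
) -> pd.DataFrame:
    """OLS of epigenetic age on every phenotype item within every series group.

    ``phenotypes`` has a ``sample_id`` column plus one column per item;
    missing values are dropped pairwise per item. Combinations with fewer
    than ``min_samples`` overlapping observations or a zero-variance
    phenotype are reported with a ``skipped`` flag instead of a fit.
    Adjusted p-values use Bonferroni (default) or Benjamini–Hochberg across
    all performed tests.
    """
    if correction not in ("bonferroni", "bh"):
        raise InvalidArgumentError("correction must be 'bonferroni' or 'bh'")
    items = [c for c in phenotypes.columns if c != "sample_id"]
    if not items:
        raise InvalidArgumentError("phenotype table has no items")
    pheno = phenotypes.set_index("sample_id")

    rows = []
    for key, group in ages.groupby(ASSOC_KEYS, sort=True, observed=True):
        meta = dict(zip(ASSOC_KEYS, key))
        merged = group.set_index("sample_id")
        for item in items:
            x = pheno[item].reindex(merged.index)
            y = merged["epigenetic_age"]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            row = {**meta, "item": item, "n": n, "model": "ols_age_on_phenotype"}
            if n < min_samples:
                row.update(skipped=True, reason="too_few_samples", slope=np.nan, se=np.nan,
                           t=np.nan, p=np.nan)
            elif float(x[ok].std(ddof=1)) == 0.0:
                row.update(skipped=True, reason="zero_variance_phenotype", slope=np.nan,
                           se=np.nan, t=np.nan, p=np.nan)
            else:
                res = stats.linregress(x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float))
                if res.stderr > 0:
                    t, p = res.slope / res.stderr, res.pvalue
                elif res.slope == 0.0:  # constant age series: nothing to explain
                    t, p = 0.0, 1.0
                else:  # exact linear relationship
                    t, p = np.sign(res.slope) * np.inf, 0.0
                row.update(
                    skipped=False,
                    reason="",
                    slope=float(res.slope),
                    se=float(res.stderr),
                    t=float(t),
                    p=float(p),
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["adjusted_p"] = np.nan
    if tested.any():
        method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        out.loc[tested, "adjusted_p"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method=method
        )[1]
    return out
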