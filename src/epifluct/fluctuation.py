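"""Within-person fluctuation indices for longitudinal epigenetic ages.

For every (individual, sample type, clock, normalization, correction)
series observed at increasing collection days, three indices summarize how
much the estimated age moves without any intervention:

range
    oldest minus youngest age across the whole observation window (years);
CV
    coefficient of variation, sample SD (n−1 denominator) over the mean;
max daily change
    the largest absolute age difference between two collections exactly one
    day apart — the sharpest possible "overnight" change the series shows.
    Consecutive-pair differences at all gaps are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SERIES_KEYS
from .errors import InsufficientDataError, OrderingError, PairingError


@dataclass
class FluctuationSummary:
    """Per-series fluctuation indices plus all consecutive-pair differences.

    ``summary`` has one row per series with columns range, cv,
    max_daily_change (NaN when no one-day pair exists, with
    ``daily_change_defined`` False) and mean_age. ``consecutive_diffs`` is a
    long table of (day_from, day_to, gap, delta) per series.
    """

    summary: pd.DataFrame
    consecutive_diffs: pd.DataFrame


def _series_stats(g: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    g = g.sort_values("day", kind="stable")
    days = g["day"].to_numpy()
    if len(days) < 2:
        raise InsufficientDataError("a series needs at least 2 time points")
    if (np.diff(days) <= 0).any():
        raise OrderingError(f"non-increasing days within a series: {days.tolist()}")
    ages = g["epigenetic_age"].to_numpy(dtype=float)
    deltas = np.diff(ages)
    gaps = np.diff(days)
    diffs = pd.DataFrame(
        {"day_from": days[:-1], "day_to": days[1:], "gap": gaps, "delta": deltas}
    )
    one_day = np.abs(deltas[gaps == 1])
    mean_age = ages.mean()
    # anchored at the first value so constant series give exactly sd = 0
    sd = (ages - ages[0]).std(ddof=1)
    row = {
        "range": float(ages.max() - ages.min()),
        "cv": float(sd / mean_age) if mean_age != 0 else np.nan,
        "mean_age": float(mean_age),
        "max_daily_change": float(one_day.max()) if one_day.size else np.nan,
        "daily_change_defined": bool(one_day.size),
        "n_timepoints": int(len(ages)),
    }
    return row, diffs


def fluctuation_summary(ages: pd.DataFrame) -> FluctuationSummary:
    """Compute range, CV and maximum daily change for every series."""
    rows = []
    diff_frames = []
    for key, group in ages.groupby(SERIES_KEYS, sort=True, observed=True):
        row, diffs = _series_stats(group)
        meta = dict(zip(SERIES_KEYS, key))
        rows.append({**meta, **row})
        diffs = diffs.assign(**meta)
        diff_frames.append(diffs)
    summary = pd.DataFrame(rows)
    consecutive = (
        pd.concat(diff_frames, ignore_index=True)
        if diff_frames
        else pd.DataFrame(columns=[*SERIES_KEYS, "day_from", "day_to", "gap", "delta"])
    )
    return FluctuationSummary(summary=summary, consecutive_diffs=consecutive)


def compare_sample_types(
    ages: pd.DataFrame,
    type_a: str,
    type_b: str,
) -> pd.DataFrame:
    """Paired t-test of epigenetic age between two sample types.

    Within each (individual, clock, normalization, corrected) combination,
    ages are paired by collection day; days observed in only one sample type
    are dropped and counted. Two-sided classical paired t-test. A series of
    zero-variance differences is reported (not raised) with a degenerate
    flag: t = 0 and p = 1 when all differences are exactly zero, t = ±inf
    and p = 0 otherwise.
    """
    keys = ["individual", "clock_name", "normalization", "corrected"]
    present = set(ages["sample_type"])
    if type_a not in present or type_b not in present:
        raise PairingError(f"sample types {type_a!r}/{type_b!r} not both present in the age table")
    rows = []
    for key, group in ages.groupby(keys, sort=True, observed=True):
        a = group[group["sample_type"] == type_a].set_index("day")["epigenetic_age"]
        b = group[group["sample_type"] == type_b].set_index("day")["epigenetic_age"]
        if a.empty or b.empty:
            continue
        shared = a.index.intersection(b.index)
        n_dropped = (len(a) - len(shared)) + (len(b) - len(shared))
        if len(shared) < 3:
            raise InsufficientDataError(
                f"only {len(shared)} paired days for {dict(zip(keys, key))}"
            )
        diffs = (a.loc[shared] - b.loc[shared]).to_numpy(dtype=float)
        n = diffs.size
        if diffs.std(ddof=1) == 0.0:
            degenerate = True
            if np.all(diffs == 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(diffs.mean()) * np.inf), 0.0
        else:
            degenerate = False
            t, p = stats.ttest_rel(a.loc[shared], b.loc[shared])
            t, p = float(t), float(p)
        rows.append(
            {
                **dict(zip(keys, key)),
                "sample_type_a": type_a,
                "sample_type_b": type_b,
                "t": t,
                "dof": n - 1,
                "p": p,
                "n_pairs": n,
                "n_dropped": n_dropped,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
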