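"""Relate epigenetic ages to blood-test phenotypes.

OLS of age on each phenotype item within every (clock, sample type,
normalization, correction) series, Bonferroni-corrected across all tests.
The simulation links one item (gamma_gtp) to the latent mixture-age signal,
so the linked item should surface while the pure-noise items stay null.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from epifluct import io as eio
from epifluct.association import associate
from epifluct.deconvolve import correct_age_for_composition

DATA_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis", "data")
RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main() -> None:
    ages = eio.read_age_table(os.path.join(DATA_DIR, "ages.csv"))
    corrected = eio.read_age_table(os.path.join(DATA_DIR, "ages_corrected.csv"))
    phenotypes = eio.read_phenotypes(os.path.join(DATA_DIR, "phenotypes.csv"))

    all_ages = pd.concat([ages, corrected], ignore_index=True)
    result = associate(all_ages, phenotypes, correction="bonferroni")
    eio.write_table(result, os.path.join(RESULTS_DIR, "associations.csv"))

    tested = result[~result["skipped"]]
    hits = tested[tested["adjusted_p"] < 0.05]
    print(f"{len(tested)} tests; {len(hits)} significant after Bonferroni:")
    cols = ["clock_name", "sample_type", "normalization", "corrected", "item",
            "slope", "p", "adjusted_p", "n"]
    if len(hits):
        print(hits[cols].round(4).to_string(index=False))
    by_item = tested.groupby("item", observed=True)["p"].median().round(4)
    print("\nmedian p by phenotype item (gamma_gtp is the linked item):")
    print(by_item.to_string())


if __name__ == "__main__":
    main()
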