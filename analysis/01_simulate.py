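"""Generate the synthetic longitudinal methylation study.

Emulates the design the analysis assumes: 2 individuals x 2 sample types
(a composition-drifting PBMC-like mixture, a purified monocyte-like
population) x 24 collection days over ~3 months, with three clocks whose
coefficient magnitudes are inversely coupled to per-CpG fluctuation SDs.

Writes the beta matrix, sample sheet, clocks, annotations, references,
phenotypes and ground-truth tables under scratch/analysis/data/ (inputs for
the numbered scripts that follow) and a small design summary under
results/analysis/.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np
import pandas as pd

from epifluct import io as eio
from epifluct.clocks import save_clock
from epifluct.pipeline import RunConfig
from epifluct.simulate import (
    generate_annotations,
    generate_cell_references,
    generate_clock,
    generate_longitudinal_betas,
    generate_phenotypes,
    generate_study_design,
)

SEED = 20220609
DATA_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "analysis", "data")
RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main() -> None:
    os.makedirs(DATA_DIR, exist_ok=True)
    os.makedirs(RESULTS_DIR, exist_ok=True)
    config = RunConfig(seed=SEED)
    rng = np.random.default_rng(SEED)

    design = generate_study_design(2, 2, 24, seed=int(rng.integers(2**31)))
    references = generate_cell_references(
        config.n_cell_types, config.n_probes, config.separation,
        seed=int(rng.integers(2**31)),
    )

    offset = 0
    clock_sds = []
    for spec in config.clocks:
        transform = ("horvath", spec.adult_age) if spec.transform == "horvath" else "identity"
        gen = generate_clock(
            spec.n_cpgs, 0.0, ("normal", spec.coef_mu, spec.coef_sigma),
            transform=transform, coupling=spec.coupling,
            seed=int(rng.integers(2**31)), name=spec.name, cpg_offset=offset,
            center_age=spec.center_age,
        )
        save_clock(gen.clock, os.path.join(DATA_DIR, f"clock_{spec.name}.csv"))
        clock_sds.append(gen.fluctuation_sd)
        if offset == 0:
            primary = gen
        offset += spec.n_cpgs

    matrix, truth = generate_longitudinal_betas(
        design, primary.clock, references,
        fluctuation={"ar1": config.ar1, "sd": pd.concat(clock_sds)},
        probe_noise=config.probe_noise, seed=int(rng.integers(2**31)),
    )
    annotations = generate_annotations(list(matrix.probe_ids), seed=int(rng.integers(2**31)))
    phenotypes = generate_phenotypes(
        design, truth.true_latent_age_signal.loc[matrix.sample_ids],
        effect=config.phenotype_effect, noise_sd=config.phenotype_noise_sd,
        seed=int(rng.integers(2**31)),
    )

    eio.write_beta_matrix(matrix, os.path.join(DATA_DIR, "betas.csv"),
                          os.path.join(DATA_DIR, "sample_sheet.csv"))
    eio.write_annotations(annotations, os.path.join(DATA_DIR, "annotations.csv"))
    eio.write_references(references.profiles, os.path.join(DATA_DIR, "references.csv"))
    eio.write_phenotypes(phenotypes, os.path.join(DATA_DIR, "phenotypes.csv"))
    eio.write_table(truth.true_cell_proportions.reset_index(),
                    os.path.join(DATA_DIR, "truth_proportions.csv"))
    eio.write_table(
        truth.fluctuation_sd.rename("fluctuation_sd").rename_axis("probe_id").reset_index(),
        os.path.join(DATA_DIR, "truth_fluctuation_sd.csv"),
    )

    summary = pd.DataFrame(
        [
            {
                "n_individuals": len(design.individuals),
                "n_sample_types": len(design.sample_types),
                "n_timepoints": design.n_timepoints,
                "n_samples": design.n_samples,
                "n_probes": matrix.n_probes,
                "span_days": design.collection_days[-1] - design.collection_days[0],
                "n_one_day_gaps": int((np.diff(design.collection_days) == 1).sum()),
            }
        ]
    )
    eio.write_table(summary, os.path.join(RESULTS_DIR, "design_summary.csv"))
    print(summary.to_string(index=False))
    print(f"wrote simulated study to {os.path.abspath(DATA_DIR)}")


if __name__ == "__main__":
    main()
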