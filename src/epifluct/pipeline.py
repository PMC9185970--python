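"""End-to-end pipeline: simulate → normalize → age → deconvolve → summarize.

The default configuration reproduces the study design this package emulates:
2 individuals × 2 sample types (a composition-drifting PBMC-like mixture and
a purified monocyte-like population) × 24 collection days spanning roughly
three months, three synthetic clocks with inverse coefficient–SD coupling,
and three normalization strategies (raw, BMIQ, gold-standard calibration).

Everything is deterministic given the seed; a JSON run manifest records the
configuration hash and package version alongside the output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .association import associate
from .clocks import compute_epigenetic_age
from .containers import BetaMatrix
from .cpgs import (
    annotation_proportion_test,
    clock_cpg_sd,
    coefficient_vs_sd_diagnostic,
    compute_contributions,
    probe_type_contribution_test,
)
from .deconvolve import (
    compare_corrected_uncorrected,
    correct_age_for_composition,
    estimate_proportions,
)
from .errors import EpifluctError, InsufficientDataError, InvalidArgumentError
from .fluctuation import compare_sample_types, fluctuation_summary
from .normalize import normalize
from .simulate import (
    generate_annotations,
    generate_cell_references,
    generate_clock,
    generate_longitudinal_betas,
    generate_phenotypes,
    generate_study_design,
)

logger = logging.getLogger("epifluct")


@dataclass
class ClockSpec:
    name: str
    n_cpgs: int = 300
    coef_mu: float = 0.0
    coef_sigma: float = 0.15
    transform: str = "horvath"
    adult_age: float = 20.0
    coupling: float = 0.8
    center_age: float = 40.0


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "results/run"
    n_individuals: int = 2
    n_sample_types: int = 2
    n_timepoints: int = 24
    day_spacing: object = "mixed"
    n_probes: int = 2000
    n_cell_types: int = 3
    separation: float = 0.5
    ar1: float = 0.5
    probe_noise: dict = field(default_factory=lambda: {"I": 0.01, "II": 0.025})
    clocks: list = field(
        default_factory=lambda: [
            ClockSpec("pan_tissue_like", 353, transform="horvath", center_age=40.0),
            ClockSpec("skin_blood_like", 391, transform="horvath", center_age=40.0),
            ClockSpec("phenoage_like", 513, coef_sigma=4.0, transform="identity",
                      center_age=55.0),
        ]
    )
    strategies: tuple = ("raw", "bmiq", "gold_standard")
    alpha: float = 0.05
    correction: str = "bonferroni"
    deconv_probes: int = 100
    phenotype_effect: float = 0.5
    phenotype_noise_sd: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        self.clocks = [c if isinstance(c, ClockSpec) else ClockSpec(**c) for c in self.clocks]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def bonferroni_threshold(alpha: float, n_clocks: int, n_sample_types: int) -> float:
    """The study-design significance threshold: alpha / (clocks × sample types)."""
    return alpha / (n_clocks * n_sample_types)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on synthetic data and write all output tables.

    Returns the result bundle as a dict of DataFrames/objects; writes CSVs
    and a JSON manifest under ``config.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    rng = np.random.default_rng(config.seed)
    os.makedirs(config.out_dir, exist_ok=True)

    logger.info("simulating design and data (seed=%d)", config.seed)
    design = generate_study_design(
        config.n_individuals,
        config.n_sample_types,
        config.n_timepoints,
        config.day_spacing,
        seed=int(rng.integers(2**31)),
    )
    references = generate_cell_references(
        config.n_cell_types, config.n_probes, config.separation, seed=int(rng.integers(2**31))
    )
    # clocks occupy disjoint blocks of the shared probe universe so each
    # clock's assigned fluctuation SDs can drive the simulated matrix
    clocks = {}
    offset = 0
    for spec in config.clocks:
        transform = (spec.transform, spec.adult_age) if spec.transform == "horvath" else spec.transform
        clocks[spec.name] = generate_clock(
            spec.n_cpgs,
            0.0,
            ("normal", spec.coef_mu, spec.coef_sigma),
            transform=transform,
            coupling=spec.coupling,
            seed=int(rng.integers(2**31)),
            name=spec.name,
            cpg_offset=offset,
            center_age=spec.center_age,
        )
        offset += spec.n_cpgs
    if offset > config.n_probes:
        raise InvalidArgumentError(
            f"clocks need {offset} probes but n_probes={config.n_probes}"
        )
    clock_sds = pd.concat([gen.fluctuation_sd for gen in clocks.values()])
    primary = clocks[config.clocks[0].name]
    matrix, truth = generate_longitudinal_betas(
        design,
        primary.clock,
        references,
        fluctuation={"ar1": config.ar1, "sd": clock_sds},
        probe_noise=config.probe_noise,
        seed=int(rng.integers(2**31)),
    )
    annotations = generate_annotations(list(matrix.probe_ids), seed=int(rng.integers(2**31)))
    phenotypes = generate_phenotypes(
        design,
        linked_signal=truth.true_latent_age_signal.loc[matrix.sample_ids],
        effect=config.phenotype_effect,
        noise_sd=config.phenotype_noise_sd,
        seed=int(rng.integers(2**31)),
    )

    gold = matrix.values.mean(axis=1)  # dataset-mean profile as calibration target
    age_tables = []
    stage = "normalize/age"
    try:
        for strategy in config.strategies:
            normed = normalize(
                matrix,
                strategy,
                annotations=annotations,
                gold_standard=gold if strategy == "gold_standard" else None,
            )
            for name, gen in clocks.items():
                age_tables.append(compute_epigenetic_age(normed, gen.clock))
        ages = pd.concat(age_tables, ignore_index=True)

        stage = "deconvolve"
        proportions = estimate_proportions(matrix, references.profiles, config.deconv_probes)
        stage = "correct"
        corrected = correct_age_for_composition(ages, proportions)

        stage = "fluctuation"
        all_ages = pd.concat([ages, corrected], ignore_index=True)
        fluct = fluctuation_summary(all_ages)
        comparison = compare_corrected_uncorrected(ages, corrected)
        type_a, type_b = design.sample_types[0], design.sample_types[-1]
        paired = (
            compare_sample_types(all_ages, type_a, type_b)
            if config.n_sample_types >= 2
            else pd.DataFrame()
        )

        stage = "characterize"
        contrib_frames = []
        test_rows = []
        diag_rows = []
        n_tests = len(clocks) * config.n_sample_types
        for name, gen in clocks.items():
            sds = clock_cpg_sd(matrix, gen.clock)
            table = compute_contributions(gen.clock, sds)
            contrib_frames.append(table.assign(clock_name=name))
            variable = table.index[table["sd_group"] == "variable"]
            stable = table.index[table["sd_group"] == "stable"]
            for axis in ("island_relation", "genic_category"):
                res = annotation_proportion_test(
                    variable, stable, annotations, axis,
                    alpha=config.alpha, n_tests=n_tests,
                )
                test_rows.append({"clock_name": name, "grouping": "sd", **{
                    k: v for k, v in res.items() if k not in ("categories", "counts")}})
                high = table.index[table["contribution_group"] == "high"]
                low = table.index[table["contribution_group"] == "low"]
                res = annotation_proportion_test(
                    high, low, annotations, axis, alpha=config.alpha, n_tests=n_tests
                )
                test_rows.append({"clock_name": name, "grouping": "contribution", **{
                    k: v for k, v in res.items() if k not in ("categories", "counts")}})
            try:
                wmw = probe_type_contribution_test(table, annotations)
            except InsufficientDataError as err:
                wmw = {"U": np.nan, "p": np.nan, "method": "skipped", "note": str(err)}
            test_rows.append({"clock_name": name, "grouping": "probe_type", **wmw})
            diag = coefficient_vs_sd_diagnostic(gen.clock, sds)
            diag_rows.append({"clock_name": name, "rho": diag["rho"], "p": diag["p"]})
        contributions = pd.concat(contrib_frames).reset_index()
        char_tests = pd.DataFrame(test_rows)
        diagnostics = pd.DataFrame(diag_rows)

        stage = "associate"
        associations = associate(all_ages, phenotypes, correction=config.correction)
    except EpifluctError as err:
        # flush whatever exists so a failed run is inspectable
        eio.write_table(pd.concat(age_tables, ignore_index=True) if age_tables else pd.DataFrame(),
                        os.path.join(config.out_dir, "partial_ages.csv"))
        raise EpifluctError(f"pipeline stage {stage!r} failed: {err}") from err

    out = config.out_dir
    eio.write_table(all_ages, os.path.join(out, "ages.csv"))
    eio.write_table(fluct.summary, os.path.join(out, "fluctuation_summary.csv"))
    eio.write_table(fluct.consecutive_diffs, os.path.join(out, "consecutive_diffs.csv"))
    eio.write_table(comparison, os.path.join(out, "correction_comparison.csv"))
    eio.write_table(paired, os.path.join(out, "sample_type_tests.csv"))
    eio.write_table(contributions, os.path.join(out, "contributions.csv"))
    eio.write_table(char_tests, os.path.join(out, "characterization_tests.csv"))
    eio.write_table(diagnostics, os.path.join(out, "coefficient_sd_diagnostic.csv"))
    eio.write_table(associations, os.path.join(out, "associations.csv"))
    eio.write_table(
        proportions.reset_index(), os.path.join(out, "cell_proportions.csv")
    )
    eio.write_sample_sheet(design.sample_sheet(), os.path.join(out, "sample_sheet.csv"))

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": design.n_samples,
        "bonferroni_threshold": bonferroni_threshold(
            config.alpha, len(clocks), config.n_sample_types
        ),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "design": design,
        "matrix": matrix,
        "truth": truth,
        "annotations": annotations,
        "references": references,
        "clocks": clocks,
        "ages": all_ages,
        "fluctuation": fluct,
        "correction_comparison": comparison,
        "sample_type_tests": paired,
        "contributions": contributions,
        "characterization_tests": char_tests,
        "diagnostics": diagnostics,
        "associations": associations,
        "proportions": proportions,
        "manifest": manifest,
    }
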