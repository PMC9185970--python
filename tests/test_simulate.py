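"""Synthetic-data generator: designs, clocks, references, betas, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epifluct.clocks import compute_epigenetic_age
from epifluct.errors import InvalidArgumentError, MissingProbeError
from epifluct.simulate import (
    StudyDesign,
    generate_annotations,
    generate_cell_references,
    generate_clock,
    generate_longitudinal_betas,
    generate_phenotypes,
    generate_study_design,
)


class TestStudyDesign:
    def test_emulated_study_size(self):
        design = generate_study_design(2, 2, 24, seed=1)
        assert design.n_samples == 96
        assert len(design.sample_sheet()) == 96
        # default spacing must include some exactly-one-day gaps
        gaps = np.diff(design.collection_days)
        assert (gaps == 1).any()

    def test_minimal_design(self):
        design = generate_study_design(1, 1, 2, day_spacing=1, seed=0)
        assert design.collection_days == (0, 1)
        assert design.n_samples == 2

    def test_constant_gap_days(self):
        design = generate_study_design(3, 2, 5, day_spacing=3, seed=7)
        assert design.n_samples == 30
        assert design.collection_days == (0, 3, 6, 9, 12)

    @pytest.mark.parametrize("bad", [(0, 2, 5), (2, 0, 5), (2, 2, 0), (2, 2, 1)])
    def test_non_positive_counts_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            generate_study_design(*bad, seed=0)

    def test_triples_unique(self):
        sheet = generate_study_design(2, 2, 6, seed=3).sample_sheet()
        assert not sheet.duplicated(["individual", "sample_type", "day"]).any()

    def test_days_must_increase(self):
        with pytest.raises(InvalidArgumentError):
            StudyDesign(("a",), ("x",), (0, 5, 5))


class TestGenerateClock:
    def test_identity_single_cpg_clock_reads_beta(self):
        gen = generate_clock(1, 0.0, ("constant", 1.0), "identity", coupling=0, seed=0)
        assert gen.clock.coefficients == {"cg00000000": 1.0}
        assert gen.clock.intercept == 0.0

    def test_zero_coefficient_clock_is_constant(self, small_design, references):
        gen = generate_clock(10, 2.0, ("constant", 0.0), "identity", coupling=0, seed=5)
        matrix, _ = generate_longitudinal_betas(small_design, gen, references, seed=1)
        ages = compute_epigenetic_age(matrix, gen.clock)
        assert np.allclose(ages["epigenetic_age"], 2.0)

    def test_coupling_produces_negative_spearman(self):
        gen = generate_clock(
            100, 0.5, ("normal", 0, 1), ("horvath", 20.0), coupling=0.8, seed=3
        )
        coef = pd.Series(gen.clock.coefficients).abs()
        rho = stats.spearmanr(coef, gen.fluctuation_sd.loc[coef.index])[0]
        assert rho < 0

    def test_coupling_preserves_coefficient_marginal(self):
        uncoupled = generate_clock(500, 0.0, ("normal", 0, 1), coupling=0.0, seed=9)
        coupled = generate_clock(500, 0.0, ("normal", 0, 1), coupling=0.9, seed=9)
        a = np.sort(np.abs(list(uncoupled.clock.coefficients.values())))
        b = np.sort(np.abs(list(coupled.clock.coefficients.values())))
        assert np.allclose(a, b)  # same magnitudes, different pairing

    def test_center_age_calibration(self):
        gen = generate_clock(
            50, 0.0, ("normal", 0, 0.2), ("horvath", 20.0), seed=2, center_age=40.0
        )
        from epifluct.clocks import forward_transform

        predictor = gen.clock.intercept + 0.5 * sum(gen.clock.coefficients.values())
        assert predictor == pytest.approx(forward_transform(40.0, 20.0), abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            generate_clock(0, 0.0, ("constant", 1.0))
        with pytest.raises(InvalidArgumentError):
            generate_clock(5, 0.0, ("constant", 1.0), coupling=1.5)


class TestCellReferences:
    def test_separation_on_discriminating_probes(self):
        refs = generate_cell_references(2, 50, 0.5, seed=1)
        spread = refs.profiles.loc[refs.discriminating]
        assert ((spread.max(axis=1) - spread.min(axis=1)) >= 0.5 - 1e-12).all()

    def test_values_in_unit_interval(self):
        refs = generate_cell_references(3, 100, 0.3, seed=2)
        assert refs.profiles.shape == (100, 3)
        assert refs.profiles.to_numpy().min() >= 0.0
        assert refs.profiles.to_numpy().max() <= 1.0

    def test_maximal_separation_hits_bounds(self):
        refs = generate_cell_references(2, 10, 1.0, seed=0)
        disc = refs.profiles.loc[refs.discriminating].to_numpy()
        assert set(np.round(disc.ravel(), 12)) <= {0.0, 1.0}

    @pytest.mark.parametrize("sep", [0.0, 1.5, -0.2])
    def test_separation_out_of_range(self, sep):
        with pytest.raises(InvalidArgumentError):
            generate_cell_references(2, 10, sep, seed=0)

    def test_too_few_cell_types(self):
        with pytest.raises(InvalidArgumentError):
            generate_cell_references(1, 10, 0.5, seed=0)


class TestLongitudinalBetas:
    def test_degenerate_noise_gives_identical_timepoints(self, small_design, references):
        gen = generate_clock(20, 0.0, ("normal", 0, 0.1), seed=1)
        mixing = {
            st_: {"base": np.array([0.5, 0.3, 0.2]), "jitter_sd": 0.0}
            for st_ in small_design.sample_types
        }
        matrix, _ = generate_longitudinal_betas(
            small_design,
            gen.clock,
            references,
            mixing=mixing,
            fluctuation={"ar1": 0.0, "sd": 0.0},
            probe_noise={"I": 0.0, "II": 0.0},
            seed=4,
        )
        for (_, _), cols in matrix.samples.groupby(["individual", "sample_type"]):
            series = matrix.values[cols["sample_id"]]
            assert (series.nunique(axis=1) == 1).all()

    def test_type_II_noise_raises_type_II_sd(self, small_design, references):
        ann = generate_annotations(list(references.profiles.index), seed=3)
        mixing = {
            st_: {"base": np.array([1.0, 0.0, 0.0]), "jitter_sd": 0.0}
            for st_ in small_design.sample_types
        }
        matrix, _ = generate_longitudinal_betas(
            small_design,
            None,
            references,
            mixing=mixing,
            fluctuation={"ar1": 0.0, "sd": 0.0},
            probe_noise={"I": 0.0, "II": 0.05},
            annotations=ann,
            seed=8,
        )
        sds = matrix.values.std(axis=1, ddof=1)
        by_type = sds.groupby(ann.set_index("probe_id")["design_type"]).mean()
        assert by_type["II"] > by_type["I"]
        assert by_type["I"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_mixture_identity(self, small_design):
        refs = generate_cell_references(2, 60, 0.5, seed=2)
        mixing = {
            st_: {"base": np.array([0.7, 0.3]), "jitter_sd": 0.0}
            for st_ in small_design.sample_types
        }
        matrix, truth = generate_longitudinal_betas(
            small_design,
            None,
            refs,
            mixing=mixing,
            fluctuation={"ar1": 0.0, "sd": 0.0},
            probe_noise={"I": 0.0, "II": 0.0},
            seed=0,
        )
        expected = 0.7 * refs.profiles.iloc[:, 0] + 0.3 * refs.profiles.iloc[:, 1]
        for sid in matrix.sample_ids:
            assert np.allclose(matrix.values[sid], expected, atol=1e-12)
        assert np.allclose(truth.true_cell_proportions.to_numpy(), [0.7, 0.3])

    def test_missing_clock_probe_raises(self, small_design):
        refs = generate_cell_references(2, 10, 0.5, seed=2)
        gen = generate_clock(5, 0.0, ("constant", 1.0), seed=0, cpg_offset=8)
        with pytest.raises(MissingProbeError) as exc:
            generate_longitudinal_betas(small_design, gen, refs, seed=0)
        assert "cg00000010" in str(exc.value)

    def test_betas_in_unit_interval_and_deterministic(self, small_design, references, gen_clock):
        m1, t1 = generate_longitudinal_betas(small_design, gen_clock, references, seed=42)
        m2, t2 = generate_longitudinal_betas(small_design, gen_clock, references, seed=42)
        arr = m1.values.to_numpy()
        assert arr.min() >= 0.0 and arr.max() <= 1.0
        # identical seed and parameters -> bit-identical outputs
        assert m1.values.equals(m2.values)
        assert t1.true_cell_proportions.equals(t2.true_cell_proportions)


class TestAnnotations:
    def test_degenerate_distribution(self):
        ann = generate_annotations(
            ["p1", "p2", "p3", "p4"],
            {"design_type": {"I": 1.0, "II": 0.0}},
            seed=0,
        )
        assert (ann["design_type"] == "I").all()

    def test_category_counts_within_binomial_bounds(self):
        probs = {"Island": 0.3, "Shore": 0.3, "Shelf": 0.2, "OpenSea": 0.2}
        ann = generate_annotations(
            [f"p{i}" for i in range(1000)], {"island_relation": probs}, seed=12
        )
        counts = ann["island_relation"].value_counts()
        for cat, p in probs.items():
            lo = stats.binom.ppf(0.005, 1000, p)
            hi = stats.binom.ppf(0.995, 1000, p)
            assert lo <= counts[cat] <= hi

    def test_empty_probe_list(self):
        ann = generate_annotations([], seed=0)
        assert len(ann) == 0
        assert list(ann.columns)[0] == "probe_id"

    def test_bad_probabilities_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_annotations(["p1"], {"design_type": {"I": 0.6, "II": 0.6}})


class TestPhenotypes:
    def test_null_effect_is_independent(self, small_design):
        signal = np.linspace(0, 10, small_design.n_samples)
        pheno = generate_phenotypes(small_design, signal, effect=0.0, noise_sd=1.0, seed=1)
        res = stats.linregress(signal, pheno["gamma_gtp"])
        assert abs(res.slope) < 3 * res.stderr

    def test_noiseless_line(self, small_design):
        signal = np.linspace(0, 10, small_design.n_samples)
        pheno = generate_phenotypes(small_design, signal, effect=1.0, noise_sd=0.0, seed=2)
        res = stats.linregress(signal, pheno["gamma_gtp"])
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.rvalue == pytest.approx(1.0, abs=1e-12)

    def test_slope_recovery_within_three_se(self):
        design = generate_study_design(1, 1, 24, day_spacing=3, seed=5)
        signal = np.random.default_rng(6).normal(40, 3, design.n_samples)
        pheno = generate_phenotypes(design, signal, effect=0.5, noise_sd=0.1, seed=7)
        res = stats.linregress(signal, pheno["gamma_gtp"])
        assert abs(res.slope - 0.5) < 3 * res.stderr

    def test_length_mismatch_rejected(self, small_design):
        with pytest.raises(InvalidArgumentError):
            generate_phenotypes(small_design, np.zeros(3), effect=1.0, seed=0)

    def test_unlinked_items_ignore_signal(self, small_design):
        signal = np.linspace(0, 100, small_design.n_samples)
        pheno = generate_phenotypes(small_design, signal, effect=5.0, noise_sd=0.1, seed=3)
        res = stats.linregress(signal, pheno["glucose"])
        assert abs(res.slope) < 3 * res.stderr
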