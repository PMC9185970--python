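"""Clock-CpG characterization: SDs, contributions, annotation and rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epifluct.clocks import ClockDefinition
from epifluct.containers import BetaMatrix
from epifluct.cpgs import (
    annotation_proportion_test,
    assign_quartile_groups,
    clock_cpg_sd,
    coefficient_vs_sd_diagnostic,
    compute_contributions,
    enrichment_test,
    probe_type_contribution_test,
)
from epifluct.errors import InsufficientDataError, InvalidArgumentError


def _annotations(probe_ids, design_types=None, islands=None, genic=None):
    n = len(probe_ids)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "design_type": design_types or ["I"] * n,
            "island_relation": islands or ["Island"] * n,
            "genic_category": genic or ["Body"] * n,
        }
    )


class TestClockCpGSD:
    def _matrix(self, values, individuals=("person_A",)):
        cols = []
        sheet_rows = []
        for ind in individuals:
            for t in range(values.shape[1] // len(individuals)):
                sid = f"{ind}_PBMC_d{t:03d}"
                cols.append(sid)
                sheet_rows.append(
                    {"sample_id": sid, "individual": ind, "sample_type": "PBMC", "day": t}
                )
        df = pd.DataFrame(values, index=[f"cg{i:08d}" for i in range(values.shape[0])],
                          columns=cols)
        return BetaMatrix(df, pd.DataFrame(sheet_rows))

    def test_constant_betas_zero_sd(self):
        m = self._matrix(np.full((3, 6), 0.4))
        clock = ClockDefinition("c", 0.0, {f"cg{i:08d}": 1.0 for i in range(3)})
        assert (clock_cpg_sd(m, clock) == 0).all()

    def test_alternating_betas_brute_force(self):
        vals = np.tile([0.4, 0.6], 12)[None, :]
        m = self._matrix(vals)
        clock = ClockDefinition("c", 0.0, {"cg00000000": 1.0})
        sd = clock_cpg_sd(m, clock).iloc[0]
        mean = sum(vals[0]) / 24
        brute = math.sqrt(sum((v - mean) ** 2 for v in vals[0]) / 23)
        assert sd == pytest.approx(brute, abs=1e-12)

    def test_mean_aggregation_across_individuals(self):
        # two individuals with per-series SDs 0.01 and 0.03 -> mean 0.02
        rng = np.random.default_rng(0)
        base = rng.standard_normal(10)
        base = (base - base.mean()) / base.std(ddof=1)
        vals = np.concatenate([0.5 + 0.01 * base, 0.5 + 0.03 * base])[None, :]
        m = self._matrix(vals, individuals=("person_A", "person_B"))
        clock = ClockDefinition("c", 0.0, {"cg00000000": 1.0})
        assert clock_cpg_sd(m, clock, grouping="mean").iloc[0] == pytest.approx(0.02, abs=1e-12)
        assert clock_cpg_sd(m, clock, grouping="max").iloc[0] == pytest.approx(0.03, abs=1e-12)


class TestQuartileGroups:
    def test_counts_for_eight_distinct_values(self):
        values = pd.Series(np.arange(8.0), index=[f"p{i}" for i in range(8)])
        groups = assign_quartile_groups(values)
        assert (groups == "top").sum() == 2
        assert (groups == "bottom").sum() == 2
        assert (groups == "middle").sum() == 4
        assert set(groups[values >= 6].unique()) == {"top"}

    def test_all_equal_uses_id_tiebreak(self):
        values = pd.Series(1.0, index=[f"p{i}" for i in range(9)])
        groups = assign_quartile_groups(values)
        assert (groups == "top").sum() == 2
        assert (groups == "bottom").sum() == 2
        # deterministic: lexicographically first ids land in bottom
        assert groups.loc["p0"] == "bottom"

    def test_study_scale_counts(self):
        values = pd.Series(np.random.default_rng(1).normal(size=353),
                           index=[f"p{i:04d}" for i in range(353)])
        groups = assign_quartile_groups(values)
        assert (groups == "top").sum() == 88
        assert (groups == "bottom").sum() == 88

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            assign_quartile_groups(pd.Series([1.0, 2.0, 3.0]))


class TestContributions:
    def test_contribution_is_abs_coef_times_sd(self):
        probes = [f"p{i}" for i in range(4)]
        clock = ClockDefinition("c", 0.0, dict(zip(probes, [2.0, -2.0, 0.0, 1.0])))
        sds = pd.Series([0.1, 0.1, 0.5, 0.2], index=probes)
        table = compute_contributions(clock, sds)
        assert table.loc["p0", "contribution"] == pytest.approx(0.2)
        assert table.loc["p1", "contribution"] == pytest.approx(0.2)  # sign-invariant
        assert table.loc["p2", "contribution"] == 0.0
        assert table.loc["p2", "contribution_group"] == "low"

    def test_quartile_labels_partition(self, gen_clock, simulated):
        matrix, _ = simulated
        sds = clock_cpg_sd(matrix, gen_clock.clock)
        table = compute_contributions(gen_clock.clock, sds)
        n = len(table)
        assert (table["sd_group"] == "variable").sum() == n // 4
        assert (table["sd_group"] == "stable").sum() == n // 4
        assert not (
            (table["contribution_group"] == "high") & (table["contribution_group"] == "low")
        ).any()


class TestAnnotationProportionTest:
    def test_identical_distributions_give_zero_chi2(self):
        probes_a = [f"a{i}" for i in range(30)]
        probes_b = [f"b{i}" for i in range(30)]
        islands = (["Island"] * 10 + ["Shore"] * 10 + ["Shelf"] * 10) * 2
        ann = _annotations(probes_a + probes_b, islands=islands)
        res = annotation_proportion_test(probes_a, probes_b, ann, "island_relation")
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_brute_force_chi2(self):
        # counts [[20, 5], [5, 20]]
        probes_a = [f"a{i}" for i in range(25)]
        probes_b = [f"b{i}" for i in range(25)]
        ann = _annotations(
            probes_a + probes_b,
            islands=["Island"] * 20 + ["Shore"] * 5 + ["Island"] * 5 + ["Shore"] * 20,
        )
        res = annotation_proportion_test(probes_a, probes_b, ann, "island_relation")
        observed = np.array([[20, 5], [5, 20]], dtype=float)
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        brute = ((observed - expected) ** 2 / expected).sum()
        assert res["chi2"] == pytest.approx(brute, abs=1e-10)
        assert res["dof"] == 1

    def test_bonferroni_threshold_reported(self):
        probes_a = [f"a{i}" for i in range(10)]
        probes_b = [f"b{i}" for i in range(10)]
        ann = _annotations(probes_a + probes_b,
                           islands=["Island"] * 10 + ["Shore"] * 10)
        res = annotation_proportion_test(
            probes_a, probes_b, ann, "island_relation", alpha=0.05, n_tests=6
        )
        assert res["bonferroni_threshold"] == pytest.approx(0.05 / 6)
        assert round(res["bonferroni_threshold"], 3) == 0.008

    def test_random_tables_match_brute_force(self, rng):
        for _ in range(20):
            counts = rng.integers(3, 30, size=(2, 3))
            probes_a = [f"a{i}" for i in range(counts[0].sum())]
            probes_b = [f"b{i}" for i in range(counts[1].sum())]
            cats = ["Island", "Shore", "OpenSea"]
            islands = [c for c, k in zip(cats, counts[0]) for _ in range(k)] + [
                c for c, k in zip(cats, counts[1]) for _ in range(k)
            ]
            ann = _annotations(probes_a + probes_b, islands=islands)
            res = annotation_proportion_test(probes_a, probes_b, ann, "island_relation")
            observed = counts.astype(float)
            expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
            brute = ((observed - expected) ** 2 / expected).sum()
            assert res["chi2"] == pytest.approx(brute, abs=1e-10)

    def test_overlapping_groups_rejected(self):
        ann = _annotations(["p1", "p2", "p3"])
        with pytest.raises(InvalidArgumentError):
            annotation_proportion_test(["p1", "p2"], ["p2", "p3"], ann, "island_relation")


class TestProbeTypeTest:
    def test_disjoint_ranks_exact_p(self):
        probes = [f"p{i}" for i in range(6)]
        table = pd.DataFrame(
            {"contribution": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, index=probes
        )
        ann = _annotations(probes, design_types=["I"] * 3 + ["II"] * 3)
        res = probe_type_contribution_test(table, ann)
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)

    def test_exact_p_matches_enumeration(self, rng):
        # full enumeration of all labelings as the independent oracle
        values = rng.normal(size=9)
        n1 = 4
        probes = [f"p{i}" for i in range(9)]
        table = pd.DataFrame({"contribution": values}, index=probes)
        ann = _annotations(probes, design_types=["I"] * n1 + ["II"] * (9 - n1))
        res = probe_type_contribution_test(table, ann)

        def u_stat(group1):
            g1 = np.array(group1)
            g2 = np.array([v for v in values if v not in g1])
            return sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)

        observed = u_stat(values[:n1])
        n_tot = math.comb(9, n1)
        mean_u = n1 * (9 - n1) / 2
        extreme = sum(
            1
            for combo in itertools.combinations(values, n1)
            if abs(u_stat(combo) - mean_u) >= abs(observed - mean_u) - 1e-12
        )
        assert res["p"] == pytest.approx(extreme / n_tot, abs=1e-10)

    def test_complete_tie_reports_p_one(self):
        probes = ["p0", "p1"]
        table = pd.DataFrame({"contribution": [0.3, 0.3]}, index=probes)
        ann = _annotations(probes, design_types=["I", "II"])
        res = probe_type_contribution_test(table, ann)
        assert res["p"] == 1.0

    def test_single_design_type_rejected(self):
        probes = ["p0", "p1"]
        table = pd.DataFrame({"contribution": [0.3, 0.5]}, index=probes)
        ann = _annotations(probes, design_types=["I", "I"])
        with pytest.raises(InsufficientDataError):
            probe_type_contribution_test(table, ann)


class TestEnrichment:
    def test_term_equal_to_background_has_p_one(self):
        background = [f"p{i}" for i in range(20)]
        out = enrichment_test(background[:5], background, {"all": background})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_hypergeometric_value(self):
        background = [f"p{i}" for i in range(20)]
        target = background[:5]
        term = background[:4]  # overlap 4 of 4
        out = enrichment_test(target, background, {"t": term})
        expected = math.comb(4, 4) * math.comb(16, 1) / math.comb(20, 5)
        assert out["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_upper_tail_is_one(self):
        background = [f"p{i}" for i in range(30)]
        out = enrichment_test(background[:5], background, {"t": background[25:]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_random_instances_match_scipy_free_formula(self, rng):
        for _ in range(10):
            N = int(rng.integers(15, 40))
            background = [f"p{i}" for i in range(N)]
            n = int(rng.integers(3, 8))
            K = int(rng.integers(2, 10))
            target = list(rng.choice(background, size=n, replace=False))
            term = list(rng.choice(background, size=K, replace=False))
            out = enrichment_test(target, background, {"t": term})
            k_obs = len(set(target) & set(term))
            brute = sum(
                math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
                for k in range(k_obs, min(K, n) + 1)
            )
            assert out["p"].iloc[0] == pytest.approx(brute, abs=1e-10)

    def test_adjustments(self):
        background = [f"p{i}" for i in range(40)]
        terms = {f"t{j}": background[j : j + 10] for j in range(5)}
        out = enrichment_test(background[:8], background, terms, correction="bonferroni")
        assert (out["adjusted_p"] >= out["p"] - 1e-15).all()
        assert np.allclose(out["adjusted_p"], np.minimum(1.0, out["p"] * len(out)))
        out_bh = enrichment_test(background[:8], background, terms, correction="bh")
        assert (out_bh["adjusted_p"] >= out_bh["p"] - 1e-15).all()

    def test_target_outside_background_rejected(self):
        with pytest.raises(InvalidArgumentError):
            enrichment_test(["x"], ["p1", "p2"], {"t": ["p1"]})


class TestCoefficientSDDiagnostic:
    def test_perfect_inverse_monotone(self):
        probes = [f"p{i}" for i in range(10)]
        coefs = dict(zip(probes, np.linspace(5, 0.5, 10)))
        clock = ClockDefinition("c", 0.0, coefs)
        sds = pd.Series(np.linspace(0.01, 0.1, 10), index=probes)
        res = coefficient_vs_sd_diagnostic(clock, sds)
        assert res["rho"] == pytest.approx(-1.0)

    def test_constant_sd_flagged_undefined(self):
        probes = [f"p{i}" for i in range(6)]
        clock = ClockDefinition("c", 0.0, dict(zip(probes, np.arange(1.0, 7.0))))
        res = coefficient_vs_sd_diagnostic(clock, pd.Series(0.05, index=probes))
        assert res["undefined"]
        assert np.isnan(res["rho"])

    def test_coupled_generator_recovered_from_data(self, gen_clock, simulated):
        matrix, _ = simulated
        sds = clock_cpg_sd(matrix, gen_clock.clock)
        res = coefficient_vs_sd_diagnostic(gen_clock.clock, sds)
        assert res["rho"] < 0

    def test_null_coupling_rho_small(self):
        rng = np.random.default_rng(10)
        rhos = []
        for rep in range(200):
            probes = [f"p{i}" for i in range(40)]
            clock = ClockDefinition("c", 0.0, dict(zip(probes, rng.normal(size=40))))
            sds = pd.Series(rng.lognormal(-2.5, 0.5, 40), index=probes)
            res = coefficient_vs_sd_diagnostic(clock, sds)
            rhos.append(res["p"] < 0.05)
        rate = np.mean(rhos)
        lo = stats.binom.ppf(0.005, 200, 0.05) / 200
        hi = stats.binom.ppf(0.995, 200, 0.05) / 200
        assert lo <= rate <= hi
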