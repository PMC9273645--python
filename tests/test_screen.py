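import math

import numpy as np
import pandas as pd
import pytest

from gecna import (
    ExpressionMatrix,
    ScreenConfig,
    burden_contrast,
    extreme_groups,
    filter_genes,
    run_screen,
)
from gecna.reference import GROUP_N, reference_screen_summaries


class TestFilterGenes:
    def test_gene_over_cutoff_excluded(self):
        values = np.zeros((2, 100))
        values[0, :40] = np.nan  # missing in 40% of patients
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=["BAD", "GOOD"], columns=[f"P{i}" for i in range(100)])
        )
        kept = filter_genes(expr, cutoff=1 / 3)
        assert list(kept.genes) == ["GOOD"]

    def test_strict_vs_relaxed_completeness(self):
        values = np.zeros((1, 10))
        values[0, 0] = np.nan  # 10% missing: below cutoff but not complete
        expr = ExpressionMatrix(pd.DataFrame(values, index=["G"], columns=[f"P{i}" for i in range(10)]))
        assert len(filter_genes(expr, 1 / 3, require_complete=True).genes) == 0
        assert len(filter_genes(expr, 1 / 3, require_complete=False).genes) == 1

    def test_planted_bad_gene_fraction(self, planted_cohort):
        config, cohort, truth = planted_cohort
        kept = filter_genes(cohort.expression, 1 / 3)
        expected = config.n_genes - round(config.missing_gene_fraction * config.n_genes)
        assert len(kept.genes) == expected


class TestExtremeGroups:
    def test_sizes_and_disjoint(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.standard_normal(592), index=[f"P{i:04d}" for i in range(592)])
        high, low = extreme_groups(values, k=10)
        assert len(high) == len(low) == 10
        assert set(high).isdisjoint(low)
        assert values[high].min() >= values.drop(high).max()

    def test_exactly_2k_partitions(self):
        values = pd.Series([3.0, 1.0, 4.0, 2.0], index=list("ABCD"))
        high, low = extreme_groups(values, k=2)
        assert set(high) | set(low) == set("ABCD")
        assert set(high) == {"C", "A"}

    def test_ties_broken_by_earliest_patient_id(self):
        # 12 patients tied at the max among 25: the 10 tied ids that sort
        # first must form the high group
        ids = [f"P{i:02d}" for i in range(25)]
        values = pd.Series(np.linspace(-1, 0, 25), index=ids)
        tied = ids[5:17]  # 12 tied at the max
        values[tied] = 99.0
        high, _ = extreme_groups(values, k=10)
        assert list(high) == sorted(tied)[:10]

    def test_too_few_usable_patients(self):
        values = pd.Series([1.0, np.nan, 2.0], index=list("ABC"))
        with pytest.raises(ValueError, match="patients"):
            extreme_groups(values, k=2)


class TestBurdenContrast:
    def test_reference_gene_summaries_reproduce_published_p(self):
        """Raw groups constructed to match a published gene's burden
        summaries must reproduce its printed p-value (worked example)."""
        row = reference_screen_summaries().loc["CAPS"]
        base = np.arange(GROUP_N, dtype=float)
        base = (base - base.mean()) / base.std(ddof=1)
        high_vals = row["mean_high"] + row["sd_high"] * base
        low_vals = row["mean_low"] + row["sd_low"] * base
        b = pd.Series(
            np.concatenate([high_vals, low_vals]),
            index=[f"H{i}" for i in range(GROUP_N)] + [f"L{i}" for i in range(GROUP_N)],
        )
        res = burden_contrast(b.index[:GROUP_N], b.index[GROUP_N:], b)
        assert abs(res["p"] - row["p_published"]) / row["p_published"] < 0.10

    def test_identical_groups(self):
        b = pd.Series([5.0, 5, 5, 7, 7, 7], index=list("ABCDEF"))
        res = burden_contrast(pd.Index(list("ABC")), pd.Index(list("ABC")), b)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_textbook_welch_formula(self):
        """p agrees to 12 digits with the Welch formula written longhand."""
        b = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("ABCDEF"))
        res = burden_contrast(pd.Index(list("DEF")), pd.Index(list("ABC")), b)
        m1, m2, s2 = 5.0, 2.0, 1.0  # means and shared sample variance
        se = math.sqrt(s2 / 3 + s2 / 3)
        t = (m1 - m2) / se
        df = (s2 / 3 + s2 / 3) ** 2 / ((s2 / 3) ** 2 / 2 + (s2 / 3) ** 2 / 2)
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df)
        assert res["t"] == pytest.approx(t, abs=1e-12)
        assert res["p"] == pytest.approx(p, rel=1e-12)

    def test_zero_variance_unequal_means_flagged(self):
        b = pd.Series([1.0, 1, 1, 2, 2, 2], index=list("ABCDEF"))
        res = burden_contrast(pd.Index(list("DEF")), pd.Index(list("ABC")), b)
        assert res["flag"] == "zero-variance-unequal-means"
        assert 0 < res["p"] < 1e-300

    def test_pooled_flavor_uses_student_df(self):
        b = pd.Series([1.0, 2, 4, 3, 5, 9], index=list("ABCDEF"))
        res = burden_contrast(pd.Index(list("DEF")), pd.Index(list("ABC")), b, flavor="pooled")
        assert res["df"] == 4.0


class TestRunScreen:
    def test_planted_genes_recovered_with_direction(self, planted_cohort):
        _, cohort, truth = planted_cohort
        result = run_screen(cohort, ScreenConfig())
        table = result.tables["total"].set_index("gene")
        planted = truth.planted
        for gene, row in planted.iterrows():
            assert table.loc[gene, "direction"] == row["label"]

    def test_direction_consistent_with_mean_sign(self, planted_cohort):
        _, cohort, _ = planted_cohort
        table = run_screen(cohort, ScreenConfig()).tables["total"]
        sig = table[table["direction"] != "none"]
        up = sig["direction"] == "facilitator"
        assert (sig.loc[up, "mean_high"] > sig.loc[up, "mean_low"]).all()
        assert (sig.loc[~up, "mean_high"] < sig.loc[~up, "mean_low"]).all()

    def test_internal_consistency_of_emitted_summaries(self, planted_cohort):
        """p recomputed from the emitted means/SDs/n matches emitted p to
        1e-9 relative, the way a published summary table lets a reader
        recompute the test."""
        from scipy.stats import ttest_ind_from_stats

        _, cohort, _ = planted_cohort
        table = run_screen(cohort, ScreenConfig()).tables["total"]
        _, p = ttest_ind_from_stats(
            table["mean_high"].to_numpy(), table["sd_high"].to_numpy(),
            table["n_high"].to_numpy(), table["mean_low"].to_numpy(),
            table["sd_low"].to_numpy(), table["n_low"].to_numpy(),
            equal_var=False,
        )
        finite = table["p"] > 1e-300
        assert np.allclose(p[finite], table.loc[finite, "p"], rtol=1e-9)

    def test_sign_flip_swaps_labels_exactly(self, planted_cohort):
        from gecna import Cohort

        _, cohort, _ = planted_cohort
        flipped = Cohort(
            expression=ExpressionMatrix(-cohort.expression.values),
            cna=cohort.cna,
            clinical=cohort.clinical,
            mutations=cohort.mutations,
        )
        t1 = run_screen(cohort, ScreenConfig()).tables["total"].set_index("gene")
        t2 = run_screen(flipped, ScreenConfig()).tables["total"].set_index("gene")
        swap = {"facilitator": "suppressor", "suppressor": "facilitator", "none": "none"}
        assert (t2["direction"] == t1["direction"].map(swap)).all()
        assert np.allclose(t1["p"], t2["p"])

    def test_patient_permutation_invariance(self, planted_cohort):
        from gecna import CnaCallMatrix, Cohort

        _, cohort, _ = planted_cohort
        rng = np.random.default_rng(2)
        perm = rng.permutation(cohort.n_patients)
        shuffled = Cohort(
            expression=ExpressionMatrix(cohort.expression.values.iloc[:, perm]),
            cna=CnaCallMatrix(cohort.cna.calls.iloc[:, perm]),
        )
        t1 = run_screen(cohort, ScreenConfig(), modes=("total",)).tables["total"]
        t2 = run_screen(shuffled, ScreenConfig(), modes=("total",)).tables["total"]
        pd.testing.assert_frame_equal(t1, t2)

    def test_mode_specific_coupling(self):
        """A gene coupled only to amplification burden is significant in the
        amp and total screens but not in the del screen."""
        from gecna import PlantedGene, SimulationConfig, generate_cohort

        hits = {"amp": 0, "total": 0, "del": 0}
        n_seeds = 5
        for seed in range(n_seeds):
            config = SimulationConfig(
                n_patients=400, n_genes=300, mu_burden=80.0,
                facilitators=[PlantedGene(4.0, "amp", "AMPFAC")],
                seed=100 + seed,
            )
            cohort, _ = generate_cohort(config)
            result = run_screen(cohort, ScreenConfig())
            for mode in hits:
                row = result.tables[mode].set_index("gene").loc["AMPFAC"]
                hits[mode] += int(row["direction"] == "facilitator")
        assert hits["amp"] >= n_seeds - 1
        assert hits["total"] >= n_seeds - 1
        assert hits["del"] <= 1


def test_screen_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(k=0)
    with pytest.raises(ValueError):
        ScreenConfig(alpha=1.5)
    with pytest.raises(ValueError):
        ScreenConfig(flavor="mann-whitney")
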