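import itertools

import numpy as np
import pandas as pd
import pytest

from gecna import (
    SimulationConfig,
    altered_contrast,
    altered_status,
    collapse_clinical,
    cox_gene,
    generate_cohort,
    hr_category,
    select_covariates,
    simulate_binary_survival,
    triage,
)
from gecna.survival import CovariateError, _fit_cox, run_survival_screen

from conftest import make_cohort


def _clinical(rows):
    df = pd.DataFrame(
        rows, columns=["patient_id", "age", "sex", "race", "stage_raw", "os_time", "os_event"]
    ).set_index("patient_id")
    return df


class TestCollapseClinical:
    def test_stage_prefix_rule(self):
        clin = _clinical(
            [
                ["P1", 60, "Male", "White", "Stage IIIB", 10.0, 1],
                ["P2", 70, "Female", "White", "Stage IA", 20.0, 0],
                ["P3", 65, "Male", "White", "STAGE IV", 5.0, 1],
                ["P4", 55, "Female", "White", "stage 2", 15.0, 0],
            ]
        )
        out = collapse_clinical(clin)
        assert out["stage"].tolist() == [3.0, 1.0, 4.0, 2.0]

    def test_race_two_levels(self):
        clin = _clinical(
            [
                ["P1", 60, "Male", "Asian", "Stage I", 1.0, 0],
                ["P2", 60, "Male", "White", "Stage I", 1.0, 0],
                ["P3", 60, "Male", "Black or African American", "Stage I", 1.0, 0],
            ]
        )
        out = collapse_clinical(clin)
        assert out["race"].tolist() == ["Other", "White", "Other"]

    def test_unparseable_stage_flags_complete_case(self):
        clin = _clinical(
            [
                ["P1", 60, "Male", "White", "Stage II", 1.0, 0],
                ["P2", 60, "Male", "White", "Unknown", 1.0, 0],
                ["P3", 60, "Male", "White", np.nan, 1.0, 0],
            ]
        )
        out = collapse_clinical(clin)
        assert out["complete"].tolist() == [True, False, False]

    def test_missing_stage_fraction_reduces_complete_case_count(self):
        config = SimulationConfig(
            n_patients=200, n_genes=20, mu_burden=5.0, stage_missing_frac=0.05, seed=5
        )
        cohort, _ = generate_cohort(config)
        out = collapse_clinical(cohort.clinical)
        n_missing = cohort.clinical["stage_raw"].isna().sum()
        assert n_missing > 0
        assert (~out["complete"]).sum() == n_missing

    def test_no_parseable_stage_raises(self):
        clin = _clinical([["P1", 60, "Male", "White", "???", 1.0, 0]])
        with pytest.raises(CovariateError):
            collapse_clinical(clin)


class TestSelectCovariates:
    def test_true_age_effect_selected_null_sex_not(self):
        hits_age = hits_sex = 0
        n_seeds = 5
        for seed in range(n_seeds):
            config = SimulationConfig(
                n_patients=600, n_genes=10, mu_burden=4.0,
                beta_age=0.05, beta_stage=0.0, seed=400 + seed,
            )
            cohort, _ = generate_cohort(config)
            covset = select_covariates(collapse_clinical(cohort.clinical))
            hits_age += "age" in covset.selected
            hits_sex += "sex" in covset.selected
        assert hits_age == n_seeds
        assert hits_sex <= 1

    def test_constant_candidate_dropped_with_warning(self, caplog):
        clin = _clinical(
            [[f"P{i}", 60, "Male", "White", "Stage II", float(i + 1), i % 2] for i in range(30)]
        )
        out = collapse_clinical(clin)
        with caplog.at_level("WARNING"):
            covset = select_covariates(out)
        assert "sex" in covset.dropped
        assert "constant" in caplog.text


class TestCoxGene:
    def test_two_group_exponential_recovers_rate_ratio(self):
        """Exponential survival at rates lambda and 2*lambda, no censoring:
        the fitted HR approaches the closed-form ratio 2."""
        df = simulate_binary_survival(n=3000, hr=2.0, censoring_fraction=0.0, seed=9)
        fit = _fit_cox(
            df.rename(columns={"time": "os_time", "event": "os_event"})
        )
        hr = float(np.exp(fit.summary.loc["group", "coef"]))
        assert hr == pytest.approx(2.0, rel=0.08)

    def test_constant_predictor_flagged(self):
        config = SimulationConfig(n_patients=80, n_genes=5, mu_burden=3.0, seed=1)
        cohort, _ = generate_cohort(config)
        clin = collapse_clinical(cohort.clinical)
        gene = cohort.expression.genes[0]
        cohort.expression.values.loc[gene] = 0.0
        rec = cox_gene(cohort, gene, [], clin, "expression")
        assert rec["flag"] == "constant predictor"
        assert np.isnan(rec["hr"])

    def test_complete_case_n_identical_across_genes(self, planted_cohort):
        _, cohort, _ = planted_cohort
        clin = collapse_clinical(cohort.clinical)
        ns = {
            cox_gene(cohort, g, ["age", "stage"], clin, "expression")["n"]
            for g in cohort.expression.genes[:5]
            if not cohort.expression.values.loc[g].isna().any()
        }
        assert len(ns) == 1


class TestAlteredStatus:
    def test_definition(self):
        cohort = make_cohort(
            np.zeros((1, 4)), np.array([[2, -2, 1, 0]]),
            patients=["P1", "P2", "P3", "P4"], genes=["G"],
        )
        cohort.mutations = pd.DataFrame(
            [[False, False, False, True]], index=["G"], columns=["P1", "P2", "P3", "P4"]
        )
        status = altered_status(cohort, "G")
        assert status.tolist() == [True, True, False, True]


class TestAlteredContrast:
    def test_exact_small_sample_matches_enumeration(self):
        """Two-sided exact rank-sum p for (1,2,3) vs (4,5,6) equals the
        enumeration of all 20 rank assignments: the observed allocation is
        the most extreme of C(6,3)=20, giving p = 2/20 = 0.1."""
        cohort = make_cohort(
            np.array([[1.0, 2, 3, 4, 5, 6]]),
            np.array([[0, 0, 0, 2, 2, 2]]),
            genes=["G"],
        )
        res = altered_contrast(cohort, "G")
        # independent oracle: enumerate every 3-subset's rank sum
        ranks = range(1, 7)
        observed = 4 + 5 + 6
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        p_exact = sum(s >= observed or s <= (21 - observed) for s in sums) / len(sums)
        assert p_exact == 0.1
        assert res["wilcoxon_p"] == pytest.approx(p_exact, abs=1e-12)

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(3)
        expr = rng.standard_normal((1, 40))
        calls = np.zeros((1, 40), dtype=int)
        calls[0, :15] = 2
        c1 = make_cohort(expr, calls, genes=["G"])
        c2 = make_cohort(expr, np.where(calls == 2, 0, 2), genes=["G"])
        p1 = altered_contrast(c1, "G")["wilcoxon_p"]
        p2 = altered_contrast(c2, "G")["wilcoxon_p"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_flagged(self):
        cohort = make_cohort(np.zeros((1, 4)), np.zeros((1, 4)), genes=["G"])
        res = altered_contrast(cohort, "G")
        assert res["flag"] == "one group empty"
        assert np.isnan(res["wilcoxon_p"])


class TestHrCategory:
    @pytest.mark.parametrize(
        "hr, expected",
        [
            (1.0, "none"),
            (1.058, "sub-small"),
            (1.468, "small-medium"),
            (1.957, "medium-large"),
            (4.55, "large"),
            (0.455, "medium-large"),   # 1/0.455 = 2.2
            (0.88, "sub-small"),
        ],
    )
    def test_bands(self, hr, expected):
        assert hr_category(hr) == expected

    def test_reciprocal_symmetry(self):
        for hr in (1.4, 2.0, 3.5):
            assert hr_category(hr) == hr_category(1.0 / hr)


class TestTriage:
    @staticmethod
    def _tables():
        screen = pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D", "E", "F"],
                "direction": [
                    "facilitator", "facilitator", "suppressor",
                    "suppressor", "facilitator", "none",
                ],
            }
        )
        surv = pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D", "E"],
                "expression_p": [0.01, 0.02, 0.001, 0.04, 0.5],
                "expression_hr": [1.5, 0.8, 2.0, 0.7, 1.1],
                "group_hr": [0.5, 0.6, 1.468, 2.0, 1.2],
                "group_p": [0.01] * 5,
                "wilcoxon_p": [0.01] * 5,
                "mean_altered": [-1.0, 1.0, -1.0, 1.0, 0.0],
                "mean_unaltered": [0.0, 0.0, 0.0, 0.0, 0.0],
            }
        ).set_index("gene")
        return screen, surv

    def test_categories_and_drug_directions(self):
        screen, surv = self._tables()
        tri = triage(screen, surv)
        # A: lower altered expression, improved survival -> (a), inhibitor
        assert tri.loc["A", ["category", "drug_direction"]].tolist() == ["a", "inhibitor"]
        # B: higher altered expression, improved survival -> (b), enhancer
        assert tri.loc["B", ["category", "drug_direction"]].tolist() == ["b", "enhancer"]
        # C: lower altered expression, decreased survival -> (c), enhancer
        assert tri.loc["C", ["category", "drug_direction"]].tolist() == ["c", "enhancer"]
        # D: higher altered expression, decreased survival -> (d), inhibitor
        assert tri.loc["D", ["category", "drug_direction"]].tolist() == ["d", "inhibitor"]

    def test_hr_band_and_actionability_line(self):
        screen, surv = self._tables()
        tri = triage(screen, surv)
        assert tri.loc["C", "hr_category"] == "small-medium"
        assert tri.loc["C", "actionable"]
        # E is not survival-critical (p = 0.5): everything none
        assert not tri.loc["E", "survival_critical"]
        assert tri.loc["E", "hr_category"] == "none"

    def test_survival_critical_subset_of_screen_significant(self):
        screen, surv = self._tables()
        tri = triage(screen, surv)
        sig_genes = set(screen.loc[screen["direction"] != "none", "gene"])
        assert set(tri.index) <= sig_genes
        assert set(tri[tri["survival_critical"]].index) <= sig_genes

    def test_hr_exactly_one_is_none(self):
        screen, surv = self._tables()
        surv.loc["A", "group_hr"] = 1.0
        tri = triage(screen, surv)
        assert tri.loc["A", ["category", "hr_category", "drug_direction"]].tolist() == [
            "none", "none", "none"
        ]


def test_run_survival_screen_smoke(planted_cohort):
    _, cohort, _ = planted_cohort
    res = run_survival_screen(cohort, ["FAC0", "SUP0"])
    assert {"expression_hr", "group_hr", "wilcoxon_p"} <= set(res.columns)
    assert res.loc["FAC0", "expression_p"] < 0.05  # planted beta = 0.5
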