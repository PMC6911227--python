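"""Logistic-regression PheWAS: estimation, skipping, and run comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from phemap import (
    CaseControlCohort,
    TerminologyError,
    compare_runs,
    fit_logistic,
    run_phewas,
)
from phemap.phewas import build_design


def _two_by_two(a, b, c, d):
    """exposed-case=a, exposed-control=b, unexposed-case=c, -control=d."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, pd.DataFrame({"dosage": x})


class TestFitLogistic:
    def test_2x2_matches_crossproduct_ratio(self):
        y, X = _two_by_two(20, 80, 10, 90)
        fit = fit_logistic(y, X)
        assert fit.odds_ratio == pytest.approx((20 * 90) / (80 * 10),
                                               rel=1e-7)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_2x2_closed_form_6_digits(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(5, 200, size=4)
        y, X = _two_by_two(a, b, c, d)
        fit = fit_logistic(y, X)
        assert fit.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_all_controls_raises_separation(self):
        y = np.zeros(50)
        X = pd.DataFrame({"dosage": np.random.default_rng(0).integers(0, 3, 50)})
        with pytest.raises(PerfectSeparationError):
            fit_logistic(y, X)

    def test_perfectly_separated_raises(self):
        x = np.r_[np.ones(30), np.zeros(30)]
        y = x.copy()
        with pytest.raises(PerfectSeparationError):
            fit_logistic(y, pd.DataFrame({"dosage": x}))

    def test_constant_column_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = pd.DataFrame({"dosage": np.tile([0, 1], 10), "flat": 1.0})
        with pytest.raises(TerminologyError, match="flat"):
            fit_logistic(y, X)

    def test_singular_design_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.tile([0.0, 1.0], 10)
        X = pd.DataFrame({"dosage": x, "copy": x + 1})
        with pytest.raises(TerminologyError, match="singular"):
            fit_logistic(y, X)

    def test_ci_contains_or_and_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (500, 5000):
            x = rng.binomial(2, 0.3, n)
            p = 1 / (1 + np.exp(-(-1.0 + 0.4 * x)))
            y = rng.random(n) < p
            fit = fit_logistic(y, pd.DataFrame({"dosage": x}))
            lo, hi = fit.ci95
            assert lo < fit.odds_ratio < hi
            widths.append(math.log(hi) - math.log(lo))
        assert widths[1] < widths[0]

    def test_planted_effect_recovered_with_covariates(self):
        """Planted per-allele log-OR 0.47 recovered inside the Wald CI."""
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.binomial(2, 0.3, n)
        age = rng.normal(50, 15, n)
        sex = rng.integers(0, 2, n)
        eta = -2.3 + math.log(1.6) * x + 0.01 * (age - 50) + 0.2 * sex
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        X = pd.DataFrame({"dosage": x, "age": age, "sex_female": sex})
        fit = fit_logistic(y, X)
        lo, hi = fit.ci95
        assert lo < 1.6 < hi


def _subjects(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "dosage": rng.binomial(2, 0.3, n),
            "age": rng.normal(50, 15, n).round(1),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["white", "black", "other"], n,
                               p=[0.7, 0.2, 0.1]),
        }
    )


class TestBuildDesign:
    def test_one_hot_race_largest_reference(self):
        design = build_design(_subjects(500, seed=1))
        assert "race_white" not in design.columns  # largest is reference
        assert {"race_black", "race_other"} <= set(design.columns)
        assert set(design["sex_female"].unique()) <= {0.0, 1.0}

    def test_dominant_coding(self):
        subjects = _subjects(100)
        design = build_design(subjects, genotype_coding="dominant")
        assert set(design["dosage"].unique()) <= {0.0, 1.0}

    def test_bad_dosage_rejected(self):
        subjects = _subjects(10)
        subjects.loc[0, "dosage"] = 3
        with pytest.raises(TerminologyError, match="dosage"):
            build_design(subjects)


class TestRunPhewas:
    def _cohorts(self, subjects, seed=0, effect=0.0, n_phecodes=5):
        rng = np.random.default_rng(seed)
        ids = subjects["patient_id"].to_numpy()
        dosage = subjects["dosage"].to_numpy()
        cohorts = []
        for j in range(n_phecodes):
            beta = effect if j == 0 else 0.0
            p = 1 / (1 + np.exp(-(-1.5 + beta * dosage)))
            is_case = rng.random(len(ids)) < p
            cohorts.append(
                CaseControlCohort(
                    phecode=f"{100 + j}.1",
                    cases=set(ids[is_case]),
                    controls=set(ids[~is_case]),
                )
            )
        return cohorts

    def test_planted_association_is_top_hit(self):
        subjects = _subjects(3000, seed=2)
        cohorts = self._cohorts(subjects, seed=3, effect=math.log(2.5))
        run = run_phewas(cohorts, subjects, min_cases=20)
        frame = run.to_frame().query("tested")
        top = frame.loc[frame["p"].idxmin()]
        assert top["phecode"] == "100.1"
        assert top["p"] < run.bonferroni_alpha

    def test_min_cases_skip_flagged(self):
        subjects = _subjects(200)
        cohorts = self._cohorts(subjects, n_phecodes=2)
        run = run_phewas(cohorts, subjects, min_cases=10_000)
        assert run.n_tested == 0
        assert run.bonferroni_alpha is None
        assert all("fewer than" in r.skip_reason for r in run.results)

    def test_bonferroni_over_tested_only(self):
        subjects = _subjects(1000, seed=4)
        cohorts = self._cohorts(subjects, seed=5, n_phecodes=4)
        # starve one cohort of cases so it is skipped
        starved = CaseControlCohort(
            phecode="999.9",
            cases=set(list(cohorts[0].controls)[:3]),
            controls=cohorts[0].cases,
        )
        run = run_phewas(cohorts + [starved], subjects, min_cases=20)
        assert run.n_tested == 4
        assert run.bonferroni_alpha == pytest.approx(0.05 / 4)

    def test_excluded_absent_from_design(self):
        subjects = _subjects(300, seed=6)
        ids = list(subjects["patient_id"])
        cohort = CaseControlCohort(
            phecode="100.1", cases=set(ids[:60]),
            controls=set(ids[60:240]), excluded=set(ids[240:]),
        )
        run = run_phewas([cohort], subjects, min_cases=20)
        res = run.results[0]
        assert res.n_cases + res.n_controls == 240

    def test_empty_cohort_list_rejected(self):
        with pytest.raises(TerminologyError):
            run_phewas([], _subjects(10))


class TestCompareRuns:
    def test_self_comparison_identical(self):
        subjects = _subjects(1000, seed=7)
        rng_cohorts = TestRunPhewas()._cohorts(subjects, seed=8,
                                               effect=math.log(2.0))
        run = run_phewas(rng_cohorts, subjects, min_cases=20)
        table = compare_runs(run, run)
        assert (table["beta_a"] == table["beta_b"]).all()
        assert table.attrs["concordance"] in (1.0,) or \
            math.isnan(table.attrs["concordance"])
        assert table["concordant_sign"].all()

    def test_disjoint_runs_warn_empty(self):
        subjects = _subjects(500, seed=9)
        helper = TestRunPhewas()
        run_a = run_phewas(helper._cohorts(subjects, seed=1, n_phecodes=2),
                           subjects, min_cases=20)
        cohorts_b = helper._cohorts(subjects, seed=2, n_phecodes=2)
        for c in cohorts_b:
            c.phecode = "7" + c.phecode
        run_b = run_phewas(cohorts_b, subjects, min_cases=20)
        with pytest.warns(UserWarning, match="no tested phecodes"):
            table = compare_runs(run_a, run_b)
        assert table.empty

    def test_zero_significant_defined_output(self):
        subjects = _subjects(300, seed=10)
        run = run_phewas(
            TestRunPhewas()._cohorts(subjects, seed=11, n_phecodes=3),
            subjects, min_cases=20,
        )
        table = compare_runs(run, run)
        if table.attrs["n_significant_both"] == 0:
            assert math.isnan(table.attrs["concordance"])
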