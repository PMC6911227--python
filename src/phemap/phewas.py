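"""Per-phecode logistic-regression PheWAS.

For each phecode cohort, case status is regressed on allele dosage with
age, sex, and race as covariates; the per-allele odds ratio, Wald 95% CI
and two-sided Wald p-value are reported. Phecodes with too few cases are
skipped, excluded patients are dropped from that phecode's model, and the
multiple-testing threshold is Bonferroni over the phecodes actually
tested. Two runs built from different maps over the same subjects can be
compared side by side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .terminology import TerminologyError

__all__ = [
    "LogisticFit",
    "PhewasResult",
    "PhewasRun",
    "fit_logistic",
    "build_design",
    "run_phewas",
    "compare_runs",
    "manhattan_plot",
]

SUBJECT_COLUMNS = ["patient_id", "dosage", "age", "sex", "race"]

#: |log-odds| beyond which a fitted coefficient is treated as diverged
_DIVERGENCE_BOUND = 15.0


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit for one term of interest."""

    beta: float
    se: float
    p_value: float
    converged: bool
    params: pd.Series
    bse: pd.Series

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        lo = math.exp(self.beta - 1.96 * self.se)
        hi = math.exp(self.beta + 1.96 * self.se)
        return lo, hi


def fit_logistic(
    case_status, design: pd.DataFrame, term: str = "dosage"
) -> LogisticFit:
    """Fit ``case_status ~ design`` by maximum likelihood.

    ``design`` must contain the ``term`` column (the exposure of
    interest) and any covariates; an intercept is added here. Raises
    :class:`TerminologyError` for a singular design and
    :class:`PerfectSeparationError` when the MLE diverges.
    """
    y = np.asarray(case_status, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise PerfectSeparationError("all-case or all-control outcome")
    X = sm.add_constant(design.astype(float), has_constant="add")
    nonconst = X.drop(columns="const")
    if (nonconst.nunique() <= 1).any():
        bad = nonconst.columns[nonconst.nunique() <= 1][0]
        raise TerminologyError(f"constant non-intercept column {bad!r}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise TerminologyError("singular design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise PerfectSeparationError(str(exc)) from exc
    beta = float(result.params[term])
    se = float(result.bse[term])
    if not np.isfinite(beta) or not np.isfinite(se) \
            or abs(beta) > _DIVERGENCE_BOUND:
        raise PerfectSeparationError("diverged estimate (quasi-separation)")
    return LogisticFit(
        beta=beta,
        se=se,
        p_value=float(result.pvalues[term]),
        converged=bool(result.mle_retvals.get("converged", True)),
        params=result.params,
        bse=result.bse,
    )


@dataclass
class PhewasResult:
    """Per-phecode association estimate (or a flagged skip)."""

    phecode: str
    n_cases: int
    n_controls: int
    beta: float = float("nan")
    se: float = float("nan")
    odds_ratio: float = float("nan")
    ci95: tuple = (float("nan"), float("nan"))
    p_value: float = float("nan")
    tested: bool = False
    skip_reason: str = ""


@dataclass
class PhewasRun:
    """One full phenome scan under one phecode map."""

    map_id: str
    results: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def n_tested(self) -> int:
        return sum(r.tested for r in self.results)

    @property
    def bonferroni_alpha(self) -> float | None:
        """0.05 / number of phecodes tested; None when nothing was tested."""
        n = self.n_tested
        return self.alpha / n if n else None

    def significant(self) -> list[PhewasResult]:
        thr = self.bonferroni_alpha
        if thr is None:
            return []
        return [r for r in self.results if r.tested and r.p_value < thr]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phecode": r.phecode,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "beta": r.beta,
                "or_": r.odds_ratio,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "p": r.p_value,
                "tested": r.tested,
                "skip_reason": r.skip_reason,
            }
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=["phecode", "n_cases", "n_controls", "beta", "or_",
                     "ci_lo", "ci_hi", "p", "tested", "skip_reason"],
        ).sort_values("phecode").reset_index(drop=True)


def build_design(
    subjects: pd.DataFrame,
    genotype_coding: str = "additive",
    covariates: bool = True,
) -> pd.DataFrame:
    """Design matrix (indexed by patient_id) from a subject table.

    Dosage enters additively (0/1/2 effect alleles) or dominantly
    (carrier indicator). Sex becomes a binary indicator; race is one-hot
    encoded with the largest category as reference.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise TerminologyError(f"subjects table missing column(s) {missing}")
    dosage = subjects["dosage"].astype(int)
    if not dosage.isin([0, 1, 2]).all():
        raise TerminologyError("dosage must be 0, 1, or 2")
    if genotype_coding == "additive":
        dose = dosage.astype(float)
    elif genotype_coding == "dominant":
        dose = (dosage > 0).astype(float)
    else:
        raise TerminologyError(f"unknown genotype coding {genotype_coding!r}")
    design = pd.DataFrame(
        {"dosage": dose.to_numpy()},
        index=subjects["patient_id"].astype(str),
    )
    if covariates:
        design["age"] = subjects["age"].astype(float).to_numpy()
        sex = subjects["sex"].astype(str)
        design["sex_female"] = (
            sex.str.upper().isin(["F", "FEMALE"]).astype(float).to_numpy()
        )
        race = subjects["race"].astype(str)
        reference = race.value_counts().idxmax()
        for level in sorted(set(race) - {reference}):
            design[f"race_{level}"] = (race == level).astype(float).to_numpy()
    return design


def run_phewas(
    cohorts,
    subjects: pd.DataFrame,
    min_cases: int = 20,
    map_id: str = "",
    genotype_coding: str = "additive",
    covariates: bool = True,
    alpha: float = 0.05,
) -> PhewasRun:
    """Scan a phenome: one logistic fit per sufficiently large cohort.

    ``cohorts`` is an iterable of :class:`~phemap.phenotyping.CaseControlCohort`
    built from one map; each phecode's excluded patients are dropped from
    its regression. Separation or nonconvergence flags the phecode as
    untested rather than reporting an estimate.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise TerminologyError("empty cohort list")
    design = build_design(subjects, genotype_coding, covariates)
    known = set(design.index)
    results = []
    for cohort in cohorts:
        cases = cohort.cases & known
        controls = cohort.controls & known
        res = PhewasResult(
            phecode=cohort.phecode, n_cases=len(cases),
            n_controls=len(controls),
        )
        if len(cases) < min_cases:
            res.skip_reason = f"fewer than {min_cases} cases"
        elif not controls:
            res.skip_reason = "no controls"
        else:
            ids = sorted(cases) + sorted(controls)
            assert not (set(ids) & cohort.excluded), \
                "excluded patient in design"
            y = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
            try:
                fit = fit_logistic(y, design.loc[ids])
            except PerfectSeparationError as exc:
                res.skip_reason = f"separation: {exc}"
            except TerminologyError as exc:
                res.skip_reason = str(exc)
            else:
                if not fit.converged:
                    res.skip_reason = "did not converge"
                else:
                    res.beta, res.se = fit.beta, fit.se
                    res.odds_ratio, res.ci95 = fit.odds_ratio, fit.ci95
                    res.p_value, res.tested = fit.p_value, True
        results.append(res)
    return PhewasRun(map_id=map_id, results=results, alpha=alpha)


def compare_runs(run_a: PhewasRun, run_b: PhewasRun) -> pd.DataFrame:
    """Side-by-side results for phecodes tested in both runs.

    Adds a ``concordant_sign`` column and a summary attribute
    ``df.attrs["concordance"]`` = fraction of phecodes Bonferroni-
    significant in both runs whose effect directions agree (NaN when the
    doubly significant set is empty).
    """
    a = run_a.to_frame().query("tested")
    b = run_b.to_frame().query("tested")
    merged = a.merge(b, on="phecode", suffixes=("_a", "_b"))
    if merged.empty:
        warnings.warn("compared runs share no tested phecodes")
    merged["concordant_sign"] = np.sign(merged.get("beta_a", pd.Series(dtype=float))) \
        == np.sign(merged.get("beta_b", pd.Series(dtype=float)))
    thr_a, thr_b = run_a.bonferroni_alpha, run_b.bonferroni_alpha
    if merged.empty or thr_a is None or thr_b is None:
        both_sig = merged.iloc[0:0]
    else:
        both_sig = merged[(merged["p_a"] < thr_a) & (merged["p_b"] < thr_b)]
    merged.attrs["n_significant_both"] = len(both_sig)
    merged.attrs["concordance"] = (
        float(both_sig["concordant_sign"].mean()) if len(both_sig) else
        float("nan")
    )
    return merged


def manhattan_plot(run: PhewasRun, path, categories=None):
    """Write a Manhattan-style plot (-log10 p by phecode) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = run.to_frame().query("tested").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(8, 3))
    if not frame.empty:
        x = np.arange(len(frame))
        color_key = (
            frame["phecode"].map(categories) if categories
            else frame["phecode"].str.split(".").str[0]
        )
        for _, idx in color_key.groupby(color_key).groups.items():
            ax.scatter(x[idx], -np.log10(frame.loc[idx, "p"]), s=12)
        thr = run.bonferroni_alpha
        if thr:
            ax.axhline(-np.log10(thr), ls="--", lw=0.8, color="red")
        ax.set_xticks(x)
        ax.set_xticklabels(frame["phecode"], rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_xlabel("phecode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
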