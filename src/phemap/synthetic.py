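"""Synthetic terminologies and synthetic two-era EHR cohorts.

No licensed terminology (UMLS, CMS GEMS, OHDSI vocabularies) or patient
data ships with, or is needed by, this package. Instead:

* :func:`build_fixture_bundle` constructs a miniature but structurally
  faithful terminology bundle — ICD code lists, GEMS-style crosswalk,
  CUI/SNOMED/OHDSI concept tables, and an ICD-9-CM phecode map — that
  encodes a set of canonical mapping chains (direct description match,
  two-hop GEMS chains, five-hop concept chains, parent/child candidate
  pairs, dual-family targets) together with decoy codes that map nowhere.
* :func:`simulate_cohort` draws a synthetic patient cohort spanning an
  ICD-9-CM era window and an ICD-10-CM era window, with latent disease
  states, configurable cross-era persistence, Hardy–Weinberg genotypes,
  an optional planted genotype effect on one phenotype, and demographic
  covariates. Diseased patients emit era-appropriate billing codes drawn
  from the fixture terminology; every patient emits a filler code per
  window so that two-window cohort membership is not phenotype-driven.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import ObservationWindow
from .phenotyping import EVENT_COLUMNS, CaseControlCohort
from .terminology import Resource, TerminologyBundle, TerminologyError, Vocabulary

__all__ = [
    "SIM_PHENOTYPES",
    "PhenotypeSim",
    "GenotypeEffect",
    "CohortSimConfig",
    "SimulatedCohort",
    "build_fixture_bundle",
    "simulate_cohort",
    "simulate_null_phenome",
]


# ---------------------------------------------------------------------------
# fixture terminology bundle
# ---------------------------------------------------------------------------

def _codes(rows):
    return pd.DataFrame(rows, columns=["code", "description"])


def _edges(rows):
    return pd.DataFrame(
        rows,
        columns=["source_vocab", "source_code", "target_vocab", "target_code",
                 "approximate_flag"],
    )


def build_fixture_bundle(n_decoys: int = 3, out_dir=None) -> TerminologyBundle:
    """Build the fixture terminology bundle (optionally writing its CSVs).

    Canonical chains encoded (each replays through the mapping engine):

    ====================  ==========================================  =========
    source                route                                       phecode
    ====================  ==========================================  =========
    ICD-10-CM H52.4       description match "Presbyopia"              367.4
    ICD-10-CM E11.9       GEMS → ICD-9-CM 250.0                       250.2
    ICD-10-CM L01.00      CUI C0021099 → SNOMED 48277006 → OHDSI
                          140480 → 44832600 → ICD-9-CM 684            686.2
    ICD-10-CM I10         GEMS → 401.9 → {401, 401.1}; child kept     401.1
    ICD-10-CM D57.812     GEMS → 282.69 → {282.5, 289.5}; both kept   282.5+289.5
    ICD-10-CM I25.708     GEMS → {413.9, 414.01}                      411.3+411.4
    ICD-10 B21.1          CUI/SNOMED → NLM → {042, 200.20}            071.1+202.2
    ICD-9-CM 311,
    296.31, 296.2         ICD-9-CM phecode map (depression group)     296.2
    ====================  ==========================================  =========

    Additional simulator-support chains: E78.5→272.4→272.1
    (hyperlipidemia), A04.7→008.45→008.5 (intestinal infection),
    E10.9→250.01→250.1 (type 1 diabetes), R73.09→790.29→250.4
    (abnormal glucose). ``n_decoys`` ICD-10-CM codes with no complete
    chain (plus the filler codes Z00.00 / V70.0) stay unmapped.
    """
    decoys = [
        (f"X{50 + i}.{i}", f"Decoy condition {i}") for i in range(n_decoys)
    ]
    icd10cm = _codes(
        [
            ("H52.4", "Presbyopia"),
            ("E11.9", "Type 2 diabetes mellitus without complications"),
            ("E10.9", "Type 1 diabetes mellitus without complications"),
            ("L01.00", "Impetigo, unspecified"),
            ("I10", "Essential (primary) hypertension"),
            ("D57.812", "Other sickle-cell disorders with splenic sequestration"),
            ("I25.708", "Atherosclerosis of coronary artery bypass graft(s), "
                        "unspecified, with other forms of angina pectoris"),
            ("E78.5", "Hyperlipidemia, unspecified"),
            ("A04.7", "Enterocolitis due to Clostridium difficile"),
            ("R73.09", "Other abnormal glucose"),
            ("Z00.00", "Encounter for general adult medical examination"),
        ]
        + decoys
    )
    icd10 = _codes(
        [
            ("B21.1", "HIV disease resulting in Burkitt lymphoma"),
            ("A16.9", "Respiratory tuberculosis unspecified"),
        ]
    )
    icd9cm = _codes(
        [
            ("250.0", "Diabetes mellitus without mention of complication"),
            ("250.01", "Diabetes mellitus without mention of complication, type I"),
            ("684", "Impetigo"),
            ("401.9", "Unspecified essential hypertension"),
            ("282.69", "Other sickle-cell disease without crisis"),
            ("413.9", "Other and unspecified angina pectoris"),
            ("414.01", "Coronary atherosclerosis of native coronary artery"),
            ("272.4", "Other and unspecified hyperlipidemia"),
            ("008.45", "Intestinal infection due to Clostridium difficile"),
            ("790.29", "Other abnormal glucose"),
            ("042", "Human immunodeficiency virus disease"),
            ("200.20", "Burkitt's tumor, unspecified site"),
            ("311", "Depressive disorder, not elsewhere classified"),
            ("296.31", "Major depressive disorder, recurrent episode, mild"),
            ("296.2", "Major depressive disorder, single episode"),
            ("V70.0", "Routine general medical examination"),
        ]
    )
    snomed = _codes(
        [
            ("48277006", "Impetigo (disorder)"),
            ("86406008", "HIV infection (disorder)"),
            ("77381001", "Burkitt lymphoma (clinical)"),
        ]
    )
    cui = _codes(
        [
            ("C0021099", "Impetigo"),
            ("C0019693", "HIV Infections"),
            ("C0006413", "Burkitt Lymphoma"),
        ]
    )
    ohdsi = _codes(
        [
            ("140480", "Impetigo (SNOMED concept)"),
            ("44832600", "Impetigo (ICD9CM concept)"),
        ]
    )
    phecodes = pd.DataFrame(
        [
            ("367.4", "Presbyopia", ""),
            ("249", "Secondary diabetes mellitus", "249-250.99"),
            ("250", "Diabetes mellitus", "249-250.99"),
            ("250.1", "Type 1 diabetes", "249-250.99"),
            ("250.2", "Type 2 diabetes", "249-250.99"),
            ("250.4", "Abnormal glucose", "249-250.99"),
            ("686.2", "Impetigo", ""),
            ("401", "Hypertension", "401-405.99"),
            ("401.1", "Essential hypertension", "401-405.99"),
            ("282.5", "Sickle cell anemia", "282-282.99"),
            ("289.5", "Diseases of spleen", ""),
            ("411.3", "Angina pectoris", "410-414.99"),
            ("411.4", "Coronary atherosclerosis", "410-414.99"),
            ("272.1", "Hyperlipidemia", "272-272.99"),
            ("008", "Intestinal infection", "008-009.99"),
            ("008.5", "Bacterial enteritis", "008-009.99"),
            ("071.1", "HIV infection, symptomatic", ""),
            ("202.2", "Non-Hodgkins lymphoma", ""),
            ("296.2", "Depression", "296-296.99"),
        ],
        columns=["phecode", "description", "exclusion_ranges"],
    )

    V, R = Vocabulary, Resource
    gems = _edges(
        [
            (V.ICD10CM.value, "E11.9", V.ICD9CM.value, "250.0", 0),
            (V.ICD10CM.value, "E10.9", V.ICD9CM.value, "250.01", 0),
            (V.ICD10CM.value, "I10", V.ICD9CM.value, "401.9", 0),
            (V.ICD10CM.value, "D57.812", V.ICD9CM.value, "282.69", 1),
            (V.ICD10CM.value, "I25.708", V.ICD9CM.value, "413.9", 1),
            (V.ICD10CM.value, "I25.708", V.ICD9CM.value, "414.01", 1),
            (V.ICD10CM.value, "E78.5", V.ICD9CM.value, "272.4", 0),
            (V.ICD10CM.value, "A04.7", V.ICD9CM.value, "008.45", 0),
            (V.ICD10CM.value, "R73.09", V.ICD9CM.value, "790.29", 0),
        ]
    )
    icd9_map = _edges(
        [
            (V.ICD9CM.value, "250.0", V.PHECODE.value, "250.2", 0),
            (V.ICD9CM.value, "250.01", V.PHECODE.value, "250.1", 0),
            (V.ICD9CM.value, "684", V.PHECODE.value, "686.2", 0),
            (V.ICD9CM.value, "401.9", V.PHECODE.value, "401", 0),
            (V.ICD9CM.value, "401.9", V.PHECODE.value, "401.1", 0),
            (V.ICD9CM.value, "282.69", V.PHECODE.value, "282.5", 0),
            (V.ICD9CM.value, "282.69", V.PHECODE.value, "289.5", 0),
            (V.ICD9CM.value, "413.9", V.PHECODE.value, "411.3", 0),
            (V.ICD9CM.value, "414.01", V.PHECODE.value, "411.4", 0),
            (V.ICD9CM.value, "272.4", V.PHECODE.value, "272.1", 0),
            (V.ICD9CM.value, "008.45", V.PHECODE.value, "008.5", 0),
            (V.ICD9CM.value, "790.29", V.PHECODE.value, "250.4", 0),
            (V.ICD9CM.value, "042", V.PHECODE.value, "071.1", 0),
            (V.ICD9CM.value, "200.20", V.PHECODE.value, "202.2", 0),
            (V.ICD9CM.value, "311", V.PHECODE.value, "296.2", 0),
            (V.ICD9CM.value, "296.31", V.PHECODE.value, "296.2", 0),
            (V.ICD9CM.value, "296.2", V.PHECODE.value, "296.2", 0),
        ]
    )
    umls_cui = _edges(
        [
            (V.ICD10CM.value, "L01.00", V.CUI.value, "C0021099", 0),
            (V.CUI.value, "C0021099", V.SNOMED.value, "48277006", 0),
            (V.ICD10.value, "B21.1", V.CUI.value, "C0019693", 0),
            (V.ICD10.value, "B21.1", V.CUI.value, "C0006413", 0),
            (V.CUI.value, "C0019693", V.SNOMED.value, "86406008", 0),
            (V.CUI.value, "C0006413", V.SNOMED.value, "77381001", 0),
        ]
    )
    nlm = _edges(
        [
            (V.SNOMED.value, "86406008", V.ICD9CM.value, "042", 0),
            (V.SNOMED.value, "77381001", V.ICD9CM.value, "200.20", 0),
        ]
    )
    ohdsi_rel = _edges(
        [
            (V.SNOMED.value, "48277006", V.OHDSI_CONCEPT.value, "140480", 0),
            (V.OHDSI_CONCEPT.value, "140480", V.OHDSI_CONCEPT.value,
             "44832600", 0),
            (V.OHDSI_CONCEPT.value, "44832600", V.ICD9CM.value, "684", 0),
        ]
    )

    bundle = TerminologyBundle(
        codes={
            V.ICD10CM: icd10cm,
            V.ICD10: icd10,
            V.ICD9CM: icd9cm,
            V.SNOMED: snomed,
            V.CUI: cui,
            V.OHDSI_CONCEPT: ohdsi,
        },
        edges={
            R.GEMS: gems,
            R.ICD9_PHECODE_MAP: icd9_map,
            R.UMLS_CUI: umls_cui,
            R.NLM_MAP: nlm,
            R.OHDSI_REL: ohdsi_rel,
        },
        phecodes=phecodes,
    ).validate()
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSim:
    """Latent-disease parameters for one simulated phenotype.

    prevalence_w1
        P(diseased in window 1).
    persistence
        probability that window-1 disease carries over into window 2; the
        two-window reproducibility statistic estimates
        1 - (1 - persistence)(1 - incidence_w2), i.e. persistence itself
        whenever new-episode risk is negligible.
    incidence_w2
        independent per-window risk of a new episode; applies to everyone
        (for a window-1 case it stacks on top of carry-over, so an acute
        disease with persistence 0 reproduces at its incidence).
    """

    target_prefix: str
    icd9_codes: tuple
    icd10cm_codes: tuple
    prevalence_w1: float
    persistence: float
    incidence_w2: float = 0.0

    def __post_init__(self):
        for name in ("prevalence_w1", "persistence", "incidence_w2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TerminologyError(f"{name} out of [0, 1]: {v}")


@dataclass(frozen=True)
class GenotypeEffect:
    """Planted per-allele effect on one phenotype's window-1 log-odds."""

    phenotype: str
    allele_freq: float
    log_or: float

    def __post_init__(self):
        if not 0.0 < self.allele_freq < 1.0:
            raise TerminologyError("allele_freq must be in (0, 1)")


#: default phenotypes: four chronic diseases plus one acute negative
#: control, with chronic persistence in the observed 70–75% band and an
#: acute phenotype that essentially never persists across eras
SIM_PHENOTYPES = {
    "hypertension": PhenotypeSim("401", ("401.9",), ("I10",), 0.25, 0.75),
    "hyperlipidemia": PhenotypeSim("272", ("272.4",), ("E78.5",), 0.20, 0.72),
    "type1_diabetes": PhenotypeSim("250.1", ("250.01",), ("E10.9",), 0.02, 0.76),
    "type2_diabetes": PhenotypeSim("250.2", ("250.0",), ("E11.9",), 0.10, 0.75),
    "intestinal_infection": PhenotypeSim(
        "008", ("008.45",), ("A04.7",), 0.02, 0.0, incidence_w2=0.02
    ),
    "abnormal_glucose": PhenotypeSim(
        "250.4", ("790.29",), ("R73.09",), 0.05, 0.60
    ),
}

_DEFAULT_W1 = ObservationWindow(date(2014, 1, 1), date(2015, 6, 30))
_DEFAULT_W2 = ObservationWindow(date(2016, 1, 1), date(2017, 6, 30))


@dataclass
class CohortSimConfig:
    """Full configuration of a simulated two-era cohort.

    Defaults mirror a mid-2010s US academic medical center cohort: two
    disjoint 18-month coding-era windows, 55.1% female, age ~ N(45, 25²)
    truncated at 0, and an uncommon risk allele (frequency 0.066, i.e.
    ~87.2/12.3/0.4% expected genotype split under Hardy–Weinberg).
    """

    n_patients: int = 1000
    seed: int = 0
    window1: ObservationWindow = _DEFAULT_W1
    window2: ObservationWindow = _DEFAULT_W2
    phenotypes: dict = field(default_factory=lambda: dict(SIM_PHENOTYPES))
    genotype: GenotypeEffect | None = GenotypeEffect(
        "type2_diabetes", 0.066, 0.0
    )
    age_mean: float = 45.0
    age_sd: float = 25.0
    female_fraction: float = 0.551
    race_probs: dict = field(
        default_factory=lambda: {"white": 0.70, "black": 0.15, "other": 0.15}
    )

    def __post_init__(self):
        if self.seed is None:
            raise TerminologyError("simulation seed is mandatory")
        if self.n_patients < 1:
            raise TerminologyError("n_patients must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise TerminologyError("female_fraction out of [0, 1]")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise TerminologyError("race_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortSimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {
            "n_patients", "seed", "window1", "window2", "phenotypes",
            "genotype", "age_mean", "age_sd", "female_fraction", "race_probs",
        }
        unknown = set(raw) - known
        if unknown:
            raise TerminologyError(f"unknown config key(s) {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("window1", "window2"):
            if key in kwargs:
                kwargs[key] = ObservationWindow.parse(kwargs[key])
        if "phenotypes" in kwargs:
            kwargs["phenotypes"] = {
                name: PhenotypeSim(
                    target_prefix=str(p["target_prefix"]),
                    icd9_codes=tuple(p["icd9_codes"]),
                    icd10cm_codes=tuple(p["icd10cm_codes"]),
                    prevalence_w1=float(p["prevalence_w1"]),
                    persistence=float(p["persistence"]),
                    incidence_w2=float(p.get("incidence_w2", 0.0)),
                )
                for name, p in kwargs["phenotypes"].items()
            }
        if kwargs.get("genotype") is not None:
            g = kwargs["genotype"]
            kwargs["genotype"] = GenotypeEffect(
                g["phenotype"], float(g["allele_freq"]), float(g["log_or"])
            )
        return cls(**kwargs)


@dataclass
class SimulatedCohort:
    """events + subjects + latent truth for one simulated cohort."""

    events: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame
    config: CohortSimConfig

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(directory / "events.csv", index=False)
        self.subjects.to_csv(directory / "subjects.csv", index=False)
        self.truth.to_csv(directory / "truth.csv", index=False)
        return directory


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _random_dates(rng, window: ObservationWindow, n: int) -> list[str]:
    span = (window.end - window.start).days + 1
    offsets = rng.integers(0, span, size=n)
    return [(window.start + timedelta(days=int(o))).isoformat() for o in offsets]


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Draw a full synthetic two-era cohort from ``config``.

    Latent disease states are drawn first (window 1 from prevalence, with
    the planted genotype effect applied on the log-odds scale for the
    target phenotype; window 2 from persistence or incidence given the
    window-1 state), then expressed as 1–3 dated era-appropriate billing
    codes per diseased window. Filler codes (ICD-9-CM V70.0 in window 1,
    ICD-10-CM Z00.00 in window 2 — both unmapped) guarantee every patient
    meets the two-window cohort-membership criterion.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- subjects -------------------------------------------------------
    if config.genotype is not None:
        q = config.genotype.allele_freq
        dosage = rng.binomial(2, q, size=n)  # Hardy–Weinberg
    else:
        dosage = np.zeros(n, dtype=int)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    while (age < 0).any():  # truncate at 0 by redrawing
        neg = age < 0
        age[neg] = rng.normal(config.age_mean, config.age_sd, size=neg.sum())
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    race_levels = sorted(config.race_probs)
    race = rng.choice(
        race_levels, size=n,
        p=[config.race_probs[r] for r in race_levels],
    )
    subjects = pd.DataFrame(
        {
            "patient_id": ids,
            "dosage": dosage,
            "age": np.round(age, 1),
            "sex": sex,
            "race": race,
        }
    )

    # --- latent disease states -----------------------------------------
    truth_rows = []
    events_rows = []
    for name in sorted(config.phenotypes):
        pheno = config.phenotypes[name]
        base = _logit(pheno.prevalence_w1)
        eta = np.full(n, base)
        if config.genotype is not None and config.genotype.phenotype == name:
            eta = eta + config.genotype.log_or * dosage
        p1 = 1.0 / (1.0 + np.exp(-eta))
        w1 = rng.random(n) < p1
        carry = 1.0 - (1.0 - pheno.persistence) * (1.0 - pheno.incidence_w2)
        p2 = np.where(w1, carry, pheno.incidence_w2)
        w2 = rng.random(n) < p2
        truth_rows.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "phenotype": name,
                    "status_w1": w1.astype(int),
                    "status_w2": w2.astype(int),
                }
            )
        )
        for window, statuses, codes, vocab in (
            (config.window1, w1, pheno.icd9_codes, Vocabulary.ICD9CM),
            (config.window2, w2, pheno.icd10cm_codes, Vocabulary.ICD10CM),
        ):
            sick = np.flatnonzero(statuses)
            n_events = 1 + rng.poisson(1.0, size=len(sick))
            for idx, k in zip(sick, n_events):
                for d in _random_dates(rng, window, int(k)):
                    events_rows.append(
                        (ids[idx], d, vocab.value, str(rng.choice(codes)))
                    )

    # filler codes: every patient has >=1 code in each window
    for window, code, vocab in (
        (config.window1, "V70.0", Vocabulary.ICD9CM),
        (config.window2, "Z00.00", Vocabulary.ICD10CM),
    ):
        dates = _random_dates(rng, window, n)
        events_rows.extend(
            (pid, d, vocab.value, code) for pid, d in zip(ids, dates)
        )

    events = (
        pd.DataFrame(events_rows, columns=EVENT_COLUMNS)
        .sort_values(EVENT_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    truth = pd.concat(truth_rows, ignore_index=True).sort_values(
        ["phenotype", "patient_id"], kind="mergesort"
    ).reset_index(drop=True)
    return SimulatedCohort(events=events, subjects=subjects, truth=truth,
                           config=config)


def simulate_null_phenome(
    n_patients: int,
    n_phecodes: int,
    seed: int,
    prevalence_range: tuple[float, float] = (0.05, 0.3),
    allele_freq: float = 0.2,
):
    """Cohorts + subjects for a phenome with no genotype effect anywhere.

    Case status for each of ``n_phecodes`` synthetic phecodes is drawn
    independently of genotype, so any association a PheWAS finds is a
    false positive — the type-I-error testbed.
    """
    rng = np.random.default_rng(seed)
    ids = np.array([f"P{i:06d}" for i in range(n_patients)])
    subjects = pd.DataFrame(
        {
            "patient_id": ids,
            "dosage": rng.binomial(2, allele_freq, size=n_patients),
            "age": np.round(np.abs(rng.normal(45, 25, size=n_patients)), 1),
            "sex": np.where(rng.random(n_patients) < 0.55, "F", "M"),
            "race": rng.choice(["white", "black", "other"],
                               size=n_patients, p=[0.7, 0.15, 0.15]),
        }
    )
    cohorts = []
    lo, hi = prevalence_range
    for j in range(n_phecodes):
        prev = rng.uniform(lo, hi)
        is_case = rng.random(n_patients) < prev
        cohorts.append(
            CaseControlCohort(
                phecode=f"{900 + j // 10}.{j % 10}",
                cases=set(ids[is_case]),
                controls=set(ids[~is_case]),
            )
        )
    return cohorts, subjects
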