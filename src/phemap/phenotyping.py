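"""Phecode-based phenotyping of patient billing-code data.

Events are dated billing-code assignments. Applying a phecode map turns
them into per-patient phenotype assignments; a case/control cohort for a
target phecode prefix is then a three-way partition of the population:

* **cases** — patients with at least ``min_code_count`` distinct dates
  carrying the target phecode or any of its hierarchy descendants;
* **excluded** — non-cases carrying any phecode inside one of the
  target's exclusion ranges (near-cases kept out of the control group);
* **controls** — everyone else.

Counting distinct dates rather than raw rows means same-day duplicate
billing never inflates a patient's code count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import pandas as pd

from .mapping import PhecodeMap
from .terminology import (
    TerminologyError,
    Vocabulary,
    in_range,
    is_strict_ancestor,
)

__all__ = [
    "EVENT_COLUMNS",
    "CaseControlCohort",
    "load_events",
    "distinct_instances",
    "map_events",
    "case_phecodes",
    "define_cases_controls",
]

EVENT_COLUMNS = ["patient_id", "date", "vocabulary", "code"]


def load_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise TerminologyError(f"events file missing column(s) {missing}")
    return events


def distinct_instances(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique (patient, date, vocabulary, code) instances."""
    return events.drop_duplicates(subset=EVENT_COLUMNS)[EVENT_COLUMNS]


def map_events(
    events: pd.DataFrame, pmap: PhecodeMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a phecode map to an event table.

    Returns ``(assignments, unmapped)``: assignments has one row per
    distinct (patient_id, phecode, date); the unmapped report tallies
    instance and unique-patient counts per unmapped code, sorted by
    unique-patient count descending. Instance conservation holds:
    mapped instances + unmapped instances = total distinct instances.
    """
    if not events.empty:
        bad = ~events["vocabulary"].isin([v.value for v in Vocabulary])
        if bad.any():
            row = events.index[bad][0]
            raise TerminologyError(
                f"unknown vocabulary {events.loc[row, 'vocabulary']!r} "
                f"in events row {row}"
            )
    inst = distinct_instances(events)
    key_table = pmap.to_frame()[["source_vocab", "source_code", "phecode"]]
    key_table = key_table.drop_duplicates()
    merged = inst.merge(
        key_table,
        left_on=["vocabulary", "code"],
        right_on=["source_vocab", "source_code"],
        how="left",
    )
    mapped = merged[merged["phecode"].notna()]
    assignments = (
        mapped[["patient_id", "phecode", "date"]]
        .drop_duplicates()
        .sort_values(["patient_id", "phecode", "date"])
        .reset_index(drop=True)
    )
    unmapped_inst = inst.merge(
        key_table[["source_vocab", "source_code"]].drop_duplicates(),
        left_on=["vocabulary", "code"],
        right_on=["source_vocab", "source_code"],
        how="left",
        indicator=True,
    )
    unmapped_inst = unmapped_inst[unmapped_inst["_merge"] == "left_only"]
    if unmapped_inst.empty:
        unmapped = pd.DataFrame(
            columns=["vocabulary", "code", "n_instances", "n_patients"]
        )
    else:
        unmapped = (
            unmapped_inst.groupby(["vocabulary", "code"])
            .agg(
                n_instances=("patient_id", "size"),
                n_patients=("patient_id", "nunique"),
            )
            .reset_index()
            .sort_values(
                ["n_patients", "n_instances", "code"],
                ascending=[False, False, True],
            )
            .reset_index(drop=True)
        )
    return assignments, unmapped


def case_phecodes(target_prefix: str, phecodes) -> set[str]:
    """Phecodes qualifying a patient as a case for a prefix target.

    The target itself plus every strict hierarchy descendant present in
    ``phecodes`` (the "401.*" convention: 401, 401.1, 401.22, ...).
    """
    target = str(target_prefix).strip()
    return {
        p for p in map(str, phecodes)
        if p == target or is_strict_ancestor(target, p)
    }


@dataclass
class CaseControlCohort:
    """Case/control/excluded partition of a population for one target."""

    phecode: str
    cases: set = field(default_factory=set)
    controls: set = field(default_factory=set)
    excluded: set = field(default_factory=set)
    min_code_count: int = 1

    def __post_init__(self):
        if self.cases & self.controls or self.cases & self.excluded \
                or self.controls & self.excluded:
            raise TerminologyError("cohort sets must be pairwise disjoint")

    @property
    def population(self) -> set:
        return self.cases | self.controls | self.excluded


def define_cases_controls(
    assignments: pd.DataFrame,
    target_prefix: str,
    exclusions,
    population,
    min_code_count: int = 1,
) -> CaseControlCohort:
    """Partition ``population`` into cases, controls, and excluded.

    ``exclusions`` is a list of (lo, hi) phecode intervals. Case status
    takes precedence over exclusion membership: exclusion ranges normally
    contain the target phenotype itself.
    """
    if min_code_count < 1:
        raise TerminologyError("min_code_count must be >= 1")
    population = set(population)
    extra = set(assignments["patient_id"]) - population
    if extra:
        raise TerminologyError(
            f"assignments contain patients outside population, e.g. "
            f"{sorted(extra)[0]!r}"
        )
    intervals = [(Decimal(str(lo)), Decimal(str(hi))) for lo, hi in exclusions]

    qualifying = case_phecodes(target_prefix, assignments["phecode"].unique())
    target_rows = assignments[assignments["phecode"].isin(qualifying)]
    date_counts = target_rows.groupby("patient_id")["date"].nunique()
    cases = set(date_counts[date_counts >= min_code_count].index)

    excluded_phecodes = {
        p for p in map(str, assignments["phecode"].unique())
        if any(in_range(p, iv) for iv in intervals)
    }
    carriers = set(
        assignments.loc[
            assignments["phecode"].isin(excluded_phecodes), "patient_id"
        ]
    )
    excluded = (carriers - cases) & population
    controls = population - cases - excluded

    cohort = CaseControlCohort(
        phecode=str(target_prefix),
        cases=cases & population,
        controls=controls,
        excluded=excluded,
        min_code_count=min_code_count,
    )
    # contamination audit: no control carries an exclusion-range phecode
    assert not (cohort.controls & carriers), "control contamination"
    assert len(cohort.cases) + len(cohort.controls) + len(cohort.excluded) \
        == len(population), "cohort does not partition population"
    return cohort
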