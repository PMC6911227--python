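"""Map evaluation: code/instance coverage and two-window reproducibility.

Coverage answers "how much of the coding system, and how much of the data,
does the map reach": unique official codes mapped, unique used codes
mapped, and code *instances* (distinct patient/date/code triples) mapped.
Reproducibility asks whether phenotypes assigned from one coding era's map
persist into the next era: among patients who are phenotype cases in an
ICD-9-CM window, what fraction are cases again in a later ICD-10-CM
window. Chronic diseases should reproduce at high rates; acute ones
should not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .mapping import PhecodeMap
from .phenotyping import (
    define_cases_controls,
    distinct_instances,
    map_events,
)
from .terminology import TerminologyError, Vocabulary

__all__ = [
    "ObservationWindow",
    "CoverageSummary",
    "coverage_summary",
    "reproducibility",
]


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded to 2 decimals; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 2)


@dataclass(frozen=True)
class ObservationWindow:
    """Closed calendar-date interval [start, end]."""

    start: date
    end: date

    def __post_init__(self):
        if self.start > self.end:
            raise TerminologyError("window start after end")

    def contains(self, dates: pd.Series) -> pd.Series:
        d = pd.to_datetime(dates)
        return (d >= pd.Timestamp(self.start)) & (d <= pd.Timestamp(self.end))

    def overlaps(self, other: "ObservationWindow") -> bool:
        return self.start <= other.end and other.start <= self.end

    @classmethod
    def parse(cls, text: str) -> "ObservationWindow":
        """Parse ``"YYYY-MM-DD:YYYY-MM-DD"``."""
        a, _, b = text.partition(":")
        return cls(date.fromisoformat(a), date.fromisoformat(b))


@dataclass
class CoverageSummary:
    """Coverage accounting for one vocabulary's map over one event table.

    ``partition`` holds the official × used × mapped cell counts: keys
    like ``official_used_mapped`` and ``unofficial_used_unmapped``
    (unofficial cells exist only on the "used" side — locally invented
    codes observed in data but absent from the official system).
    """

    vocabulary: str
    official_unique: int
    official_unique_mapped: int
    used_unique: int
    used_unique_mapped: int
    total_instances: int
    instances_mapped: int
    partition: dict = field(default_factory=dict)
    unmapped_breakdown: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["vocabulary", "code", "n_instances", "n_patients"]
        )
    )
    no_events: bool = False

    @property
    def official_unique_mapped_pct(self) -> float:
        return _pct(self.official_unique_mapped, self.official_unique)

    @property
    def used_unique_mapped_pct(self) -> float:
        return _pct(self.used_unique_mapped, self.used_unique)

    @property
    def instances_mapped_pct(self) -> float:
        return _pct(self.instances_mapped, self.total_instances)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("official unique codes", self.official_unique, ""),
            ("official unique codes mapped", self.official_unique_mapped,
             self.official_unique_mapped_pct),
            ("used unique codes", self.used_unique, ""),
            ("used unique codes mapped", self.used_unique_mapped,
             self.used_unique_mapped_pct),
            ("total instances", self.total_instances, ""),
            ("instances mapped", self.instances_mapped,
             self.instances_mapped_pct),
        ]
        return pd.DataFrame(rows, columns=["quantity", "n", "percent"])


def coverage_summary(
    pmap: PhecodeMap,
    official_codes: pd.DataFrame,
    events: pd.DataFrame,
    vocabulary: Vocabulary | str,
) -> CoverageSummary:
    """Compute coverage of ``pmap`` over official codes and observed events.

    Events must carry only the stated vocabulary (others are rejected).
    "Used" codes are counted whether or not they are official; codes used
    but unofficial populate their own partition cells.
    """
    vocabulary = Vocabulary(vocabulary)
    map_vocabs = {r.source_vocab for r in pmap}
    if map_vocabs - {vocabulary}:
        raise TerminologyError(
            f"map contains vocabularies {sorted(v.value for v in map_vocabs)} "
            f"but coverage requested for {vocabulary.value}"
        )
    if not events.empty and (events["vocabulary"] != vocabulary.value).any():
        raise TerminologyError(
            "events contain vocabularies other than " + vocabulary.value
        )
    official = set(official_codes["code"].astype(str))
    mapped_codes = pmap.source_codes()
    inst = distinct_instances(events)
    used = set(inst["code"].astype(str))

    partition = {
        "official_used_mapped": len(official & used & mapped_codes),
        "official_used_unmapped": len((official & used) - mapped_codes),
        "official_unused_mapped": len((official - used) & mapped_codes),
        "official_unused_unmapped": len(official - used - mapped_codes),
        "unofficial_used_mapped": len((used - official) & mapped_codes),
        "unofficial_used_unmapped": len(used - official - mapped_codes),
    }
    assert sum(partition.values()) == len(official | used)

    _, unmapped = map_events(events, pmap)
    n_instances = len(inst)
    n_mapped_inst = n_instances - int(unmapped["n_instances"].sum())

    return CoverageSummary(
        vocabulary=vocabulary.value,
        official_unique=len(official),
        official_unique_mapped=len(official & mapped_codes),
        used_unique=len(used),
        used_unique_mapped=len(used & mapped_codes),
        total_instances=n_instances,
        instances_mapped=n_mapped_inst,
        partition=partition,
        unmapped_breakdown=unmapped,
        no_events=events.empty,
    )


def reproducibility(
    events: pd.DataFrame,
    map9: PhecodeMap,
    map10: PhecodeMap,
    window1: ObservationWindow,
    window2: ObservationWindow,
    targets,
    min_code_count: int = 1,
) -> pd.DataFrame:
    """Two-window phenotype reproducibility (ICD-9-CM era → ICD-10-CM era).

    The cohort is every patient with ≥1 ICD-9-CM event in ``window1`` AND
    ≥1 ICD-10-CM event in ``window2`` (any code, not just target codes).
    For each ``(name, prefix)`` target, counts cohort members who are
    cases in window 1 under ``map9`` and, among those, cases again in
    window 2 under ``map10``; the conditional percentage is rounded to 2
    decimals.
    """
    if window1.overlaps(window2):
        raise TerminologyError("observation windows overlap")
    ev = events.copy()
    in_w1 = window1.contains(ev["date"]) & (
        ev["vocabulary"] == Vocabulary.ICD9CM.value
    )
    vocab10 = {r.source_vocab for r in map10} or {Vocabulary.ICD10CM}
    in_w2 = window2.contains(ev["date"]) & ev["vocabulary"].isin(
        [v.value for v in vocab10]
    )
    cohort = set(ev.loc[in_w1, "patient_id"]) & set(ev.loc[in_w2, "patient_id"])

    asg1, _ = map_events(ev[in_w1], map9)
    asg2, _ = map_events(ev[in_w2], map10)
    asg1 = asg1[asg1["patient_id"].isin(cohort)]
    asg2 = asg2[asg2["patient_id"].isin(cohort)]

    rows = []
    for name, prefix in targets:
        c1 = define_cases_controls(
            asg1, prefix, exclusions=[], population=cohort,
            min_code_count=min_code_count,
        ).cases
        c2 = define_cases_controls(
            asg2, prefix, exclusions=[], population=cohort,
            min_code_count=min_code_count,
        ).cases
        both = c1 & c2
        rows.append(
            {
                "phenotype": name,
                "phecodes": f"{prefix}*" if "." in prefix else f"{prefix}.*",
                "w1_cases": len(c1),
                "w1_and_w2_cases": len(both),
                "percent": _pct(len(both), len(c1)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["phenotype", "phecodes", "w1_cases", "w1_and_w2_cases",
                 "percent"],
    )
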