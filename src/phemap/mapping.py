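"""ICD-10/ICD-10-CM → phecode map construction.

Six routes contribute mapping candidates:

* **A** — direct string match: identical code/phecode descriptions,
  case-insensitively.
* **B** — GEMS crosswalk: ICD-10-CM → ICD-9-CM → phecode (ICD-10-CM only;
  no GEMS exists for WHO ICD-10). Equivalent (flag 0) and approximate
  (flag 1) GEMS entries both participate.
* **C** — CUI shortcut: ICD → UMLS CUI → ICD-9-CM → phecode.
* **D/E/F** — concept chain: ICD → CUI → SNOMED CT, then SNOMED CT →
  ICD-9-CM via NLM rule maps (D), OHDSI concept relationships (E, possibly
  through several internal concept-id hops), or UMLS equivalences (F),
  then ICD-9-CM → phecode.

All routes are unioned — no precedence — then two resolution rules apply:
within one source code's candidate set, a phecode that is a strict
ancestor of another candidate is dropped (keep the more granular child);
candidates in unrelated phecode families are all kept. Every retained
mapping carries its full provenance chain(s).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .terminology import (
    Resource,
    TerminologyBundle,
    TerminologyError,
    Vocabulary,
    is_strict_ancestor,
)

__all__ = [
    "PathLabel",
    "Hop",
    "MappingRecord",
    "PhecodeMap",
    "direct_string_match",
    "gems_path",
    "concept_path",
    "icd9_direct_map",
    "resolve_hierarchy",
    "build_map",
    "write_map",
    "read_map",
]

#: maximum OHDSI concept-id → concept-id internal hops followed on path E
OHDSI_HOP_LIMIT = 5


class PathLabel(str, Enum):
    A_DIRECT_STRING = "A_DIRECT_STRING"
    B_GEMS = "B_GEMS"
    C_CUI_ICD9 = "C_CUI_ICD9"
    D_SNOMED_NLM = "D_SNOMED_NLM"
    E_SNOMED_OHDSI = "E_SNOMED_OHDSI"
    F_SNOMED_CUI = "F_SNOMED_CUI"
    ICD9_DIRECT = "ICD9_DIRECT"  # auxiliary: the given ICD-9-CM phecode map


@dataclass(frozen=True)
class Hop:
    """One traversed crosswalk edge."""

    source_vocab: Vocabulary
    source_code: str
    target_vocab: Vocabulary
    target_code: str
    resource: Resource

    def __str__(self):
        return (
            f"{self.source_vocab.value}:{self.source_code}"
            f">{self.resource.value}>"
            f"{self.target_vocab.value}:{self.target_code}"
        )

    @classmethod
    def parse(cls, text: str) -> "Hop":
        src, resource, dst = text.split(">")
        sv, sc = src.split(":", 1)
        tv, tc = dst.split(":", 1)
        return cls(Vocabulary(sv), sc, Vocabulary(tv), tc, Resource(resource))


@dataclass(frozen=True)
class MappingRecord:
    """One resolved source-code → phecode mapping with provenance.

    ``provenance`` holds one or more hop chains (tuples of :class:`Hop`);
    several chains accumulate when distinct intermediates reach the same
    phecode. Each chain is connected, starts at the source code, and ends
    at the phecode.
    """

    source_vocab: Vocabulary
    source_code: str
    phecode: str
    path_label: PathLabel
    provenance: tuple = ()

    def __post_init__(self):
        for chain in self.provenance:
            if not chain:
                raise TerminologyError("empty provenance chain")
            if (chain[0].source_vocab, chain[0].source_code) != (
                self.source_vocab,
                self.source_code,
            ):
                raise TerminologyError("provenance does not start at source")
            for a, b in itertools.pairwise(chain):
                if (a.target_vocab, a.target_code) != (
                    b.source_vocab,
                    b.source_code,
                ):
                    raise TerminologyError("provenance chain disconnected")
            last = chain[-1]
            if last.target_vocab is not Vocabulary.PHECODE:
                raise TerminologyError("provenance must end at a phecode")
            if last.target_code != self.phecode:
                raise TerminologyError("provenance ends at wrong phecode")
        if self.path_label is PathLabel.A_DIRECT_STRING and any(
            len(chain) != 1 for chain in self.provenance
        ):
            raise TerminologyError("path A chains must have exactly one hop")


def _merge_records(records) -> list[MappingRecord]:
    """Deduplicate by (source, phecode, path), merging provenance chains."""
    merged: dict = {}
    for rec in records:
        key = (rec.source_vocab, rec.source_code, rec.phecode, rec.path_label)
        if key in merged:
            chains = merged[key].provenance
            extra = tuple(c for c in rec.provenance if c not in chains)
            merged[key] = MappingRecord(
                rec.source_vocab, rec.source_code, rec.phecode,
                rec.path_label, chains + extra,
            )
        else:
            merged[key] = rec
    return sorted(
        merged.values(),
        key=lambda r: (r.source_code, r.phecode, r.path_label.value),
    )


@dataclass
class PhecodeMap:
    """A resolved set of mapping records, indexed by source code."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        self.records = _merge_records(self.records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def phecodes_for(self, source_code: str) -> set[str]:
        return {r.phecode for r in self.records if r.source_code == source_code}

    def source_codes(self) -> set[str]:
        return {r.source_code for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source_vocab": r.source_vocab.value,
                "source_code": r.source_code,
                "phecode": r.phecode,
                "path_label": r.path_label.value,
                "provenance": "|".join(
                    ";".join(str(h) for h in chain) for chain in r.provenance
                ),
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["source_vocab", "source_code", "phecode", "path_label",
                     "provenance"],
        )


# ---------------------------------------------------------------------------
# individual paths
# ---------------------------------------------------------------------------

def _norm_desc(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.lower()


def direct_string_match(
    icd_codes: pd.DataFrame,
    phecodes: pd.DataFrame,
    vocabulary: Vocabulary,
) -> list[MappingRecord]:
    """Path A: equal descriptions after lowercasing and trimming."""
    if icd_codes.empty or phecodes.empty:
        return []
    left = icd_codes.assign(_desc=_norm_desc(icd_codes["description"]))
    right = phecodes.assign(_desc=_norm_desc(phecodes["description"]))
    left = left[left["_desc"] != ""]
    right = right[right["_desc"] != ""]
    hit = left.merge(right, on="_desc")
    records = []
    for _, row in hit.iterrows():
        hop = Hop(vocabulary, row["code"], Vocabulary.PHECODE,
                  str(row["phecode"]), Resource.STRING_MATCH)
        records.append(
            MappingRecord(vocabulary, row["code"], str(row["phecode"]),
                          PathLabel.A_DIRECT_STRING, ((hop,),))
        )
    return records


def _resource_edges(
    bundle: TerminologyBundle,
    resource: Resource,
    source_vocab: Vocabulary | None = None,
    target_vocab: Vocabulary | None = None,
) -> pd.DataFrame:
    table = bundle.edge_table(resource)
    if table.empty:
        return table
    mask = pd.Series(True, index=table.index)
    if source_vocab is not None:
        mask &= table["source_vocab"] == source_vocab.value
    if target_vocab is not None:
        mask &= table["target_vocab"] == target_vocab.value
    return table[mask]


def _hops_from_rows(rows, resource: Resource):
    return [
        Hop(Vocabulary(r["source_vocab"]), str(r["source_code"]),
            Vocabulary(r["target_vocab"]), str(r["target_code"]), resource)
        for _, r in rows.iterrows()
    ]


def gems_path(bundle: TerminologyBundle) -> list[MappingRecord]:
    """Path B: ICD-10-CM —GEMS→ ICD-9-CM —map→ phecode (both GEMS flags)."""
    gems = _resource_edges(bundle, Resource.GEMS,
                           Vocabulary.ICD10CM, Vocabulary.ICD9CM)
    i9map = _resource_edges(bundle, Resource.ICD9_PHECODE_MAP,
                            Vocabulary.ICD9CM, Vocabulary.PHECODE)
    if gems.empty or i9map.empty:
        return []
    codes = set(bundle.code_table(Vocabulary.ICD10CM)["code"].astype(str))
    records = []
    for _, g in gems.iterrows():
        if codes and str(g["source_code"]) not in codes:
            continue
        hop1 = Hop(Vocabulary.ICD10CM, str(g["source_code"]),
                   Vocabulary.ICD9CM, str(g["target_code"]), Resource.GEMS)
        tail = i9map[i9map["source_code"].astype(str) == str(g["target_code"])]
        for hop2 in _hops_from_rows(tail, Resource.ICD9_PHECODE_MAP):
            records.append(
                MappingRecord(Vocabulary.ICD10CM, hop1.source_code,
                              hop2.target_code, PathLabel.B_GEMS,
                              ((hop1, hop2),))
            )
    return records


def _ohdsi_bridges(bundle: TerminologyBundle, snomed_code: str):
    """SNOMED → ICD-9-CM routes through the OHDSI concept graph.

    Internal concept-id → concept-id relationships are followed
    breadth-first up to :data:`OHDSI_HOP_LIMIT` hops with cycle detection.
    Yields (icd9_code, hop_chain) pairs.
    """
    table = bundle.edge_table(Resource.OHDSI_REL)
    if table.empty:
        return
    frontier = [((Vocabulary.SNOMED, snomed_code), ())]
    seen = {(Vocabulary.SNOMED.value, snomed_code)}
    for _ in range(OHDSI_HOP_LIMIT + 1):
        next_frontier = []
        for (vocab, code), chain in frontier:
            out = table[
                (table["source_vocab"] == vocab.value)
                & (table["source_code"].astype(str) == code)
            ]
            for hop in _hops_from_rows(out, Resource.OHDSI_REL):
                if hop.target_vocab is Vocabulary.ICD9CM:
                    yield hop.target_code, chain + (hop,)
                    continue
                key = (hop.target_vocab.value, hop.target_code)
                if key in seen:
                    continue  # cycle guard
                seen.add(key)
                if len(chain) + 1 <= OHDSI_HOP_LIMIT:
                    next_frontier.append(
                        ((hop.target_vocab, hop.target_code), chain + (hop,))
                    )
        frontier = next_frontier
        if not frontier:
            return


_BRIDGE_LABEL = {
    Resource.NLM_MAP: PathLabel.D_SNOMED_NLM,
    Resource.OHDSI_REL: PathLabel.E_SNOMED_OHDSI,
    Resource.UMLS_CUI: PathLabel.F_SNOMED_CUI,
}


def concept_path(
    bundle: TerminologyBundle,
    source_vocab: Vocabulary,
    bridge_resource: Resource,
    include_nlm_one_to_many: bool = False,
) -> list[MappingRecord]:
    """Paths D/E/F: ICD → CUI → SNOMED → (bridge) → ICD-9-CM → phecode.

    ``bridge_resource`` selects the SNOMED → ICD-9-CM leg. NLM rule maps
    are restricted to one-to-one/many-to-one entries unless
    ``include_nlm_one_to_many``; OHDSI bridges may pass through internal
    concept-id hops. Incomplete chains yield nothing.
    """
    label = _BRIDGE_LABEL[Resource(bridge_resource)]
    to_cui = _resource_edges(bundle, Resource.UMLS_CUI,
                             source_vocab, Vocabulary.CUI)
    cui_to_snomed = _resource_edges(bundle, Resource.UMLS_CUI,
                                    Vocabulary.CUI, Vocabulary.SNOMED)
    i9map = _resource_edges(bundle, Resource.ICD9_PHECODE_MAP,
                            Vocabulary.ICD9CM, Vocabulary.PHECODE)
    if to_cui.empty or cui_to_snomed.empty or i9map.empty:
        return []

    nlm_multi_sources: set[str] = set()
    if bridge_resource is Resource.NLM_MAP and not include_nlm_one_to_many:
        nlm = _resource_edges(bundle, Resource.NLM_MAP,
                              Vocabulary.SNOMED, Vocabulary.ICD9CM)
        counts = nlm.groupby(nlm["source_code"].astype(str)).size()
        nlm_multi_sources = set(counts[counts > 1].index)

    def bridge_routes(snomed_code: str):
        if bridge_resource is Resource.OHDSI_REL:
            yield from _ohdsi_bridges(bundle, snomed_code)
            return
        if snomed_code in nlm_multi_sources:
            return
        table = _resource_edges(bundle, bridge_resource,
                                Vocabulary.SNOMED, Vocabulary.ICD9CM)
        rows = table[table["source_code"].astype(str) == snomed_code]
        for hop in _hops_from_rows(rows, Resource(bridge_resource)):
            yield hop.target_code, (hop,)

    codes = set(bundle.code_table(source_vocab)["code"].astype(str))
    records = []
    for _, e1 in to_cui.iterrows():
        if codes and str(e1["source_code"]) not in codes:
            continue
        hop1 = Hop(source_vocab, str(e1["source_code"]),
                   Vocabulary.CUI, str(e1["target_code"]), Resource.UMLS_CUI)
        step2 = cui_to_snomed[
            cui_to_snomed["source_code"].astype(str) == hop1.target_code
        ]
        for hop2 in _hops_from_rows(step2, Resource.UMLS_CUI):
            for icd9, bridge_chain in bridge_routes(hop2.target_code):
                tail = i9map[i9map["source_code"].astype(str) == icd9]
                for hop_last in _hops_from_rows(tail, Resource.ICD9_PHECODE_MAP):
                    chain = (hop1, hop2) + bridge_chain + (hop_last,)
                    records.append(
                        MappingRecord(source_vocab, hop1.source_code,
                                      hop_last.target_code, label, (chain,))
                    )
    return records


def cui_shortcut_path(
    bundle: TerminologyBundle, source_vocab: Vocabulary
) -> list[MappingRecord]:
    """Path C: ICD → CUI → ICD-9-CM → phecode, skipping the SNOMED hop."""
    to_cui = _resource_edges(bundle, Resource.UMLS_CUI,
                             source_vocab, Vocabulary.CUI)
    cui_to_i9 = _resource_edges(bundle, Resource.UMLS_CUI,
                                Vocabulary.CUI, Vocabulary.ICD9CM)
    i9map = _resource_edges(bundle, Resource.ICD9_PHECODE_MAP,
                            Vocabulary.ICD9CM, Vocabulary.PHECODE)
    if to_cui.empty or cui_to_i9.empty or i9map.empty:
        return []
    codes = set(bundle.code_table(source_vocab)["code"].astype(str))
    records = []
    for _, e1 in to_cui.iterrows():
        if codes and str(e1["source_code"]) not in codes:
            continue
        hop1 = Hop(source_vocab, str(e1["source_code"]),
                   Vocabulary.CUI, str(e1["target_code"]), Resource.UMLS_CUI)
        step2 = cui_to_i9[
            cui_to_i9["source_code"].astype(str) == hop1.target_code
        ]
        for hop2 in _hops_from_rows(step2, Resource.UMLS_CUI):
            tail = i9map[i9map["source_code"].astype(str) == hop2.target_code]
            for hop3 in _hops_from_rows(tail, Resource.ICD9_PHECODE_MAP):
                records.append(
                    MappingRecord(source_vocab, hop1.source_code,
                                  hop3.target_code, PathLabel.C_CUI_ICD9,
                                  ((hop1, hop2, hop3),))
                )
    return records


def icd9_direct_map(bundle: TerminologyBundle) -> PhecodeMap:
    """The given ICD-9-CM → phecode map as a :class:`PhecodeMap`.

    This is the gold-standard input map, passed through verbatim (no
    hierarchy resolution is applied to it).
    """
    i9map = _resource_edges(bundle, Resource.ICD9_PHECODE_MAP,
                            Vocabulary.ICD9CM, Vocabulary.PHECODE)
    records = [
        MappingRecord(Vocabulary.ICD9CM, hop.source_code, hop.target_code,
                      PathLabel.ICD9_DIRECT, ((hop,),))
        for hop in _hops_from_rows(i9map, Resource.ICD9_PHECODE_MAP)
    ]
    return PhecodeMap(records)


# ---------------------------------------------------------------------------
# resolution and assembly
# ---------------------------------------------------------------------------

def resolve_hierarchy(records) -> list[MappingRecord]:
    """Drop, per source code, phecodes that are strict ancestors of another.

    A phecode is removed iff some other candidate for the same source code
    is its strict descendant; unrelated phecodes all survive. The rule is
    transitive (a grandparent falls to any retained descendant) and
    idempotent.
    """
    records = list(records)
    by_source: dict = {}
    for rec in records:
        by_source.setdefault((rec.source_vocab, rec.source_code), set()).add(
            rec.phecode
        )
    pruned = {
        key: {p for p in phecodes
              if any(is_strict_ancestor(p, q) for q in phecodes)}
        for key, phecodes in by_source.items()
    }
    return [
        rec for rec in records
        if rec.phecode not in pruned[(rec.source_vocab, rec.source_code)]
    ]


_DEFAULT_PATHS = {
    Vocabulary.ICD10CM: (
        PathLabel.A_DIRECT_STRING, PathLabel.B_GEMS, PathLabel.C_CUI_ICD9,
        PathLabel.D_SNOMED_NLM, PathLabel.E_SNOMED_OHDSI,
        PathLabel.F_SNOMED_CUI,
    ),
    # no GEMS exists for WHO ICD-10; the CUI shortcut is CM-specific
    Vocabulary.ICD10: (
        PathLabel.A_DIRECT_STRING, PathLabel.D_SNOMED_NLM,
        PathLabel.E_SNOMED_OHDSI, PathLabel.F_SNOMED_CUI,
    ),
}


def build_map(
    bundle: TerminologyBundle,
    source_vocab: Vocabulary | str,
    paths=None,
    include_nlm_one_to_many: bool = False,
) -> PhecodeMap:
    """Union all applicable paths, merge duplicates, resolve hierarchy."""
    source_vocab = Vocabulary(source_vocab)
    if source_vocab not in _DEFAULT_PATHS:
        raise TerminologyError(
            f"source vocabulary must be ICD10CM or ICD10, got {source_vocab}"
        )
    if paths is None:
        selected = _DEFAULT_PATHS[source_vocab]
    else:
        selected = tuple(PathLabel(p) for p in paths)
        illegal = set(selected) - set(_DEFAULT_PATHS[source_vocab])
        if illegal:
            raise TerminologyError(
                f"paths {sorted(p.value for p in illegal)} not applicable "
                f"to {source_vocab.value}"
            )
    records: list[MappingRecord] = []
    if PathLabel.A_DIRECT_STRING in selected:
        records += direct_string_match(
            bundle.code_table(source_vocab), bundle.phecodes, source_vocab
        )
    if PathLabel.B_GEMS in selected:
        records += gems_path(bundle)
    if PathLabel.C_CUI_ICD9 in selected:
        records += cui_shortcut_path(bundle, source_vocab)
    for bridge, label in (
        (Resource.NLM_MAP, PathLabel.D_SNOMED_NLM),
        (Resource.OHDSI_REL, PathLabel.E_SNOMED_OHDSI),
        (Resource.UMLS_CUI, PathLabel.F_SNOMED_CUI),
    ):
        if label in selected:
            records += concept_path(
                bundle, source_vocab, bridge,
                include_nlm_one_to_many=include_nlm_one_to_many,
            )
    resolved = resolve_hierarchy(records)
    pmap = PhecodeMap(resolved)
    # post-hoc audit: no retained ancestor/descendant pair per source
    for code in pmap.source_codes():
        kept = pmap.phecodes_for(code)
        for p, q in itertools.permutations(kept, 2):
            if is_strict_ancestor(p, q):
                raise AssertionError(
                    f"hierarchy resolution left ancestor pair ({p}, {q}) "
                    f"for {code}"
                )
    return pmap


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_map(pmap: PhecodeMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pmap.to_frame().to_csv(path, index=False)
    return path


def read_map(path) -> PhecodeMap:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in table.iterrows():
        chains = tuple(
            tuple(Hop.parse(h) for h in chain.split(";"))
            for chain in row["provenance"].split("|")
            if chain
        )
        records.append(
            MappingRecord(
                Vocabulary(row["source_vocab"]), row["source_code"],
                row["phecode"], PathLabel(row["path_label"]), chains,
            )
        )
    return PhecodeMap(records)
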