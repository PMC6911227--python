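"""Code systems, crosswalk resources, and the phecode system.

Phecodes are decimal-string phenotype identifiers ("250.2", "008", "401.1")
whose hierarchy is implicit in the id: a phecode is an ancestor of another
when both share the same integer part and the descendant's digit sequence
(decimal point removed, leading zeros preserved) extends the ancestor's.
Each phecode may carry closed numeric *exclusion ranges* — intervals of
phecodes whose carriers must not serve as controls for that phenotype.

A :class:`TerminologyBundle` holds the delimited tables everything else
consumes: per-vocabulary code lists, per-resource crosswalk edge tables, and
the phecode definition table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from enum import Enum
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "Resource",
    "ConceptCode",
    "PhecodeDefinition",
    "CrosswalkEdge",
    "TerminologyBundle",
    "TerminologyError",
    "canonicalize_code",
    "phecode_value",
    "is_strict_ancestor",
    "in_range",
    "parse_exclusion_ranges",
    "format_exclusion_ranges",
    "load_bundle",
]


class TerminologyError(ValueError):
    """Raised for malformed codes, edges, or bundle files."""


class Vocabulary(str, Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"
    ICD10 = "ICD10"
    SNOMED = "SNOMED"
    CUI = "CUI"
    OHDSI_CONCEPT = "OHDSI_CONCEPT"
    PHECODE = "PHECODE"


class Resource(str, Enum):
    """Mapping resources, each backing one kind of crosswalk assertion."""

    STRING_MATCH = "STRING_MATCH"
    GEMS = "GEMS"
    UMLS_CUI = "UMLS_CUI"
    NLM_MAP = "NLM_MAP"
    OHDSI_REL = "OHDSI_REL"
    ICD9_PHECODE_MAP = "ICD9_PHECODE_MAP"


#: vocabularies whose codes are written with an embedded dot
_ICD_VOCABS = {Vocabulary.ICD9CM, Vocabulary.ICD10CM, Vocabulary.ICD10}

_PHECODE_RE = re.compile(r"^\d+(\.\d{1,2})?$")


def canonicalize_code(raw: str, vocabulary: Vocabulary | str) -> str:
    """Return the canonical (uppercase, dotted) form of a code.

    ICD vocabularies accept both dotted ("E11.9") and undotted ("E119")
    input and return the dotted form. ICD-10/ICD-10-CM place the dot after
    the third character; ICD-9-CM after the third, except E-codes (dot
    after the fourth). Idempotent: canonical input passes through.
    """
    vocabulary = Vocabulary(vocabulary)
    code = str(raw).strip().upper()
    if not code:
        raise TerminologyError(f"empty code for vocabulary {vocabulary.value}")
    if vocabulary not in _ICD_VOCABS:
        return code
    if "." in code:
        head, dot, tail = code.partition(".")
        if not head or "." in tail:
            raise TerminologyError(f"malformed dotted ICD code {raw!r}")
        return code if tail else head
    if vocabulary in (Vocabulary.ICD10, Vocabulary.ICD10CM):
        if not re.fullmatch(r"[A-Z][0-9][0-9A-Z]+", code):
            raise TerminologyError(
                f"cannot canonicalize {raw!r} as {vocabulary.value}: "
                "expected letter + digit + alphanumerics"
            )
        return code if len(code) <= 3 else f"{code[:3]}.{code[3:]}"
    # ICD-9-CM: numeric (dot after 3), V-codes (dot after 3), E-codes (dot after 4)
    if re.fullmatch(r"\d+", code) or re.fullmatch(r"V\d+", code):
        return code if len(code) <= 3 else f"{code[:3]}.{code[3:]}"
    if re.fullmatch(r"E\d+", code):
        return code if len(code) <= 4 else f"{code[:4]}.{code[4:]}"
    raise TerminologyError(
        f"cannot canonicalize {raw!r} as ICD9CM: dot position ambiguous"
    )


def phecode_value(phecode: str) -> Decimal:
    """Numeric value of a phecode id (used only for range comparisons)."""
    phecode = str(phecode).strip()
    if not _PHECODE_RE.match(phecode):
        raise TerminologyError(f"invalid phecode {phecode!r}")
    return Decimal(phecode)


def is_strict_ancestor(a: str, b: str) -> bool:
    """True iff phecode ``a`` is a strict ancestor of ``b`` in the hierarchy.

    Holds when a != b, the integer parts agree, and b's digit sequence
    (decimal point removed, leading zeros preserved) extends a's. Defines a
    strict partial order; e.g. 401 is an ancestor of 401.1, and 250 of
    250.23, but 41 is unrelated to 411.
    """
    a, b = str(a).strip(), str(b).strip()
    for p in (a, b):
        if not _PHECODE_RE.match(p):
            raise TerminologyError(f"invalid phecode {p!r}")
    if a == b:
        return False
    if int(a.split(".")[0]) != int(b.split(".")[0]):
        return False
    da, db = a.replace(".", ""), b.replace(".", "")
    return len(db) > len(da) and db.startswith(da)


def in_range(phecode: str, interval: tuple[float | str, float | str]) -> bool:
    """True iff the phecode's numeric value lies in [lo, hi], inclusive."""
    lo, hi = (Decimal(str(x)) for x in interval)
    if lo > hi:
        raise TerminologyError(f"interval lo > hi: [{lo}, {hi}]")
    return lo <= phecode_value(phecode) <= hi


def parse_exclusion_ranges(spec: str) -> list[tuple[Decimal, Decimal]]:
    """Parse semicolon-joined "lo-hi" spans, e.g. ``"249-250.99"``."""
    if spec is None or str(spec).strip() in ("", "nan"):
        return []
    out = []
    for span in str(spec).split(";"):
        span = span.strip()
        if not span:
            continue
        parts = span.split("-")
        if len(parts) != 2:
            raise TerminologyError(f"malformed exclusion span {span!r}")
        try:
            lo, hi = Decimal(parts[0].strip()), Decimal(parts[1].strip())
        except InvalidOperation as exc:
            raise TerminologyError(f"malformed exclusion span {span!r}") from exc
        if lo > hi:
            raise TerminologyError(f"exclusion span lo > hi: {span!r}")
        out.append((lo, hi))
    return out


def format_exclusion_ranges(ranges) -> str:
    return ";".join(f"{lo}-{hi}" for lo, hi in ranges)


@dataclass(frozen=True)
class ConceptCode:
    """A code in one vocabulary, in canonical form."""

    vocabulary: Vocabulary
    code: str
    description: str = ""

    def __post_init__(self):
        if not self.code:
            raise TerminologyError("empty code")


@dataclass(frozen=True)
class PhecodeDefinition:
    """A phecode id, its description, and its control exclusion ranges."""

    phecode: str
    description: str = ""
    exclusion_ranges: tuple = ()

    def __post_init__(self):
        phecode_value(self.phecode)  # validates
        for lo, hi in self.exclusion_ranges:
            if Decimal(str(lo)) > Decimal(str(hi)):
                raise TerminologyError(
                    f"exclusion interval lo > hi for phecode {self.phecode}"
                )


@dataclass(frozen=True)
class CrosswalkEdge:
    """One directed mapping assertion between two codes, tagged by resource.

    ``approximate_flag`` is meaningful only for GEMS entries (0 =
    equivalent, 1 = approximate); both flags participate in mapping.
    """

    source: ConceptCode
    target: ConceptCode
    resource: Resource
    approximate_flag: int = 0

    def __post_init__(self):
        if (
            self.source.vocabulary == self.target.vocabulary
            and self.resource is not Resource.OHDSI_REL
        ):
            raise TerminologyError(
                "same-vocabulary edge only allowed for OHDSI_REL "
                f"({self.source.vocabulary.value} {self.source.code})"
            )


_EDGE_COLUMNS = [
    "source_vocab",
    "source_code",
    "target_vocab",
    "target_code",
    "approximate_flag",
]
_CODE_COLUMNS = ["code", "description"]
_PHECODE_COLUMNS = ["phecode", "description", "exclusion_ranges"]


@dataclass
class TerminologyBundle:
    """All terminology tables needed to build and apply a phecode map.

    codes
        per-vocabulary DataFrames with columns (code, description).
    edges
        per-resource DataFrames with columns (source_vocab, source_code,
        target_vocab, target_code, approximate_flag).
    phecodes
        DataFrame with columns (phecode, description, exclusion_ranges).
    """

    codes: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)
    phecodes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_PHECODE_COLUMNS)
    )

    def code_table(self, vocabulary: Vocabulary) -> pd.DataFrame:
        return self.codes.get(
            Vocabulary(vocabulary), pd.DataFrame(columns=_CODE_COLUMNS)
        )

    def edge_table(self, resource: Resource) -> pd.DataFrame:
        return self.edges.get(
            Resource(resource), pd.DataFrame(columns=_EDGE_COLUMNS)
        )

    def exclusion_ranges(self, phecode: str):
        row = self.phecodes.loc[self.phecodes["phecode"] == str(phecode)]
        if row.empty:
            return []
        return parse_exclusion_ranges(row.iloc[0]["exclusion_ranges"])

    def validate(self) -> "TerminologyBundle":
        """Enforce bundle invariants; log (not fail) dangling edges."""
        for vocab, table in self.codes.items():
            _require_columns(table, _CODE_COLUMNS, f"codes_{vocab.value.lower()}")
        _require_columns(self.phecodes, _PHECODE_COLUMNS, "phecodes")
        dup = self.phecodes["phecode"].astype(str).duplicated()
        if dup.any():
            raise TerminologyError(
                "duplicate phecode definition: "
                f"{self.phecodes.loc[dup, 'phecode'].iloc[0]}"
            )
        for _, row in self.phecodes.iterrows():
            phecode_value(row["phecode"])
            parse_exclusion_ranges(row["exclusion_ranges"])
        known = {
            v: set(t["code"].astype(str)) for v, t in self.codes.items()
        }
        for resource, table in self.edges.items():
            _require_columns(
                table, _EDGE_COLUMNS, f"edges_{resource.value.lower()}"
            )
            trip = table[["source_vocab", "source_code", "target_vocab",
                          "target_code"]].astype(str)
            dup = trip.duplicated()
            if dup.any():
                bad = trip.loc[dup].iloc[0]
                raise TerminologyError(
                    f"duplicate edge in {resource.value}: "
                    f"{bad['source_code']} -> {bad['target_code']}"
                )
            n_dangling = 0
            phecode_ids = set(self.phecodes["phecode"].astype(str))
            for _, row in table.iterrows():
                for end in ("source", "target"):
                    vocab = Vocabulary(row[f"{end}_vocab"])
                    code = str(row[f"{end}_code"])
                    if vocab is Vocabulary.PHECODE:
                        if code not in phecode_ids:
                            n_dangling += 1
                    elif code not in known.get(vocab, set()):
                        n_dangling += 1
            if n_dangling:
                logger.info(
                    "bundle: %d dangling edge endpoint(s) in %s",
                    n_dangling, resource.value,
                )
        return self

    # ---- serialization -------------------------------------------------

    def write(self, directory) -> Path:
        """Write the bundle as the CSV file family under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for vocab, table in sorted(self.codes.items(), key=lambda kv: kv[0].value):
            table[_CODE_COLUMNS].to_csv(
                directory / f"codes_{vocab.value.lower()}.csv", index=False
            )
        for resource, table in sorted(self.edges.items(), key=lambda kv: kv[0].value):
            table[_EDGE_COLUMNS].to_csv(
                directory / f"edges_{resource.value.lower()}.csv", index=False
            )
        self.phecodes[_PHECODE_COLUMNS].to_csv(
            directory / "phecodes.csv", index=False
        )
        return directory


def _require_columns(table: pd.DataFrame, columns, name: str):
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise TerminologyError(f"{name}: missing required column(s) {missing}")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_bundle(directory) -> TerminologyBundle:
    """Load a bundle from its CSV file family and validate it.

    Recognizes ``codes_<vocab>.csv``, ``edges_<resource>.csv`` and
    ``phecodes.csv``. Missing files mean empty tables; a missing
    ``phecodes.csv`` is an error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise TerminologyError(f"bundle directory not found: {directory}")
    codes, edges = {}, {}
    for vocab in Vocabulary:
        path = directory / f"codes_{vocab.value.lower()}.csv"
        if path.exists():
            table = _read_csv(path)
            _require_columns(table, _CODE_COLUMNS, path.name)
            table["code"] = [
                canonicalize_code(c, vocab) for c in table["code"]
            ]
            codes[vocab] = table
    for resource in Resource:
        path = directory / f"edges_{resource.value.lower()}.csv"
        if path.exists():
            table = _read_csv(path)
            _require_columns(table, _EDGE_COLUMNS, path.name)
            if "approximate_flag" in table:
                table["approximate_flag"] = (
                    table["approximate_flag"].replace("", "0").astype(int)
                )
            edges[resource] = table
    phecode_path = directory / "phecodes.csv"
    if not phecode_path.exists():
        raise TerminologyError(f"missing phecodes.csv in {directory}")
    phecodes = _read_csv(phecode_path)
    bundle = TerminologyBundle(codes=codes, edges=edges, phecodes=phecodes)
    return bundle.validate()
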