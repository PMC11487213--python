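"""Data model and I/O for hospitalization diagnosis tables and comorbidity networks.

The analysis unit is one hospitalization record carrying a set of 3-character
ICD-10 codes. Input is a long (tidy) CSV with one row per encounter-diagnosis;
a wide one-row-per-encounter dialect is accepted behind a schema flag. Network
outputs are node/edge CSVs plus GraphML for exchange with other tools.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Sex",
    "EncounterRecord",
    "Cohort",
    "DiseaseCatalog",
    "CodeError",
    "CohortError",
    "normalize_code",
    "read_icd9_map",
    "read_cohort",
    "write_cohort",
    "write_network",
    "read_network_graphml",
    "chapter_of",
    "THYROID_CODES",
]

# Thyroid-disease indication: benign thyroid disease E00-E07 plus thyroid cancer C73.
BENIGN_THYROID_CODES = frozenset(f"E{i:02d}" for i in range(8))
THYROID_CODES = BENIGN_THYROID_CODES | {"C73"}

_ICD10_3CHAR = re.compile(r"^[A-Z][0-9]{2}$")
# Unambiguous ICD-9 shapes: purely numeric rubrics (001-999) and external-cause
# codes E800-E999. "E04" is ICD-10 while "E812" can only be ICD-9; dotless
# ICD-10 subcategories like "E051" stay ICD-10. V codes are ambiguous between
# ICD-9 supplementary (V01-V91) and ICD-10 chapter XX, so they resolve through
# the user map when one matches and parse as ICD-10 otherwise.
_ICD9_NUMERIC = re.compile(r"^[0-9]{1,3}(\.[0-9A-Z]*)?$")
_ICD9_E = re.compile(r"^E[89][0-9]{2}(\.[0-9A-Z]*)?$")


class CodeError(ValueError):
    """Malformed or unmappable diagnosis code; carries the raw value."""

    def __init__(self, kind: str, raw: str):
        self.kind = kind
        self.raw = raw
        super().__init__(f"{kind}: {raw!r}")


class CohortError(ValueError):
    """Schema or emptiness problem with a cohort table."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    OTHER = "other"  # kept for overall analyses, excluded from sex strata


@dataclass(frozen=True)
class EncounterRecord:
    """One hospitalization treated as an independent individual."""

    encounter_id: str
    age: int
    sex: Sex
    codes: frozenset[str]

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        for c in self.codes:
            if not _ICD10_3CHAR.match(c):
                raise CodeError("malformed code", c)

    @property
    def thyroid_codes(self) -> frozenset[str]:
        return self.codes & THYROID_CODES

    @property
    def has_thyroid(self) -> bool:
        return bool(self.codes & THYROID_CODES)


@dataclass
class Cohort:
    """A collection of encounter records plus provenance of applied filters."""

    records: list[EncounterRecord]
    filter_log: list[tuple[str, int, int]] = field(default_factory=list)
    label: str = "all"

    def __len__(self) -> int:
        return len(self.records)

    def log_filter(self, name: str, before: int, after: int) -> None:
        # Entries mix record-level and code-level counts; within each step the
        # count never increases (checked here), monotonicity across record-level
        # steps is asserted by the filtering pipeline's tests.
        if after > before:
            raise ValueError("a filter step cannot increase its count")
        self.filter_log.append((name, before, after))

    def code_universe(self) -> list[str]:
        """All distinct codes present, in lexicographic order."""
        codes: set[str] = set()
        for r in self.records:
            codes |= r.codes
        return sorted(codes)

    def prevalence_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            for c in r.codes:
                counts[c] = counts.get(c, 0) + 1
        return counts


# Roman-numeral ICD-10 chapters keyed by 3-character code. Letters D and H span
# two chapters each and are split on the numeric part.
_LETTER_CHAPTER = {
    "A": "I", "B": "I", "C": "II", "E": "IV", "F": "V", "G": "VI",
    "I": "IX", "J": "X", "K": "XI", "L": "XII", "M": "XIII", "N": "XIV",
    "O": "XV", "P": "XVI", "Q": "XVII", "R": "XVIII", "S": "XIX", "T": "XIX",
    "U": "XXII", "Z": "XXI",
}


def chapter_of(code: str) -> str:
    """Roman-numeral ICD-10 chapter for a 3-character code."""
    if not _ICD10_3CHAR.match(code):
        raise CodeError("malformed code", code)
    letter, num = code[0], int(code[1:])
    if letter == "D":
        return "II" if num <= 48 else "III"
    if letter == "H":
        return "VII" if num <= 59 else "VIII"
    if letter in "VWXY":
        return "XX"
    return _LETTER_CHAPTER[letter]


@dataclass
class DiseaseCatalog:
    """Code -> label/chapter/category lookup used for reporting and node colors."""

    entries: dict[str, dict] = field(default_factory=dict)

    def label(self, code: str) -> str:
        return self.entries.get(code, {}).get("label", code)

    def chapter(self, code: str) -> str:
        return self.entries.get(code, {}).get("chapter") or chapter_of(code)

    def category(self, code: str) -> str:
        # Default coarse category = chapter; lets plots color by disease system.
        return self.entries.get(code, {}).get("category") or self.chapter(code)


def _looks_icd9(raw: str) -> bool:
    return bool(_ICD9_NUMERIC.match(raw) or _ICD9_E.match(raw))


def normalize_code(raw: str, icd9_map: Optional[Mapping[str, str]] = None) -> str:
    """Standardize a raw diagnosis code to a 3-character ICD-10 code.

    Uppercases, strips the dot and any suffix, truncates to 3 characters. A code
    with ICD-9 shape (numeric rubric, or E/V supplementary code) is first mapped
    through the user-supplied ``icd9_map`` (matched on the full raw code, then on
    the pre-dot stem), then truncated.

    Raises
    ------
    CodeError
        ``"unmapped code"`` for an ICD-9-shaped code absent from the map (or when
        no map was given); ``"malformed code"`` when the result is not
        letter + two digits.
    """
    if not raw or not str(raw).strip():
        raise CodeError("malformed code", raw)
    code = str(raw).strip().upper()
    mapped = None
    if icd9_map is not None:
        mapped = icd9_map.get(code) or icd9_map.get(code.split(".")[0])
    if mapped is not None:
        code = str(mapped).strip().upper()
    elif _looks_icd9(code):
        raise CodeError("unmapped code", raw)
    code = code.split(".")[0][:3]
    if not _ICD10_3CHAR.match(code):
        raise CodeError("malformed code", raw)
    return code


def read_icd9_map(path) -> dict[str, str]:
    """Read a two-column (icd9, icd10) mapping CSV into a dict."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise CohortError(f"icd9 map needs 2 columns, got {df.shape[1]}")
    c9, c10 = df.columns[:2]
    return {str(a).strip().upper(): str(b).strip().upper()
            for a, b in zip(df[c9], df[c10])}


DEFAULT_SEX_RECODE = {
    "m": Sex.MALE, "male": Sex.MALE, "1": Sex.MALE,
    "f": Sex.FEMALE, "female": Sex.FEMALE, "2": Sex.FEMALE,
}


@dataclass
class CohortSchema:
    """Column names and recodings for the input CSV."""

    encounter_id: str = "encounter_id"
    age: str = "age"
    sex: str = "sex"
    icd_code: str = "icd_code"
    sex_recode: Mapping[str, Sex] = field(default_factory=lambda: dict(DEFAULT_SEX_RECODE))
    wide: bool = False            # one row per encounter, codes separated by `wide_sep`
    wide_sep: str = ";"


def _recode_sex(value, recode: Mapping[str, Sex]) -> Sex:
    key = str(value).strip().lower()
    return recode.get(key, Sex.OTHER)


def read_cohort(
    path,
    schema: Optional[CohortSchema] = None,
    icd9_map: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read a diagnosis CSV into a Cohort, normalizing and de-duplicating codes.

    Long format (default): one row per encounter-diagnosis, grouped on the
    encounter id. Duplicate (encounter, code) rows collapse under set semantics;
    the dropped-duplicate count is logged so that
    ``rows in == sum(|codes|) + duplicates``.
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path, dtype={schema.encounter_id: str, schema.icd_code: str})
    required = [schema.encounter_id, schema.age, schema.sex, schema.icd_code]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"missing required column(s): {missing}")
    if df.empty:
        raise CohortError(f"empty cohort file: {path}")

    records: list[EncounterRecord] = []
    n_rows = 0
    n_dupes = 0
    for enc_id, grp in df.groupby(schema.encounter_id, sort=True):
        age = int(grp[schema.age].iloc[0])
        sex = _recode_sex(grp[schema.sex].iloc[0], schema.sex_recode)
        codes: set[str] = set()
        raw_codes: list[str] = []
        if schema.wide:
            for cell in grp[schema.icd_code]:
                raw_codes.extend(p for p in str(cell).split(schema.wide_sep) if p.strip())
        else:
            raw_codes = list(grp[schema.icd_code])
        for raw in raw_codes:
            n_rows += 1
            code = normalize_code(raw, icd9_map)
            if code in codes:
                n_dupes += 1
            codes.add(code)
        records.append(EncounterRecord(str(enc_id), age, sex, frozenset(codes)))

    cohort = Cohort(records)
    cohort.log_filter("read", n_rows, sum(len(r.codes) for r in records))
    if n_dupes:
        cohort.log_filter("dedup_codes", n_rows, n_rows - n_dupes)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to the canonical long CSV (codes sorted per record)."""
    rows = [
        {"encounter_id": r.encounter_id, "age": r.age, "sex": r.sex.value, "icd_code": c}
        for r in cohort.records
        for c in sorted(r.codes)
    ]
    pd.DataFrame(rows, columns=["encounter_id", "age", "sex", "icd_code"]).to_csv(
        path, index=False
    )


def write_filter_log(cohort: Cohort, path) -> None:
    log = [{"filter": n, "before": b, "after": a} for n, b, a in cohort.filter_log]
    Path(path).write_text(json.dumps(log, indent=2))


def write_network(net, node_path, edge_path, graphml_path,
                  catalog: Optional[DiseaseCatalog] = None) -> None:
    """Write a ComorbidityNetwork as node CSV, edge CSV, and GraphML.

    The node CSV carries code, label, prevalence and the structural metrics;
    the edge CSV carries the pair counts and cosine/phi/p statistics. A GraphML
    round-trip reproduces the node/edge sets and weights exactly.
    """
    if not net.nodes:
        raise ValueError("cannot write an empty network")
    catalog = catalog or DiseaseCatalog()
    g = net.graph
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False) if len(g) > 1 else {}
    pr = (nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-9, max_iter=10_000)
          if g.number_of_edges() else {n: 1.0 / len(g) for n in g})

    node_rows = [
        {
            "code": code,
            "label": catalog.label(code),
            "prevalence": net.nodes[code].prevalence,
            "degree": deg.get(code, 0),
            "betweenness": btw.get(code, 0.0),
            "pagerank": pr.get(code, 0.0),
        }
        for code in sorted(net.nodes)
    ]
    pd.DataFrame(node_rows).to_csv(node_path, index=False)

    edge_rows = [
        {
            "code_a": p.code_a, "code_b": p.code_b, "n_ab": p.n_ab,
            "cosine": p.cosine, "phi": p.phi, "p": p.p_value,
        }
        for p in sorted(net.edges, key=lambda p: (p.code_a, p.code_b))
    ]
    pd.DataFrame(
        edge_rows, columns=["code_a", "code_b", "n_ab", "cosine", "phi", "p"]
    ).to_csv(edge_path, index=False)

    nx.write_graphml(g, graphml_path)


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
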