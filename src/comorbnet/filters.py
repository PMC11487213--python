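"""Cohort cleaning pipeline and subgroup stratification.

The cleaning pipeline keeps adult thyroid-disease records, removes codes from
ICD-10 chapters XV-XXII (pregnancy/perinatal/symptom/external-cause chapters,
leading letters O-Z), drops records left with too few codes, and finally drops
rare diseases below a prevalence floor. Strata: sex, disease type (thyroid
cancer vs benign thyroid disease), thyroid-disease subtype, and age bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .emr_io import (
    BENIGN_THYROID_CODES,
    Cohort,
    EncounterRecord,
    Sex,
    THYROID_CODES,
)

__all__ = [
    "EmptyCohortError",
    "AGE_BINS",
    "age_bin_label",
    "filter_cohort",
    "comorbidity_universe",
    "stratify",
    "SUBGROUP_AXES",
]

# Chapters XV-XXII at the 3-character level: every code whose leading letter is
# O..Z (pregnancy, perinatal, congenital, symptoms, injury, external causes,
# health-status factors, special purposes).
EXCLUDED_CHAPTER_LETTERS = frozenset("OPQRSTUVWXYZ")

AGE_BINS: list[tuple[int, Optional[int]]] = [
    (18, 39), (40, 49), (50, 59), (60, 69), (70, None),
]


class EmptyCohortError(ValueError):
    """A filtering step removed every record."""

    def __init__(self, step: str):
        self.step = step
        super().__init__(f"empty cohort after step: {step}")


def age_bin_label(age: int, bins: Sequence[tuple[int, Optional[int]]] = AGE_BINS) -> str:
    for lo, hi in bins:
        if hi is None:
            if age >= lo:
                return f">={lo}"
        elif lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} falls outside the configured bins")


def _strip_chapters(record: EncounterRecord) -> EncounterRecord:
    kept = frozenset(c for c in record.codes if c[0] not in EXCLUDED_CHAPTER_LETTERS)
    if kept == record.codes:
        return record
    return EncounterRecord(record.encounter_id, record.age, record.sex, kept)


def filter_cohort(
    raw: Cohort,
    min_codes: int = 2,
    min_prevalence: float = 0.02,
    subgroup_axes: Sequence[str] = (),
) -> Cohort:
    """Apply the cleaning pipeline in a fixed order, logging each step.

    Steps: (a) keep records with age >= 18 carrying a thyroid code (E00-E07 or
    C73); (b) drop codes from chapters XV-XXII; (c) drop records with fewer
    than ``min_codes`` codes remaining; (d) drop diseases whose prevalence in
    the filtered cohort — or, when ``subgroup_axes`` are declared, in any
    stratum along those axes — is below ``min_prevalence``.
    """
    if not raw.records:
        raise EmptyCohortError("input")

    out = Cohort(list(raw.records), list(raw.filter_log), label=raw.label)

    # (a) adults with a thyroid-disease indication
    n0 = len(out.records)
    out.records = [r for r in out.records if r.age >= 18 and r.has_thyroid]
    out.log_filter("adult_thyroid", n0, len(out.records))
    if not out.records:
        raise EmptyCohortError("adult_thyroid")

    # (b) chapter XV-XXII code exclusion (records kept, codes dropped)
    n_codes_before = sum(len(r.codes) for r in out.records)
    out.records = [_strip_chapters(r) for r in out.records]
    out.log_filter("chapter_exclusion", n_codes_before,
                   sum(len(r.codes) for r in out.records))

    # (c) minimum code count per record
    n0 = len(out.records)
    out.records = [r for r in out.records if len(r.codes) >= min_codes]
    out.log_filter("min_codes", n0, len(out.records))
    if not out.records:
        raise EmptyCohortError("min_codes")

    # (d) rare-disease removal on the filtered denominator
    rare = _rare_codes(out, min_prevalence)
    if subgroup_axes:
        for axis in subgroup_axes:
            for sub in stratify(out, axis).values():
                if sub.records:
                    rare |= _rare_codes(sub, min_prevalence,
                                        universe=out.code_universe())
    n_codes_before = sum(len(r.codes) for r in out.records)
    out.records = [
        EncounterRecord(r.encounter_id, r.age, r.sex, frozenset(r.codes - rare))
        for r in out.records
    ]
    out.log_filter("rare_disease", n_codes_before,
                   sum(len(r.codes) for r in out.records))
    if not any(r.codes for r in out.records):
        raise EmptyCohortError("rare_disease")
    return out


def _rare_codes(cohort: Cohort, min_prevalence: float,
                universe: Optional[Sequence[str]] = None) -> set[str]:
    n = len(cohort.records)
    counts = cohort.prevalence_counts()
    codes = universe if universe is not None else list(counts)
    return {c for c in codes if counts.get(c, 0) / n < min_prevalence}


def comorbidity_universe(filtered: Cohort) -> list[str]:
    """Surviving disease codes minus every thyroid code, lexicographically ordered.

    Thyroid-disease codes (the E00-E07 block and C73) define the cohort rather
    than its comorbidities, so they are excluded from prevalence/difference
    tables even though they may appear as network nodes.
    """
    return sorted(set(filtered.code_universe()) - THYROID_CODES)


SUBGROUP_AXES = ("sex", "disease_type", "td_subtype", "age_bin")

_TD_SUBTYPES = {
    "nontoxic_goiter": frozenset({"E04"}),
    "hypothyroidism": frozenset({"E02", "E03"}),
    "hyperthyroidism": frozenset({"E05"}),
}


def _sub_cohort(parent: Cohort, label: str, records: list[EncounterRecord]) -> Cohort:
    c = Cohort(records, list(parent.filter_log), label=f"{parent.label}/{label}")
    c.log_filter(f"stratify:{label}", len(parent.records), len(records))
    return c


def stratify(filtered: Cohort, axis: str) -> dict[str, Cohort]:
    """Split a cohort along one subgroup axis.

    Sex and age-bin strata partition the cohort (records with unknown sex are
    excluded from sex strata). Disease type is malignancy-dominant: a record
    carrying both C73 and a benign E00-E07 code is assigned to the thyroid
    cancer (TC) stratum. Thyroid-disease subtypes may overlap, so a record can
    appear in several subtype strata.
    """
    if axis == "sex":
        groups = {
            "male": [r for r in filtered.records if r.sex is Sex.MALE],
            "female": [r for r in filtered.records if r.sex is Sex.FEMALE],
        }
    elif axis == "age_bin":
        groups = {}
        for lo, hi in AGE_BINS:
            label = f">={lo}" if hi is None else f"{lo}-{hi}"
            groups[label] = []
        for r in filtered.records:
            groups[age_bin_label(r.age)].append(r)
    elif axis == "disease_type":
        groups = {"TC": [], "BTD": []}
        for r in filtered.records:
            if "C73" in r.codes:
                groups["TC"].append(r)
            elif r.codes & BENIGN_THYROID_CODES:
                groups["BTD"].append(r)
    elif axis == "td_subtype":
        groups = {
            name: [r for r in filtered.records if r.codes & codes]
            for name, codes in _TD_SUBTYPES.items()
        }
    else:
        raise ValueError(f"unknown subgroup axis: {axis!r}")
    return {label: _sub_cohort(filtered, label, recs) for label, recs in groups.items()}
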