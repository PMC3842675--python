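"""Claims data model, tabular IO, and study-cohort construction.

One row of the claims file is one inpatient admission (one "case").
Repeat admissions of the same person are deliberately distinct cases.
The file format is UTF-8 TSV with a fixed header; list-valued fields
(secondary diagnoses, prior-year diagnoses, medications) are
semicolon-joined tokens, booleans are 0/1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._errors import RecordValidationError, SchemaError

logger = logging.getLogger(__name__)

#: Maximum plausible age at admission, in days (120 years).
MAX_AGE_DAYS = 120 * 365

CLAIMS_COLUMNS = [
    "case_id", "age_days", "sex", "insurance", "emergency_admission",
    "operated", "mrdx", "mrdx_category", "secondary_dx", "prior_year_dx",
    "medications", "died_in_hospital", "los_days", "transfer_in",
    "transfer_out",
]

EXCLUSION_CRITERIA = ("age", "long_stay", "transfer", "mrdx_category")


def normalize_icd(code: str) -> str:
    """Normalize an ICD-10 code: uppercase, dots stripped."""
    return code.replace(".", "").strip().upper()


@dataclass
class AdmissionRecord:
    """A single inpatient admission as billed in the claims data."""

    case_id: str
    age_days: int
    sex: str                      # "male" | "female"
    insurance: str                # "NHI" | "MedicalAid"
    emergency_admission: bool
    operated: bool
    mrdx: str                     # most responsible diagnosis, ICD-10
    mrdx_category: str            # grouped MRDx category identifier
    secondary_dx: list[str] = field(default_factory=list)
    prior_year_dx: list[str] = field(default_factory=list)
    medications: list[str] = field(default_factory=list)
    died_in_hospital: bool = False
    los_days: int = 0
    transfer_in: bool = False
    transfer_out: bool = False

    def __post_init__(self):
        self.mrdx = normalize_icd(self.mrdx)
        self.secondary_dx = [normalize_icd(c) for c in self.secondary_dx]
        self.prior_year_dx = [normalize_icd(c) for c in self.prior_year_dx]
        self.medications = [m.strip().lower() for m in self.medications]
        self.validate()

    def validate(self) -> None:
        if self.age_days < 0:
            raise RecordValidationError(self.case_id, "age_days must be >= 0")
        if self.los_days < 0:
            raise RecordValidationError(self.case_id, "los_days must be >= 0")
        if self.sex not in ("male", "female"):
            raise RecordValidationError(self.case_id, f"bad sex {self.sex!r}")
        if self.insurance not in ("NHI", "MedicalAid"):
            raise RecordValidationError(
                self.case_id, f"bad insurance {self.insurance!r}")
        for code in [self.mrdx, *self.secondary_dx, *self.prior_year_dx]:
            if len(code) < 3:
                raise RecordValidationError(
                    self.case_id, f"ICD code too short: {code!r}")


@dataclass
class Cohort:
    """The study cohort with its MRDx categories and exclusion audit."""

    records: list[AdmissionRecord]
    mrdx_categories: list[str]
    exclusion_log: dict[str, int]

    def __len__(self):
        return len(self.records)


def _parse_bool(value: str, case_id: str, column: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise RecordValidationError(case_id, f"{column} must be 0/1, got {value!r}")


def _parse_int(value: str, case_id: str, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise RecordValidationError(
            case_id, f"unparseable {column}: {value!r}") from None


def _split_list(value: str) -> list[str]:
    value = value.strip()
    return value.split(";") if value else []


def read_claims(path) -> list[AdmissionRecord]:
    """Read and validate a claims TSV into admission records.

    Unknown columns are preserved in the file but ignored here; a missing
    mandatory column raises :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"claims file missing mandatory column(s): "
                          f"{', '.join(missing)}")
    if df.empty:
        logger.warning("claims file %s contains no records", path)
        return []
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        cid = row.case_id
        if cid in seen:
            raise RecordValidationError(cid, "duplicate case_id")
        seen.add(cid)
        records.append(AdmissionRecord(
            case_id=cid,
            age_days=_parse_int(row.age_days, cid, "age_days"),
            sex=row.sex,
            insurance=row.insurance,
            emergency_admission=_parse_bool(
                row.emergency_admission, cid, "emergency_admission"),
            operated=_parse_bool(row.operated, cid, "operated"),
            mrdx=row.mrdx,
            mrdx_category=row.mrdx_category,
            secondary_dx=_split_list(row.secondary_dx),
            prior_year_dx=_split_list(row.prior_year_dx),
            medications=_split_list(row.medications),
            died_in_hospital=_parse_bool(
                row.died_in_hospital, cid, "died_in_hospital"),
            los_days=_parse_int(row.los_days, cid, "los_days"),
            transfer_in=_parse_bool(row.transfer_in, cid, "transfer_in"),
            transfer_out=_parse_bool(row.transfer_out, cid, "transfer_out"),
        ))
    return records


def write_claims(records: list[AdmissionRecord], path, header_comment=None):
    """Write admission records to the claims TSV format."""
    rows = []
    for r in records:
        rows.append({
            "case_id": r.case_id,
            "age_days": r.age_days,
            "sex": r.sex,
            "insurance": r.insurance,
            "emergency_admission": int(r.emergency_admission),
            "operated": int(r.operated),
            "mrdx": r.mrdx,
            "mrdx_category": r.mrdx_category,
            "secondary_dx": ";".join(r.secondary_dx),
            "prior_year_dx": ";".join(r.prior_year_dx),
            "medications": ";".join(r.medications),
            "died_in_hospital": int(r.died_in_hospital),
            "los_days": r.los_days,
            "transfer_in": int(r.transfer_in),
            "transfer_out": int(r.transfer_out),
        })
    df = pd.DataFrame(rows, columns=CLAIMS_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def select_mrdx_categories(records: list[AdmissionRecord],
                           coverage: float = 0.8) -> list[str]:
    """Rank MRDx categories by death count and keep the leading ones.

    Returns the shortest prefix of categories, sorted by descending
    in-hospital death count (ties by category id), whose cumulative share
    of all deaths reaches ``coverage``.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    deaths: dict[str, int] = {}
    for r in records:
        if r.died_in_hospital:
            deaths[r.mrdx_category] = deaths.get(r.mrdx_category, 0) + 1
    total = sum(deaths.values())
    if total == 0:
        raise ValueError("no mortality to rank")
    ranked = sorted(deaths.items(), key=lambda kv: (-kv[1], kv[0]))
    selected, cum = [], 0
    for cat, n in ranked:
        selected.append(cat)
        cum += n
        if cum / total >= coverage:
            break
    return selected


def apply_exclusions(records: list[AdmissionRecord],
                     excluded_categories: set[str] = frozenset(),
                     malignancy_categories: set[str] = frozenset()) -> Cohort:
    """Apply the study exclusion criteria, logging first-match counts.

    Criteria, in order: (1) implausible age (<= 28 days or >= 120 years);
    (2) stay longer than a year; (3) transferred in or out; (4) MRDx in a
    clinically heterogeneous ("wide spectrum") category or a malignancy
    category. A record failing several criteria is counted once, under the
    first, so the log is a partition of the removed records.
    """
    log = {c: 0 for c in EXCLUSION_CRITERIA}
    dropped_cats = set(excluded_categories) | set(malignancy_categories)
    kept = []
    for r in records:
        if r.age_days <= 28 or r.age_days >= MAX_AGE_DAYS:
            log["age"] += 1
        elif r.los_days > 365:
            log["long_stay"] += 1
        elif r.transfer_in or r.transfer_out:
            log["transfer"] += 1
        elif r.mrdx_category in dropped_cats:
            log["mrdx_category"] += 1
        else:
            kept.append(r)
    categories = sorted({r.mrdx_category for r in kept})
    return Cohort(records=kept, mrdx_categories=categories, exclusion_log=log)
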