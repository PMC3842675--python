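"""Inference of missed comorbidities from inpatient medication lists.

A drug is eligible as evidence of a comorbidity only when it is used
exclusively for one disease entity: multi-indication drugs, drugs usable
in mild conditions (including topicals), antineoplastics and parenteral
drugs are all removed, as are drugs mapping into severity-split condition
families (hypertension, diabetes) that a prescription alone cannot
disambiguate. One prescription event during the stay suffices. Inferred
conditions are screened for POA with the same DRG exclusion map used for
claim-derived Elixhauser conditions, then unioned with the claim-derived
set (hierarchy re-applied).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._errors import ConfigurationError, StatisticalError
from .coding import (ConditionMap, ConditionSet, _check_vocabulary,
                     apply_hierarchy)

#: Condition families whose severity split a drug cannot disambiguate.
SEVERITY_AMBIGUOUS_CONDITIONS = frozenset({
    "hypertension_uncomplicated", "hypertension_complicated",
    "diabetes_uncomplicated", "diabetes_complicated",
})

INELIGIBLE_ROUTES = frozenset({"parenteral", "topical"})


class DrugConditionMap:
    """Curated drug → condition table with eligibility flags.

    Columns: ``drug_id``, ``condition_id``, ``vocabulary``, ``route``
    (oral/parenteral/topical/other), ``is_antineoplastic``,
    ``multi_indication``, ``mild_condition_only`` (0/1 flags). The flags
    are curator-supplied; they are not computed from an indications
    database.
    """

    def __init__(self, entries: pd.DataFrame, *, validated: bool = False):
        entries = entries.copy()
        entries["drug_id"] = entries["drug_id"].str.strip().str.lower()
        self.entries = entries
        self.validated = validated
        # vocabulary -> drug -> condition (eligible maps are one-to-one)
        self._lookup: dict[str, dict[str, str]] = {}
        for vocab, grp in entries.groupby("vocabulary"):
            self._lookup[vocab] = dict(
                zip(grp["drug_id"], grp["condition_id"]))

    @classmethod
    def from_csv(cls, path) -> "DrugConditionMap":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "DrugConditionMap":
        """Synthetic fixture map shipped with the package (the study's
        national formulary curation is not public)."""
        from importlib.resources import files
        return cls.from_csv(files("comorbidrx") / "data" / "drug_map.csv")


def validate_drug_map(dmap: DrugConditionMap,
                      cmap: ConditionMap) -> tuple[DrugConditionMap,
                                                   dict[str, int]]:
    """Apply the drug-eligibility criteria; return (eligible map, log).

    The log counts removed entries by first-matching criterion:
    ``multi_indication``, ``antineoplastic``, ``mild_condition``,
    ``parenteral`` (covers topical too), ``severity_ambiguous``.
    """
    log = {k: 0 for k in ("multi_indication", "antineoplastic",
                          "mild_condition", "parenteral",
                          "severity_ambiguous")}
    keep_rows = []
    for _, row in dmap.entries.iterrows():
        if row["condition_id"] not in cmap.conditions(row["vocabulary"]):
            raise ConfigurationError(
                f"drug map references unknown condition "
                f"{row['condition_id']!r} in {row['vocabulary']}")
        if int(row["multi_indication"]):
            log["multi_indication"] += 1
        elif int(row["is_antineoplastic"]):
            log["antineoplastic"] += 1
        elif int(row["mild_condition_only"]):
            log["mild_condition"] += 1
        elif row["route"] in INELIGIBLE_ROUTES:
            log["parenteral"] += 1
        elif row["condition_id"] in SEVERITY_AMBIGUOUS_CONDITIONS:
            log["severity_ambiguous"] += 1
        else:
            keep_rows.append(row)
    eligible = pd.DataFrame(keep_rows, columns=dmap.entries.columns)
    if eligible.duplicated(["drug_id", "vocabulary"]).any():
        raise ConfigurationError(
            "eligible drug map must map one drug to one condition "
            "per vocabulary")
    return DrugConditionMap(eligible, validated=True), log


def infer_conditions(medications: list[str], dmap: DrugConditionMap,
                     vocabulary: str) -> ConditionSet:
    """Conditions inferred from prescriptions (one event suffices)."""
    _check_vocabulary(vocabulary)
    if not dmap.validated:
        raise ConfigurationError(
            "drug map must pass validate_drug_map before inference")
    lookup = dmap._lookup.get(vocabulary, {})
    hit = {lookup[m.strip().lower()] for m in medications
           if m.strip().lower() in lookup}
    return ConditionSet.from_drug(hit, vocabulary)


def merge_conditions(claim_cs: ConditionSet, drug_cs: ConditionSet,
                     cmap: ConditionMap) -> ConditionSet:
    """Union claim-derived and drug-inferred sets; reapply hierarchy.

    Provenance is ``claim``/``drug``/``both`` by membership.
    """
    if claim_cs.vocabulary != drug_cs.vocabulary:
        raise ConfigurationError(
            f"vocabulary mismatch: {claim_cs.vocabulary} vs "
            f"{drug_cs.vocabulary}")
    conds = claim_cs.conditions | drug_cs.conditions
    prov = {}
    for c in conds:
        in_claim = c in claim_cs.conditions
        in_drug = c in drug_cs.conditions
        prov[c] = "both" if (in_claim and in_drug) else (
            "claim" if in_claim else "drug")
    merged = ConditionSet(claim_cs.vocabulary, conds, prov)
    return apply_hierarchy(merged, cmap)


@dataclass(frozen=True)
class OverlapCounts:
    """Case counts for one condition: claim-coded (A), drug-inferred (B),
    and both (A∩B)."""

    n_claim: int
    n_drug: int
    n_both: int

    def __post_init__(self):
        if min(self.n_claim, self.n_drug, self.n_both) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_both > min(self.n_claim, self.n_drug):
            raise ValueError("n_both cannot exceed min(n_claim, n_drug)")

    @property
    def n_union(self) -> int:
        return self.n_claim + self.n_drug - self.n_both


def additional_fraction(oc: OverlapCounts) -> float:
    """Fraction of cases detected only by prescriptions:
    (|A∪B| − |A|) / |A∪B|."""
    if oc.n_union == 0:
        raise StatisticalError("undefined fraction: empty union")
    return (oc.n_union - oc.n_claim) / oc.n_union


def overlap_table(coded: pd.DataFrame, vocabulary: str) -> pd.DataFrame:
    """Per-condition claim/drug detection overlap across a coded cohort.

    ``coded`` must carry per-case claim-derived and drug-inferred (POA
    screened) condition sets in columns ``{vocabulary}_claim`` and
    ``{vocabulary}_drug``. Conditions nobody has are omitted; rows are
    sorted by descending fraction, ties by condition id.
    """
    _check_vocabulary(vocabulary)
    claim_col, drug_col = f"{vocabulary}_claim", f"{vocabulary}_drug"
    counts: dict[str, list[int]] = {}
    for claim_cs, drug_cs in zip(coded[claim_col], coded[drug_col]):
        claim = claim_cs.conditions if isinstance(
            claim_cs, ConditionSet) else frozenset(claim_cs)
        drug = drug_cs.conditions if isinstance(
            drug_cs, ConditionSet) else frozenset(drug_cs)
        for c in claim | drug:
            row = counts.setdefault(c, [0, 0, 0])
            row[0] += c in claim
            row[1] += c in drug
            row[2] += (c in claim) and (c in drug)
    rows = []
    for cond, (na, nb, nboth) in counts.items():
        oc = OverlapCounts(na, nb, nboth)
        rows.append({"condition_id": cond, "n_claim": na, "n_drug": nb,
                     "n_both": nboth, "fraction": additional_fraction(oc)})
    df = pd.DataFrame(rows, columns=["condition_id", "n_claim", "n_drug",
                                     "n_both", "fraction"])
    return df.sort_values(["fraction", "condition_id"],
                          ascending=[False, True]).reset_index(drop=True)
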