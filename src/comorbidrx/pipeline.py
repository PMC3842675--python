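"""Cohort coding: claims + mapping resources → per-case condition sets.

For every admission this computes, per vocabulary:

* the claim-derived condition set (secondary diagnoses mapped, hierarchy
  applied, then POA-screened — prior-year rule for Charlson, DRG
  screening for Elixhauser);
* the drug-inferred condition set (eligible prescriptions mapped, DRG
  screened);
* the enhanced set (union, hierarchy re-applied);

plus the original and enhanced Charlson scores. The most responsible
diagnosis itself is never counted as a comorbidity: only secondary
diagnoses are mapped.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import pandas as pd

from .claims import AdmissionRecord
from .coding import (ConditionMap, ConditionSet, DrgExclusionMap,
                     apply_hierarchy, charlson_score, deyo_poa_filter,
                     drg_screen, map_diagnoses)
from .drugs import DrugConditionMap, infer_conditions, merge_conditions, \
    validate_drug_map

CODED_SET_COLUMNS = ["charlson_claim", "charlson_drug", "charlson_enhanced",
                     "elixhauser_claim", "elixhauser_drug",
                     "elixhauser_enhanced"]


@dataclass
class MappingResources:
    """All configurable mapping resources used by the coding step."""

    condition_map: ConditionMap
    drg_exclusions: DrgExclusionMap
    drug_map: DrugConditionMap          # eligible (validated) map
    drug_removal_log: dict[str, int]

    @classmethod
    def from_maps(cls, condition_map: ConditionMap,
                  drg_exclusions: DrgExclusionMap,
                  drug_map: DrugConditionMap) -> "MappingResources":
        eligible, log = validate_drug_map(drug_map, condition_map)
        return cls(condition_map, drg_exclusions, eligible, log)

    @classmethod
    def default(cls) -> "MappingResources":
        return cls.from_maps(ConditionMap.default(),
                             DrgExclusionMap.default(),
                             DrugConditionMap.default())

    @classmethod
    def from_dir(cls, path) -> "MappingResources":
        """Load condition_map.csv, charlson_meta.csv, hierarchy.csv,
        drg_exclusions.csv and drug_map.csv from a directory."""
        path = Path(path)
        cmap = ConditionMap(
            pd.read_csv(path / "condition_map.csv"),
            pd.read_csv(path / "charlson_meta.csv"),
            pd.read_csv(path / "hierarchy.csv"))
        excl = DrgExclusionMap.from_frame(
            pd.read_csv(path / "drg_exclusions.csv"))
        dmap = DrugConditionMap.from_csv(path / "drug_map.csv")
        return cls.from_maps(cmap, excl, dmap)


def code_admission(record: AdmissionRecord,
                   res: MappingResources) -> dict:
    """Code one admission into claim/drug/enhanced condition sets."""
    cmap, excl = res.condition_map, res.drg_exclusions
    out = {
        "case_id": record.case_id,
        "mrdx_category": record.mrdx_category,
        "age_years": record.age_days / 365.25,
        "male": int(record.sex == "male"),
        "medical_aid": int(record.insurance == "MedicalAid"),
        "emergency": int(record.emergency_admission),
        "operated": int(record.operated),
        "died": int(record.died_in_hospital),
    }

    # Charlson: hierarchy, then the prior-year POA rule
    ch_raw = apply_hierarchy(
        map_diagnoses(record.secondary_dx, cmap, "charlson"), cmap)
    ch_prior = map_diagnoses(record.prior_year_dx, cmap, "charlson")
    ch_claim = deyo_poa_filter(ch_raw, ch_prior, cmap)

    # Elixhauser: hierarchy, then DRG screening
    el_raw = apply_hierarchy(
        map_diagnoses(record.secondary_dx, cmap, "elixhauser"), cmap)
    el_claim = drg_screen(el_raw, record.mrdx_category, excl)

    for vocab, claim_cs in (("charlson", ch_claim),
                            ("elixhauser", el_claim)):
        drug_cs = drg_screen(
            infer_conditions(record.medications, res.drug_map, vocab),
            record.mrdx_category, excl)
        enhanced = merge_conditions(claim_cs, drug_cs, cmap)
        out[f"{vocab}_claim"] = claim_cs
        out[f"{vocab}_drug"] = drug_cs
        out[f"{vocab}_enhanced"] = enhanced

    out["charlson_score"] = charlson_score(out["charlson_claim"], cmap)
    out["charlson_score_enhanced"] = charlson_score(
        out["charlson_enhanced"], cmap)
    return out


def code_cohort(records: list[AdmissionRecord],
                res: MappingResources | None = None) -> pd.DataFrame:
    """Code a list of admissions into the analysis DataFrame."""
    if res is None:
        res = MappingResources.default()
    return pd.DataFrame([code_admission(r, res) for r in records])


def _serialize_set(cs: ConditionSet) -> str:
    return ";".join(f"{c}:{cs.provenance[c]}" for c in sorted(cs.conditions))


def _parse_set(text: str, vocabulary: str) -> ConditionSet:
    if not text:
        return ConditionSet(vocabulary)
    prov = dict(tok.split(":") for tok in text.split(";"))
    return ConditionSet(vocabulary, frozenset(prov), prov)


def write_coded(coded: pd.DataFrame, path, header_comment=None) -> None:
    """Write a coded cohort to TSV (condition sets serialized)."""
    df = coded.copy()
    for col in CODED_SET_COLUMNS:
        df[col] = [_serialize_set(cs) for cs in df[col]]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_coded(path) -> pd.DataFrame:
    """Read a coded cohort written by :func:`write_coded`."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     dtype={c: str for c in CODED_SET_COLUMNS})
    for col in CODED_SET_COLUMNS:
        vocab = col.split("_")[0]
        df[col] = [_parse_set(t, vocab) for t in df[col]]
    return df
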