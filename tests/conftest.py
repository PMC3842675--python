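import pandas as pd
import pytest

from comorbidrx import (AdmissionRecord, ConditionMap, ConditionSet,
                        DrugConditionMap, MappingResources)
from comorbidrx.coding import DrgExclusionMap


def make_record(**kwargs) -> AdmissionRecord:
    """An admission record with sensible defaults, overridable per test."""
    base = dict(
        case_id="c0", age_days=22000, sex="male", insurance="NHI",
        emergency_admission=False, operated=False, mrdx="I500",
        mrdx_category="congestive_heart_failure", secondary_dx=[],
        prior_year_dx=[], medications=[], died_in_hospital=False,
        los_days=7, transfer_in=False, transfer_out=False)
    base.update(kwargs)
    return AdmissionRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def default_resources() -> MappingResources:
    return MappingResources.default()


@pytest.fixture(scope="session")
def default_cmap(default_resources) -> ConditionMap:
    return default_resources.condition_map


def build_cmap(entries, meta, hierarchy=()) -> ConditionMap:
    """Construct a ConditionMap from plain tuples."""
    edf = pd.DataFrame(entries,
                       columns=["icd_prefix", "condition_id", "vocabulary"])
    mdf = pd.DataFrame(meta, columns=["condition_id", "weight", "chronic"])
    hdf = pd.DataFrame(hierarchy,
                       columns=["superseding", "superseded", "vocabulary"])
    return ConditionMap(edf, mdf, hdf)


@pytest.fixture
def tiny_cmap() -> ConditionMap:
    """Small fixture vocabulary independent of the shipped tables."""
    entries = [
        ("I50", "chf", "charlson"),
        ("J44", "cpd", "charlson"),
        ("E10", "dm", "charlson"),
        ("E102", "dm_c", "charlson"),
        ("N18", "renal", "charlson"),
        ("C50", "cancer", "charlson"),
        ("C77", "meta", "charlson"),
        ("I21", "mi", "charlson"),
        ("I50", "chf", "elixhauser"),
        ("J44", "cpd", "elixhauser"),
        ("I10", "hypertension_uncomplicated", "elixhauser"),
        ("I11", "hypertension_complicated", "elixhauser"),
        ("F32", "depression", "elixhauser"),
    ]
    meta = [
        ("chf", 1, 1), ("cpd", 1, 1), ("dm", 1, 1), ("dm_c", 2, 1),
        ("renal", 2, 1), ("cancer", 2, 1), ("meta", 6, 1), ("mi", 1, 0),
    ]
    hierarchy = [
        ("dm_c", "dm", "charlson"),
        ("meta", "cancer", "charlson"),
        ("hypertension_complicated", "hypertension_uncomplicated",
         "elixhauser"),
    ]
    return build_cmap(entries, meta, hierarchy)


@pytest.fixture
def tiny_drug_map() -> DrugConditionMap:
    rows = [
        # drug, condition, vocab, route, antineo, multi, mild
        ("digoxin", "chf", "charlson", "oral", 0, 0, 0),
        ("tiotropium", "cpd", "charlson", "oral", 0, 0, 0),
        ("amlodipine", "hypertension_uncomplicated", "elixhauser",
         "oral", 0, 0, 0),
        ("heparin", "chf", "elixhauser", "parenteral", 0, 0, 0),
        ("paroxetine", "depression", "elixhauser", "oral", 0, 1, 0),
        ("methotrexate", "cancer", "charlson", "oral", 1, 0, 0),
        ("lotion", "cpd", "elixhauser", "topical", 0, 0, 1),
        ("digoxin", "chf", "elixhauser", "oral", 0, 0, 0),
    ]
    return DrugConditionMap(pd.DataFrame(rows, columns=[
        "drug_id", "condition_id", "vocabulary", "route",
        "is_antineoplastic", "multi_indication", "mild_condition_only"]))


@pytest.fixture
def tiny_excl() -> DrgExclusionMap:
    return DrgExclusionMap({"congestive_heart_failure": frozenset({"chf"})})


def claim_set(conditions, vocabulary="charlson") -> ConditionSet:
    return ConditionSet.from_claim(conditions, vocabulary)
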