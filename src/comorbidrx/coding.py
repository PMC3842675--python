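"""ICD-10 → comorbidity-condition mapping and present-on-admission screening.

Two vocabularies are supported: the 17 weighted Charlson conditions and the
31 binary Elixhauser conditions, both defined (in the shipped default
tables) by published ICD-10 prefix lists. Two POA discriminators are
implemented: the prior-year rule for the Charlson index (chronic conditions
are POA by definition; non-chronic ones must be mentioned in claims from
the year before the index admission) and DRG screening (conditions in the
same disease category as the most responsible diagnosis are treated as
complications, not comorbidities).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._errors import ConfigurationError

VOCABULARIES = ("charlson", "elixhauser")

#: Minimum ICD prefix length considered during matching.
MIN_PREFIX_LEN = 3


def _check_vocabulary(vocabulary: str) -> str:
    if vocabulary not in VOCABULARIES:
        raise ConfigurationError(
            f"unknown vocabulary {vocabulary!r}; expected one of "
            f"{VOCABULARIES}")
    return vocabulary


@dataclass(frozen=True)
class ConditionSet:
    """A set of comorbidity conditions with per-condition provenance.

    Provenance is ``"claim"`` (from diagnosis codes), ``"drug"`` (inferred
    from medications) or ``"both"``.
    """

    vocabulary: str
    conditions: frozenset[str] = frozenset()
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        _check_vocabulary(self.vocabulary)
        object.__setattr__(self, "conditions", frozenset(self.conditions))
        prov = dict(self.provenance) or {
            c: "claim" for c in self.conditions}
        if set(prov) != set(self.conditions):
            raise ValueError("provenance keys must equal conditions")
        object.__setattr__(self, "provenance", prov)

    @classmethod
    def from_claim(cls, conditions: Iterable[str], vocabulary: str):
        conds = frozenset(conditions)
        return cls(vocabulary, conds, {c: "claim" for c in conds})

    @classmethod
    def from_drug(cls, conditions: Iterable[str], vocabulary: str):
        conds = frozenset(conditions)
        return cls(vocabulary, conds, {c: "drug" for c in conds})

    def restrict(self, keep: Iterable[str]) -> "ConditionSet":
        keep = self.conditions & frozenset(keep)
        return ConditionSet(self.vocabulary, keep,
                            {c: self.provenance[c] for c in keep})

    def __contains__(self, condition):
        return condition in self.conditions

    def __iter__(self):
        return iter(self.conditions)

    def __len__(self):
        return len(self.conditions)


class ConditionMap:
    """ICD-prefix → condition tables plus Charlson metadata and hierarchy.

    Parameters
    ----------
    entries
        DataFrame with columns ``icd_prefix``, ``condition_id``,
        ``vocabulary``. Prefixes are normalized (uppercase, no dots).
    charlson_meta
        DataFrame with columns ``condition_id``, ``weight`` (1-6),
        ``chronic`` (0/1), one row per Charlson condition.
    hierarchy
        DataFrame with columns ``superseding``, ``superseded``,
        ``vocabulary`` listing mutually exclusive severity pairs.
    """

    def __init__(self, entries: pd.DataFrame, charlson_meta: pd.DataFrame,
                 hierarchy: pd.DataFrame):
        entries = entries.copy()
        entries["icd_prefix"] = (entries["icd_prefix"].str.upper()
                                 .str.replace(".", "", regex=False))
        if entries.duplicated(["icd_prefix", "condition_id",
                               "vocabulary"]).any():
            raise ConfigurationError("duplicated condition map entry")
        bad = set(entries["vocabulary"]) - set(VOCABULARIES)
        if bad:
            raise ConfigurationError(f"unknown vocabulary in map: {bad}")
        self.entries = entries
        # prefix lookup: vocabulary -> prefix -> frozenset(conditions)
        self._lookup: dict[str, dict[str, frozenset]] = {}
        for vocab, grp in entries.groupby("vocabulary"):
            d: dict[str, set] = {}
            for pfx, cond in zip(grp["icd_prefix"], grp["condition_id"]):
                d.setdefault(pfx, set()).add(cond)
            self._lookup[vocab] = {k: frozenset(v) for k, v in d.items()}
        self._max_prefix_len = int(entries["icd_prefix"].str.len().max())

        self.weights = dict(zip(charlson_meta["condition_id"],
                                charlson_meta["weight"].astype(int)))
        self.chronic_flags = dict(zip(charlson_meta["condition_id"],
                                      charlson_meta["chronic"].astype(bool)))
        charlson_conds = self.conditions("charlson")
        missing = charlson_conds - set(self.weights)
        if missing:
            raise ConfigurationError(
                f"charlson conditions without weight/chronic metadata: "
                f"{sorted(missing)}")
        if not all(1 <= w <= 6 for w in self.weights.values()):
            raise ConfigurationError("charlson weights must be in [1, 6]")

        self.hierarchy: dict[str, list[tuple[str, str]]] = {
            v: [] for v in VOCABULARIES}
        for row in hierarchy.itertuples(index=False):
            _check_vocabulary(row.vocabulary)
            self.hierarchy[row.vocabulary].append(
                (row.superseding, row.superseded))
        for vocab, pairs in self.hierarchy.items():
            self._check_acyclic(pairs, vocab)

        # fixed Elixhauser indicator ordering = first appearance in the table
        self.elixhauser_order = list(dict.fromkeys(
            entries.loc[entries["vocabulary"] == "elixhauser",
                        "condition_id"]))

    @staticmethod
    def _check_acyclic(pairs, vocab):
        succ: dict[str, set] = {}
        for sup, sub in pairs:
            succ.setdefault(sup, set()).add(sub)
        state: dict[str, int] = {}

        def visit(node):
            state[node] = 1
            for nxt in succ.get(node, ()):
                if state.get(nxt) == 1:
                    raise ConfigurationError(
                        f"hierarchy cycle in {vocab} vocabulary at {nxt!r}")
                if nxt not in state:
                    visit(nxt)
            state[node] = 2

        for node in list(succ):
            if node not in state:
                visit(node)

    def conditions(self, vocabulary: str) -> set[str]:
        _check_vocabulary(vocabulary)
        return set(self.entries.loc[
            self.entries["vocabulary"] == vocabulary, "condition_id"])

    @classmethod
    def default(cls) -> "ConditionMap":
        """The shipped transcription of the published ICD-10 tables."""
        data = files("comorbidrx") / "data"
        return cls(
            pd.read_csv(data / "condition_map.csv"),
            pd.read_csv(data / "charlson_meta.csv"),
            pd.read_csv(data / "hierarchy.csv"),
        )


@dataclass
class DrgExclusionMap:
    """MRDx category → conditions treated as same-category (non-POA)."""

    mapping: dict[str, frozenset[str]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrgExclusionMap":
        mapping: dict[str, set] = {}
        for row in df.itertuples(index=False):
            mapping.setdefault(row.mrdx_category, set()).add(row.condition_id)
        return cls({k: frozenset(v) for k, v in mapping.items()})

    @classmethod
    def default(cls) -> "DrgExclusionMap":
        data = files("comorbidrx") / "data"
        return cls.from_frame(pd.read_csv(data / "drg_exclusions.csv"))


def map_diagnoses(codes: Iterable[str], cmap: ConditionMap,
                  vocabulary: str) -> ConditionSet:
    """Map normalized ICD-10 codes to a claim-derived condition set.

    A code matches a table entry whose prefix it starts with; the longest
    matching prefix wins (specificity), and same-length ties map to all
    tied conditions. Unmatched codes are ignored; the result is the union
    over codes.
    """
    _check_vocabulary(vocabulary)
    lookup = cmap._lookup.get(vocabulary, {})
    hit: set[str] = set()
    for code in codes:
        top = min(len(code), cmap._max_prefix_len)
        for ln in range(top, MIN_PREFIX_LEN - 1, -1):
            conds = lookup.get(code[:ln])
            if conds:
                hit |= conds
                break
    return ConditionSet.from_claim(hit, vocabulary)


def apply_hierarchy(cs: ConditionSet, cmap: ConditionMap) -> ConditionSet:
    """Drop superseded severity levels when the superseding one is present.

    Membership is tested against the input set, so chains (a supersedes b,
    b supersedes c) collapse to the top level in one application.
    """
    drop = {sub for sup, sub in cmap.hierarchy[cs.vocabulary]
            if sup in cs.conditions and sub in cs.conditions}
    return cs.restrict(cs.conditions - drop)


def deyo_poa_filter(cs: ConditionSet, prior_cs: ConditionSet,
                    cmap: ConditionMap) -> ConditionSet:
    """Prior-year POA rule for Charlson conditions.

    A condition is kept when it is flagged chronic, or when it appears in
    the claims from the year preceding the index admission.
    """
    keep = set()
    for c in cs.conditions:
        if c not in cmap.chronic_flags:
            raise ConfigurationError(f"no chronic flag for condition {c!r}")
        if cmap.chronic_flags[c] or c in prior_cs.conditions:
            keep.add(c)
    return cs.restrict(keep)


def drg_screen(cs: ConditionSet, mrdx_category: str,
               excl: DrgExclusionMap) -> ConditionSet:
    """Remove conditions in the MRDx category's same-category set."""
    drop = excl.mapping.get(mrdx_category, frozenset())
    return cs.restrict(cs.conditions - drop)


def charlson_score(cs: ConditionSet, cmap: ConditionMap) -> int:
    """Weighted Charlson comorbidity score (sum of condition weights)."""
    total = 0
    for c in cs.conditions:
        if c not in cmap.weights:
            raise ConfigurationError(f"no weight for condition {c!r}")
        total += cmap.weights[c]
    return total


def elixhauser_indicators(cs: ConditionSet,
                          cmap: ConditionMap) -> np.ndarray:
    """0/1 indicator vector over the fixed Elixhauser condition ordering."""
    return np.array([int(c in cs.conditions)
                     for c in cmap.elixhauser_order], dtype=int)
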