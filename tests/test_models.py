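import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from comorbidrx import (InsufficientEventsError, ModelSpec, MortalityModel,
                        SeparationError, StatisticalError, bootstrap_c_ci,
                        build_design, c_statistic, code_cohort,
                        compare_models, fit_logistic, generate_cohort,
                        hosmer_lemeshow, scenario_presets,
                        wilcoxon_signed_rank)
from comorbidrx.coding import ConditionSet


def _coded_frame(n=20, deaths=None, seed=0, elix_sets=None):
    """Hand-built coded cohort frame for one MRDx stratum."""
    rng = np.random.default_rng(seed)
    if deaths is None:
        deaths = rng.random(n) < 0.3
    df = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(n)],
        "mrdx_category": "pneumonia",
        "age_years": rng.uniform(30, 90, n),
        "male": rng.integers(0, 2, n),
        "medical_aid": rng.integers(0, 2, n),
        "emergency": rng.integers(0, 2, n),
        "operated": rng.integers(0, 2, n),
        "died": np.asarray(deaths, dtype=int),
        "charlson_score": rng.integers(0, 5, n),
        "charlson_score_enhanced": rng.integers(0, 6, n),
    })
    if elix_sets is None:
        elix_sets = [set() for _ in range(n)]
    df["elixhauser_claim"] = [ConditionSet.from_claim(s, "elixhauser")
                              for s in elix_sets]
    df["elixhauser_enhanced"] = df["elixhauser_claim"]
    return df


class TestBuildDesign:
    def test_charlson_column_count(self):
        X, y, dropped = build_design(_coded_frame(),
                                     ModelSpec("pneumonia", "charlson"),
                                     min_events=1)
        assert list(X.columns) == ["intercept", "age_years", "male",
                                   "medical_aid", "emergency", "operated",
                                   "charlson_score"]

    def test_enhancement_changes_only_comorbidity_columns(self):
        df = _coded_frame()
        Xo, _, _ = build_design(df, ModelSpec("pneumonia", "charlson"),
                                min_events=1)
        Xe, _, _ = build_design(df, ModelSpec("pneumonia", "charlson",
                                              enhanced=True), min_events=1)
        base = ["intercept", "age_years", "male", "medical_aid",
                "emergency", "operated"]
        assert Xo[base].equals(Xe[base])
        assert (Xe["charlson_score"]
                == df["charlson_score_enhanced"]).all()

    def test_zero_variance_indicator_dropped(self):
        sets = [{"chf"} for _ in range(20)]
        df = _coded_frame(elix_sets=sets)
        X, _, dropped = build_design(df, ModelSpec("pneumonia",
                                                   "elixhauser"),
                                     min_events=1)
        assert ("chf", "zero variance") in dropped
        assert "chf" not in X.columns

    def test_zero_event_indicator_dropped(self):
        deaths = [1] * 5 + [0] * 15
        sets = [set() for _ in range(20)]
        for i in range(12, 18):
            sets[i] = {"obesity"}          # carriers all survive
        df = _coded_frame(deaths=deaths, elix_sets=sets)
        X, _, dropped = build_design(df, ModelSpec("pneumonia",
                                                   "elixhauser"),
                                     min_events=1)
        assert ("obesity", "no deaths among carriers") in dropped

    def test_insufficient_events_refusal(self):
        df = _coded_frame(deaths=[1] + [0] * 19)
        with pytest.raises(InsufficientEventsError):
            build_design(df, ModelSpec("pneumonia", "charlson"))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        y = pd.Series([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        params, probs, _ = fit_logistic(X, y)
        assert params["intercept"] == pytest.approx(math.log(3 / 7),
                                                    abs=1e-6)
        assert probs == pytest.approx(np.full(10, 0.3), abs=1e-6)

    def test_perfect_separation_detected(self):
        X = pd.DataFrame({"intercept": np.ones(20),
                          "x": np.r_[np.zeros(10), np.ones(10)]})
        y = pd.Series(np.r_[np.zeros(10), np.ones(10)])
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_parameter_recovery_on_true_condition_sets(self):
        # single-stratum generator with known coefficients
        cfg = replace(
            scenario_presets()["paper_like"], n_cases=5000, seed=9,
            categories={"pneumonia": (1.0, "J189", -3.8)})
        cohort = generate_cohort(cfg)
        info = cohort.case_info
        rng = np.random.default_rng(1)
        X = pd.DataFrame({
            "intercept": 1.0,
            "age_c": [r.age_days / 365.25 - 60 for r in cohort.records],
            "male": [int(r.sex == "male") for r in cohort.records],
            "medical_aid": [int(r.insurance == "MedicalAid")
                            for r in cohort.records],
            "emergency": [int(r.emergency_admission)
                          for r in cohort.records],
            "operated": [int(r.operated) for r in cohort.records],
            "score": info["true_charlson_score"].to_numpy(),
        })
        y = info["died"]
        params, _, bse = fit_logistic(X, y)
        truth = {"intercept": -3.8, "age_c": 0.030, "male": 0.10,
                 "medical_aid": 0.30, "emergency": 0.50,
                 "operated": -0.30, "score": 0.35}
        for term, true_beta in truth.items():
            assert abs(params[term] - true_beta) < 3 * bse[term], term


class TestCStatistic:
    def test_perfectly_ranked(self):
        assert c_statistic([0.9, 0.1], [1, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert c_statistic([0.3] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_four_case_pairs(self):
        assert c_statistic([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(StatisticalError, match="single-class"):
            c_statistic([0.1, 0.2], [1, 1])

    @staticmethod
    def brute_force(probs, outcomes):
        num = pairs = 0
        for i, (pi, yi) in enumerate(zip(probs, outcomes)):
            for pj, yj in zip(probs[:i], outcomes[:i]):
                if yi == yj:
                    continue
                pairs += 1
                hi, lo = (pi, pj) if yi > yj else (pj, pi)
                num += 1.0 if hi > lo else (0.5 if hi == lo else 0.0)
        return num / pairs

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(10, 80)
            probs = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)
            outcomes = rng.integers(0, 2, n)
            if outcomes.min() == outcomes.max():
                continue
            c = c_statistic(probs, outcomes)
            assert c == pytest.approx(self.brute_force(list(probs),
                                                       list(outcomes)))
            assert c == pytest.approx(roc_auc_score(outcomes, probs))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        probs = rng.random(60)
        outcomes = rng.integers(0, 2, 60)
        c1 = c_statistic(probs, outcomes)
        c2 = c_statistic(np.exp(3 * probs) - 0.5, outcomes)
        assert c1 == pytest.approx(c2)


class TestHosmerLemeshow:
    def test_perfect_calibration(self):
        # 10 groups of 20, group death rate exactly the predicted prob
        probs, outcomes = [], []
        for k in range(1, 11):
            p = k / 20
            probs += [p] * 20
            outcomes += [1] * k + [0] * (20 - k)
        chi2, p = hosmer_lemeshow(probs, outcomes, g=10)
        assert chi2 == pytest.approx(0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_two_group_hand_formula(self):
        probs = [0.2] * 10 + [0.8] * 10
        outcomes = [1] * 3 + [0] * 7 + [1] * 7 + [0] * 3
        chi2, _ = hosmer_lemeshow(probs, outcomes, g=2)
        # O=[3,7], E=[2,8], n_g=10: (1)^2/(2*0.8) + (1)^2/(8*0.2) = 1.25
        assert chi2 == pytest.approx(1.25)

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        probs = rng.random(200)
        outcomes = (rng.random(200) < probs).astype(int)
        chi2_a, _ = hosmer_lemeshow(probs, outcomes)
        perm = rng.permutation(200)
        chi2_b, _ = hosmer_lemeshow(probs[perm], outcomes[perm])
        assert chi2_a == pytest.approx(chi2_b)

    def test_small_sample_guard(self):
        with pytest.raises(StatisticalError, match="2g"):
            hosmer_lemeshow([0.5] * 15, [0, 1] * 7 + [0], g=10)


class TestWilcoxon:
    def test_all_zero_differences(self):
        with pytest.raises(StatisticalError, match="nonzero"):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_exact_three_pair_enumeration(self):
        # diffs +1,+2,+3: T+ distribution over 8 sign assignments gives
        # two-sided p = 2/8
        _, p = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert p == pytest.approx(0.25)

    def test_direction_of_enhancement(self):
        orig = [1, 0, 2, 3, 1, 0, 2, 1]
        enh = [2, 1, 2, 4, 1, 1, 3, 1]   # scores only ever increase
        stat, p = wilcoxon_signed_rank(enh, orig)
        d = np.array(enh) - np.array(orig)
        assert (d >= 0).all() and (d > 0).any()
        assert p < 1


@pytest.fixture(scope="module")
def coded(default_resources):
    cfg = replace(
        scenario_presets()["paper_like"], n_cases=2000, seed=13,
        categories={"pneumonia": (1.0, "J189", -3.0)})
    cohort = generate_cohort(cfg)
    return code_cohort(cohort.records, default_resources)


class TestBootstrapAndModel:
    def test_bootstrap_deterministic(self, coded):
        spec = ModelSpec("pneumonia", "charlson")
        ci1 = bootstrap_c_ci(coded, spec, B=30, seed=21)
        ci2 = bootstrap_c_ci(coded, spec, B=30, seed=21)
        assert ci1 == ci2

    def test_bootstrap_interval_contains_point_estimate(self, coded):
        res = MortalityModel(coded,
                             ModelSpec("pneumonia", "charlson")).fit(
            bootstrap_B=200, seed=5)
        assert res.c_ci_low <= res.c_statistic <= res.c_ci_high

    def test_insufficient_events_propagates(self, coded):
        tiny = coded.head(5).copy()
        tiny["died"] = [1, 0, 0, 0, 0]
        with pytest.raises(InsufficientEventsError):
            MortalityModel(tiny, ModelSpec("pneumonia", "charlson")).fit()

    def test_summary_mentions_key_quantities(self, coded):
        res = MortalityModel(coded,
                             ModelSpec("pneumonia", "elixhauser",
                                       enhanced=True)).fit()
        text = res.summary()
        assert "c-statistic" in text and "Hosmer-Lemeshow" in text
        assert "pneumonia" in text and "enhanced" in text


class TestCompareModels:
    def test_empty_stratum_is_annotated(self):
        df = _coded_frame(n=30, deaths=[1] * 2 + [0] * 28)
        out = compare_models(df, tools=("charlson",))
        assert (out["note"].str.contains("insufficient")).all()
        assert out["c_orig"].isna().all()
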