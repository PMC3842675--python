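"""Per-MRDx logistic models of in-hospital mortality.

For each most-responsible-diagnosis (MRDx) category four models are fitted:
original and enhanced (medication-augmented) versions of a Charlson-score
model and an Elixhauser-indicator model. All share the fixed covariates
age (years, continuous), sex, insurance status, emergency admission and
operative status. Discrimination is the c-statistic (all-pairs concordance,
ties scored 0.5) with a case-resampling percentile bootstrap CI;
calibration is the Hosmer-Lemeshow decile test; paired Charlson scores are
compared by the Wilcoxon signed-rank test.

The public surface follows the Model/Results idiom::

    model = MortalityModel(coded, ModelSpec("pneumonia", "charlson",
                                            enhanced=True))
    res = model.fit(bootstrap_B=1000, seed=7)
    print(res.summary())
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._errors import (ConfigurationError, InsufficientEventsError,
                      SeparationError, StatisticalError)

logger = logging.getLogger(__name__)

BASE_COVARIATES = ["age_years", "male", "medical_aid", "emergency",
                   "operated"]

#: |coefficient| above which a fit is treated as separated (logit scale).
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: MRDx stratum × tool × enhancement."""

    mrdx_category: str
    comorbidity_tool: str           # "charlson" | "elixhauser"
    enhanced: bool = False

    def __post_init__(self):
        if self.comorbidity_tool not in ("charlson", "elixhauser"):
            raise ConfigurationError(
                f"unknown comorbidity tool {self.comorbidity_tool!r}")

    @property
    def set_column(self) -> str:
        state = "enhanced" if self.enhanced else "claim"
        return f"{self.comorbidity_tool}_{state}"


def build_design(coded: pd.DataFrame, spec: ModelSpec,
                 min_events: int = 10):
    """Design matrix and outcome for one model configuration.

    Returns ``(X, y, dropped_terms)``. The Charlson tool contributes one
    integer score column; the Elixhauser tool contributes one 0/1 column
    per condition. Any 0/1 column (condition indicator or binary base
    covariate) is excluded, and logged in ``dropped_terms``, when it has
    zero variance or a zero cell against the outcome (no deaths among
    carriers, or no survivors among carriers) — the two directions of
    quasi-complete separation.
    """
    cats = set(coded["mrdx_category"])
    if cats != {spec.mrdx_category}:
        raise ValueError(
            f"records must all belong to {spec.mrdx_category!r}; got {cats}")
    y = coded["died"].astype(int).reset_index(drop=True)
    if int(y.sum()) < min_events:
        raise InsufficientEventsError(
            f"insufficient events in {spec.mrdx_category!r}: "
            f"{int(y.sum())} deaths < {min_events}")
    X = pd.DataFrame({"intercept": np.ones(len(coded))})
    for cov in BASE_COVARIATES:
        X[cov] = coded[cov].to_numpy(dtype=float)
    dropped: list[tuple[str, str]] = []
    yv = y.to_numpy()

    def indicator_drop_reason(ind):
        if ind.min() == ind.max():
            return "zero variance"
        if yv[ind == 1].sum() == 0:
            return "no deaths among carriers"
        if yv[ind == 1].sum() == (ind == 1).sum():
            return "no survivors among carriers"
        return None

    if spec.comorbidity_tool == "charlson":
        col = ("charlson_score_enhanced" if spec.enhanced
               else "charlson_score")
        X["charlson_score"] = coded[col].to_numpy(dtype=float)
    else:
        sets = coded[spec.set_column].tolist()
        order = sorted({c for cs in sets for c in cs.conditions})
        for cond in order:
            ind = np.array([int(cond in cs.conditions) for cs in sets],
                           dtype=float)
            reason = indicator_drop_reason(ind)
            if reason:
                dropped.append((cond, reason))
            else:
                X[cond] = ind
    for cov in BASE_COVARIATES:
        col = X[cov].to_numpy()
        if col.min() == col.max():
            dropped.append((cov, "zero variance"))
            X = X.drop(columns=cov)
        elif set(np.unique(col)) <= {0.0, 1.0}:
            reason = indicator_drop_reason(col)
            if reason:
                dropped.append((cov, reason))
                X = X.drop(columns=cov)
    for term, reason in dropped:
        logger.debug("dropping term %s (%s)", term, reason)
    return X, y, dropped


def fit_logistic(X: pd.DataFrame, y):
    """Maximum-likelihood logistic fit (binomial IRLS).

    Returns ``(params, fitted_probabilities, bse)``. Raises
    :class:`SeparationError` when any coefficient exceeds 15 in magnitude
    at convergence, and :class:`StatisticalError` on non-convergence.
    """
    model = sm.GLM(np.asarray(y, dtype=float), X,
                   family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except PerfectSeparationError as exc:
        raise SeparationError(list(X.columns)) from exc
    if not getattr(res, "converged", True):
        raise StatisticalError(
            "IRLS did not converge in 100 iterations; deviance trace: "
            f"{res.fit_history.get('deviance', [])!r}")
    params = pd.Series(res.params, index=X.columns)
    offending = params.index[params.abs() > SEPARATION_BOUND].tolist()
    if offending:
        raise SeparationError(offending)
    return params, np.asarray(res.fittedvalues), pd.Series(res.bse,
                                                           index=X.columns)


def c_statistic(probs, outcomes) -> float:
    """All-pairs concordance of predictions with outcomes (AUROC).

    Over all (death, survivor) pairs: 1 if the death got the higher
    predicted risk, 0.5 on ties, 0 otherwise. Computed via mid-ranks,
    which realizes exactly that tie convention.
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    if n1 == 0 or n0 == 0:
        raise StatisticalError("c-statistic undefined: single-class outcome")
    ranks = stats.rankdata(probs)
    return float((ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2)
                 / (n1 * n0))


def hosmer_lemeshow(probs, outcomes, g: int = 10):
    """Hosmer-Lemeshow goodness-of-fit test.

    Cases are ranked by predicted probability and split into ``g``
    near-equal groups (tied probabilities stay together, reducing the
    group count if needed). Returns ``(chi2, p)`` with
    ``chi2 = sum (O-E)^2 / (E (1 - E/n_g))`` and p from a chi-square with
    (groups - 2) degrees of freedom (NaN when fewer than 3 groups
    remain).
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    n = len(probs)
    if n < 2 * g:
        raise StatisticalError(f"need n >= 2g cases for the HL test "
                               f"(n={n}, g={g})")
    bins = pd.qcut(probs, g, labels=False, duplicates="drop")
    groups = []
    for b in np.unique(bins):
        mask = bins == b
        groups.append((int(outcomes[mask].sum()), float(probs[mask].sum()),
                       int(mask.sum())))
    # merge degenerate groups (expected 0 or n_g) into their neighbor
    merged = []
    for grp in groups:
        if merged and (grp[1] <= 0 or grp[1] >= grp[2]):
            o, e, m = merged[-1]
            merged[-1] = (o + grp[0], e + grp[1], m + grp[2])
            logger.debug("HL: merged degenerate group into neighbor")
        else:
            merged.append(grp)
    if merged and (merged[0][1] <= 0 or merged[0][1] >= merged[0][2]):
        if len(merged) > 1:
            o, e, m = merged.pop(0)
            o2, e2, m2 = merged[0]
            merged[0] = (o + o2, e + e2, m + m2)
    chi2 = 0.0
    for o, e, m in merged:
        denom = e * (1 - e / m)
        if denom > 0:
            chi2 += (o - e) ** 2 / denom
    dof = len(merged) - 2
    p = float(stats.chi2.sf(chi2, dof)) if dof >= 1 else float("nan")
    return float(chi2), p


def wilcoxon_signed_rank(scores_a, scores_b):
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped; tied magnitudes are mid-ranked; the
    exact null distribution is used for up to 25 nonzero pairs (when
    magnitudes are untied), otherwise the continuity-corrected normal
    approximation. Returns ``(statistic, p)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise StatisticalError("no nonzero pairs")
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bootstrap_c_ci(coded: pd.DataFrame, spec: ModelSpec, B: int,
                   seed: int, min_events: int = 10):
    """Percentile-bootstrap 95% CI for the c-statistic.

    Admissions are resampled with replacement (same n) and the model is
    refitted per replicate. Replicates that fail to fit are redrawn, up
    to 10·B total draws; more than 10% failures aborts.
    """
    # the full-data fit must succeed before resampling
    X, y, _ = build_design(coded, spec, min_events)
    fit_logistic(X, y)
    rng = np.random.default_rng(seed)
    n = len(coded)
    cs, failures, draws = [], 0, 0
    while len(cs) < B:
        if draws >= 10 * B:
            raise StatisticalError(
                f"unstable bootstrap: {failures} failures in {draws} draws")
        draws += 1
        idx = rng.integers(0, n, size=n)
        sample = coded.iloc[idx].reset_index(drop=True)
        try:
            Xb, yb, _ = build_design(sample, spec, min_events)
            _, probs, _ = fit_logistic(Xb, yb)
            cs.append(c_statistic(probs, yb))
        except StatisticalError:
            failures += 1
    if failures / draws > 0.1:
        raise StatisticalError(
            f"unstable bootstrap: {failures}/{draws} replicates failed")
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class MortalityResults:
    """Fitted in-hospital-mortality model for one configuration."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray
    n_cases: int
    n_deaths: int
    c_statistic: float
    c_ci_low: float
    c_ci_high: float
    hl_chi2: float
    hl_p: float
    dropped_terms: list = field(default_factory=list)

    def summary(self) -> str:
        s = self.spec
        lines = [
            f"In-hospital mortality model: {s.mrdx_category} "
            f"[{s.comorbidity_tool}{', enhanced' if s.enhanced else ''}]",
            f"  cases: {self.n_cases}   deaths: {self.n_deaths} "
            f"({100 * self.n_deaths / self.n_cases:.1f}%)",
            f"  c-statistic: {self.c_statistic:.3f} "
            + (f"(95% CI {self.c_ci_low:.3f}-{self.c_ci_high:.3f})"
               if np.isfinite(self.c_ci_low) else "(no bootstrap CI)"),
            f"  Hosmer-Lemeshow: chi2={self.hl_chi2:.1f} (p={self.hl_p:.2f})",
            "  coefficients (log-odds):",
        ]
        for term, beta in self.params.items():
            lines.append(f"    {term:<28s} {beta:+.4f} "
                         f"(se {self.bse[term]:.4f})")
        for term, reason in self.dropped_terms:
            lines.append(f"    [dropped] {term}: {reason}")
        return "\n".join(lines)


class MortalityModel:
    """Logistic in-hospital-mortality model for one MRDx stratum.

    Parameters
    ----------
    coded
        Coded cohort DataFrame (see :func:`comorbidrx.pipeline.code_cohort`);
        rows outside ``spec.mrdx_category`` are ignored.
    spec
        The configuration (tool and enhancement state) to fit.
    min_events
        Minimum number of deaths required to fit (default 10).
    """

    def __init__(self, coded: pd.DataFrame, spec: ModelSpec,
                 min_events: int = 10):
        self.spec = spec
        self.min_events = min_events
        self.data = coded.loc[coded["mrdx_category"] == spec.mrdx_category] \
            .reset_index(drop=True)

    @classmethod
    def from_cohort(cls, coded: pd.DataFrame, mrdx_category: str,
                    tool: str = "charlson", enhanced: bool = False,
                    min_events: int = 10) -> "MortalityModel":
        return cls(coded, ModelSpec(mrdx_category, tool, enhanced),
                   min_events)

    def fit(self, bootstrap_B: int = 0, seed: int = 0) -> MortalityResults:
        X, y, dropped = build_design(self.data, self.spec, self.min_events)
        params, probs, bse = fit_logistic(X, y)
        c = c_statistic(probs, y)
        try:
            hl_chi2, hl_p = hosmer_lemeshow(probs, y)
        except StatisticalError:
            hl_chi2, hl_p = float("nan"), float("nan")
        if bootstrap_B > 0:
            lo, hi = bootstrap_c_ci(self.data, self.spec, bootstrap_B,
                                    seed, self.min_events)
        else:
            lo, hi = float("nan"), float("nan")
        return MortalityResults(
            spec=self.spec, params=params, bse=bse, fitted=probs,
            n_cases=len(y), n_deaths=int(y.sum()), c_statistic=c,
            c_ci_low=lo, c_ci_high=hi, hl_chi2=hl_chi2, hl_p=hl_p,
            dropped_terms=dropped)


COMPARISON_COLUMNS = ["mrdx", "tool", "c_orig", "c_orig_lo", "c_orig_hi",
                      "c_enh", "c_enh_lo", "c_enh_hi", "hl_chi2_orig",
                      "hl_p_orig", "hl_chi2_enh", "hl_p_enh",
                      "enh_within_orig_ci", "note"]


def compare_models(coded: pd.DataFrame, mrdx_list=None,
                   tools=("charlson", "elixhauser"), B: int = 0,
                   seed: int = 0, min_events: int = 10) -> pd.DataFrame:
    """Original-vs-enhanced model comparison across MRDx strata.

    One row per MRDx × tool with both c-statistics (and bootstrap CIs when
    ``B > 0``), both Hosmer-Lemeshow results, and a flag for whether the
    enhanced c lies inside the original model's CI. Per-model failures
    become annotated rows rather than aborting the whole comparison.
    """
    if mrdx_list is None:
        mrdx_list = sorted(coded["mrdx_category"].unique())
    seeds = np.random.SeedSequence(seed).generate_state(
        2 * len(mrdx_list) * len(tools)) % (2 ** 31)
    rows, k = [], 0
    for mrdx in mrdx_list:
        for tool in tools:
            row = {c: float("nan") for c in COMPARISON_COLUMNS}
            row.update(mrdx=mrdx, tool=tool, note="")
            try:
                res_o = MortalityModel(
                    coded, ModelSpec(mrdx, tool, False), min_events
                ).fit(bootstrap_B=B, seed=int(seeds[k]))
                res_e = MortalityModel(
                    coded, ModelSpec(mrdx, tool, True), min_events
                ).fit(bootstrap_B=B, seed=int(seeds[k + 1]))
            except StatisticalError as exc:
                row["note"] = f"model failed: {exc}"
                rows.append(row)
                k += 2
                continue
            k += 2
            row.update(
                c_orig=res_o.c_statistic, c_orig_lo=res_o.c_ci_low,
                c_orig_hi=res_o.c_ci_high, c_enh=res_e.c_statistic,
                c_enh_lo=res_e.c_ci_low, c_enh_hi=res_e.c_ci_high,
                hl_chi2_orig=res_o.hl_chi2, hl_p_orig=res_o.hl_p,
                hl_chi2_enh=res_e.hl_chi2, hl_p_enh=res_e.hl_p)
            if np.isfinite(res_o.c_ci_low):
                row["enh_within_orig_ci"] = float(
                    res_o.c_ci_low <= res_e.c_statistic <= res_o.c_ci_high)
            rows.append(row)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
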