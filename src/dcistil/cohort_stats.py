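"""Cohort validation statistics.

Implements the statistical toolkit used to validate the TIL biomarker
against time-to-event outcomes: crosstabs with rank tests, Kaplan-Meier
estimates, cause-specific Cox proportional-hazards models with
likelihood-ratio model comparison and treatment-interaction tests, and
conditional logistic regression on age/treatment-matched nested
case-control sets.

Cox and Kaplan-Meier fitting is delegated to lifelines (Efron tie
handling); conditional logistic regression to statsmodels. Competing event
types are handled cause-specifically: when modelling one recurrence type,
the other type is censored at its event time, matching a first-event
analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergence
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    ModelConvergenceError,
    NonNestedModelError,
    UndefinedORError,
    UnknownFieldError,
)
from .synthetic_cohort import EVENT_DCIS, EVENT_INVASIVE, EVENT_NONE

OUTCOMES = ("IBE", EVENT_INVASIVE, EVENT_DCIS)

#: Display order of categorical covariate levels.
LEVEL_ORDERS = {
    "grade": ["low", "intermediate", "high"],
    "necrosis": ["absent", "<10%", "10-50%", ">50%"],
    "er": ["neg", "pos"],
    "her2": ["neg", "pos"],
    "excision": ["complete", "uncertain", "incomplete"],
}


# ---------------------------------------------------------------------------
# design-matrix encoding

def encode_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix for model fitting.

    The TIL category becomes a 0/1 high indicator; ordered categorical
    covariates become treatment-coded dummies against their first level;
    binary string covariates become 0/1; numeric covariates pass through.
    Rows with missing values are retained (complete-case filtering is the
    caller's job); the string "missing" is treated as NaN.
    """
    cols = {}
    for name in covariates:
        if name not in df.columns:
            raise UnknownFieldError(name)
        s = df[name]
        if name == "category":
            cols["category_high"] = (s == "high").astype(float)
        elif name in ("grade", "excision", "necrosis") and s.dtype == object:
            levels = LEVEL_ORDERS[name]
            for lv in levels[1:]:
                cols[f"{name}_{lv}"] = (s == lv).astype(float)
            unknown = ~s.isin(levels) & s.notna()
            for lv in levels[1:]:
                cols[f"{name}_{lv}"][unknown] = np.nan
        elif s.dtype == object:
            mapped = s.replace({"missing": np.nan}).map(
                {"neg": 0.0, "pos": 1.0, "no": 0.0, "yes": 1.0})
            if mapped.isna().all() and s.notna().any():
                raise UnknownFieldError(
                    f"cannot encode non-numeric covariate {name!r}")
            cols[name] = mapped.astype(float)
        else:
            cols[name] = s.astype(float)
    return pd.DataFrame(cols, index=df.index)


def _event_indicator(df: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "IBE":
        return (df["event"] != EVENT_NONE).astype(int)
    if outcome in (EVENT_INVASIVE, EVENT_DCIS):
        return (df["event"] == outcome).astype(int)
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMEstimate:
    """Product-limit estimate with a t-year event rate.

    ``event_rate`` is 1 - S(horizon) with a Greenwood-type CI (lifelines'
    exponential Greenwood interval). ``horizon_truncated`` flags a horizon
    beyond the last observed time, where the estimate is carried forward
    from the last event time.
    """

    survival: pd.DataFrame
    horizon: float
    survival_at_horizon: float
    event_rate: float
    ci_low: float
    ci_high: float
    horizon_truncated: bool
    fitter: KaplanMeierFitter


def km_estimate(times, events, horizon: float = 10.0) -> KMEstimate:
    """Kaplan-Meier curve and the event rate at ``horizon`` years."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    truncated = horizon > times.max()
    t_eval = min(horizon, times.max())
    s = float(kmf.predict(t_eval))
    ci = kmf.confidence_interval_survival_function_
    idx = ci.index[ci.index <= t_eval]
    if len(idx):
        lo = float(ci.iloc[ci.index.get_loc(idx[-1]), 0])
        hi = float(ci.iloc[ci.index.get_loc(idx[-1]), 1])
    else:  # pragma: no cover - horizon before first event
        lo = hi = s
    return KMEstimate(
        survival=kmf.survival_function_, horizon=horizon,
        survival_at_horizon=s, event_rate=1.0 - s,
        ci_low=1.0 - hi, ci_high=1.0 - lo,
        horizon_truncated=bool(truncated), fitter=kmf)


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass(frozen=True)
class TermResult:
    name: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


@dataclass
class SurvivalFit:
    """A fitted cause-specific Cox model."""

    outcome: str
    terms: list[TermResult]
    model_chi2: float
    model_df: int
    log_likelihood: float
    n: int
    n_events: int
    covariates: tuple[str, ...]
    fitter: CoxPHFitter | None = None

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def cox_fit(
    cohort: pd.DataFrame,
    outcome: str = "IBE",
    covariates: list[str] | None = None,
    extra_columns: pd.DataFrame | None = None,
) -> SurvivalFit:
    """Cause-specific Cox PH fit with Efron ties and Wald CIs.

    ``outcome`` selects the event definition: the composite IBE or one
    cause (the competing cause is censored at its event time). Missing
    covariate values drop the row (complete case); the model chi-square is
    the likelihood-ratio statistic against the null model.
    ``extra_columns`` lets callers append pre-built numeric columns (for
    example an interaction product) to the design.
    """
    covariates = list(covariates or ["category"])
    design = encode_design(cohort, covariates)
    if extra_columns is not None:
        design = pd.concat([design, extra_columns], axis=1)
    design = design.copy()
    design["time"] = cohort["time"].astype(float)
    design["event_ind"] = _event_indicator(cohort, outcome)
    design = design.dropna()
    n, n_events = len(design), int(design["event_ind"].sum())
    if n_events < 2:
        raise InsufficientDataError(
            f"need >= 2 events for outcome {outcome}, got {n_events}")
    feature_cols = [c for c in design.columns
                    if c not in ("time", "event_ind")]
    for c in feature_cols:
        if design[c].nunique() < 2:
            raise InsufficientDataError(f"covariate {c} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event_ind")
    except (_LifelinesConvergence, np.linalg.LinAlgError) as err:
        raise ModelConvergenceError(
            f"Cox fit failed for outcome {outcome}: {err}") from err
    lrt = cph.log_likelihood_ratio_test()
    summary = cph.summary
    terms = [TermResult(
        name=str(name), hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]), coef=float(row["coef"]),
        se=float(row["se(coef)"])) for name, row in summary.iterrows()]
    return SurvivalFit(
        outcome=outcome, terms=terms,
        model_chi2=float(lrt.test_statistic),
        model_df=len(feature_cols),
        log_likelihood=float(cph.log_likelihood_),
        n=n, n_events=n_events,
        covariates=tuple(feature_cols), fitter=cph)


@dataclass(frozen=True)
class LRTResult:
    delta_chi2: float
    df: int
    p: float


def lrt_compare(full: SurvivalFit, reduced: SurvivalFit) -> LRTResult:
    """Likelihood-ratio comparison of nested Cox models on the same rows."""
    if not set(reduced.covariates) <= set(full.covariates):
        raise NonNestedModelError(
            "reduced model covariates are not a subset of the full model's")
    if full.n != reduced.n or full.n_events != reduced.n_events:
        raise NonNestedModelError(
            "models were fitted on different observations")
    delta = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if delta < -1e-8:
        raise NonNestedModelError(
            f"negative delta chi-square ({delta:.3g}); models not nested")
    delta = max(delta, 0.0)
    df = full.model_df - reduced.model_df
    p = 1.0 if df == 0 else float(stats.chi2.sf(delta, df))
    return LRTResult(delta_chi2=float(delta), df=df, p=p)


@dataclass
class InteractionResult:
    """Treatment x biomarker interaction analysis.

    ``subgroup_hrs`` holds the treatment HR within each biomarker level
    from stratified fits (the default display); ``joint_hrs`` the same
    quantities derived from the joint model's (beta_b, beta_b + beta_ab).
    """

    p_interaction: float
    delta_chi2: float
    subgroup_hrs: dict[str, TermResult]
    joint_hrs: dict[str, float]
    full_fit: SurvivalFit
    reduced_fit: SurvivalFit


def interaction_test(
    cohort: pd.DataFrame,
    outcome: str = "IBE",
    factor_a: str = "category",
    factor_b: str = "radiotherapy",
) -> InteractionResult:
    """Interaction between a binary biomarker and a binary treatment.

    The p value is the likelihood-ratio test of the product term added to
    the main-effects Cox model; subgroup treatment HRs come from fits
    stratified by the biomarker.
    """
    design_ab = encode_design(cohort, [factor_a, factor_b])
    a_col, b_col = design_ab.columns[:2]
    for col in (a_col, b_col):
        if not set(design_ab[col].dropna().unique()) <= {0.0, 1.0}:
            raise ValueError(f"factor {col} is not binary")
    product = (design_ab[a_col] * design_ab[b_col]).rename(f"{a_col}_x_{b_col}")
    reduced = cox_fit(cohort, outcome, [factor_a, factor_b])
    full = cox_fit(cohort, outcome, [factor_a, factor_b],
                   extra_columns=product.to_frame())
    lrt = lrt_compare(full, reduced)

    subgroup_hrs: dict[str, TermResult] = {}
    for level in (0.0, 1.0):
        sub = cohort[design_ab[a_col] == level]
        label = f"{factor_a}={'high' if level else 'low'}" \
            if factor_a == "category" else f"{factor_a}={int(level)}"
        if sub.empty:
            raise InsufficientDataError(f"empty subgroup cell {label}")
        subgroup_hrs[label] = cox_fit(sub, outcome, [factor_b]).terms[0]

    beta_b = full.term(b_col).coef
    beta_ab = full.term(product.name).coef
    lo = f"{factor_a}=low" if factor_a == "category" else f"{factor_a}=0"
    hi = f"{factor_a}=high" if factor_a == "category" else f"{factor_a}=1"
    joint = {lo: float(np.exp(beta_b)), hi: float(np.exp(beta_b + beta_ab))}
    return InteractionResult(
        p_interaction=lrt.p, delta_chi2=lrt.delta_chi2,
        subgroup_hrs=subgroup_hrs, joint_hrs=joint,
        full_fit=full, reduced_fit=reduced)


# ---------------------------------------------------------------------------
# nested case-control

@dataclass
class MatchedSets:
    """Matched nested case-control sets.

    ``data`` holds one row per participant with ``set_id`` and ``is_case``
    columns joined onto the cohort columns.
    """

    data: pd.DataFrame
    ratio: int
    n_sets: int
    n_partial_sets: int
    n_dropped_cases: int


def match_case_control(
    cohort: pd.DataFrame,
    ratio: int = 2,
    age_caliper: float = 7.0,
    seed: int = 0,
) -> MatchedSets:
    """Match each case to controls by age and treatment allocation.

    A control is eligible if it shares the case's treatment allocation
    (tamoxifen and radiotherapy), is within ``age_caliper`` years of the
    case's age, remained event-free, and was followed at least as long as
    the case's time to event. Up to ``ratio`` eligible controls per case
    are drawn at random (seeded) without replacement across sets; cases
    with some but fewer than ``ratio`` eligible controls keep a partial
    set, cases with none are dropped and counted.
    """
    cases = cohort[cohort["event"] != EVENT_NONE].sort_values("patient_id")
    controls = cohort[cohort["event"] == EVENT_NONE]
    if cases.empty or controls.empty:
        raise InsufficientDataError("need both cases and event-free controls")
    rng = np.random.default_rng(seed)
    used: set = set()
    rows = []
    n_partial = n_dropped = 0
    set_id = 0
    for case in cases.itertuples():
        eligible = controls[
            (controls["tamoxifen"] == case.tamoxifen)
            & (controls["radiotherapy"] == case.radiotherapy)
            & ((controls["age"] - case.age).abs() <= age_caliper)
            & (controls["time"] >= case.time)
            & ~controls["patient_id"].isin(used)]
        if eligible.empty:
            n_dropped += 1
            continue
        k = min(ratio, len(eligible))
        if k < ratio:
            n_partial += 1
        chosen = rng.choice(eligible["patient_id"].to_numpy(), size=k,
                            replace=False)
        used.update(chosen)
        rows.append((set_id, case.patient_id, True))
        rows.extend((set_id, pid, False) for pid in sorted(chosen))
        set_id += 1
    if set_id == 0:
        raise InsufficientDataError("no case could be matched to a control")
    frame = pd.DataFrame(rows, columns=["set_id", "patient_id", "is_case"])
    data = frame.merge(cohort, on="patient_id", how="left")
    return MatchedSets(data=data, ratio=ratio, n_sets=set_id,
                       n_partial_sets=n_partial, n_dropped_cases=n_dropped)


@dataclass
class MatchedORResult:
    """Matched odds ratio from conditional logistic regression."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_sets: int
    coef: float
    se: float
    terms: list[TermResult] = field(default_factory=list)


def conditional_logistic(
    matched: MatchedSets | pd.DataFrame,
    exposure: str = "category",
    covariates: list[str] | None = None,
) -> MatchedORResult:
    """Conditional logistic regression over matched sets.

    Maximises the per-set conditional likelihood (statsmodels
    ConditionalLogit, Newton iterations) and reports the Wald CI for the
    exposure odds ratio. Requires at least one exposure-discordant set.
    """
    data = matched.data if isinstance(matched, MatchedSets) else matched
    all_cov = [exposure] + list(covariates or [])
    design = encode_design(data, all_cov)
    design = design.assign(_y=data["is_case"].astype(int),
                           _g=data["set_id"].to_numpy())
    design = design.dropna()
    exp_col = design.columns[0]
    discordant = design.groupby("_g")[exp_col].nunique() > 1
    if not discordant.any():
        raise UndefinedORError(
            "exposure is concordant within every matched set")
    from statsmodels.discrete.conditional_models import ConditionalLogit
    exog_cols = [c for c in design.columns if c not in ("_y", "_g")]
    model = ConditionalLogit(design["_y"].to_numpy(),
                             design[exog_cols].to_numpy(),
                             groups=design["_g"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, disp=0, tol=1e-12)
        except (np.linalg.LinAlgError, ValueError):
            res = model.fit(method="bfgs", maxiter=500, disp=0, gtol=1e-10)
    coefs = np.atleast_1d(res.params)
    ses = np.atleast_1d(res.bse)
    pvals = np.atleast_1d(res.pvalues)
    z = stats.norm.ppf(0.975)
    terms = [TermResult(name=name, hr=float(np.exp(b)),
                        ci_low=float(np.exp(b - z * s)),
                        ci_high=float(np.exp(b + z * s)),
                        p=float(p), coef=float(b), se=float(s))
             for name, b, s, p in zip(exog_cols, coefs, ses, pvals)]
    t0 = terms[0]
    return MatchedORResult(
        odds_ratio=t0.hr, ci_low=t0.ci_low, ci_high=t0.ci_high, p=t0.p,
        n_sets=int(design["_g"].nunique()), coef=t0.coef, se=t0.se,
        terms=terms)


# ---------------------------------------------------------------------------
# rank statistics

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    defined: bool


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with mid-rank ties; flags constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("spearman needs equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=float("nan"), p=float("nan"), defined=False)
    res = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(res.statistic), p=float(res.pvalue),
                          defined=True)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p: float
    test: str
    exact: bool


def _exact_kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    """Exact Kruskal-Wallis p by enumerating all group assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = stats.kruskal(*groups).statistic

    def h_of(split_idx: list[np.ndarray]) -> float:
        return stats.kruskal(*(pooled[ix] for ix in split_idx)).statistic

    n = len(pooled)
    indices = np.arange(n)
    count = total = 0
    # recursively choose which pooled indices go to each group
    def recurse(remaining: np.ndarray, gi: int, chosen: list) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            split = chosen + [remaining]
            total += 1
            if h_of(split) >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[gi]):
            mask = np.zeros(len(remaining), dtype=bool)
            mask[list(combo)] = True
            recurse(remaining[~mask], gi + 1, chosen + [remaining[mask]])

    recurse(indices, 0, [])
    return float(h_obs), count / total


def rank_tests(groups: list) -> RankTestResult:
    """Mann-Whitney (two groups) or Kruskal-Wallis (more) rank test.

    Exact enumeration is used when the pooled sample size is at most 10
    (and, for Mann-Whitney, the data are tie-free); otherwise the normal /
    chi-square approximation with tie correction. The two-group asymptotic
    Mann-Whitney is computed without continuity correction and so agrees
    with the two-group Kruskal-Wallis chi-square.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InsufficientDataError("need >= 2 non-empty groups")
    n_total = sum(len(g) for g in groups)
    if len(groups) == 2:
        x, y = groups
        pooled = np.concatenate(groups)
        no_ties = len(np.unique(pooled)) == len(pooled)
        if n_total <= 10 and no_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            return RankTestResult(statistic=float(res.statistic),
                                  p=float(res.pvalue),
                                  test="mann-whitney", exact=True)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        return RankTestResult(statistic=float(res.statistic),
                              p=float(res.pvalue),
                              test="mann-whitney", exact=False)
    if n_total <= 10:
        h, p = _exact_kruskal(groups)
        return RankTestResult(statistic=h, p=p, test="kruskal-wallis",
                              exact=True)
    res = stats.kruskal(*groups)
    return RankTestResult(statistic=float(res.statistic),
                          p=float(res.pvalue), test="kruskal-wallis",
                          exact=False)


# ---------------------------------------------------------------------------
# crosstabs

@dataclass
class CrosstabResult:
    """One covariate summarised by TIL category.

    For categorical covariates, ``table`` holds counts and within-column
    percentages (denominator: the column total over non-missing values);
    for continuous covariates, medians and IQRs. ``n_missing`` counts rows
    excluded from the denominators.
    """

    covariate: str
    kind: str
    table: pd.DataFrame
    p: float
    test: str
    n: int
    n_missing: int


def crosstab_summary(
    cohort: pd.DataFrame,
    covariate: str,
    category_col: str = "category",
) -> CrosstabResult:
    """Distribution of one covariate across TIL-low/TIL-high columns."""
    if covariate not in cohort.columns:
        raise UnknownFieldError(covariate)
    cats = cohort[category_col]
    values = cohort[covariate]
    numeric = pd.api.types.is_numeric_dtype(values) \
        and covariate not in LEVEL_ORDERS
    if numeric:
        mask = values.notna() & cats.notna()
        lo = values[mask & (cats == "low")].to_numpy(dtype=float)
        hi = values[mask & (cats == "high")].to_numpy(dtype=float)
        if len(lo) == 0 or len(hi) == 0:
            raise InsufficientDataError("a TIL column is empty")
        rt = rank_tests([lo, hi])
        rows = {}
        for name, v in (("low", lo), ("high", hi)):
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows[name] = {"n": len(v), "median": med, "iqr_low": q1,
                          "iqr_high": q3}
        table = pd.DataFrame(rows).T
        return CrosstabResult(covariate=covariate, kind="continuous",
                              table=table, p=rt.p, test=rt.test,
                              n=int(mask.sum()),
                              n_missing=int((~mask).sum()))

    levels = LEVEL_ORDERS.get(covariate)
    if levels is None:
        levels = sorted(values.dropna().unique().tolist())
    if covariate == "her2" and pd.api.types.is_numeric_dtype(values):
        values = values.map({0: "neg", 1: "pos"})
    mask = values.isin(levels) & cats.notna()
    vals, cat = values[mask], cats[mask]
    table_rows = []
    col_totals = {c: int((cat == c).sum()) for c in ("low", "high")}
    for lv in levels:
        row = {"level": lv}
        for c in ("low", "high"):
            count = int(((vals == lv) & (cat == c)).sum())
            row[f"{c}_n"] = count
            row[f"{c}_pct"] = (100.0 * count / col_totals[c]
                               if col_totals[c] else np.nan)
        table_rows.append(row)
    table = pd.DataFrame(table_rows).set_index("level")
    codes = vals.map({lv: i for i, lv in enumerate(levels)}).to_numpy(float)
    lo_codes = codes[(cat == "low").to_numpy()]
    hi_codes = codes[(cat == "high").to_numpy()]
    if len(lo_codes) == 0 or len(hi_codes) == 0:
        raise InsufficientDataError("a TIL column is empty")
    kw = stats.kruskal(lo_codes, hi_codes)
    return CrosstabResult(covariate=covariate, kind="categorical",
                          table=table, p=float(kw.pvalue),
                          test="kruskal-wallis", n=int(mask.sum()),
                          n_missing=int((~mask & cats.notna()).sum()))
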