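"""Validation statistics for methylation risk scores in a case-cohort study.

Implements the full battery applied to a derived risk score: covariate-
adjusted standardized residuals anchored on the random subcohort, Barlow-
weighted case-cohort Cox associations (with age as the timescale, robust
sandwich errors clustered by woman, optional latency exclusion, tertile and
stratified forms), unconditional logistic validation, risk gradients as odds
ratios per adjusted standard deviation (OPERA), ROC/AUC with DeLong variance
and paired AUC-difference tests, case-only etiologic-heterogeneity tests, and
correlation reports.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .design import CaseCohortDesign, barlow_weights

__all__ = [
    "ResidualizedScore",
    "AssociationResult",
    "OperaResult",
    "AucResult",
    "TertileResult",
    "standardized_residuals",
    "casecohort_cox",
    "apply_latency_exclusion",
    "tertile_association",
    "logistic_validation",
    "opera",
    "auc",
    "delong_test",
    "sequential_auc",
    "heterogeneity_test",
    "effect_modification",
    "correlation_report",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ResidualizedScore:
    """Covariate-adjusted, reference-standardized score residuals."""

    residual_standardized: pd.Series  # all samples
    raw_score: pd.Series
    adjustment_covariates: List[str]
    reference_ids: List[str]
    residual_sd: float


@dataclass
class AssociationResult:
    """One association estimate (HR or OR) with its Wald inference."""

    estimate_type: str  # "HR" or "OR"
    estimate: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n: int
    events: int
    model: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the point estimate")

    def to_dict(self):
        return {
            "type": self.estimate_type, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "z": self.z,
            "p": self.p, "n": self.n, "events": self.events, "model": self.model,
        }


@dataclass
class OperaResult:
    """Risk gradient: OR per adjusted SD for each predictor in a joint
    logistic model, with the model log-likelihood and LR test vs null."""

    estimates: Dict[str, AssociationResult]
    loglik: float
    loglik_null: float
    lr_chi2: float
    df: int

    def __post_init__(self):
        if self.lr_chi2 < -1e-8:
            raise ValueError("LR chi-square must be nonnegative")
        self.lr_chi2 = max(self.lr_chi2, 0.0)


@dataclass
class AucResult:
    """Area under the ROC curve with a DeLong-variance CI."""

    label: str
    auc: float
    ci_low: float
    ci_high: float
    p_diff_vs: Optional[str] = None
    p_diff: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        self.ci_low = float(np.clip(self.ci_low, 0.0, 1.0))
        self.ci_high = float(np.clip(self.ci_high, 0.0, 1.0))


@dataclass
class TertileResult:
    cutpoints: tuple
    associations: Dict[str, AssociationResult]  # "T2", "T3" (vs T1)
    trend_p: float
    counts: Dict[str, int]


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def standardized_residuals(scores: pd.Series, covariates: pd.DataFrame,
                           reference_ids: Sequence[str]) -> ResidualizedScore:
    """Regress the score on covariates within the reference set, residualize
    all samples, and divide by the reference-set residual SD.

    The reference set is conventionally the random subcohort, so residuals
    are standardized to the distribution of representative noncases.  Raises
    if the covariate matrix is rank deficient or the reference residuals are
    degenerate (zero variance).
    """
    reference_ids = list(reference_ids)
    covariates = covariates.loc[scores.index]
    if len(reference_ids) <= covariates.shape[1] + 1:
        raise ValueError("reference set too small for the adjustment model")
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    ref_pos = scores.index.get_indexer(reference_ids)
    Xr = X[ref_pos]
    yr = scores.to_numpy(float)[ref_pos]
    rank = np.linalg.matrix_rank(Xr)
    if rank < Xr.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = ["(intercept)"] + list(covariates.columns)
        r = 0
        for j in range(Xr.shape[1]):
            rj = np.linalg.matrix_rank(Xr[:, : j + 1])
            if rj == r:
                bad.append(cols[j])
            r = rj
        raise ValueError(f"rank-deficient covariate matrix; collinear: {bad}")
    coef, *_ = np.linalg.lstsq(Xr, yr, rcond=None)
    resid = scores.to_numpy(float) - X @ coef
    sd = float(np.std(resid[ref_pos], ddof=1))
    if sd <= 1e-12:
        raise ValueError("degenerate residuals: score is exactly linear in covariates")
    return ResidualizedScore(
        residual_standardized=pd.Series(resid / sd, index=scores.index,
                                        name=f"{scores.name or 'score'}_resid"),
        raw_score=scores.copy(),
        adjustment_covariates=list(covariates.columns),
        reference_ids=reference_ids,
        residual_sd=sd,
    )


# ---------------------------------------------------------------------------
# case-cohort Cox
# ---------------------------------------------------------------------------

def apply_latency_exclusion(design: CaseCohortDesign,
                            years: float) -> CaseCohortDesign:
    """Exclude the first ``years`` of follow-up.

    Any woman whose follow-up ends within the window is dropped (events and
    censorings alike), and the remaining women enter the risk set ``years``
    after their original entry.
    """
    if years <= 0:
        return design
    t = design.table.copy()
    keep = (t["age_exit"] - t["age_entry"]) > years
    t = t[keep].copy()
    t["age_entry"] = t["age_entry"] + years
    return CaseCohortDesign(t.reset_index(drop=True), design.sampling_fraction)


def _fit_barlow_cox(covariate_df: pd.DataFrame, design: CaseCohortDesign):
    """lifelines counting-process Cox fit on Barlow intervals; returns the
    fitted CoxPHFitter, n women and n events."""
    intervals = barlow_weights(design)
    df = intervals.merge(covariate_df.reset_index().rename(
        columns={covariate_df.index.name or "index": "sample_id"}),
        on="sample_id", how="left")
    if df.drop(columns=["sample_id"]).isna().any().any():
        missing = df.loc[df.isna().any(axis=1), "sample_id"].unique()
        raise ValueError(f"missing covariate values for samples {missing[:5]}")
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError("fewer than 2 events after exclusions")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="stop", event_col="event", entry_col="start",
                weights_col="weight", cluster_col="sample_id", robust=True)
    return cph, design.table["sample_id"].nunique(), n_events


def _wald_result(estimate_type, coef, se, n, events, model) -> AssociationResult:
    z = coef / se
    p = 2 * stats.norm.sf(abs(z))
    return AssociationResult(
        estimate_type=estimate_type, estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        z=float(z), p=float(p), n=int(n), events=int(events), model=model,
    )


def casecohort_cox(predictors: pd.DataFrame, design: CaseCohortDesign,
                   latency_exclusion_years: float = 0.0
                   ) -> Dict[str, AssociationResult]:
    """Barlow-weighted Cox model with age as the timescale.

    All columns of ``predictors`` (indexed by sample_id) enter one model;
    pass a single column for a univariate association.  The variance is the
    robust sandwich aggregated by woman.  Returns one AssociationResult per
    predictor (HR per unit — per adjusted SD when the predictor is a
    standardized residual).
    """
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    design = apply_latency_exclusion(design, latency_exclusion_years)
    cph, n, events = _fit_barlow_cox(predictors, design)
    label = ("Barlow-weighted Cox, age timescale"
             + (f", first {latency_exclusion_years:g}y excluded"
                if latency_exclusion_years else "")
             + f"; covariates: {list(predictors.columns)}")
    return {
        name: _wald_result("HR", cph.params_[name], cph.standard_errors_[name],
                           n, events, label)
        for name in predictors.columns
    }


def tertile_association(score: pd.Series, design: CaseCohortDesign,
                        reference_ids: Optional[Sequence[str]] = None,
                        latency_exclusion_years: float = 0.0) -> TertileResult:
    """Tertile contrasts (T2 and T3 vs T1) from the Barlow-weighted Cox model.

    Cutpoints are the 1/3 and 2/3 quantiles of the reference distribution —
    by default the subcohort noncases of the design.
    """
    design = apply_latency_exclusion(design, latency_exclusion_years)
    t = design.table
    if reference_ids is None:
        ref = t.loc[(t["subcohort"] == 1) & (t["case"] == 0), "sample_id"]
    else:
        ref = pd.Series(list(reference_ids))
    ref_scores = score.loc[ref]
    c1, c2 = np.quantile(ref_scores.to_numpy(float), [1 / 3, 2 / 3])
    members = score.loc[t["sample_id"]]
    tert = np.digitize(members.to_numpy(float), [c1, c2])  # 0, 1, 2

    counts = {f"T{k + 1}": int((tert == k).sum()) for k in range(3)}
    ev = t["event"].to_numpy(bool)
    for k in range(3):
        if not ((tert == k) & ev).any():
            raise ValueError(f"tertile T{k + 1} holds no events")

    dummies = pd.DataFrame(
        {"T2": (tert == 1).astype(float), "T3": (tert == 2).astype(float)},
        index=t["sample_id"],
    )
    cph, n, events = _fit_barlow_cox(dummies, design)
    assoc = {
        name: _wald_result("HR", cph.params_[name], cph.standard_errors_[name],
                           n, events, "tertile contrasts vs T1")
        for name in ("T2", "T3")
    }
    ordinal = pd.DataFrame({"tertile_ordinal": tert.astype(float)},
                           index=t["sample_id"])
    cph_tr, _, _ = _fit_barlow_cox(ordinal, design)
    z = cph_tr.params_["tertile_ordinal"] / cph_tr.standard_errors_["tertile_ordinal"]
    trend_p = float(2 * stats.norm.sf(abs(z)))
    return TertileResult(cutpoints=(float(c1), float(c2)), associations=assoc,
                         trend_p=trend_p, counts=counts)


def effect_modification(score: pd.Series, design: CaseCohortDesign,
                        stratum: pd.Series):
    """Per-stratum Barlow-weighted Cox fits plus a pooled interaction test.

    ``stratum`` is a categorical series indexed by sample_id.  Returns
    (dict stratum level -> AssociationResult, interaction P from the joint
    robust Wald test on the score-by-stratum product terms).
    """
    t = design.table
    stratum = stratum.loc[t["sample_id"]]
    levels = sorted(stratum.dropna().unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least two strata")
    per_stratum = {}
    for lev in levels:
        ids = stratum.index[stratum == lev]
        sub = design.subset(ids)
        if sub.table["event"].sum() == 0:
            raise ValueError(f"stratum {lev!r} holds no events")
        per_stratum[lev] = casecohort_cox(score.loc[ids].to_frame(), sub)[
            score.name or 0]

    # pooled model: score + stratum dummies + products
    cols = {"score": score.loc[t["sample_id"]].to_numpy(float)}
    for lev in levels[1:]:
        ind = (stratum == lev).astype(float).to_numpy()
        cols[f"stratum_{lev}"] = ind
        cols[f"score_x_{lev}"] = cols["score"] * ind
    pooled = pd.DataFrame(cols, index=t["sample_id"])
    cph, _, _ = _fit_barlow_cox(pooled, design)
    inter = [c for c in pooled.columns if c.startswith("score_x_")]
    b = cph.params_[inter].to_numpy()
    V = cph.variance_matrix_.loc[inter, inter].to_numpy()
    chi2 = float(b @ np.linalg.solve(V, b))
    p_int = float(stats.chi2.sf(chi2, len(inter)))
    return per_stratum, p_int


# ---------------------------------------------------------------------------
# logistic validation / OPERA
# ---------------------------------------------------------------------------

def _logit_fit(X: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or np.any(
            ~np.isfinite(res.bse)):
        raise ValueError("logistic fit did not converge (complete separation?)")
    return res


def logistic_validation(score: pd.Series, case: pd.Series) -> AssociationResult:
    """Unconditional logistic OR per SD of the (residualized) score."""
    y = case.loc[score.index].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both case and noncase samples are required")
    X = sm.add_constant(score.to_numpy(float))
    res = _logit_fit(X, y)
    return _wald_result("OR", res.params[1], res.bse[1], len(y), int(y.sum()),
                        "unconditional logistic, OR per SD")


def opera(predictors: pd.DataFrame, case: pd.Series) -> OperaResult:
    """Odds ratio per adjusted SD for each predictor in one joint logistic
    model, with the log-likelihood and LR chi-square against the null.

    Predictors must be covariate-residualized standardized scores (age's own
    residual adjusted for every risk factor except itself)."""
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    y = case.loc[predictors.index].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both case and noncase samples are required")
    X = sm.add_constant(predictors.to_numpy(float))
    res = _logit_fit(X, y)
    estimates = {
        name: _wald_result("OR", res.params[j + 1], res.bse[j + 1], len(y),
                           int(y.sum()), "OPERA joint logistic")
        for j, name in enumerate(predictors.columns)
    }
    return OperaResult(
        estimates=estimates, loglik=float(res.llf), loglik_null=float(res.llnull),
        lr_chi2=float(2 * (res.llf - res.llnull)), df=predictors.shape[1],
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(score: np.ndarray, case: np.ndarray):
    """Structural components of the DeLong AUC estimator.

    Returns (auc, v10 per-case components, v01 per-noncase components)."""
    pos = score[case]
    neg = score[~case]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both case and noncase samples are required")
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc_val = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    return auc_val, v10, v01


def auc(score: pd.Series, case: pd.Series, label: str = "score") -> AucResult:
    """AUC as the tie-corrected Mann-Whitney concordance probability with a
    DeLong-variance normal CI (clipped to [0, 1])."""
    score = pd.Series(score)
    c = pd.Series(case).loc[score.index].to_numpy(float).astype(bool)
    a, v10, v01 = _delong_components(score.to_numpy(float), c)
    var = (np.var(v10, ddof=1) / v10.size) + (np.var(v01, ddof=1) / v01.size)
    half = 1.959963984540054 * np.sqrt(var)
    return AucResult(label=label, auc=float(a), ci_low=a - half, ci_high=a + half)


def delong_test(score1: pd.Series, score2: pd.Series, case: pd.Series):
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (auc1, auc2, z, two-sided p)."""
    s1 = pd.Series(score1)
    s2 = pd.Series(score2).loc[s1.index]
    c = pd.Series(case).loc[s1.index].to_numpy(float).astype(bool)
    a1, v10_1, v01_1 = _delong_components(s1.to_numpy(float), c)
    a2, v10_2, v01_2 = _delong_components(s2.to_numpy(float), c)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return float(a1), float(a2), 0.0, 1.0
    z = (a1 - a2) / np.sqrt(var_diff)
    return float(a1), float(a2), float(z), float(2 * stats.norm.sf(abs(z)))


def sequential_auc(rf_covariates: pd.DataFrame, prs: pd.Series,
                   score: pd.Series, case: pd.Series) -> List[AucResult]:
    """AUC ladder for nested logistic models: risk factors; + PRS; + score.

    Each model is fit on the full evaluation sample and its AUC computed on
    the fitted (apparent) probabilities, matching a single-split design;
    consecutive models are compared with the paired DeLong test.
    """
    idx = rf_covariates.index
    if not (prs.index.equals(idx) and score.index.equals(idx)
            and case.index.equals(idx)):
        raise ValueError("all inputs must be aligned on the same samples")
    y = case.to_numpy(float)
    blocks = [
        ("RFs", rf_covariates.to_numpy(float)),
        ("RFs+PRS", np.column_stack([rf_covariates.to_numpy(float),
                                     prs.to_numpy(float)])),
        ("RFs+PRS+score", np.column_stack([rf_covariates.to_numpy(float),
                                           prs.to_numpy(float),
                                           score.to_numpy(float)])),
    ]
    preds = []
    for _, Xb in blocks:
        res = _logit_fit(sm.add_constant(Xb), y)
        preds.append(pd.Series(res.predict(), index=idx))
    results = []
    for k, (label, _) in enumerate(blocks):
        r = auc(preds[k], case, label=label)
        if k > 0:
            _, _, _, p = delong_test(preds[k], preds[k - 1], case)
            r.p_diff_vs = blocks[k - 1][0]
            r.p_diff = p
        results.append(r)
    return results


# ---------------------------------------------------------------------------
# heterogeneity / correlations
# ---------------------------------------------------------------------------

def heterogeneity_test(score: pd.Series, subtype: pd.Series):
    """Case-only etiologic heterogeneity: regress case subtype on the score.

    Two subtype levels use a logistic model (Wald P on the score
    coefficient); more levels use a polytomous (multinomial) model with a
    joint Wald chi-square.  Returns (p, fitted coefficient(s))."""
    subtype = subtype.loc[score.index].astype(str)
    levels = sorted(subtype.unique())
    if len(levels) < 2:
        raise ValueError("need at least two subtype levels among cases")
    X = sm.add_constant(score.to_numpy(float))
    if len(levels) == 2:
        y = (subtype == levels[1]).to_numpy(float)
        res = _logit_fit(X, y)
        z = res.params[1] / res.bse[1]
        return float(2 * stats.norm.sf(abs(z))), {levels[1]: float(res.params[1])}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(pd.get_dummies(subtype)[levels].to_numpy().argmax(1), X
                         ).fit(disp=0, maxiter=200)
    b = res.params.iloc[1].to_numpy()  # score row, one column per non-ref level
    rows = [2 * j + 1 for j in range(b.size)]
    V = res.cov_params().to_numpy()[np.ix_(rows, rows)]
    chi2 = float(b @ np.linalg.solve(V, b))
    p = float(stats.chi2.sf(chi2, b.size))
    return p, {lev: float(bj) for lev, bj in zip(levels[1:], b)}


def correlation_report(score: pd.Series, companions: pd.DataFrame,
                       reference_ids: Sequence[str]) -> pd.DataFrame:
    """Pearson r (with two-sided t-reference P) between the score and each
    companion variable within the stated reference set."""
    ref = list(reference_ids)
    if len(ref) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    s = score.loc[ref].to_numpy(float)
    for col in companions.columns:
        x = companions.loc[ref, col].to_numpy(float)
        ok = np.isfinite(s) & np.isfinite(x)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 paired observations for {col!r}")
        if np.std(x[ok]) == 0 or np.std(s[ok]) == 0:
            raise ValueError(f"zero variance in pair (score, {col!r})")
        r, p = stats.pearsonr(s[ok], x[ok])
        rows.append({"variable": col, "r": float(r), "p": float(p),
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)
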