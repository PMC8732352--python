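"""End-to-end study pipeline on synthetic case-cohort data.

Chains the full derivation and validation: simulate a cohort, apply sample
QC, assemble the feature table (DNAm estimators + candidate CpGs), split the
case-cohort sample 70/30, compute age-balancing training weights, fit the
elastic-net Cox risk score, and run the validation battery on the held-out
test set (Barlow-weighted Cox HRs, tertiles, OPERA grid, sequential AUC
ladder, correlations, case-only heterogeneity).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .design import (CaseCohortDesign, split_train_test,
                     training_selection_weights)
from .features import assemble_feature_table
from .io import MethylationMatrix
from .model import RiskScoreModel, fit_mbcrs
from .qc import impute_missing, sample_qc
from .simulate import (RISK_FACTOR_COLUMNS, SimulationConfig, simulate_cohort)
from .validation import (auc, casecohort_cox, correlation_report,
                         heterogeneity_test, opera, sequential_auc,
                         standardized_residuals, tertile_association)

__all__ = ["StudyResult", "run_study", "design_from_phenotypes",
           "study_scale_config", "auc_gain_experiment"]

ADJUSTMENT_COVARIATES = ("age_entry",) + RISK_FACTOR_COLUMNS


def study_scale_config(seed: int = 0, n_cohort: int = 40_000) -> SimulationConfig:
    """A cohort sized so its case-cohort sample matches a large prospective
    study's methylation subsample (~2.8k women, ~55% cases)."""
    return SimulationConfig(n_cohort=n_cohort, seed=seed)


def design_from_phenotypes(phenotypes: pd.DataFrame) -> CaseCohortDesign:
    """Case-cohort design (all cases + flagged subcohort) from a phenotype
    table whose ``subcohort`` column is already drawn."""
    sampled = (phenotypes["event"].astype(bool)
               | phenotypes["subcohort"].astype(bool))
    t = phenotypes.loc[sampled, ["sample_id", "age_entry", "age_exit",
                                 "event", "subcohort"]].copy()
    t["case"] = t["event"].astype(int)
    frac = phenotypes["subcohort"].mean()
    return CaseCohortDesign(
        t[["sample_id", "case", "subcohort", "age_entry", "age_exit",
           "event"]].reset_index(drop=True),
        sampling_fraction=float(frac),
    )


def auc_gain_experiment(seed: int, informative: bool = True,
                        n_cohort: int = 40_000):
    """One end-to-end run reduced to the discrimination question.

    Simulates a cohort (methylation signal on by default; ``informative=False``
    zeroes the methylation effects while questionnaire and PRS effects stay),
    runs QC, feature assembly, split, IPW, risk-score fitting and test-set
    residualization, then compares the apparent AUC of risk factors + PRS
    with and without the methylation score.

    Returns (auc_rf_prs, auc_with_score, delong_p).
    """
    cfg = SimulationConfig(
        n_cohort=n_cohort, seed=seed,
        effect_per_sd=SimulationConfig().effect_per_sd if informative else 0.0,
    )
    matrix, phenotypes, truth = simulate_cohort(cfg)
    design = design_from_phenotypes(phenotypes)
    sampled = matrix.select_samples(design.sample_ids)
    passing, _ = sample_qc(sampled)
    sampled = sampled.select_samples(passing)
    design = design.subset(passing)
    features = assemble_feature_table(sampled, truth.estimator_sets,
                                      truth.candidate_cpgs)
    design = split_train_test(design, 0.70, seed=seed + 1)
    t = design.table
    is_train = (t["train_test"] == "train").to_numpy()
    ipw = np.full(len(t), np.nan)
    ipw[is_train] = training_selection_weights(
        t.loc[is_train, "age_entry"], t.loc[is_train, "case"])
    design.table = t.assign(ipw=ipw)

    model = fit_mbcrs(features, design, fold_seed=seed + 2)
    scores = model.score(features)

    ph = phenotypes.set_index("sample_id")
    test = design.subset((t["train_test"] == "test").to_numpy())
    test_ids = test.sample_ids
    sub_ids = list(test.table.loc[test.table["subcohort"] == 1, "sample_id"])
    covars = ph.loc[test_ids, list(ADJUSTMENT_COVARIATES)]
    prs = ph.loc[test_ids, "prs"]
    case = ph.loc[test_ids, "event"]
    if not model.coefficients:
        # empty model: the score is a constant and adds nothing
        from .validation import auc as auc_stat
        import statsmodels.api as sm
        X = sm.add_constant(np.column_stack([covars.to_numpy(float),
                                             prs.to_numpy(float)]))
        res_fit = sm.Logit(case.to_numpy(float), X).fit(disp=0)
        base = auc_stat(pd.Series(res_fit.predict(), index=covars.index), case)
        return base.auc, base.auc, 1.0
    res = standardized_residuals(scores.loc[test_ids], covars, sub_ids)
    ladder = sequential_auc(covars, prs, res.residual_standardized, case)
    return ladder[1].auc, ladder[2].auc, ladder[2].p_diff


@dataclass
class StudyResult:
    """Everything a validation report needs, as plain objects."""

    model: RiskScoreModel
    design: CaseCohortDesign
    scores: pd.Series
    cox: Dict
    tertiles: object
    opera_grid: Dict
    auc_ladder: list
    correlations: pd.DataFrame
    heterogeneity_p: float
    qc_report: object
    n_imputed: int


def run_study(config: Optional[SimulationConfig] = None, seed: int = 0,
              latency_years: float = 2.0, alpha: float = 0.5,
              n_folds: int = 10, lambda_rule: str = "1se",
              train_fraction: float = 0.70) -> StudyResult:
    """Run the whole derivation + validation on one simulated cohort."""
    cfg = replace(config or SimulationConfig(), seed=seed)
    matrix, phenotypes, truth = simulate_cohort(cfg)

    design = design_from_phenotypes(phenotypes)
    sampled_matrix = matrix.select_samples(design.sample_ids)

    # sample QC, then drop excluded women from the design
    passing, qc_report = sample_qc(sampled_matrix)
    sampled_matrix = sampled_matrix.select_samples(passing)
    design = design.subset(passing)
    sampled_matrix, n_imputed = impute_missing(sampled_matrix)

    features = assemble_feature_table(sampled_matrix, truth.estimator_sets,
                                      truth.candidate_cpgs)

    # 70/30 split and age-balancing training weights
    design = split_train_test(design, train_fraction, seed=seed + 1)
    t = design.table
    is_train = (t["train_test"] == "train").to_numpy()
    ipw = np.full(len(t), np.nan)
    ipw[is_train] = training_selection_weights(
        t.loc[is_train, "age_entry"], t.loc[is_train, "case"])
    design.table = t.assign(ipw=ipw)

    model = fit_mbcrs(features, design, alpha=alpha, n_folds=n_folds,
                      fold_seed=seed + 2, lambda_rule=lambda_rule)
    scores = model.score(features).rename("mbcrs")

    # ---- test-set validation ----------------------------------------------
    ph = phenotypes.set_index("sample_id")
    test = design.subset((t["train_test"] == "test").to_numpy())
    test_ids = test.sample_ids
    sub_ids = list(test.table.loc[test.table["subcohort"] == 1, "sample_id"])

    covars = ph.loc[test_ids, list(ADJUSTMENT_COVARIATES)]
    mbcrs_res = standardized_residuals(scores.loc[test_ids], covars, sub_ids)
    prs_res = standardized_residuals(ph.loc[test_ids, "prs"], covars, sub_ids)
    preds = pd.DataFrame({
        "mbcrs": mbcrs_res.residual_standardized,
        "prs": prs_res.residual_standardized,
    })

    cox = {
        "mbcrs": casecohort_cox(preds[["mbcrs"]], test)["mbcrs"],
        "prs": casecohort_cox(preds[["prs"]], test)["prs"],
        "joint": casecohort_cox(preds, test),
        "mbcrs_latency": casecohort_cox(preds[["mbcrs"]], test,
                                        latency_years)["mbcrs"],
        "prs_latency": casecohort_cox(preds[["prs"]], test,
                                      latency_years)["prs"],
    }
    tert = tertile_association(scores.loc[test_ids], test)

    # OPERA grid: residuals adjusted for every risk factor except age; age's
    # own residual adjusted for the risk factors
    rf_only = ph.loc[test_ids, list(RISK_FACTOR_COLUMNS)]
    mbcrs_op = standardized_residuals(scores.loc[test_ids], rf_only, sub_ids)
    prs_op = standardized_residuals(ph.loc[test_ids, "prs"], rf_only, sub_ids)
    age_op = standardized_residuals(ph.loc[test_ids, "age_entry"], rf_only,
                                    sub_ids)
    op_preds = pd.DataFrame({
        "mbcrs": mbcrs_op.residual_standardized,
        "prs": prs_op.residual_standardized,
        "age": age_op.residual_standardized,
    })
    case_test = ph.loc[test_ids, "event"]
    opera_grid = {}
    for combo in (("mbcrs",), ("prs",), ("age",), ("mbcrs", "prs"),
                  ("mbcrs", "age"), ("prs", "age"), ("mbcrs", "prs", "age")):
        opera_grid["+".join(combo)] = opera(op_preds[list(combo)], case_test)

    ladder = sequential_auc(
        ph.loc[test_ids, list(ADJUSTMENT_COVARIATES)],
        ph.loc[test_ids, "prs"],
        mbcrs_res.residual_standardized,
        case_test,
    )

    corr = correlation_report(
        scores.loc[test_ids],
        ph.loc[test_ids, ["prs", "age_entry"]],
        sub_ids,
    )

    case_ids = list(test.table.loc[test.table["case"] == 1, "sample_id"])
    het_p, _ = heterogeneity_test(
        mbcrs_res.residual_standardized.loc[case_ids],
        ph.loc[case_ids, "subtype"],
    )

    return StudyResult(model=model, design=design, scores=scores, cox=cox,
                       tertiles=tert, opera_grid=opera_grid, auc_ladder=ladder,
                       correlations=corr, heterogeneity_p=het_p,
                       qc_report=qc_report, n_imputed=n_imputed)
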