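"""The fitted methylation risk score (mBCRS-style model).

A risk score model is the set of features selected by the weighted
elastic-net Cox fit together with their coefficients on the original feature
scale, plus the training metadata (alpha, selected lambda, fold seed,
standardization constants) needed to score new samples reproducibly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .coxnet import CoxnetRiskScore
from .design import CaseCohortDesign
from .features import FeatureTable

__all__ = ["RiskScoreModel", "fit_mbcrs", "score_samples"]


@dataclass
class RiskScoreModel:
    """Selected features and coefficients defining a methylation risk score."""

    coefficients: Dict[str, float]  # nonzero only, original feature scale
    feature_class: Dict[str, str]  # selected feature -> {"estimator", "cpg"}
    alpha: float
    lambda_: float
    lambda_rule: str
    fold_seed: int
    timescale: str = "time_on_study"
    feature_means: Dict[str, float] = field(default_factory=dict)
    feature_sds: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v == 0 for v in self.coefficients.values()):
            raise ValueError("coefficients must be nonzero exactly on the "
                             "selected features")

    @property
    def selected_features(self):
        return list(self.coefficients)

    def selection_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for f in self.coefficients:
            cls = self.feature_class.get(f, "unknown")
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    # -- scoring ------------------------------------------------------------
    def score(self, features) -> pd.Series:
        """Linear combination sum_j coef_j * feature_ij (original scale)."""
        values = features.values if isinstance(features, FeatureTable) else features
        missing = [f for f in self.coefficients if f not in values.columns]
        if missing:
            raise ValueError(f"features missing from the table: {missing}")
        if not self.coefficients:
            return pd.Series(0.0, index=values.index, name="risk_score")
        cols = list(self.coefficients)
        coefs = np.array([self.coefficients[c] for c in cols])
        out = values[cols].to_numpy(dtype=float) @ coefs
        return pd.Series(out, index=values.index, name="risk_score")

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "coefficients": self.coefficients,
            "feature_class": self.feature_class,
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "lambda_rule": self.lambda_rule,
            "fold_seed": self.fold_seed,
            "timescale": self.timescale,
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RiskScoreModel":
        d = json.loads(text)
        return cls(
            coefficients=d["coefficients"], feature_class=d["feature_class"],
            alpha=d["alpha"], lambda_=d["lambda"], lambda_rule=d["lambda_rule"],
            fold_seed=d["fold_seed"], timescale=d.get("timescale", "time_on_study"),
            feature_means=d.get("feature_means", {}),
            feature_sds=d.get("feature_sds", {}),
        )

    @classmethod
    def load(cls, path) -> "RiskScoreModel":
        return cls.from_json(Path(path).read_text())


def fit_mbcrs(features: FeatureTable, design: CaseCohortDesign,
              alpha: float = 0.5, n_folds: int = 10, fold_seed: int = 0,
              lambda_rule: str = "1se", timescale: str = "time_on_study",
              tol: float = 1e-5) -> RiskScoreModel:
    """Fit the risk score on the IPW-weighted training rows of the design.

    Requires ``design.table`` to carry a filled train_test column and
    training selection weights (ipw).  The training Cox model runs on the
    time-on-study scale by default; pass ``timescale='age'`` for a
    left-truncated age-scale fit.
    """
    t = design.table
    train = t[t["train_test"] == "train"]
    if train.empty:
        raise ValueError("design has no training rows (run split_train_test)")
    if train["ipw"].isna().any():
        raise ValueError("training rows lack ipw weights")
    ids = list(train["sample_id"])
    X = features.values.loc[ids]
    event = train["event"].to_numpy(float)
    if timescale == "age":
        entry = train["age_entry"].to_numpy(float)
        stop = train["age_exit"].to_numpy(float)
    elif timescale == "time_on_study":
        entry = None
        stop = (train["age_exit"] - train["age_entry"]).to_numpy(float)
    else:
        raise ValueError("timescale must be 'age' or 'time_on_study'")

    est = CoxnetRiskScore(alpha=alpha, cv=n_folds, lambda_rule=lambda_rule,
                          random_state=fold_seed, tol=tol)
    est.fit(X, (event, stop), sample_weight=train["ipw"].to_numpy(float),
            entry=entry)

    names = list(X.columns)
    coefficients = {names[j]: float(est.coef_[j])
                    for j in np.flatnonzero(est.selected_)}
    return RiskScoreModel(
        coefficients=coefficients,
        feature_class={f: features.feature_class[f] for f in coefficients},
        alpha=alpha, lambda_=float(est.lambda_), lambda_rule=lambda_rule,
        fold_seed=fold_seed, timescale=timescale,
        feature_means={names[j]: float(est.x_mean_[j])
                       for j in range(len(names)) if est.selected_[j]},
        feature_sds={names[j]: float(est.x_scale_[j])
                     for j in range(len(names)) if est.selected_[j]},
    )


def score_samples(model: RiskScoreModel, features) -> pd.Series:
    """Per-sample risk score; errors if any selected feature is missing."""
    return model.score(features)
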