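"""DNAm estimators and candidate-CpG feature assembly.

A DNAm estimator is a published weighted linear combination of CpG beta
values — intercept + sum of probe weights — optionally passed through a
calibration transform (first-generation epigenetic clocks train on a
log-compressed age scale and invert it at prediction time).  This module
computes such estimators from a beta matrix, derives epigenetic
age-acceleration residuals, and assembles the candidate feature table
(estimator columns plus raw candidate-CpG betas) that the risk-score builder
consumes.

The package ships no published coefficient sets; they are data, loaded from a
CSV of (probe_id, weight) plus a JSON sidecar, or generated synthetically.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd

from .io import MethylationMatrix

__all__ = [
    "CoefficientSet",
    "FeatureTable",
    "compute_linear_estimator",
    "age_acceleration",
    "assemble_feature_table",
    "read_coefficient_set",
    "write_coefficient_set",
    "register_transform",
    "ADULT_AGE",
]

ADULT_AGE = 20.0


def _identity(x):
    return x


def _age_calibration(x):
    """Invert the log-compressed age scale used by first-generation clocks.

    The training transform maps age a to log(a+1) - log(adult+1) below the
    adult threshold and to (a - adult)/(adult+1) above it; this is its
    inverse, applied to the linear predictor to return years.
    """
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, (1 + ADULT_AGE) * np.exp(x) - 1,
                    (1 + ADULT_AGE) * x + ADULT_AGE)


_TRANSFORMS: Dict[str, Callable] = {
    "identity": _identity,
    "age_calibration": _age_calibration,
}


def register_transform(name: str, func: Callable) -> None:
    """Register a custom (monotone) output transform under ``name``."""
    _TRANSFORMS[name] = func


@dataclass
class CoefficientSet:
    """A named linear DNAm estimator: intercept + probe weights (+ transform)."""

    name: str
    intercept: float
    weights: Dict[str, float]
    transform: str = "identity"
    output_units: str = ""

    def __post_init__(self):
        if not self.weights:
            raise ValueError(f"estimator {self.name!r} has no probes")
        if len(set(self.weights)) != len(self.weights):
            raise ValueError("duplicate probe IDs in coefficient set")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class FeatureTable:
    """Sample-by-feature values with the estimator/CpG class of each column."""

    values: pd.DataFrame  # samples x features
    feature_class: Dict[str, str]  # feature -> {"estimator", "cpg"}
    dropped_probes: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dups = list(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicated feature IDs: {dups}")

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    def classes(self) -> pd.Series:
        return pd.Series({f: self.feature_class[f] for f in self.feature_ids})


def compute_linear_estimator(matrix: MethylationMatrix, coeffs: CoefficientSet,
                             missing_probes: str = "drop"):
    """Evaluate transform(intercept + sum_j w_j * beta_ij) per sample.

    ``missing_probes`` is the policy for coefficient probes absent from the
    matrix: "drop" drops them with a warning, "error" raises.  Returns
    (values: Series indexed by sample, dropped probe list).
    """
    present = [p for p in coeffs.weights if p in matrix.beta.index]
    dropped = [p for p in coeffs.weights if p not in matrix.beta.index]
    if not present:
        raise ValueError(
            f"estimator {coeffs.name!r}: none of its {len(coeffs.weights)} "
            f"probes are in the matrix; missing e.g. {dropped[:5]}"
        )
    if dropped:
        if missing_probes == "error":
            raise ValueError(
                f"estimator {coeffs.name!r}: missing probes {dropped[:10]}"
            )
        warnings.warn(
            f"estimator {coeffs.name!r}: dropping {len(dropped)} absent probe(s)",
            stacklevel=2,
        )
    w = np.array([coeffs.weights[p] for p in present])
    lin = coeffs.intercept + w @ matrix.beta.loc[present].to_numpy(dtype=float)
    out = _TRANSFORMS[coeffs.transform](lin)
    return pd.Series(out, index=matrix.beta.columns, name=coeffs.name), dropped


def age_acceleration(dnam_age: pd.Series, chron_age: pd.Series,
                     reference_ids: Sequence[str]) -> pd.Series:
    """Age-acceleration residuals: DNAm age regressed on chronological age.

    The regression line is fit by least squares within ``reference_ids``
    (conventionally the random subcohort) and applied to all samples, so
    residuals in the reference set are mean-zero and orthogonal to
    chronological age.
    """
    reference_ids = list(reference_ids)
    if len(reference_ids) < 3:
        raise ValueError("need at least 3 reference samples")
    x = chron_age.loc[reference_ids].to_numpy(dtype=float)
    y = dnam_age.loc[reference_ids].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ages must be finite")
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant in the reference set")
    slope, intercept = np.polyfit(x, y, 1)
    resid = dnam_age - (intercept + slope * chron_age)
    return resid.rename(f"{dnam_age.name or 'dnam_age'}_accel")


def assemble_feature_table(matrix: MethylationMatrix,
                           estimator_sets: Sequence[CoefficientSet],
                           candidate_cpgs: Sequence[str],
                           missing_probes: str = "drop") -> FeatureTable:
    """One column per DNAm estimator and per candidate CpG.

    Candidate-CpG features are the raw beta values; estimator features are
    the linear-combination values.  Missing candidate CpGs follow the
    ``missing_probes`` policy.  Duplicate names across estimators and CpGs
    raise.
    """
    cols = {}
    classes = {}
    dropped_report: Dict[str, List[str]] = {}

    for cs in estimator_sets:
        if cs.name in cols:
            raise ValueError(f"duplicate feature name {cs.name!r}")
        vals, dropped = compute_linear_estimator(matrix, cs, missing_probes)
        cols[cs.name] = vals
        classes[cs.name] = "estimator"
        if dropped:
            dropped_report[cs.name] = dropped

    missing_cpgs = [c for c in candidate_cpgs if c not in matrix.beta.index]
    if missing_cpgs:
        if missing_probes == "error":
            raise ValueError(f"candidate CpGs absent from matrix: {missing_cpgs[:10]}")
        warnings.warn(
            f"dropping {len(missing_cpgs)} absent candidate CpG(s)", stacklevel=2
        )
        dropped_report["candidate_cpgs"] = missing_cpgs
    for c in candidate_cpgs:
        if c in missing_cpgs:
            continue
        if c in cols:
            raise ValueError(f"duplicate feature name {c!r} (estimator vs CpG)")
        cols[c] = matrix.beta.loc[c].astype(float)
        classes[c] = "cpg"

    values = pd.DataFrame(cols, index=matrix.beta.columns)
    return FeatureTable(values=values, feature_class=classes,
                        dropped_probes=dropped_report)


# ---------------------------------------------------------------------------
# coefficient file IO: CSV (probe_id, weight) + JSON sidecar
# ---------------------------------------------------------------------------

def write_coefficient_set(cs: CoefficientSet, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"probe_id": list(cs.weights), "weight": list(cs.weights.values())}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "name": cs.name, "intercept": cs.intercept,
        "transform": cs.transform, "output_units": cs.output_units,
    }, indent=2, sort_keys=True))


def read_coefficient_set(csv_path) -> CoefficientSet:
    csv_path = Path(csv_path)
    tab = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    weights = dict(zip(tab["probe_id"].astype(str), tab["weight"].astype(float)))
    return CoefficientSet(
        name=meta["name"], intercept=float(meta["intercept"]),
        weights=weights, transform=meta.get("transform", "identity"),
        output_units=meta.get("output_units", ""),
    )
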