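"""Sample-level quality control.

A sample is excluded when its mean bisulfite-conversion intensity falls below
the intensity threshold (default 4000 units) or when more than the allowed
fraction of its probes (default 5%) carry low-quality methylation values.
Both inequalities are strict, so boundary samples are retained.

Probe-level low quality means any of: detection P-value above 1e-6, fewer
than 3 beads, or a beta value outside three interquartile ranges of the
probe's across-sample quartiles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .io import MethylationMatrix

__all__ = [
    "QCReport",
    "sample_qc",
    "compute_low_quality_fraction",
    "iqr_outlier_flags",
    "impute_missing",
    "DETECTION_P_THRESHOLD",
    "MIN_BEADS",
    "IQR_MULTIPLIER",
]

DETECTION_P_THRESHOLD = 1e-6
MIN_BEADS = 3
IQR_MULTIPLIER = 3.0


@dataclass
class QCReport:
    """Exclusion report: one row per excluded sample with its reason(s)."""

    exclusions: pd.DataFrame  # columns: sample_id, low_intensity, high_bad_probe
    intensity_threshold: float
    bad_probe_fraction: float

    @property
    def excluded_ids(self) -> List[str]:
        return list(self.exclusions["sample_id"])

    def summary(self) -> str:
        n = len(self.exclusions)
        n_int = int(self.exclusions["low_intensity"].sum()) if n else 0
        n_bad = int(self.exclusions["high_bad_probe"].sum()) if n else 0
        return (f"{n} samples excluded "
                f"({n_int} mean intensity < {self.intensity_threshold:g}, "
                f"{n_bad} low-quality probe fraction > {self.bad_probe_fraction:g})")


def sample_qc(matrix: MethylationMatrix, intensity_threshold: float = 4000.0,
              bad_probe_fraction: float = 0.05):
    """Apply the sample-exclusion rules; returns (passing_ids, QCReport).

    A sample fails iff mean_intensity < intensity_threshold OR
    low_quality_fraction > bad_probe_fraction (strict inequalities).
    """
    qc = matrix.sample_qc.loc[matrix.sample_ids]
    bad_meta = qc[["mean_intensity", "low_quality_fraction"]].isna().any(axis=1)
    if bad_meta.any():
        raise ValueError(
            "QC metadata missing for sample(s): "
            f"{list(qc.index[bad_meta])[:10]}"
        )
    low_int = qc["mean_intensity"] < intensity_threshold
    high_bad = qc["low_quality_fraction"] > bad_probe_fraction
    failed = low_int | high_bad
    exclusions = pd.DataFrame({
        "sample_id": qc.index[failed],
        "low_intensity": low_int[failed].to_numpy(),
        "high_bad_probe": high_bad[failed].to_numpy(),
    }).reset_index(drop=True)
    passing = [s for s in matrix.sample_ids if not failed.loc[s]]
    report = QCReport(exclusions, intensity_threshold, bad_probe_fraction)
    return passing, report


def iqr_outlier_flags(beta: pd.DataFrame, multiplier: float = IQR_MULTIPLIER) -> pd.DataFrame:
    """Flag beta values outside [Q1 - m*IQR, Q3 + m*IQR] per probe.

    Quartiles are computed across samples within the analysis batch, probe by
    probe; NaN betas are never flagged.
    """
    vals = beta.to_numpy(dtype=float)
    q1 = np.nanpercentile(vals, 25, axis=1)
    q3 = np.nanpercentile(vals, 75, axis=1)
    iqr = q3 - q1
    lo = (q1 - multiplier * iqr)[:, None]
    hi = (q3 + multiplier * iqr)[:, None]
    with np.errstate(invalid="ignore"):
        flags = (vals < lo) | (vals > hi)
    flags &= np.isfinite(vals)
    return pd.DataFrame(flags, index=beta.index, columns=beta.columns)


def compute_low_quality_fraction(detection_p, beads, iqr_outlier) -> float:
    """Fraction of one sample's probes failing any probe-quality rule.

    Rules (union): detection P > 1e-6, bead count < 3, IQR outlier flag set.
    """
    detection_p = np.asarray(detection_p, dtype=float)
    beads = np.asarray(beads)
    iqr_outlier = np.asarray(iqr_outlier, dtype=bool)
    if detection_p.size == 0:
        raise ValueError("empty probe set")
    bad = (detection_p > DETECTION_P_THRESHOLD) | (beads < MIN_BEADS) | iqr_outlier
    return float(bad.sum()) / float(bad.size)


def impute_missing(matrix: MethylationMatrix):
    """Mean-impute missing betas per probe; returns (matrix, n_imputed).

    Probes that are missing in every sample stay missing (reported in the
    count as zero; downstream fitting rejects non-finite features).
    """
    beta = matrix.beta.copy()
    vals = beta.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        probe_means = beta.mean(axis=1, skipna=True).to_numpy()
        idx = np.where(np.isnan(vals))
        vals[idx] = probe_means[idx[0]]
        beta = pd.DataFrame(vals, index=beta.index, columns=beta.columns)
    out = MethylationMatrix(beta=beta, sample_qc=matrix.sample_qc.copy())
    return out, n_missing
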