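"""Case-cohort design weights.

Two weighting schemes drive the analysis:

* age-balancing inverse-probability-of-selection weights (IPW) for the
  training set — cases keep weight one and noncases are reweighted within age
  bins so the weighted noncase age distribution matches the cases', removing
  the case/noncase age gap at blood draw;
* Barlow pseudo-likelihood weights for case-cohort Cox validation — subcohort
  person-time is upweighted by the inverse sampling fraction and every case
  enters the risk set just before its event age with weight one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CaseCohortDesign",
    "split_train_test",
    "training_selection_weights",
    "barlow_weights",
    "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 0.001  # years; case risk-interval entry offset


@dataclass
class CaseCohortDesign:
    """Membership and weights of a case-cohort sample.

    ``table`` has one row per sampled woman with columns: sample_id, case,
    subcohort, age_entry, age_exit, event, train_test ('train'/'test'/'none')
    and ipw (training selection weight, NaN until computed).
    ``sampling_fraction`` is the realized subcohort sampling fraction
    (subcohort size / cohort size).
    """

    table: pd.DataFrame
    sampling_fraction: float

    REQUIRED = ("sample_id", "case", "subcohort", "age_entry", "age_exit", "event")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must lie in (0, 1]")
        if "train_test" not in self.table.columns:
            self.table = self.table.assign(train_test="none")
        if "ipw" not in self.table.columns:
            self.table = self.table.assign(ipw=np.nan)
        t = self.table
        if (t["age_exit"] <= t["age_entry"]).any():
            raise ValueError("age_exit must exceed age_entry for every woman")
        ipw = t["ipw"].dropna()
        if (ipw < 0).any():
            raise ValueError("ipw must be nonnegative")

    @property
    def sample_ids(self):
        return list(self.table["sample_id"])

    def subset(self, mask_or_ids) -> "CaseCohortDesign":
        t = self.table
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
                mask_or_ids, "dtype", None) == bool:
            sub = t[mask_or_ids]
        else:
            sub = t[t["sample_id"].isin(set(mask_or_ids))]
        return CaseCohortDesign(sub.reset_index(drop=True).copy(),
                                self.sampling_fraction)


def split_train_test(design: CaseCohortDesign, train_fraction: float = 0.70,
                     seed: int = 0) -> CaseCohortDesign:
    """Random woman-level train/test split, reproducible under ``seed``."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    t = design.table.copy()
    is_train = rng.random(len(t)) < train_fraction
    t["train_test"] = np.where(is_train, "train", "test")
    return CaseCohortDesign(t, design.sampling_fraction)


def training_selection_weights(ages, case, bin_width: float = 1.0,
                               return_bins: bool = False):
    """Age-balancing inverse-probability-of-selection weights.

    Cases receive weight 1.  Noncases in age bin b receive a weight
    proportional to (cases in b)/(noncases in b), rescaled so the total
    noncase weight equals the noncase count; the weighted noncase age
    distribution over bins then matches the case distribution exactly.
    Bins are widened (width doubled) while any case-containing bin lacks
    noncases; with ``return_bins=True`` the per-sample labels of the bins
    actually used are returned alongside the weights.
    """
    ages = np.asarray(ages, dtype=float)
    case = np.asarray(case, dtype=float).astype(bool)
    if not case.any() or case.all():
        raise ValueError("both cases and noncases are required")

    a0 = ages.min()
    width = float(bin_width)
    span = max(ages.max() - a0, 1e-9)
    while True:
        bins = np.floor((ages - a0) / width).astype(int)
        n_bins = bins.max() + 1
        n_case = np.bincount(bins[case], minlength=n_bins)
        n_non = np.bincount(bins[~case], minlength=n_bins)
        if not np.any((n_case > 0) & (n_non == 0)):
            break
        if width > 2 * span:
            raise ValueError(
                "a case-containing age bin has no noncases even after "
                "maximal widening"
            )
        width *= 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_non > 0, n_case / np.maximum(n_non, 1), 0.0)
    w = np.ones(ages.size)
    w[~case] = ratio[bins[~case]]
    # rescale so total noncase weight equals the noncase count
    total = w[~case].sum()
    if total <= 0:
        raise ValueError("no noncase falls in any case-containing bin")
    w[~case] *= (~case).sum() / total
    if return_bins:
        return w, bins
    return w


def barlow_weights(design: CaseCohortDesign, sampling_fraction: Optional[float] = None,
                   eps: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Barlow case-cohort risk intervals in start-stop-weight long format.

    Subcohort noncases contribute (entry, exit] at weight 1/f; subcohort
    cases contribute (entry, event-eps] at weight 1/f plus (event-eps, event]
    at weight 1; cases outside the subcohort contribute only the short
    event interval at weight 1.  With f = 1 the scheme reduces to a standard
    left-truncated full-cohort setup (single unit-weight intervals).

    Returns a DataFrame with columns sample_id, start, stop, event, weight.
    """
    f = design.sampling_fraction if sampling_fraction is None else sampling_fraction
    if not 0 < f <= 1:
        raise ValueError("sampling_fraction must lie in (0, 1]")
    t = design.table
    if ((t["age_exit"] - t["age_entry"]) <= 0).any():
        raise ValueError("zero-length follow-up")

    rows = []
    inv_f = 1.0 / f
    for sid, is_case, sub, a0, a1 in zip(
            t["sample_id"], t["case"].astype(bool), t["subcohort"].astype(bool),
            t["age_entry"].to_numpy(float), t["age_exit"].to_numpy(float)):
        if f == 1.0:
            rows.append((sid, a0, a1, int(is_case), 1.0))
            continue
        if is_case:
            s = max(a1 - eps, a0)
            if sub and s > a0:
                rows.append((sid, a0, s, 0, inv_f))
            rows.append((sid, s, a1, 1, 1.0))
        elif sub:
            rows.append((sid, a0, a1, 0, inv_f))
        # noncases outside the subcohort carry no information in this design
    out = pd.DataFrame(rows, columns=["sample_id", "start", "stop", "event", "weight"])
    return out
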