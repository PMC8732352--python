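"""Synthetic case-cohort methylation studies with known ground truth.

The generator emulates the structure of a prospective women's cohort with a
blood-methylation case-cohort subsample: beta-distributed (logit-normal)
methylation at 450K-style probes, DNAm estimator components built as weighted
sums of dedicated probe panels, a sparse set of hazard-associated probes and
estimators, questionnaire risk factors and a polygenic score, and
age-as-timescale time-to-event with a piecewise-constant baseline hazard that
increases with age (so incident cases are systematically older than noncases
at blood draw).  All covariates are generated independently; real risk
factors are correlated, which this generator deliberately does not model.

Every public operation takes an explicit seed; all randomness flows from a
single ``numpy.random.default_rng`` spawned per operation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import CaseCohortDesign
from .features import CoefficientSet
from .io import MethylationMatrix

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "simulate_cohort",
    "apply_case_cohort_sampling",
    "plant_qc_failures",
    "RISK_FACTOR_COLUMNS",
    "DEFAULT_RF_EFFECTS",
]

RISK_FACTOR_COLUMNS = (
    "bmi", "menopause", "physical_activity", "alcohol", "total_births",
    "age_menarche", "pack_years", "n_biopsies", "n_affected_relatives",
    "education",
)

# log-HR per SD of each (standardized) questionnaire covariate; modest,
# established-risk-factor-sized effects
DEFAULT_RF_EFFECTS: Dict[str, float] = {
    "bmi": 0.08,
    "menopause": 0.05,
    "physical_activity": -0.08,
    "alcohol": 0.08,
    "total_births": -0.05,
    "age_menarche": -0.05,
    "pack_years": 0.05,
    "n_biopsies": 0.12,
    "n_affected_relatives": 0.10,
    "education": 0.0,
}

# piecewise-constant age effect on the baseline hazard (edges in years,
# increasing multipliers -> cases older than noncases at entry)
AGE_HAZARD_EDGES = (0.0, 45.0, 55.0, 65.0, np.inf)
AGE_HAZARD_MULTIPLIERS = (0.55, 0.85, 1.25, 1.70)


@dataclass
class SimulationConfig:
    """Study-design parameters of one synthetic cohort.

    Scales follow a large prospective cohort with ~3% random subcohort,
    enrollment ages 35-74, mean administrative follow-up 5.2 years, and a
    breast cancer incidence near 6.5 per 1000 person-years.
    """

    n_cohort: int = 20_000
    n_probes: int = 600
    n_causal_probes: int = 19
    n_estimators: int = 36
    n_causal_estimators: int = 5
    n_candidate_cpgs: int = 100
    probes_per_estimator: int = 10
    effect_per_sd: float = 0.18  # log-HR per SD of each causal feature (HR ~ 1.2)
    baseline_hazard: float = 0.0065  # events per person-year
    age_range: Tuple[float, float] = (35.0, 74.0)
    admin_followup: float = 5.2  # mean administrative censoring, years
    subcohort_fraction: float = 0.03
    rf_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RF_EFFECTS))
    prs_effect: float = 0.45  # log-HR per SD of the polygenic score
    seed: int = 0

    def __post_init__(self):
        counts = dict(n_cohort=self.n_cohort, n_probes=self.n_probes,
                      n_candidate_cpgs=self.n_candidate_cpgs,
                      probes_per_estimator=self.probes_per_estimator)
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_causal_probes < 0 or self.n_causal_estimators < 0:
            raise ValueError("causal counts must be nonnegative")
        if self.n_causal_probes > min(self.n_probes, self.n_candidate_cpgs):
            raise ValueError("n_causal_probes exceeds the candidate panel")
        if self.n_causal_estimators > self.n_estimators:
            raise ValueError("n_causal_estimators exceeds n_estimators")
        panel_probes = self.n_estimators * self.probes_per_estimator
        if panel_probes + self.n_candidate_cpgs > self.n_probes:
            raise ValueError(
                "n_probes too small for the estimator panels plus the "
                "candidate-CpG panel"
            )
        if not 0 < self.subcohort_fraction <= 1:
            raise ValueError("subcohort_fraction must lie in (0, 1]")
        effects = [self.effect_per_sd, self.prs_effect, *self.rf_effects.values()]
        if not np.all(np.isfinite(effects)):
            raise ValueError("effect sizes must be finite")
        lo, hi = self.age_range
        if not hi > lo:
            raise ValueError("age_range is degenerate")


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort.

    ``true_linear_predictor`` is the total log relative hazard per woman;
    it equals ``causal_feature_values @ true_effects`` (the causal feature
    values are stored standardized, in the column order of
    ``causal_feature_values``).
    """

    causal_probe_ids: List[str]
    causal_estimator_ids: List[str]
    true_effects: pd.Series  # per causal feature, log-HR per SD
    true_linear_predictor: pd.Series  # per woman
    causal_feature_values: pd.DataFrame  # standardized causal features
    estimator_sets: List[CoefficientSet]
    candidate_cpgs: List[str]


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def _simulate_risk_factors(n: int, rng: np.random.Generator) -> pd.DataFrame:
    smoker = rng.random(n) < 0.45
    return pd.DataFrame({
        "bmi": rng.normal(27.5, 5.5, n).clip(15, 60),
        "menopause": (rng.random(n) < 0.65).astype(int),
        "physical_activity": rng.normal(0.0, 1.0, n),
        "alcohol": rng.exponential(3.0, n),
        "total_births": rng.poisson(2.0, n),
        "age_menarche": rng.normal(12.8, 1.5, n),
        "pack_years": np.where(smoker, rng.exponential(15.0, n), 0.0),
        "n_biopsies": rng.poisson(0.3, n),
        "n_affected_relatives": 1 + rng.poisson(0.15, n),
        "education": rng.choice(4, n, p=[0.15, 0.30, 0.35, 0.20]),
    })


def _piecewise_event_times(entry: np.ndarray, hazard_scale: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Event ages from the piecewise-constant age-baseline hazard, conditional
    on being event-free at entry (left truncation by construction)."""
    edges = np.asarray(AGE_HAZARD_EDGES)
    rates = np.asarray(AGE_HAZARD_MULTIPLIERS)
    target = rng.exponential(1.0, entry.size) / hazard_scale  # baseline cum hazard to spend
    t = entry.copy()
    remaining = target.copy()
    event_age = np.full(entry.size, np.inf)
    for b in range(rates.size):
        lo, hi = edges[b], edges[b + 1]
        in_bin = (t < hi) & np.isinf(event_age)
        if not in_bin.any():
            continue
        start = np.maximum(t[in_bin], lo)
        width = hi - start
        spend = rates[b] * width
        done = remaining[in_bin] <= spend
        idx = np.flatnonzero(in_bin)
        hit = idx[done]
        event_age[hit] = start[done] + remaining[hit] / rates[b]
        rest = idx[~done]
        remaining[rest] -= spend[~done]
        t[rest] = hi
    return event_age


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort; returns (MethylationMatrix, phenotypes, CohortTruth).

    The phenotype table has one row per woman: sample_id, age_entry,
    age_exit, event, subtype, er_status, subcohort (filled by the 3% random
    subcohort draw), prs and the questionnaire risk-factor columns.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cohort
    sample_ids = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    probe_ids = np.array([f"cg{i:08d}" for i in range(1, cfg.n_probes + 1)])

    # --- probe layout: estimator panels first, then the candidate panel ----
    pps = cfg.probes_per_estimator
    panel_slices = [slice(e * pps, (e + 1) * pps) for e in range(cfg.n_estimators)]
    cand_start = cfg.n_estimators * pps
    candidate_idx = np.arange(cand_start, cand_start + cfg.n_candidate_cpgs)
    causal_probe_idx = candidate_idx[: cfg.n_causal_probes]

    # --- methylation: logit-normal around per-probe means ------------------
    mu = logit(rng.uniform(0.1, 0.9, cfg.n_probes))
    sigma = rng.uniform(0.25, 0.75, cfg.n_probes)
    logits = mu[:, None] + sigma[:, None] * rng.standard_normal((cfg.n_probes, n))

    # shared latent risk factor correlates the causal probes
    u = rng.standard_normal(n)
    gamma = (rng.choice([-1.0, 1.0], cfg.n_causal_probes)
             * rng.uniform(0.15, 0.35, cfg.n_causal_probes))
    logits[causal_probe_idx] += gamma[:, None] * u[None, :]

    # estimator panels load on a latent per-woman component
    s_lat = rng.standard_normal((cfg.n_estimators, n))
    loadings = []
    for e, sl in enumerate(panel_slices):
        lam = (rng.choice([-1.0, 1.0], pps) * rng.uniform(0.4, 0.8, pps))
        logits[sl] += lam[:, None] * s_lat[e][None, :]
        loadings.append(lam)

    beta = expit(logits)
    matrix = MethylationMatrix(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        sample_qc=pd.DataFrame({
            "mean_intensity": np.maximum(rng.normal(9000, 1500, n), 4500.0),
            "low_quality_fraction": rng.uniform(0.0, 0.04, n),
        }, index=sample_ids),
    )

    # --- estimator coefficient sets (sign-matched to the panel loadings) ---
    estimator_sets = []
    for e, sl in enumerate(panel_slices):
        w = np.sign(loadings[e]) * rng.uniform(2.0, 6.0, pps)
        estimator_sets.append(CoefficientSet(
            name=f"estimator_{e + 1:02d}",
            intercept=float(rng.uniform(10.0, 60.0)),
            weights=dict(zip(probe_ids[sl], w)),
            transform="identity",
            output_units="synthetic",
        ))

    # --- causal features and the methylation linear predictor --------------
    causal_probe_ids = list(probe_ids[causal_probe_idx])
    causal_estimator_ids = [estimator_sets[e].name
                            for e in range(cfg.n_causal_estimators)]
    feat_cols = {}
    for pid, row in zip(causal_probe_ids, beta[causal_probe_idx]):
        feat_cols[pid] = _zscore(row)
    for e in range(cfg.n_causal_estimators):
        cs = estimator_sets[e]
        w = np.array([cs.weights[p] for p in probe_ids[panel_slices[e]]])
        vals = cs.intercept + w @ beta[panel_slices[e]]
        feat_cols[cs.name] = _zscore(vals)

    rf = _simulate_risk_factors(n, rng)
    prs = rng.standard_normal(n)
    for name in RISK_FACTOR_COLUMNS:
        eff = cfg.rf_effects.get(name, 0.0)
        if eff != 0.0:
            feat_cols[f"rf:{name}"] = _zscore(rf[name].to_numpy(float))
    if cfg.prs_effect != 0.0:
        feat_cols["prs"] = _zscore(prs)

    effects = {}
    for pid in causal_probe_ids:
        effects[pid] = cfg.effect_per_sd
    for name in causal_estimator_ids:
        effects[name] = cfg.effect_per_sd
    for name in RISK_FACTOR_COLUMNS:
        eff = cfg.rf_effects.get(name, 0.0)
        if eff != 0.0:
            effects[f"rf:{name}"] = eff
    if cfg.prs_effect != 0.0:
        effects["prs"] = cfg.prs_effect

    feature_values = pd.DataFrame(feat_cols, index=sample_ids)
    true_effects = pd.Series(effects).reindex(feature_values.columns)
    lp = feature_values.to_numpy(float) @ true_effects.to_numpy(float) \
        if len(effects) else np.zeros(n)

    # --- survival on the age timescale --------------------------------------
    lo, hi = cfg.age_range
    age_entry = rng.uniform(lo, hi, n)
    hazard_scale = cfg.baseline_hazard * np.exp(lp)
    event_age = _piecewise_event_times(age_entry, hazard_scale, rng)
    censor_age = age_entry + cfg.admin_followup * rng.uniform(0.5, 1.5, n)
    age_exit = np.minimum(event_age, censor_age)
    event = (event_age <= censor_age).astype(int)

    subtype = np.where(event == 1,
                       np.where(rng.random(n) < 0.77, "invasive", "DCIS"),
                       "none")
    er = np.where((subtype == "invasive") & (rng.random(n) < 0.80), "positive",
                  np.where(subtype == "invasive", "negative", "unknown"))

    phenotypes = pd.DataFrame({
        "sample_id": sample_ids,
        "age_entry": age_entry,
        "age_exit": age_exit,
        "event": event,
        "subtype": subtype,
        "er_status": er,
        "subcohort": 0,
        "prs": prs,
        **{c: rf[c] for c in RISK_FACTOR_COLUMNS},
    })

    # random subcohort drawn from the full cohort at baseline
    design = apply_case_cohort_sampling(
        phenotypes, cfg.subcohort_fraction,
        seed=int(rng.integers(0, 2**31 - 1)))
    in_sub = phenotypes["sample_id"].isin(
        design.table.loc[design.table["subcohort"] == 1, "sample_id"])
    phenotypes["subcohort"] = in_sub.astype(int)

    truth = CohortTruth(
        causal_probe_ids=causal_probe_ids,
        causal_estimator_ids=causal_estimator_ids,
        true_effects=true_effects,
        true_linear_predictor=pd.Series(lp, index=sample_ids),
        causal_feature_values=feature_values,
        estimator_sets=estimator_sets,
        candidate_cpgs=list(probe_ids[candidate_idx]),
    )
    return matrix, phenotypes, truth


def apply_case_cohort_sampling(phenotypes: pd.DataFrame, fraction: float,
                               seed: int) -> CaseCohortDesign:
    """All cases plus a random subcohort of expected size fraction*n_cohort.

    Subcohort members who become cases are flagged as both.  Reproducible
    under ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(phenotypes) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    in_sub = rng.random(len(phenotypes)) < fraction if fraction < 1 else \
        np.ones(len(phenotypes), dtype=bool)
    case = phenotypes["event"].to_numpy().astype(bool)
    sampled = in_sub | case
    t = phenotypes.loc[sampled, ["sample_id", "age_entry", "age_exit", "event"]].copy()
    t["case"] = phenotypes.loc[sampled, "event"].astype(int).to_numpy()
    t["subcohort"] = in_sub[sampled].astype(int)
    realized = in_sub.sum() / len(phenotypes)
    if fraction == 1:
        realized = 1.0
    elif realized == 0:
        realized = fraction  # tiny cohorts can draw an empty subcohort
    return CaseCohortDesign(
        t[["sample_id", "case", "subcohort", "age_entry", "age_exit", "event"]]
        .reset_index(drop=True),
        sampling_fraction=float(realized),
    )


def plant_qc_failures(matrix: MethylationMatrix, n_low_intensity: int,
                      n_high_badprobe: int, seed: int) -> MethylationMatrix:
    """Return a copy in which exactly the requested numbers of samples fail
    the two QC rules (disjoint sets); every other sample passes both."""
    n = matrix.n_samples
    if n_low_intensity + n_high_badprobe > n:
        raise ValueError("planted failure counts exceed the sample count")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_low_intensity + n_high_badprobe, replace=False)
    low = chosen[:n_low_intensity]
    bad = chosen[n_low_intensity:]

    qc = matrix.sample_qc.copy()
    intensity = np.maximum(qc["mean_intensity"].to_numpy(float), 4000.0)
    frac = np.minimum(qc["low_quality_fraction"].to_numpy(float), 0.05)
    intensity[low] = rng.uniform(1000.0, 3999.0, n_low_intensity)
    frac[bad] = rng.uniform(0.051, 0.20, n_high_badprobe)
    qc["mean_intensity"] = intensity
    qc["low_quality_fraction"] = frac
    return MethylationMatrix(beta=matrix.beta.copy(), sample_qc=qc)
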