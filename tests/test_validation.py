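"""Validation statistics against brute-force oracles and design reductions."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mbcrs.design import CaseCohortDesign
from mbcrs.validation import (apply_latency_exclusion, auc, casecohort_cox,
                              correlation_report, delong_test,
                              effect_modification, heterogeneity_test,
                              logistic_validation, opera, sequential_auc,
                              standardized_residuals, tertile_association)

from oracles import (auc_all_pairs, cox_newton_brute, logistic_irls,
                     pearson_r_formula, residualize_normal_equations)


def _full_cohort_design(n=300, seed=0, beta=0.5):
    """A fraction-1 design with one predictive covariate; returns
    (design, covariate series)."""
    rng = np.random.default_rng(seed)
    entry = rng.uniform(35, 70, n)
    x = rng.normal(size=n)
    T = rng.exponential(1 / (0.08 * np.exp(beta * x)))
    C = rng.uniform(1, 8, n)
    exit_ = entry + np.minimum(T, C)
    event = (T <= C).astype(int)
    ids = [f"S{i}" for i in range(n)]
    t = pd.DataFrame({
        "sample_id": ids, "case": event, "subcohort": 1,
        "age_entry": entry, "age_exit": exit_, "event": event,
    })
    return (CaseCohortDesign(t, sampling_fraction=1.0),
            pd.Series(x, index=ids, name="x"))


class TestStandardizedResiduals:
    def test_constant_covariates_reduce_to_zscore(self):
        rng = np.random.default_rng(1)
        ids = [f"S{i}" for i in range(50)]
        s = pd.Series(rng.normal(10, 2, 50), index=ids, name="s")
        Z = pd.DataFrame({"c": np.ones(50)}, index=ids)
        # constant covariate is collinear with the intercept
        with pytest.raises(ValueError, match="collinear"):
            standardized_residuals(s, Z, ids[:30])

    def test_reference_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        ids = [f"S{i}" for i in range(80)]
        Z = pd.DataFrame(rng.normal(size=(80, 3)), index=ids,
                         columns=list("abc"))
        s = pd.Series(Z["a"] * 0.5 + rng.normal(size=80), index=ids, name="s")
        ref = ids[:40]
        out = standardized_residuals(s, Z, ref)
        r = out.residual_standardized.loc[ref]
        assert abs(r.mean()) < 1e-8
        assert r.std(ddof=1) == pytest.approx(1.0, abs=1e-8)
        # residuals orthogonal to each adjustment covariate in the reference
        for c in "abc":
            assert abs(np.corrcoef(r, Z.loc[ref, c])[0, 1]) < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        ids = [f"S{i}" for i in range(60)]
        Z = pd.DataFrame(rng.normal(size=(60, 2)), index=ids,
                         columns=["u", "v"])
        s = pd.Series(rng.normal(size=60), index=ids, name="s")
        ref_mask = np.zeros(60, bool)
        ref_mask[:35] = True
        out = standardized_residuals(s, Z, list(np.array(ids)[ref_mask]))
        oracle = residualize_normal_equations(s.to_numpy(), Z.to_numpy(),
                                              ref_mask)
        assert np.abs(out.residual_standardized.to_numpy() - oracle).max() < 1e-10

    def test_exactly_linear_score_is_degenerate(self):
        ids = [f"S{i}" for i in range(30)]
        Z = pd.DataFrame({"a": np.arange(30.0)}, index=ids)
        s = pd.Series(2.0 * Z["a"] + 1, index=ids, name="s")
        with pytest.raises(ValueError, match="degenerate"):
            standardized_residuals(s, Z, ids)


class TestCaseCohortCox:
    def test_fraction_one_equals_full_cohort_cox(self):
        design, x = _full_cohort_design(seed=4)
        got = casecohort_cox(x.to_frame(), design)["x"]
        from lifelines import CoxPHFitter
        df = pd.DataFrame({
            "x": x.to_numpy(),
            "entry": design.table["age_entry"].to_numpy(),
            "stop": design.table["age_exit"].to_numpy(),
            "event": design.table["event"].to_numpy(),
        })
        cph = CoxPHFitter().fit(df, duration_col="stop", event_col="event",
                                entry_col="entry")
        assert np.log(got.estimate) == pytest.approx(cph.params_["x"], abs=1e-6)

    def test_fraction_one_matches_newton_oracle(self):
        design, x = _full_cohort_design(n=120, seed=5)
        got = casecohort_cox(x.to_frame(), design)["x"]
        t = design.table
        oracle = cox_newton_brute(
            x.to_numpy()[:, None], t["age_entry"].to_numpy(),
            t["age_exit"].to_numpy(), t["event"].to_numpy().astype(bool),
            np.ones(len(t)))
        assert np.log(got.estimate) == pytest.approx(oracle[0], abs=1e-4)

    def test_latency_exclusion_drops_short_followup(self):
        design, _ = _full_cohort_design(seed=6)
        out = apply_latency_exclusion(design, 2.0)
        fu = design.table["age_exit"] - design.table["age_entry"]
        assert len(out.table) == (fu > 2.0).sum()
        kept = design.table.loc[fu > 2.0, "sample_id"].tolist()
        assert out.table["sample_id"].tolist() == kept
        assert np.allclose(
            out.table["age_entry"].to_numpy(),
            design.table.set_index("sample_id").loc[kept, "age_entry"] + 2.0)

    def test_ci_contains_estimate_and_p_matches_z(self):
        design, x = _full_cohort_design(seed=7)
        r = casecohort_cox(x.to_frame(), design)["x"]
        assert r.ci_low <= r.estimate <= r.ci_high
        from scipy import stats
        assert r.p == pytest.approx(2 * stats.norm.sf(abs(r.z)), rel=1e-12)


class TestTertiles:
    def test_cutpoints_are_reference_quantiles(self):
        design, x = _full_cohort_design(seed=8, beta=0.8)
        res = tertile_association(x, design)
        t = design.table
        ref = x.loc[t.loc[(t["subcohort"] == 1) & (t["case"] == 0),
                          "sample_id"]]
        expect = np.quantile(ref.to_numpy(), [1 / 3, 2 / 3])
        assert res.cutpoints == pytest.approx(tuple(expect), abs=1e-12)

    def test_monotone_gradient_with_strong_score(self):
        design, x = _full_cohort_design(n=600, seed=9, beta=0.8)
        res = tertile_association(x, design)
        assert res.associations["T3"].estimate > res.associations["T2"].estimate > 1
        assert res.trend_p < 0.01


class TestLogisticAndOpera:
    def test_logistic_matches_irls_oracle(self):
        rng = np.random.default_rng(10)
        n = 200
        s = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)],
                      name="s")
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-0.8 * s))).astype(int),
                      index=s.index)
        got = logistic_validation(s, y)
        X = np.column_stack([np.ones(n), s.to_numpy()])
        coef, cov = logistic_irls(X, y.to_numpy())
        assert np.log(got.estimate) == pytest.approx(coef[1], abs=1e-8)
        se = np.sqrt(cov[1, 1])
        assert got.z == pytest.approx(coef[1] / se, abs=1e-6)

    def test_separation_reported(self):
        ids = [f"S{i}" for i in range(20)]
        s = pd.Series(np.arange(20.0), index=ids, name="s")
        y = pd.Series((np.arange(20) >= 10).astype(int), index=ids)
        with pytest.raises(ValueError):
            logistic_validation(s, y)

    def test_opera_identity_with_logistic_coefficient(self):
        rng = np.random.default_rng(11)
        n = 300
        ids = [f"S{i}" for i in range(n)]
        z = pd.Series(rng.normal(size=n), index=ids, name="z")
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-(0.6 * z)))).astype(int),
                      index=ids)
        got = opera(z.to_frame(), y)
        X = np.column_stack([np.ones(n), z.to_numpy()])
        coef, _ = logistic_irls(X, y.to_numpy())
        assert got.estimates["z"].estimate == pytest.approx(np.exp(coef[1]),
                                                            rel=1e-7)
        assert got.lr_chi2 >= 0 and got.df == 1

    def test_opera_lr_chi2_nesting(self):
        rng = np.random.default_rng(12)
        n = 400
        ids = [f"S{i}" for i in range(n)]
        P = pd.DataFrame(rng.normal(size=(n, 3)), index=ids,
                         columns=["a", "b", "c"])
        lp = 0.5 * P["a"] + 0.4 * P["b"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int),
                      index=ids)
        full = opera(P, y).lr_chi2
        for pair in (["a", "b"], ["a", "c"], ["b", "c"]):
            assert full >= opera(P[pair], y).lr_chi2 - 1e-8


class TestAuc:
    def test_perfect_separation_is_one(self):
        ids = [f"S{i}" for i in range(10)]
        s = pd.Series(np.arange(10.0), index=ids)
        y = pd.Series([0] * 5 + [1] * 5, index=ids)
        assert auc(s, y).auc == 1.0

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(13)
        n = 80
        ids = [f"S{i}" for i in range(n)]
        s = pd.Series(rng.integers(0, 10, n).astype(float), index=ids)
        y = pd.Series(rng.integers(0, 2, n), index=ids)
        got = auc(s, y)
        assert got.auc == pytest.approx(auc_all_pairs(s, y), abs=1e-12)
        assert got.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert 0 <= got.ci_low <= got.auc <= got.ci_high <= 1

    def test_one_class_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            auc(pd.Series([1.0, 2, 3], index=ids),
                pd.Series([1, 1, 1], index=ids))

    def test_delong_symmetry(self):
        rng = np.random.default_rng(14)
        n = 150
        ids = [f"S{i}" for i in range(n)]
        s1 = pd.Series(rng.normal(size=n), index=ids)
        s2 = pd.Series(rng.normal(size=n), index=ids)
        y = pd.Series(rng.integers(0, 2, n), index=ids)
        a1, a2, z, p = delong_test(s1, s2, y)
        b2, b1, z2, p2 = delong_test(s2, s1, y)
        assert (a1, a2) == (b1, b2)
        assert z == pytest.approx(-z2) and p == pytest.approx(p2)


class TestSequentialAuc:
    def _data(self, n=400, seed=15, score_beta=0.6):
        rng = np.random.default_rng(seed)
        ids = [f"S{i}" for i in range(n)]
        rf = pd.DataFrame(rng.normal(size=(n, 3)), index=ids,
                          columns=["r1", "r2", "r3"])
        prs = pd.Series(rng.normal(size=n), index=ids, name="prs")
        score = pd.Series(rng.normal(size=n), index=ids, name="score")
        lp = 0.4 * rf["r1"] + 0.5 * prs + score_beta * score
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int),
                      index=ids)
        return rf, prs, score, y

    def test_first_rung_consistent_with_auc(self):
        rf, prs, score, y = self._data()
        ladder = sequential_auc(rf, prs, score, y)
        import statsmodels.api as sm
        res = sm.Logit(y.to_numpy(),
                       sm.add_constant(rf.to_numpy())).fit(disp=0)
        direct = auc(pd.Series(res.predict(), index=rf.index), y)
        assert ladder[0].auc == pytest.approx(direct.auc, abs=1e-12)
        assert ladder[1].p_diff_vs == "RFs"
        assert ladder[2].p_diff is not None

    def test_informative_score_raises_auc(self):
        rf, prs, score, y = self._data(seed=16)
        ladder = sequential_auc(rf, prs, score, y)
        assert ladder[2].auc > ladder[1].auc > ladder[0].auc

    def test_misaligned_inputs_rejected(self):
        rf, prs, score, y = self._data()
        with pytest.raises(ValueError, match="aligned"):
            sequential_auc(rf.iloc[:-5], prs, score, y)


class TestHeterogeneityAndModification:
    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(17)
        n = 200
        ids = [f"S{i}" for i in range(n)]
        s = pd.Series(rng.normal(size=n), index=ids, name="s")
        subtype = pd.Series(np.where(rng.random(n) < 1 / (1 + np.exp(-0.5 * s)),
                                     "invasive", "DCIS"), index=ids)
        p1, c1 = heterogeneity_test(s, subtype)
        swapped = subtype.map({"invasive": "DCIS", "DCIS": "invasive"})
        p2, c2 = heterogeneity_test(s, swapped)
        assert p1 == pytest.approx(p2, rel=1e-6)
        assert list(c1.values())[0] == pytest.approx(-list(c2.values())[0],
                                                     rel=1e-6)

    def test_single_subtype_rejected(self):
        ids = ["a", "b", "c", "d"]
        s = pd.Series([0.1, 0.4, -0.2, 0.3], index=ids)
        with pytest.raises(ValueError):
            heterogeneity_test(s, pd.Series(["invasive"] * 4, index=ids))

    def test_identical_strata_give_equal_estimates(self):
        design, x = _full_cohort_design(n=250, seed=18, beta=0.6)
        # duplicate every woman into a second stratum
        t = design.table.copy()
        t2 = t.copy()
        t2["sample_id"] = t2["sample_id"] + "_dup"
        both = CaseCohortDesign(pd.concat([t, t2], ignore_index=True),
                                sampling_fraction=1.0)
        x2 = pd.concat([x, x.rename(lambda s: s + "_dup")])
        x2.name = "x"
        stratum = pd.Series(["A"] * len(t) + ["B"] * len(t),
                            index=x2.index)
        per, p_int = effect_modification(x2, both, stratum)
        assert np.log(per["A"].estimate) == pytest.approx(
            np.log(per["B"].estimate), abs=1e-8)
        assert 0 <= p_int <= 1


class TestCorrelationReport:
    def test_self_correlation_is_one_and_formula_oracle(self):
        rng = np.random.default_rng(19)
        n = 60
        ids = [f"S{i}" for i in range(n)]
        s = pd.Series(rng.normal(size=n), index=ids, name="s")
        comp = pd.DataFrame({"self": s, "other": rng.normal(size=n)},
                            index=ids)
        out = correlation_report(s, comp, ids).set_index("variable")
        assert out.loc["self", "r"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["other", "r"] == pytest.approx(
            pearson_r_formula(s, comp["other"]), abs=1e-12)

    def test_zero_variance_rejected(self):
        ids = ["a", "b", "c", "d"]
        s = pd.Series([1.0, 2, 3, 4], index=ids, name="s")
        comp = pd.DataFrame({"flat": [2.0, 2, 2, 2]}, index=ids)
        with pytest.raises(ValueError, match="variance"):
            correlation_report(s, comp, ids)
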