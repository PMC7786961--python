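import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from fctopo.similarity import SimilarityResult
from fctopo.stats import ari_anova, nodal_group_glm, residual_correlation


def make_metrics(values, subjects, node=0, metric="degree"):
    return pd.DataFrame({
        "subject_id": subjects, "node_id": node, "metric": metric, "value": values,
    })


def make_cohort(groups, rng, education=None):
    n = len(groups)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "age": rng.normal(65, 5, n),
        "gender": rng.choice(["F", "M"], n),
        "education": rng.normal(14, 2, n) if education is None else education,
        "scanner": rng.choice(["A", "B"], n),
        "frames_retained": rng.integers(150, 240, n).astype(float),
    })


class TestNodalGroupGLM:
    def test_covariate_free_balanced_matches_t_test(self, rng):
        groups = ["HC"] * 10 + ["AD"] * 10
        vals = rng.normal(size=20)
        vals[10:] += 1.0
        cohort = make_cohort(groups, rng)
        res = nodal_group_glm(make_metrics(vals, cohort["subject_id"]), cohort,
                              covariates=())
        row = res[res.contrast == "AD-HC"].iloc[0]
        t, p = sps.ttest_ind(vals[10:], vals[:10])
        assert row.t == pytest.approx(t)
        assert row.p_uncorrected == pytest.approx(p)

    def test_coefficients_match_normal_equations(self, rng):
        # tiny 6-row dataset, closed-form OLS oracle
        groups = ["HC", "HC", "HC", "AD", "AD", "AD"]
        edu = np.array([10.0, 12.0, 14.0, 11.0, 15.0, 13.0])
        vals = np.array([1.0, 2.0, 1.5, 3.0, 4.0, 3.5])
        cohort = make_cohort(groups, rng, education=edu)
        res = nodal_group_glm(make_metrics(vals, cohort["subject_id"]), cohort,
                              covariates=("education",))
        X = np.column_stack([np.ones(6), edu, [0, 0, 0, 1, 1, 1]])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        row = res[res.contrast == "AD-HC"].iloc[0]
        assert row.estimate == pytest.approx(beta[2], abs=1e-8)

    def test_three_group_contrasts_all_reported(self, rng):
        groups = ["HC"] * 5 + ["AD"] * 5 + ["bvFTD"] * 5
        cohort = make_cohort(groups, rng)
        res = nodal_group_glm(make_metrics(rng.normal(size=15),
                                           cohort["subject_id"]), cohort)
        assert set(res.contrast) == {"AD-HC", "bvFTD-HC", "AD-bvFTD"}

    def test_ad_vs_bvftd_matches_rereferenced_model(self, rng):
        groups = ["HC"] * 8 + ["AD"] * 8 + ["bvFTD"] * 8
        vals = rng.normal(size=24)
        cohort = make_cohort(groups, rng)
        m = make_metrics(vals, cohort["subject_id"])
        res_hc = nodal_group_glm(m, cohort, covariates=("education",))
        res_ad = nodal_group_glm(m, cohort, covariates=("education",),
                                 reference_group="AD")
        a = res_hc[res_hc.contrast == "AD-bvFTD"].iloc[0]
        b = res_ad[res_ad.contrast == "bvFTD-AD"].iloc[0]
        assert a.estimate == pytest.approx(-b.estimate)
        assert a.p_uncorrected == pytest.approx(b.p_uncorrected)

    def test_type_one_error_calibrated(self, rng):
        # null simulation: no group effect; nominal .05 within [0.03, 0.07]
        n_rep, n_per, hits, total = 200, 15, 0, 0
        for _ in range(n_rep):
            groups = ["HC"] * n_per + ["AD"] * n_per
            cohort = make_cohort(groups, rng)
            vals = rng.normal(size=2 * n_per)
            res = nodal_group_glm(make_metrics(vals, cohort["subject_id"]), cohort)
            hits += int((res.p_uncorrected <= 0.05).sum())
            total += len(res)
        assert 0.03 <= hits / total <= 0.07

    def test_planted_effect_sign_recovered(self, rng):
        # 1-SD within-module-degree reduction in AD, n=20/group
        correct = 0
        for _ in range(100):
            groups = ["HC"] * 20 + ["AD"] * 20
            cohort = make_cohort(groups, rng)
            vals = rng.normal(size=40)
            vals[20:] -= 1.0
            res = nodal_group_glm(
                make_metrics(vals, cohort["subject_id"], metric="within_module_z"),
                cohort)
            correct += int(res.iloc[0].estimate < 0)
        assert correct >= 80

    def test_rank_deficient_design_rejected(self, rng):
        groups = ["HC"] * 6 + ["AD"] * 6
        cohort = make_cohort(groups, rng)
        cohort["education"] = 12.0
        cohort["frames_retained"] = 200.0
        cohort["dup"] = cohort["education"]
        with pytest.raises(ValueError, match="rank"):
            nodal_group_glm(make_metrics(rng.normal(size=12), cohort["subject_id"]),
                            cohort, covariates=("education", "dup"))

    def test_gm_volume_covariate_is_node_matched(self, rng):
        groups = ["HC"] * 10 + ["AD"] * 10
        cohort = make_cohort(groups, rng)
        m = pd.concat([
            make_metrics(rng.normal(size=20), cohort["subject_id"], node=k)
            for k in range(3)
        ])
        gm = pd.DataFrame(rng.normal(5, 0.5, size=(20, 3)),
                          index=cohort["subject_id"], columns=range(3))
        res = nodal_group_glm(m, cohort, covariates=(), gm_volume=gm)
        assert len(res) == 3  # one AD-HC contrast per node


class TestAriAnova:
    def make_results(self, means, scope="whole_brain", n=20, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        return [SimilarityResult(group=g, scope=scope,
                                 ari_values=rng.normal(mu, sd, n))
                for g, mu in means.items()]

    def test_f_matches_hand_computed_mean_squares(self):
        groups = {"HC": np.array([0.8, 0.9, 0.85]),
                  "AD": np.array([0.5, 0.6, 0.55]),
                  "bvFTD": np.array([0.3, 0.4, 0.2])}
        results = [SimilarityResult(group=g, scope="whole_brain", ari_values=v)
                   for g, v in groups.items()]
        out = ari_anova(results)
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert out.F.iloc[0] == pytest.approx(f_hand)

    def test_shifted_group_flagged_after_bonferroni(self):
        out = ari_anova(self.make_results({"HC": 0.9, "AD": 0.9, "bvFTD": 0.3}))
        flagged = out[out.bonferroni_significant]
        assert set(flagged.contrast) == {"HC-bvFTD", "AD-bvFTD"}

    def test_bonferroni_family_is_pair_count(self):
        out = ari_anova(self.make_results({"HC": 0.8, "AD": 0.5, "bvFTD": 0.3}))
        row = out.iloc[0]
        assert row.p_bonferroni == pytest.approx(min(1.0, row.p * 3))

    def test_null_rejection_rate_nominal(self, rng):
        hits, total = 0, 0
        for rep in range(200):
            results = [
                SimilarityResult(group=g, scope="whole_brain",
                                 ari_values=rng.normal(0.7, 0.1, 20))
                for g in ("HC", "AD", "bvFTD")
            ]
            out = ari_anova(results)
            hits += int(out.p_anova.iloc[0] <= 0.05)
            total += 1
        assert 0.02 <= hits / total <= 0.08

    def test_degenerate_zero_variance_rejected(self):
        results = [SimilarityResult(group=g, scope="whole_brain",
                                    ari_values=np.full(5, 0.5))
                   for g in ("HC", "AD")]
        with pytest.raises(ValueError, match="variance"):
            ari_anova(results)


class TestResidualCorrelation:
    def test_exact_linear_relation_gives_r_one(self, rng):
        cohort = make_cohort(["HC"] * 20, rng)
        metric = rng.normal(size=20)
        score = 2.0 * metric + 1.0
        r, p = residual_correlation(metric, score, cohort)
        assert r == pytest.approx(1.0)

    def test_matches_partial_correlation_identity(self, rng):
        # oracle: partial correlation from the full correlation matrix
        n = 200
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = -z + rng.normal(size=n)
        cohort = pd.DataFrame({"z": z})
        r, _ = residual_correlation(x, y, cohort, covariates=("z",))
        R = np.corrcoef([x, y, z])
        expected = (R[0, 1] - R[0, 2] * R[1, 2]) / np.sqrt(
            (1 - R[0, 2] ** 2) * (1 - R[1, 2] ** 2))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_null_mean_r_near_zero(self, rng):
        cohort = make_cohort(["HC"] * 30, rng)
        rs = []
        hits = 0
        for _ in range(500):
            m = rng.normal(size=30)
            s = rng.normal(size=30)
            r, p = residual_correlation(m, s, cohort)
            rs.append(r)
            hits += int(p <= 0.05)
        assert abs(np.mean(rs)) < 0.02
        assert 0.02 <= hits / 500 <= 0.09

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        cohort = make_cohort(["HC"] * 25, rng)
        m, s = rng.normal(size=25), rng.normal(size=25)
        r1, p1 = residual_correlation(m, s, cohort, covariates=("age", "education"))
        cohort2 = cohort.copy()
        cohort2["age"] = 10 * cohort2["age"] - 3
        cohort2["education"] = 0.1 * cohort2["education"] + 100
        r2, p2 = residual_correlation(m, s, cohort2, covariates=("age", "education"))
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_constant_residuals_rejected(self, rng):
        cohort = make_cohort(["HC"] * 15, rng)
        with pytest.raises(ValueError, match="constant"):
            residual_correlation(np.full(15, 2.0), rng.normal(size=15), cohort)


def test_glm_pvalues_uniform_under_null(rng):
    # Kolmogorov-Smirnov on pooled null p-values
    ps = []
    for _ in range(500):
        groups = ["HC"] * 12 + ["AD"] * 12
        cohort = make_cohort(groups, rng)
        res = nodal_group_glm(make_metrics(rng.normal(size=24),
                                           cohort["subject_id"]), cohort)
        ps.append(res.p_uncorrected.iloc[0])
    assert sps.kstest(ps, "uniform").pvalue > 0.01
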