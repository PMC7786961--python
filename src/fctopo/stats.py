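"""Group statistics: covariate-adjusted nodal GLMs, ANOVA with post hoc
t-tests on ARI distributions, and residualized brain-behavior correlations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .similarity import SimilarityResult

DEFAULT_GLM_COVARIATES = ("education", "scanner", "frames_retained")
DEFAULT_CORR_COVARIATES = ("age", "gender", "education", "scanner")
_CATEGORICAL = {"scanner", "gender", "group"}


def _design(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Covariate design matrix with intercept; categoricals dummy-coded."""
    cols = [pd.Series(1.0, index=cohort.index, name="const")]
    for c in covariates:
        if c not in cohort.columns:
            raise ValueError(f"covariate {c!r} not in cohort table")
        if c in _CATEGORICAL or cohort[c].dtype == object:
            d = pd.get_dummies(cohort[c], prefix=c, drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(cohort[c].astype(float))
    X = pd.concat(cols, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {list(X.columns)}")
    return X


def nodal_group_glm(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_GLM_COVARIATES,
    extra_covariates: tuple[str, ...] = (),
    reference_group: str = "HC",
    gm_volume: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-node, per-metric OLS of the metric on group plus covariates.

    ``metrics`` is long format (subject_id, node_id, metric, value). Group
    enters as indicator contrasts against ``reference_group``; every
    pairwise group contrast is reported with a two-sided t-test
    (non-reference pairs via linear contrasts on the same fit). When a
    per-subject x node ``gm_volume`` table is supplied as an extra
    covariate it is matched to each node.

    Returns one row per node x metric x contrast with estimate, se, t,
    p_uncorrected, an FDR (Benjamini-Hochberg) column per metric x
    contrast family, and a significance flag at p <= .05 uncorrected.
    """
    cohort = cohort.set_index("subject_id", drop=False) if "subject_id" in cohort else cohort
    groups = [g for g in pd.unique(cohort["group"])]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a contrast")
    others = [g for g in groups if g != reference_group]
    contrasts = [(g, reference_group) for g in others] + list(combinations(others, 2))

    rows = []
    for (metric, node), sub in metrics.groupby(["metric", "node_id"], sort=True):
        sub = sub.set_index("subject_id")
        coh = cohort.loc[sub.index]
        X = _design(coh, tuple(covariates) + tuple(extra_covariates))
        gdum = pd.get_dummies(coh["group"], prefix="group", dtype=float)
        gdum = gdum.drop(columns=f"group_{reference_group}")
        X = pd.concat([X, gdum], axis=1)
        if gm_volume is not None:
            X["gm_volume"] = gm_volume.loc[sub.index, node].astype(float)
        res = sm.OLS(sub["value"].astype(float), X).fit()
        for ga, gb in contrasts:
            vec = pd.Series(0.0, index=X.columns)
            if f"group_{ga}" in vec.index:
                vec[f"group_{ga}"] = 1.0
            if f"group_{gb}" in vec.index:
                vec[f"group_{gb}"] = -1.0
            t_res = res.t_test(vec.to_numpy())
            rows.append({
                "node_id": node, "metric": metric,
                "contrast": f"{ga}-{gb}",
                "estimate": float(np.squeeze(t_res.effect)),
                "se": float(np.squeeze(t_res.sd)),
                "t": float(np.squeeze(t_res.tvalue)),
                "p_uncorrected": float(np.squeeze(t_res.pvalue)),
            })
    out = pd.DataFrame(rows)
    out["significant"] = out["p_uncorrected"] <= 0.05
    out["p_fdr"] = (
        out.groupby(["metric", "contrast"])["p_uncorrected"]
        .transform(lambda p: sps.false_discovery_control(p, method="bh"))
    )
    return out


def ari_anova(
    results: list[SimilarityResult], alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA across groups per scope, with post hoc t-tests.

    All pairwise two-tailed two-sample t-tests follow the ANOVA; the
    Bonferroni family is the number of pairwise contrasts within a scope.
    Returns one row per scope x contrast carrying the scope's F and ANOVA
    p alongside the pairwise t, p, and Bonferroni flag.
    """
    by_scope: dict[str, dict[str, np.ndarray]] = {}
    for r in results:
        by_scope.setdefault(r.scope, {})[r.group] = r.ari_values
    rows = []
    for scope, groups in by_scope.items():
        names = list(groups)
        if len(names) < 2 or any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"scope {scope!r}: need >= 2 groups with >= 2 values each")
        if all(np.var(v) == 0 for v in groups.values()):
            raise ValueError(f"scope {scope!r}: zero within-group variance in all groups")
        F, p_anova = sps.f_oneway(*groups.values())
        pairs = list(combinations(names, 2))
        for ga, gb in pairs:
            t, p = sps.ttest_ind(groups[ga], groups[gb])
            rows.append({
                "scope": scope, "F": float(F), "p_anova": float(p_anova),
                "contrast": f"{ga}-{gb}", "t": float(t), "p": float(p),
                "p_bonferroni": float(min(1.0, p * len(pairs))),
                "bonferroni_significant": p * len(pairs) < alpha,
            })
    return pd.DataFrame(rows)


def residual_correlation(
    metric_values: pd.Series | np.ndarray,
    scores: pd.Series | np.ndarray,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_CORR_COVARIATES,
) -> tuple[float, float]:
    """Pearson correlation after residualizing both variables on covariates.

    Both the nodal metric and the behavior score are regressed on the
    covariate design (least squares); the correlation and two-sided p are
    computed on the residuals.
    """
    y1 = np.asarray(metric_values, dtype=float)
    y2 = np.asarray(scores, dtype=float)
    X = _design(cohort.reset_index(drop=True), tuple(covariates)).to_numpy()
    if len(y1) < X.shape[1] + 3:
        raise ValueError("too few subjects for the covariate design")
    beta1, *_ = np.linalg.lstsq(X, y1, rcond=None)
    beta2, *_ = np.linalg.lstsq(X, y2, rcond=None)
    r1 = y1 - X @ beta1
    r2 = y2 - X @ beta2
    if np.allclose(r1.std(), 0) or np.allclose(r2.std(), 0):
        raise ValueError("constant residuals: correlation undefined")
    r, p = sps.pearsonr(r1, r2)
    return float(r), float(p)
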