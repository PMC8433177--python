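"""Ordinal scoring, composite ranking, lasso signatures, set arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from fibroscope.signature import (
    cluster_gene_patterns,
    composite_score,
    cross_validate_lambda,
    fit_lasso_signature,
    fit_ordinal_per_gene,
    gene_level_score,
    gene_set_overlap,
    load_progression_clusters,
    load_signature_gene_sets,
    score_and_validate,
    transform_expression,
    _lasso_path,
)
from fibroscope.syndata import STAGES


def stage_series(stages, index=None):
    index = index if index is not None else [f"s{i}" for i in range(len(stages))]
    return pd.Series(
        pd.Categorical(stages, categories=list(STAGES), ordered=True), index=index
    )


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------


def test_transform_arithmetic_and_cpm_invariance():
    counts = pd.DataFrame(
        {"s1": [999.0, 1e6 - 999.0], "s2": [0.0, 1000.0]}, index=["g1", "g2"]
    )
    t = transform_expression(counts)
    assert t.loc["g1", "s1"] == pytest.approx(np.log2(1000.0), abs=1e-9)
    assert t.loc["g1", "s2"] == 0.0
    doubled = transform_expression(counts * 2.0)
    pd.testing.assert_frame_equal(t, doubled)
    with pytest.raises(ValueError, match="zero total"):
        transform_expression(pd.DataFrame({"s1": [0.0]}, index=["g1"]))


# ---------------------------------------------------------------------------
# proportional-odds models
# ---------------------------------------------------------------------------


def test_zero_slope_thresholds_equal_cumulative_logits():
    """Expression patterns repeated identically in every stage force the MLE
    slope to zero, where the cutpoints have a closed form."""
    stages = [s for s in STAGES for _ in range(3)]
    x = np.tile([-1.0, 0.0, 1.0], 6)  # same multiset within each stage
    expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(18)])
    fits = fit_ordinal_per_gene(expr, stage_series(stages))
    assert fits.converged.all()
    assert fits.params.loc["g", "beta"] == pytest.approx(0.0, abs=1e-6)
    cum = np.arange(1, 6) * 3 / 18  # P(Y <= k) empirically
    expected = np.log(cum / (1 - cum))
    assert fits.thresholds.loc["g"].to_numpy() == pytest.approx(expected, abs=1e-6)


def test_two_level_case_matches_logistic_regression():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    n = 80
    x = rng.normal(size=n)
    p = expit(0.8 * x - 0.3)
    y = (rng.random(n) < p).astype(int)
    stages = np.where(y == 0, "F0", "F4")
    expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(n)])
    fits = fit_ordinal_per_gene(expr, stage_series(stages))
    sm_fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, tol=1e-12)
    # P(Y=1) = expit(beta x - theta1): slope beta, intercept -theta1
    assert fits.params.loc["g", "beta"] == pytest.approx(sm_fit.params[1], abs=1e-6)
    assert -fits.thresholds.loc["g", "theta_1"] == pytest.approx(sm_fit.params[0], abs=1e-6)


def test_ordinal_loglik_matches_statsmodels_ordered_model(small_study):
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    vst = transform_expression(small_study.bulk_counts)
    gene = vst.var(axis=1).idxmax()
    stages = small_study.metadata["stage"]
    fits = fit_ordinal_per_gene(vst.loc[[gene]], stages)
    om = OrderedModel(stages.cat.codes.to_numpy(), vst.loc[gene].to_numpy()[:, None], distr="logit")
    om_fit = om.fit(method="bfgs", disp=0)
    assert fits.params.loc[gene, "loglik"] == pytest.approx(om_fit.llf, abs=1e-4)
    assert fits.params.loc[gene, "beta"] == pytest.approx(om_fit.params[0], abs=1e-3)


def test_monotone_expression_gives_positive_slope_and_concordance():
    rng = np.random.default_rng(9)
    stages = [s for s in STAGES for _ in range(8)]
    x = np.repeat([0.0, 1.0, 2.0, 3.0, 4.0, 5.0], 8) + rng.normal(0, 1.0, 48)
    expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(48)])
    fits = fit_ordinal_per_gene(expr, stage_series(stages))
    assert fits.converged.loc["g"]
    assert fits.params.loc["g", "beta"] > 0
    scores = gene_level_score(fits, expr)
    # expected-stage score is a monotone function of expression when beta > 0
    order = np.argsort(x)
    assert (np.diff(scores.loc["g"].to_numpy()[order]) >= 0).all()


def test_perfect_separation_is_flagged_not_fatal():
    stages = ["F0"] * 6 + ["F4"] * 6
    x = np.array([0.0] * 6 + [10.0] * 6) + np.arange(12) * 1e-3
    expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(12)])
    fits = fit_ordinal_per_gene(expr, stage_series(stages))
    assert not fits.converged.loc["g"]


def test_gene_level_score_closed_cases():
    # all mass on one level, a symmetric binary case, uniform over 6 levels
    stages = stage_series([s for s in STAGES for _ in range(2)])
    expr = pd.DataFrame(
        np.zeros((1, 12)), index=["g"], columns=stages.index
    )
    fits = fit_ordinal_per_gene(expr, stages)
    scores = gene_level_score(fits, expr)
    # constant gene at zero slope: masses are the empirical stage frequencies
    assert scores.loc["g"].to_numpy() == pytest.approx(np.full(12, 2.5), abs=1e-8)
    assert ((scores.to_numpy() >= 0) & (scores.to_numpy() <= 5)).all()


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------


def test_composite_cv_arithmetic_and_ranking():
    scores = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 2.0],
            "s2": [2.0, 2.0, 2.0],
            "s3": [3.0, 2.0, 2.0],
        },
        index=["varying", "flat", "flat2"],
    )
    comp = composite_score(scores, top_n=1)
    assert comp.cv["varying"] == pytest.approx(0.5)  # sd 1 (ddof=1) over |mean| 2
    assert comp.cv["flat"] == 0.0
    assert comp.ranked_genes == ["varying"]
    assert comp.per_sample.to_numpy() == pytest.approx([1.0, 2.0, 3.0])


def test_composite_gene_order_invariance_and_tie_break():
    rng = np.random.default_rng(5)
    scores = pd.DataFrame(
        rng.uniform(0.5, 4.5, size=(20, 10)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"s{i}" for i in range(10)],
    )
    a = composite_score(scores, top_n=5)
    b = composite_score(scores.iloc[::-1], top_n=5)
    pd.testing.assert_series_equal(a.per_sample, b.per_sample)
    assert a.ranked_genes == b.ranked_genes


# ---------------------------------------------------------------------------
# lasso
# ---------------------------------------------------------------------------


def test_lasso_limits_and_soft_threshold(rng):
    n, p = 40, 6
    X = rng.normal(size=(n, p))
    y = X @ np.array([1.0, -2.0, 0.0, 0.5, 0.0, 0.0]) + 0.1 * rng.normal(size=n)
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(p)], columns=[f"s{i}" for i in range(n)])
    comp = pd.Series(y, index=expr.columns)

    sig = fit_lasso_signature(expr, comp, folds=5, lambda_rule="min_mse", seed=0)
    assert 1 <= len(sig.genes) <= p
    # lambda -> infinity: empty model, intercept = mean response
    Xs = (X - X.mean(0)) / X.std(0)
    coefs, intercepts = _lasso_path(Xs, y, np.array([1e9]))
    assert np.all(coefs[0] == 0)
    assert intercepts[0] == pytest.approx(y.mean())
    # lambda = 0 on a full-rank problem equals OLS (normal equations oracle)
    coefs0, icepts0 = _lasso_path(Xs, y, np.array([0.0]))
    Xa = np.hstack([np.ones((n, 1)), Xs])
    ols = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
    assert icepts0[0] == pytest.approx(ols[0], abs=1e-8)
    assert coefs0[0] == pytest.approx(ols[1:], abs=1e-8)
    # univariate closed form: soft threshold of cov at lambda
    x1 = Xs[:, [0]]
    lam = 0.3
    c, _ = _lasso_path(x1, y, np.array([lam]), tol=1e-12)
    cov = float(x1[:, 0] @ (y - y.mean())) / n
    # column has unit variance: beta = soft(cov, lam)
    expected = np.sign(cov) * max(abs(cov) - lam, 0.0)
    assert c[0, 0] == pytest.approx(expected, abs=1e-8)


def test_lasso_path_support_monotone_in_lambda(rng):
    n, p = 50, 20
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:5] = rng.normal(size=5) * 2
    y = X @ beta + 0.2 * rng.normal(size=n)
    Xs = (X - X.mean(0)) / X.std(0)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    lambdas = np.logspace(np.log10(lam_max * 1.01), np.log10(lam_max) - 3, 30)
    coefs, _ = _lasso_path(Xs, y, lambdas)
    nnz = (coefs != 0).sum(axis=1)
    assert nnz[0] == 0
    assert (np.diff(nnz) >= 0).all()  # grid descends in lambda


def test_lasso_target_size_rule_and_warning(rng):
    n, p = 60, 30
    X = rng.normal(size=(n, p))
    y = X @ np.concatenate([rng.normal(size=10) * 2, np.zeros(p - 10)]) + 0.1 * rng.normal(size=n)
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(p)], columns=[f"s{i}" for i in range(n)])
    comp = pd.Series(y, index=expr.columns)
    sig = fit_lasso_signature(expr, comp, folds=5, lambda_rule="target_size:5", seed=0)
    assert len(sig.genes) in (4, 5, 6)  # nearest achievable size
    cv = cross_validate_lambda(expr, comp, sig.lambda_, folds=5, seed=1)
    assert cv["mean_mse"] >= 0


def test_scoring_reproduces_training_fit_and_ignores_zero_weight_genes(rng):
    n, p = 30, 8
    X = rng.normal(size=(n, p))
    y = X[:, 0] * 2.0 + 0.05 * rng.normal(size=n)
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(p)], columns=[f"s{i}" for i in range(n)])
    comp = pd.Series(y, index=expr.columns)
    sig = fit_lasso_signature(expr, comp, folds=5, lambda_rule="min_mse", seed=0)
    out = score_and_validate(sig, expr, composite=comp)
    # training scores equal the lasso fitted values by definition
    Xs = (expr.T[sig.genes] - sig.feature_means) / sig.feature_sds
    fitted = sig.intercept + Xs @ sig.weights
    assert out["scores"].to_numpy() == pytest.approx(fitted.to_numpy(), abs=1e-10)
    # perturbing a zero-weight gene leaves the scores unchanged
    zero_gene = next(g for g in expr.index if g not in sig.genes)
    expr2 = expr.copy()
    expr2.loc[zero_gene] += 100.0
    out2 = score_and_validate(sig, expr2, composite=comp)
    assert out2["scores"].to_numpy() == pytest.approx(out["scores"].to_numpy())


def test_scoring_missing_genes_warns_and_errors():
    sig_genes = [f"g{i}" for i in range(4)]
    from fibroscope.signature import LassoSignature

    sig = LassoSignature(
        lambda_=0.1,
        genes=sig_genes,
        weights=pd.Series(1.0, index=sig_genes),
        intercept=0.0,
        cv_mse=pd.DataFrame(),
        feature_means=pd.Series(0.0, index=sig_genes),
        feature_sds=pd.Series(1.0, index=sig_genes),
        seed=0,
    )
    expr = pd.DataFrame(np.ones((3, 2)), index=["g0", "g1", "g2"], columns=["s1", "s2"])
    with pytest.warns(UserWarning, match="missing"):
        out = score_and_validate(sig, expr)
    assert out["n_genes_used"] == 3
    with pytest.raises(ValueError, match="present"):
        score_and_validate(sig, expr.iloc[:1], min_present=0.9)


# ---------------------------------------------------------------------------
# trend clustering and set arithmetic
# ---------------------------------------------------------------------------


def test_cluster_gene_patterns_recovers_archetypes(rng):
    stages = stage_series([s for s in STAGES for _ in range(4)])
    up = np.repeat(np.linspace(-1, 1, 6), 4)
    genes, rows = [], []
    for i in range(100):
        genes.append(f"up{i}")
        rows.append(up * rng.uniform(0.5, 2.0) + rng.normal(0, 0.1, 24))
    for i in range(100):
        genes.append(f"dn{i}")
        rows.append(-up * rng.uniform(0.5, 2.0) + rng.normal(0, 0.1, 24))
    expr = pd.DataFrame(rows, index=genes, columns=stages.index)
    out = cluster_gene_patterns(expr, stages, genes, n_clusters=2, min_cluster=50)
    truth = [0] * 100 + [1] * 100
    assert adjusted_rand_score(truth, out["labels"].to_numpy()) == 1.0
    assert len(out["reported_clusters"]) == 2


def test_cluster_report_excludes_small_clusters(rng):
    stages = stage_series([s for s in STAGES for _ in range(2)])
    up = np.repeat(np.linspace(-1, 1, 6), 2)
    rows = [up + rng.normal(0, 0.05, 12) for _ in range(50)]
    rows += [-up + rng.normal(0, 0.05, 12) for _ in range(60)]
    genes = [f"g{i}" for i in range(110)]
    expr = pd.DataFrame(rows, index=genes, columns=stages.index)
    out = cluster_gene_patterns(expr, stages, genes, n_clusters=2, min_cluster=50)
    # the 50-gene cluster is excluded (strictly more than 50 required)
    assert out["reported_clusters"] == [
        int(out["sizes"].idxmax())
    ]


def test_zscore_rows_are_standardized(rng, small_study):
    vst = transform_expression(small_study.bulk_counts)
    genes = list(vst.index[:30])
    out = cluster_gene_patterns(vst, small_study.metadata["stage"], genes, n_clusters=3, min_cluster=5)
    assert set(out["labels"].index) == set(genes)


def test_gene_set_overlap_published_lists():
    sets = load_signature_gene_sets()
    rep = gene_set_overlap(sets)
    assert rep["pairwise"].loc["signature26", "signature98"] == 23
    assert rep["pairwise"].loc["signature26", "signature26"] == 26
    assert rep["pairwise"].loc["signature98", "signature98"] == 98
    same = gene_set_overlap({"a": sets["signature26"], "b": sets["signature26"]})
    assert len(same["intersection_all"]) == same["union_size"] == 26
    disjoint = gene_set_overlap({"a": ["X1"], "b": ["X2"]})
    assert disjoint["intersection_all"] == []
    clusters = load_progression_clusters()
    assert len(clusters) == 17
    assert sorted(clusters.unique()) == [2, 3, 5]
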