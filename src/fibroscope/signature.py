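"""Fibrosis gene signatures from ordinal models and lasso regression.

Pipeline: per-gene proportional-odds (ordinal logistic) models of fibrosis
stage on variance-stabilized expression -> per-gene, per-sample expected
stage scores -> genes ranked by coefficient of variation of their scores ->
composite sample score (mean of the top-n genes) -> lasso regression of the
composite score on expression, with k-fold cross-validated penalty selection,
yielding sparse gene signatures that can score new cohorts.

The proportional-odds fitter is implemented here (stable log-likelihood with
analytic gradient) because the pipeline fits one model per gene across
thousands of genes; statsmodels' OrderedModel is the natural cross-check at
small scale.

Also houses gene-pattern trend clustering, gene-set overlap arithmetic, and
the packaged published signature gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from sklearn.linear_model import lasso_path as sk_lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "OrdinalFitSet",
    "CompositeScore",
    "LassoSignature",
    "transform_expression",
    "fit_ordinal_per_gene",
    "gene_level_score",
    "composite_score",
    "fit_lasso_signature",
    "cross_validate_lambda",
    "score_and_validate",
    "cluster_gene_patterns",
    "gene_set_overlap",
    "load_signature_gene_sets",
    "load_progression_clusters",
]


# ---------------------------------------------------------------------------
# expression transform
# ---------------------------------------------------------------------------


def transform_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing stand-in: log2(CPM + 1) per sample.

    Deterministic and monotone; invariant to scaling a sample's library size.
    A user-supplied variance-stabilized matrix can be passed downstream
    instead wherever this output is accepted.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    cpm = counts.div(totals, axis=1) * 1e6
    return np.log2(cpm + 1.0)


# ---------------------------------------------------------------------------
# per-gene proportional-odds models
# ---------------------------------------------------------------------------


@dataclass
class OrdinalFitSet:
    """Per-gene proportional-odds fits P(Y <= k | x) = sigmoid(theta_k - beta x)."""

    params: pd.DataFrame  # per gene: beta, loglik, converged
    thresholds: pd.DataFrame  # genes x (K-1) increasing cutpoints
    levels: list  # ordered stage levels present, coded 0..K-1

    @property
    def converged(self) -> pd.Series:
        return self.params["converged"]


def _ordinal_nll_grad(z: np.ndarray, x: np.ndarray, y: np.ndarray, K: int):
    """Negative log-likelihood and gradient, cutpoints parameterized as
    (theta_1, log-increments) to keep them strictly increasing."""
    th = np.empty(K - 1)
    th[0] = z[0]
    if K > 2:
        th[1:] = z[0] + np.cumsum(np.exp(z[1 : K - 1]))
    beta = z[K - 1]
    a = th[None, :] - beta * x[:, None]  # n x (K-1)

    n = x.shape[0]
    ll = np.empty(n)
    g_up = np.zeros(n)  # d ll / d a_{y}
    g_lo = np.zeros(n)  # d ll / d a_{y-1}

    lo_mask = y == 0
    hi_mask = y == K - 1
    mid_mask = ~(lo_mask | hi_mask)

    if lo_mask.any():
        a_up = a[lo_mask, 0]
        ll[lo_mask] = log_expit(a_up)
        g_up[lo_mask] = expit(-a_up)
    if hi_mask.any():
        a_lo = a[hi_mask, K - 2]
        ll[hi_mask] = log_expit(-a_lo)
        g_lo[hi_mask] = -expit(a_lo)
    if mid_mask.any():
        ym = y[mid_mask]
        a_up = a[mid_mask, ym]
        a_lo = a[mid_mask, ym - 1]
        # sigma(b) - sigma(a) = sigma(b) sigma(-a) (1 - e^{a-b}), b > a
        diff = -np.expm1(a_lo - a_up)
        diff = np.maximum(diff, 1e-300)
        ll[mid_mask] = log_expit(a_up) + log_expit(-a_lo) + np.log(diff)
        P = expit(a_up) - expit(a_lo)
        P = np.maximum(P, 1e-300)
        g_up[mid_mask] = expit(a_up) * expit(-a_up) / P
        g_lo[mid_mask] = -expit(a_lo) * expit(-a_lo) / P

    grad_th = np.zeros(K - 1)
    np.add.at(grad_th, np.minimum(y, K - 2), np.where(hi_mask, 0.0, g_up))
    np.add.at(grad_th, np.maximum(y - 1, 0), np.where(lo_mask, 0.0, g_lo))
    grad = np.empty(K)
    grad[0] = grad_th.sum()
    if K > 2:
        # u_j scales every cutpoint from index j upward
        tail = np.cumsum(grad_th[::-1])[::-1]
        grad[1 : K - 1] = np.exp(z[1 : K - 1]) * tail[1:]
    grad[K - 1] = -np.sum(x * (g_up + g_lo))
    return -ll.sum(), -grad


def _closed_form_thresholds(y: np.ndarray, K: int) -> np.ndarray:
    """Zero-slope MLE: cutpoints are the empirical cumulative logits."""
    cum = np.cumsum(np.bincount(y, minlength=K))[: K - 1] / len(y)
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    return np.log(cum / (1 - cum))


def fit_ordinal_per_gene(
    expr: pd.DataFrame,
    stages: pd.Series,
    tol: float = 1e-8,
    max_beta: float = 30.0,
) -> OrdinalFitSet:
    """Fit one proportional-odds model per gene (rows of ``expr``).

    ``stages`` is an ordered categorical aligned with the sample columns;
    levels actually present are coded 0..K-1. Expression is standardized
    internally for numerical stability and estimates mapped back. Genes whose
    fit fails or drifts into separation (|standardized slope| > ``max_beta``)
    are flagged non-converged and excluded downstream; constant genes get the
    zero-slope closed form. Non-coding genes are not treated specially --
    every row of the matrix is fit.
    """
    stages = stages.reindex(expr.columns)
    if stages.isna().any():
        raise ValueError("stages missing for some samples")
    cat = stages.astype("category")
    if hasattr(stages, "cat"):
        present = [lv for lv in stages.cat.categories if (stages == lv).any()]
    else:
        present = list(cat.cat.categories)
    y = pd.Categorical(stages.astype(str), categories=[str(l) for l in present], ordered=True).codes
    y = np.asarray(y, dtype=int)
    K = len(present)
    if K < 2:
        raise ValueError("need at least 2 stage levels")
    counts = np.bincount(y, minlength=K)
    if (counts < 2).any():
        raise ValueError("each stage level present needs at least 2 samples")

    th0 = _closed_form_thresholds(y, K)
    z0 = np.empty(K)
    z0[0] = th0[0]
    if K > 2:
        z0[1 : K - 1] = np.log(np.maximum(np.diff(th0), 1e-6))
    z0[K - 1] = 0.0

    genes = expr.index
    betas = np.zeros(len(genes))
    logliks = np.empty(len(genes))
    conv = np.zeros(len(genes), dtype=bool)
    thresholds = np.empty((len(genes), K - 1))
    Xmat = expr.to_numpy(dtype=float)

    for gi in range(len(genes)):
        x = Xmat[gi]
        mx, sx = x.mean(), x.std()
        if sx == 0:
            thresholds[gi] = th0
            logliks[gi] = -_ordinal_nll_grad(z0, np.zeros_like(x), y, K)[0]
            conv[gi] = True
            continue
        xs = (x - mx) / sx
        res = minimize(
            _ordinal_nll_grad,
            z0,
            args=(xs, y, K),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": tol * 1e-5, "gtol": tol * 10},
        )
        z = res.x
        th = np.empty(K - 1)
        th[0] = z[0]
        if K > 2:
            th[1:] = z[0] + np.cumsum(np.exp(z[1 : K - 1]))
        beta_std = z[K - 1]
        betas[gi] = beta_std / sx
        thresholds[gi] = th + beta_std * mx / sx
        logliks[gi] = -res.fun
        # a (near-)zero maximized log-likelihood means every observation is
        # predicted with probability ~1: perfect separation, slope unbounded
        separated = abs(beta_std) > max_beta or -res.fun > -1e-3
        conv[gi] = bool(res.success) and np.isfinite(res.fun) and not separated

    params = pd.DataFrame(
        {"beta": betas, "loglik": logliks, "converged": conv}, index=genes
    )
    thr = pd.DataFrame(
        thresholds, index=genes, columns=[f"theta_{k + 1}" for k in range(K - 1)]
    )
    return OrdinalFitSet(params=params, thresholds=thr, levels=[str(l) for l in present])


def gene_level_score(fits: OrdinalFitSet, expr: pd.DataFrame) -> pd.DataFrame:
    """Expected stage level per gene and sample under the fitted models.

    score_gs = sum_k k * P(Y = k | x_gs) with levels coded 0..K-1, so scores
    live in [0, K-1]. Only converged genes are scored.
    """
    genes = fits.params.index[fits.converged]
    genes = genes.intersection(expr.index)
    K = len(fits.levels)
    X = expr.loc[genes].to_numpy(dtype=float)  # G x n
    beta = fits.params.loc[genes, "beta"].to_numpy()[:, None]
    th = fits.thresholds.loc[genes].to_numpy()  # G x (K-1)
    # cumulative P(Y <= k), then masses by differencing
    cum = expit(th[:, None, :] - beta[:, :, None] * X[:, :, None])  # G x n x (K-1)
    ones = np.ones((*cum.shape[:2], 1))
    masses = np.diff(np.concatenate([np.zeros_like(ones), cum, ones], axis=2), axis=2)
    scores = np.einsum("gnk,k->gn", masses, np.arange(K, dtype=float))
    return pd.DataFrame(scores, index=genes, columns=expr.columns)


# ---------------------------------------------------------------------------
# composite score and lasso signatures
# ---------------------------------------------------------------------------


@dataclass
class CompositeScore:
    per_sample: pd.Series
    ranked_genes: list  # the genes actually averaged, highest cv first
    cv: pd.Series  # coefficient of variation per scored gene
    tau_vs_stage: float | None = None


def composite_score(
    scores: pd.DataFrame,
    top_n: int = 1000,
    stages: pd.Series | None = None,
) -> CompositeScore:
    """Mean of the top-``top_n`` genes ranked by coefficient of variation.

    cv = sd / |mean| of the gene-level scores across samples (genes with
    |mean| below 1e-8 are excluded); ties in cv break lexicographically by
    gene identifier so the ranking is deterministic. The composite is
    invariant to the row order of ``scores``.
    """
    if scores.empty:
        raise ValueError("no scored genes")
    mean = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    keep = mean.abs() >= 1e-8
    cv = (sd[keep] / mean[keep].abs()).rename("cv")
    order = pd.DataFrame(
        {"cv": cv.to_numpy(), "_gene": cv.index.astype(str)}, index=cv.index
    ).sort_values(["cv", "_gene"], ascending=[False, True])
    top = order.index[: min(top_n, len(order))]
    composite = scores.loc[top].mean(axis=0).rename("composite_score")
    tau = None
    if stages is not None:
        tau = float(
            stats.kendalltau(composite.to_numpy(), stages.reindex(composite.index).cat.codes)[0]
        )
    return CompositeScore(per_sample=composite, ranked_genes=list(top), cv=cv, tau_vs_stage=tau)


@dataclass
class LassoSignature:
    lambda_: float
    genes: list
    weights: pd.Series  # nonzero coefficients, on standardized-expression scale
    intercept: float
    cv_mse: pd.DataFrame  # lambda grid -> mean and se of CV mse
    feature_means: pd.Series  # training standardization of the signature genes
    feature_sds: pd.Series
    seed: int


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd


def _lasso_path(
    Xs: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 10_000,
):
    """Coefficients over a descending lambda grid (warm-started coordinate descent).

    Objective per lambda: (1/2n)||y - Xw - b||^2 + lambda ||w||_1. Predictors
    are assumed column-centered, so the intercept is the response mean;
    lambda == 0 falls back to least squares.
    """
    n, p = Xs.shape
    yc = y - y.mean()
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.full(len(lambdas), float(y.mean()))
    pos = lambdas > 0
    if pos.any():
        order = np.argsort(-lambdas[pos])  # solver expects a descending grid
        alphas = lambdas[pos][order]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, cf, _ = sk_lasso_path(Xs, yc, alphas=alphas, tol=tol, max_iter=max_iter)
        sorted_coefs = cf.T  # n_alphas x p, aligned with `alphas`
        back = np.empty_like(sorted_coefs)
        back[order] = sorted_coefs
        coefs[pos] = back
    if (~pos).any():
        Xa = np.hstack([np.ones((n, 1)), Xs])
        sol = np.linalg.lstsq(Xa, y, rcond=None)[0]
        coefs[~pos] = sol[1:]
        intercepts[~pos] = sol[0]
    return coefs, intercepts


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambda: int, decades: float) -> np.ndarray:
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def fit_lasso_signature(
    expr: pd.DataFrame,
    composite: pd.Series,
    folds: int = 10,
    lambda_rule: str = "min_mse",
    seed: int = 0,
    n_lambda: int = 100,
    lambda_decades: float = 4.0,
) -> LassoSignature:
    """Sparse gene signature: lasso of the composite score on expression.

    Predictors (genes) are standardized; the penalty grid spans ``n_lambda``
    log-spaced values from the smallest all-zeroing lambda down
    ``lambda_decades`` decades. ``lambda_rule`` picks the working penalty:

    * ``"min_mse"`` -- minimizer of the k-fold cross-validated MSE,
    * ``"one_se"`` -- largest lambda within one standard error of that minimum,
    * ``"target_size:k"`` -- lambda whose full-data fit keeps k genes (the
      nearest achievable size is used, with a warning, if k is not on the path).
    """
    if expr.shape[1] < folds:
        raise ValueError("need at least as many samples as folds")
    y = composite.reindex(expr.columns).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("composite score missing for some samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    Xs, mu, sd = _standardize(X)
    lambdas = _lambda_grid(Xs, y, n_lambda, lambda_decades)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((folds, len(lambdas)))
    for fi, (tr, te) in enumerate(kf.split(Xs)):
        Xtr, mu_tr, sd_tr = _standardize(X[tr])
        sd_safe = np.where(sd_tr > 0, sd_tr, 1.0)
        Xte = (X[te] - mu_tr) / sd_safe
        coefs, intercepts = _lasso_path(Xtr, y[tr], lambdas)
        pred = Xte @ coefs.T + intercepts[None, :]
        fold_mse[fi] = ((pred - y[te, None]) ** 2).mean(axis=0)
    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)

    coefs, intercepts = _lasso_path(Xs, y, lambdas)
    nnz = (coefs != 0).sum(axis=1)

    if lambda_rule == "min_mse":
        pick = int(np.argmin(mean_mse))
    elif lambda_rule == "one_se":
        imin = int(np.argmin(mean_mse))
        ok = np.flatnonzero(mean_mse <= mean_mse[imin] + se_mse[imin])
        pick = int(ok[0])  # grid is descending in lambda: first hit = largest lambda
    elif lambda_rule.startswith("target_size:"):
        k = int(lambda_rule.split(":", 1)[1])
        gap = np.abs(nnz - k)
        pick = int(np.argmin(gap))  # ties resolve to the larger lambda
        if nnz[pick] != k:
            warnings.warn(
                f"no lambda on the grid yields exactly {k} genes; "
                f"returning the nearest size {nnz[pick]}",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    w = coefs[pick]
    sel = np.flatnonzero(w)
    genes = list(expr.index[sel])
    return LassoSignature(
        lambda_=float(lambdas[pick]),
        genes=genes,
        weights=pd.Series(w[sel], index=genes, name="weight"),
        intercept=float(intercepts[pick]),
        cv_mse=pd.DataFrame({"lambda": lambdas, "mean_mse": mean_mse, "se_mse": se_mse, "n_genes": nnz}),
        feature_means=pd.Series(mu[sel], index=genes),
        feature_sds=pd.Series(sd[sel], index=genes),
        seed=seed,
    )


def cross_validate_lambda(
    expr: pd.DataFrame,
    composite: pd.Series,
    lambda_: float,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Re-validate one penalty value with a fresh k-fold split (mean/se MSE)."""
    y = composite.reindex(expr.columns).to_numpy(dtype=float)
    X = expr.to_numpy(dtype=float).T
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mses = []
    for tr, te in kf.split(X):
        Xtr, mu_tr, sd_tr = _standardize(X[tr])
        sd_safe = np.where(sd_tr > 0, sd_tr, 1.0)
        Xte = (X[te] - mu_tr) / sd_safe
        coefs, intercepts = _lasso_path(Xtr, y[tr], np.array([lambda_]))
        pred = Xte @ coefs[0] + intercepts[0]
        mses.append(float(((pred - y[te]) ** 2).mean()))
    mses = np.asarray(mses)
    return {"mean_mse": float(mses.mean()), "se_mse": float(mses.std(ddof=1) / np.sqrt(folds)), "fold_mse": mses}


def score_and_validate(
    signature: LassoSignature,
    expr: pd.DataFrame,
    stages: pd.Series | None = None,
    composite: pd.Series | None = None,
    min_present: float = 0.5,
) -> dict:
    """Score samples with a fitted signature and report rank agreement.

    score = intercept + sum_g w_g * (x_g - mean_g) / sd_g with the training
    standardization. Signature genes absent from ``expr`` contribute zero
    (with a warning); below ``min_present`` coverage an error is raised.
    """
    present = [g for g in signature.genes if g in expr.index]
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    if len(present) < min_present * len(signature.genes):
        raise ValueError(
            f"only {len(present)}/{len(signature.genes)} signature genes present"
        )
    if len(present) < len(signature.genes):
        warnings.warn(
            f"{len(signature.genes) - len(present)} signature genes missing; treated as zero",
            stacklevel=2,
        )
    X = expr.loc[present].to_numpy(dtype=float).T
    sd = signature.feature_sds[present].to_numpy()
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - signature.feature_means[present].to_numpy()) / sd_safe
    scores = pd.Series(
        signature.intercept + Xs @ signature.weights[present].to_numpy(),
        index=expr.columns,
        name="signature_score",
    )
    out: dict = {"scores": scores, "n_genes_used": len(present)}
    if stages is not None:
        codes = stages.reindex(expr.columns).cat.codes
        out["tau_vs_stage"] = float(stats.kendalltau(scores, codes)[0])
    if composite is not None:
        out["tau_vs_composite"] = float(
            stats.kendalltau(scores, composite.reindex(expr.columns))[0]
        )
    return out


# ---------------------------------------------------------------------------
# gene-pattern trend clustering and set arithmetic
# ---------------------------------------------------------------------------


def cluster_gene_patterns(
    expr: pd.DataFrame,
    stages: pd.Series,
    de_genes: Sequence[str],
    n_clusters: int = 6,
    min_cluster: int = 50,
) -> dict:
    """Cluster differential genes by their stage-trajectory shape.

    Each gene is z-scored across samples, reduced to its per-stage mean
    trajectory, and the trajectories are hierarchically clustered
    (correlation distance, average linkage; tree cut to ``n_clusters``).
    Clusters with ``min_cluster`` genes or fewer are dropped from the report
    (strictly more than ``min_cluster`` genes are required); labels for every
    gene are still returned. Flat trajectories (undefined correlation) get
    label 0 and are never reported.
    """
    de_genes = [g for g in de_genes if g in expr.index]
    if not de_genes:
        raise ValueError("no de_genes found in the expression matrix")
    X = expr.loc[de_genes].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    zf = pd.DataFrame(Z, index=de_genes, columns=expr.columns)
    stages = stages.reindex(expr.columns)
    traj = zf.T.groupby(stages, observed=True).mean().T  # genes x stages

    flat = traj.std(axis=1) < 1e-12
    labels = pd.Series(0, index=pd.Index(de_genes, name="gene"), name="cluster")
    informative = traj.index[~flat]
    if len(informative) >= 2:
        link = hierarchy.linkage(
            traj.loc[informative].to_numpy(),
            method="average",
            metric="correlation",
        )
        cut = hierarchy.fcluster(link, t=min(n_clusters, len(informative)), criterion="maxclust")
        labels.loc[informative] = cut
    elif len(informative) == 1:
        labels.loc[informative] = 1

    sizes = labels[labels > 0].value_counts().sort_index()
    reported = [int(c) for c, n in sizes.items() if n > min_cluster]
    mean_traj = traj.loc[labels.index[labels.isin(reported)]].groupby(
        labels[labels.isin(reported)]
    ).mean()
    return {
        "labels": labels,
        "sizes": sizes,
        "reported_clusters": reported,
        "trajectories": mean_traj,
    }


def gene_set_overlap(sets: Mapping[str, Sequence[str]]) -> dict:
    """Pairwise and k-way intersections of named gene sets (case-normalized)."""
    if not sets or any(len(v) == 0 for v in sets.values()):
        raise ValueError("all gene sets must be nonempty")
    norm = {name: {str(g).upper() for g in genes} for name, genes in sets.items()}
    names = list(norm)
    pairwise = pd.DataFrame(0, index=names, columns=names)
    for a in names:
        for b in names:
            pairwise.loc[a, b] = len(norm[a] & norm[b])
    inter_all = set.intersection(*norm.values())
    union = set.union(*norm.values())
    return {
        "pairwise": pairwise,
        "intersection_all": sorted(inter_all),
        "union_size": len(union),
        "sets": norm,
    }


# ---------------------------------------------------------------------------
# packaged published gene lists
# ---------------------------------------------------------------------------


def _read_list(name: str) -> list[str]:
    text = resources.files("fibroscope.data").joinpath(name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_signature_gene_sets() -> dict[str, list[str]]:
    """The published 26- and 98-gene fibrosis signatures (fixture lists)."""
    return {
        "signature26": _read_list("signature26_genes.txt"),
        "signature98": _read_list("signature98_genes.txt"),
    }


def load_progression_clusters() -> pd.Series:
    """Published 25-gene progression signature genes mapped to trend clusters."""
    text = resources.files("fibroscope.data").joinpath("progression25_clusters.tsv").read_text()
    import io as _io

    df = pd.read_csv(_io.StringIO(text), sep="\t")
    return pd.Series(df["cluster"].to_numpy(), index=df["gene"], name="cluster")
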