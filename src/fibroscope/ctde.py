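"""Cell-type-specific differential expression from bulk RNA-seq.

ctassoc-style proportion-interaction regression: bulk expression is modelled
per gene as a linear combination of estimated cell-type proportions plus
proportion x disease interaction terms, so each interaction coefficient reads
as the cell-type-specific disease effect. The disease contrast is advanced
fibrosis (F3/F4) versus non-fibrotic liver (F0/normal histology), controlling
for covariates (sex by default). Expression enters as log2(TPM + 1) so the
effects are log2 fold changes.

Also provides reference-based marker selection and marker/cluster overlap
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CtdeConfig", "ctassoc", "select_markers", "overlap_with_clusters"]


@dataclass
class CtdeConfig:
    disease_levels: tuple = ("F3", "F4")
    control_levels: tuple = ("F0", "N")
    covariates: Sequence[str] = field(default_factory=lambda: ["sex"])
    ridge_penalty: float = 1e-6
    condition_threshold: float = 1e8

    def validate(self) -> None:
        if set(self.disease_levels) & set(self.control_levels):
            raise ValueError("disease and control level sets must be disjoint")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")


def ctassoc(
    expression: pd.DataFrame,
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    config: CtdeConfig | None = None,
) -> pd.DataFrame:
    """Cell-type-specific disease effects by proportion-interaction regression.

    Parameters
    ----------
    expression
        Genes x samples matrix on TPM scale (any library-size-normalized
        relative unit works; it is log2(x+1)-transformed internally).
    proportions
        Samples x cell-types fractions, e.g. from :func:`fibroscope.deconv.deconvolve`.
    metadata
        Sample table with an ordered ``stage`` column and the covariates.

    Per gene g the model is
    ``y_i = sum_c p_ic a_gc + sum_c p_ic d_i b_gc + sum_k z_ik g_k + e_i``
    with d the disease indicator. There is no intercept: the proportion block
    sums to one per sample and absorbs it. A small ridge penalty on the
    interaction block stabilizes the near-collinear design; samples outside
    disease/control are dropped.

    Returns a long table with one row per (gene, cell type): ``beta`` (log2
    fold change), ``se``, ``t``, ``p`` and BH-adjusted ``q`` across all tests
    jointly, plus an ``ill_conditioned`` flag.
    """
    config = config or CtdeConfig()
    config.validate()
    stage = metadata["stage"].astype(str)
    keep = stage.isin(config.disease_levels) | stage.isin(config.control_levels)
    samples = metadata.index[keep]
    if len(samples) < proportions.shape[1] * 2 + len(config.covariates) + 2:
        raise ValueError("too few disease/control samples for the interaction design")
    d = stage.loc[samples].isin(config.disease_levels).to_numpy(dtype=float)

    P = proportions.loc[samples].to_numpy(dtype=float)
    Z = metadata.loc[samples, list(config.covariates)].to_numpy(dtype=float) if config.covariates else np.empty((len(samples), 0))
    X = np.hstack([P, P * d[:, None], Z])
    n, p = X.shape
    n_types = P.shape[1]

    # ridge on the interaction block only
    lam = np.zeros(p)
    lam[n_types : 2 * n_types] = config.ridge_penalty
    XtX = X.T @ X
    H = np.linalg.inv(XtX + np.diag(lam))
    A = H @ X.T

    ill = bool(np.linalg.cond(X) > config.condition_threshold)

    Y = np.log2(expression.loc[:, samples].to_numpy(dtype=float) + 1.0).T  # samples x genes
    coefs = A @ Y  # p x genes
    resid = Y - X @ coefs
    df = n - p
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    # var(beta_j) = sigma^2 * [H XtX H]_jj  (equals H_jj when ridge -> 0)
    V = np.diag(H @ XtX @ H)

    rows = []
    for ci, ctype in enumerate(proportions.columns):
        j = n_types + ci
        beta = coefs[j]
        se = np.sqrt(np.maximum(sigma2 * V[j], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.nan)
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
        rows.append(
            pd.DataFrame(
                {
                    "gene": expression.index,
                    "cell_type": ctype,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": pvals,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["ill_conditioned"] = ill
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def select_markers(
    reference: ad.AnnData,
    fold: float = 4.0,
    min_expr: float = 1.0,
    cell_type_key: str = "cell_type",
    subject_key: str = "subject",
) -> dict[str, list[str]]:
    """Cell-type marker gene sets from the single-cell reference.

    Gene g is a marker of type c iff its cross-subject mean count in c is at
    least ``min_expr`` and at least ``fold`` times the maximum mean over the
    other types. Sets are disjoint by construction; ``fold = inf`` yields
    empty sets for any gene expressed anywhere else.
    """
    X = reference.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    obs = reference.obs
    cell_types = list(reference.uns.get("cell_types", sorted(obs[cell_type_key].unique())))
    groups = obs.groupby([subject_key, cell_type_key], observed=True).indices
    means = np.zeros((X.shape[1], len(cell_types)))
    for ci, ctype in enumerate(cell_types):
        per_subject = [X[idx].mean(axis=0) for (s, c), idx in groups.items() if c == ctype]
        if not per_subject:
            raise ValueError(f"cell type {ctype!r} has no cells")
        means[:, ci] = np.mean(per_subject, axis=0)

    markers: dict[str, list[str]] = {}
    genes = np.asarray(reference.var_names)
    for ci, ctype in enumerate(cell_types):
        own = means[:, ci]
        others = np.delete(means, ci, axis=1).max(axis=1)
        with np.errstate(invalid="ignore", over="ignore"):
            sel = (own >= min_expr) & (own >= fold * others)
        if np.isinf(fold):
            sel = (own >= min_expr) & (others == 0)
        markers[ctype] = list(genes[sel])
    return markers


def overlap_with_clusters(
    marker_sets: Mapping[str, Sequence[str]],
    gene_clusters: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """Count matrix n[type, cluster] = |markers(type) intersect cluster|."""
    clusters = pd.Series(gene_clusters)
    labels = sorted(clusters.unique())
    out = pd.DataFrame(0, index=list(marker_sets), columns=labels)
    for ctype, genes in marker_sets.items():
        hit = clusters.reindex(pd.Index(set(genes))).dropna()
        for label, count in hit.value_counts().items():
            out.loc[ctype, label] = int(count)
    return out
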