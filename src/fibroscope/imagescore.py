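"""Continuous fibrosis severity from morphometric tile features (ImageScore).

Each biopsy image is represented by a variable number of tiles carrying eight
morphometric features (collagen areas, void/tissue compactness, ...). One
repetition of the procedure: down-sample every image to a fixed number of
tiles, split the patients into cross-validation folds, fit PCA on the
training tiles, summarize each patient as the componentwise median of their
tiles' PC scores, train an epsilon-insensitive RBF support-vector regression
against numeric stage targets (normal = -1, F0..F4 = 0..4) and predict the
held-out patients. Repeating the down-sampling many times gives each sample a
distribution of predictions whose median is the final ImageScore.

Folds split patients, never tiles: tiles of one patient would otherwise leak
between training and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .syndata import STAGE_TARGETS, TILE_FEATURES

__all__ = [
    "ImageScoreConfig",
    "ImageScoreResult",
    "PCABasis",
    "downsample_tiles",
    "fit_pca_basis",
    "patient_features",
    "fit_predict_rep",
    "compute_imagescore",
    "cluster_tiles",
    "rank_concordance",
]


@dataclass
class ImageScoreConfig:
    n_reps: int = 100
    tiles_per_image: int = 6
    cv_folds: int = 20
    stage_targets: Mapping[str, float] = field(default_factory=lambda: dict(STAGE_TARGETS))
    pca_var_kept: float = 0.90
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    n_tile_clusters: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.tiles_per_image < 1:
            raise ValueError("tiles_per_image must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        targets = [self.stage_targets[s] for s in STAGE_TARGETS if s in self.stage_targets]
        if any(b <= a for a, b in zip(targets, targets[1:])):
            raise ValueError("stage_targets must be strictly increasing over the stage order")


@dataclass
class PCABasis:
    scaler: StandardScaler
    pca: PCA
    n_components: int

    def transform(self, features: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(features))[:, : self.n_components]


@dataclass
class ImageScoreResult:
    per_sample: pd.DataFrame  # imagescore (median of rep scores), n_predictions
    rep_scores: pd.DataFrame  # samples x repetitions
    tau_vs_stage: float  # Kendall tau-b (standard, tie-penalized)
    gamma_vs_stage: float  # Goodman-Kruskal gamma: 1 iff every cross-stage pair is ordered
    tile_clusters: pd.Series | None = None
    cluster_ratios: pd.DataFrame | None = None
    cluster_tau_vs_stage: pd.Series | None = None


def rank_concordance(score, ordinal) -> tuple[float, float]:
    """(Kendall tau-b, Goodman-Kruskal gamma) of a continuous score against an
    ordinal grade.

    tau-b penalizes the grade's ties, so it cannot reach 1 for a continuous
    score; gamma drops tied pairs from the denominator and equals 1 exactly
    when every pair of samples from different grades is ranked correctly.
    """
    score = np.asarray(score, dtype=float)
    ordinal = np.asarray(ordinal, dtype=float)
    tau = float(stats.kendalltau(score, ordinal)[0])
    ds = np.sign(score[:, None] - score[None, :])
    do = np.sign(ordinal[:, None] - ordinal[None, :])
    prod = ds * do
    concordant = np.sum(prod > 0) // 2
    discordant = np.sum(prod < 0) // 2
    denom = concordant + discordant
    gamma = float((concordant - discordant) / denom) if denom else np.nan
    return tau, gamma


def _feature_matrix(tiles: pd.DataFrame) -> np.ndarray:
    missing = [f for f in TILE_FEATURES if f not in tiles.columns]
    if missing:
        raise ValueError(f"tile table lacks feature columns: {missing}")
    if tiles[list(TILE_FEATURES)].isna().any().any():
        raise ValueError("tile features contain missing values")
    return tiles[list(TILE_FEATURES)].to_numpy(dtype=float)


def downsample_tiles(tiles: pd.DataFrame, k: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sample min(k, n_tiles) tiles per image without replacement."""
    if tiles.empty:
        raise ValueError("empty tile table")
    if k < 1:
        raise ValueError("k must be >= 1")
    picks = []
    for _, group in tiles.groupby("image_id", sort=True):
        # canonical within-image order, so the draw ignores input row order
        group = group.sort_values("tile_id", kind="mergesort")
        if len(group) <= k:
            picks.append(group)
        else:
            picks.append(group.iloc[np.sort(rng.choice(len(group), size=k, replace=False))])
    return pd.concat(picks, axis=0)


def fit_pca_basis(train_tiles: pd.DataFrame, var_kept: float = 0.90) -> PCABasis:
    """Center/scale the training tiles and fit PCA; keep the smallest number
    of components reaching ``var_kept`` cumulative explained variance."""
    F = _feature_matrix(train_tiles)
    scaler = StandardScaler().fit(F)
    pca = PCA().fit(scaler.transform(F))
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cum, var_kept) + 1)
    n_components = max(1, min(n_components, F.shape[1]))
    return PCABasis(scaler=scaler, pca=pca, n_components=n_components)


def patient_features(tiles: pd.DataFrame, basis: PCABasis) -> pd.DataFrame:
    """Per-sample feature vectors: componentwise median of tile PC scores."""
    scores = basis.transform(_feature_matrix(tiles))
    df = pd.DataFrame(scores, index=tiles["image_id"].to_numpy())
    med = df.groupby(level=0, sort=True).median()
    med.columns = [f"PC{i + 1}" for i in range(med.shape[1])]
    med.index.name = "sample_id"
    return med


def fit_predict_rep(
    tiles: pd.DataFrame,
    metadata: pd.DataFrame,
    config: ImageScoreConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """One repetition: down-sample tiles, patient-level CV, PCA + SVR, predict.

    Every sample receives exactly one held-out prediction. PCA is fit on
    training tiles only; the SVR (RBF kernel, gamma = 1/n_features) regresses
    patient feature medians on the numeric stage targets.
    """
    config.validate()
    sub = downsample_tiles(tiles, config.tiles_per_image, rng)
    samples = metadata.index.to_numpy()
    if len(samples) < config.cv_folds:
        raise ValueError("fewer samples than cv_folds")
    targets = metadata["stage"].astype(str).map(config.stage_targets)
    if targets.isna().any():
        raise ValueError("stage_targets does not cover every stage present")

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    preds = pd.Series(np.nan, index=metadata.index, name="imagescore")
    by_image = sub.groupby("image_id", sort=False).indices
    for tr_idx, te_idx in kf.split(samples):
        if len(tr_idx) < 2:
            raise ValueError("a cross-validation fold has fewer than 2 training samples")
        tr_samples, te_samples = samples[tr_idx], samples[te_idx]
        tr_tiles = sub.iloc[np.concatenate([by_image[s] for s in tr_samples if s in by_image])]
        basis = fit_pca_basis(tr_tiles, config.pca_var_kept)
        Xtr = patient_features(tr_tiles, basis)
        svr = SVR(kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon, gamma="auto")
        svr.fit(Xtr.to_numpy(), targets.loc[Xtr.index].to_numpy())
        te_tiles = sub.iloc[np.concatenate([by_image[s] for s in te_samples if s in by_image])]
        Xte = patient_features(te_tiles, basis)
        preds.loc[Xte.index] = svr.predict(Xte.to_numpy())
    if preds.isna().any():
        raise ValueError("some samples received no prediction (missing tiles?)")
    return preds


def compute_imagescore(
    tiles: pd.DataFrame,
    metadata: pd.DataFrame,
    config: ImageScoreConfig | None = None,
    with_clusters: bool = True,
) -> ImageScoreResult:
    """Full ImageScore: median of ``n_reps`` repeated down-sampled predictions.

    Reports Kendall tau between the final score and the ordinal stage, and
    (optionally) the tile clustering with per-sample cluster ratios and their
    stage associations.
    """
    config = config or ImageScoreConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    reps = {}
    for r in range(config.n_reps):
        reps[f"rep{r + 1:03d}"] = fit_predict_rep(tiles, metadata, config, rng)
    rep_scores = pd.DataFrame(reps)
    per_sample = pd.DataFrame(
        {
            "imagescore": rep_scores.median(axis=1),
            "n_predictions": rep_scores.notna().sum(axis=1),
        }
    )
    tau, gamma = rank_concordance(
        per_sample["imagescore"].to_numpy(), metadata["stage"].cat.codes.to_numpy()
    )
    result = ImageScoreResult(
        per_sample=per_sample, rep_scores=rep_scores, tau_vs_stage=tau, gamma_vs_stage=gamma
    )
    if with_clusters:
        labels, ratios, taus = cluster_tiles(
            tiles,
            n_clusters=config.n_tile_clusters,
            rng=np.random.default_rng([config.seed, 997]),
            stages=metadata["stage"],
        )
        result.tile_clusters = labels
        result.cluster_ratios = ratios
        result.cluster_tau_vs_stage = taus
    return result


def cluster_tiles(
    tiles: pd.DataFrame,
    n_clusters: int = 4,
    rng: np.random.Generator | None = None,
    stages: pd.Series | None = None,
    var_kept: float = 0.90,
):
    """K-means on standardized tile PC scores; per-sample cluster ratios.

    Returns (labels in 1..n_clusters per tile, samples x clusters ratio
    matrix, Kendall tau of each cluster's ratio vs stage -- NaN series when
    stages are not given).
    """
    if len(tiles) < n_clusters:
        raise ValueError("fewer tiles than clusters")
    rng = rng or np.random.default_rng(0)
    basis = fit_pca_basis(tiles, var_kept)
    scores = basis.transform(_feature_matrix(tiles))
    scores = StandardScaler().fit_transform(scores)
    km = KMeans(
        n_clusters=n_clusters,
        n_init=10,
        random_state=int(rng.integers(2**31)),
    ).fit(scores)
    labels = pd.Series(km.labels_ + 1, index=tiles["tile_id"].to_numpy(), name="cluster")

    tab = pd.crosstab(tiles["image_id"].to_numpy(), km.labels_ + 1)
    tab = tab.reindex(columns=range(1, n_clusters + 1), fill_value=0)
    ratios = tab.div(tab.sum(axis=1), axis=0)
    ratios.index.name = "sample_id"

    taus = pd.Series(np.nan, index=ratios.columns, name="kendall_stage")
    if stages is not None:
        codes = stages.reindex(ratios.index).cat.codes.to_numpy()
        for c in ratios.columns:
            taus[c] = float(stats.kendalltau(ratios[c].to_numpy(), codes)[0])
    return labels, ratios, taus
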