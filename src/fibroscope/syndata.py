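"""Synthetic NAFLD-fibrosis study generator.

Emulates the inputs of a bulk + single-cell liver fibrosis study so that every
downstream stage (morphometric scoring, deconvolution, cell-type-specific DE,
signature derivation) can be exercised end-to-end with known ground truth:

* a multi-subject single-cell reference with planted cell-type marker genes,
* stage-dependent cell-type proportions (hepatocytes falling, cholangiocytes /
  HSCs / macrophages rising with fibrosis severity),
* negative-binomial bulk mixtures with planted stage-monotone and
  cell-type-specific disease effects,
* per-image morphometric tile features monotone in a hidden continuous
  fibrosis severity.

All randomness flows from ``StudyConfig.seed`` through per-component
``numpy.random.Generator`` streams, so every generator is reproducible and the
components of one study are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "STAGES",
    "STAGE_TARGETS",
    "TILE_FEATURES",
    "StudyConfig",
    "GeneratedStudy",
    "default_gene_names",
    "generate_metadata",
    "generate_reference",
    "generate_proportions",
    "generate_bulk",
    "generate_tiles",
    "plant_effects",
    "generate_study",
]

#: Ordered histology levels: normal liver then NASH CRN fibrosis stages 0-4.
STAGES = ("N", "F0", "F1", "F2", "F3", "F4")

#: Numeric regression targets per stage (normal = -1, F0..F4 = 0..4).
STAGE_TARGETS = {"N": -1.0, "F0": 0.0, "F1": 1.0, "F2": 2.0, "F3": 3.0, "F4": 4.0}

#: The eight morphometric features recorded per histology tile.
TILE_FEATURES = (
    "compactness_tissue",
    "compactness_voids",
    "n_voids",
    "equivalence_radius",
    "collagen_area",
    "collagen_per_tissue",
    "collagen_per_section",
    "void_area",
)

_DEFAULT_CELL_TYPES = ("hepatocyte", "cholangiocyte", "HSC", "macrophage")

# Stage-mean proportion vectors (hepatocyte, cholangiocyte, HSC, macrophage).
# Hepatocytes fall monotonically N -> F4; the three non-parenchymal types rise.
_DEFAULT_STAGE_PROPORTIONS = {
    "N": (0.70, 0.04, 0.10, 0.16),
    "F0": (0.65, 0.05, 0.12, 0.18),
    "F1": (0.59, 0.07, 0.14, 0.20),
    "F2": (0.52, 0.09, 0.17, 0.22),
    "F3": (0.44, 0.12, 0.20, 0.24),
    "F4": (0.35, 0.15, 0.24, 0.26),
}

# Relative per-cell library size by cell type (hepatocytes are large,
# transcript-rich cells; stellate cells small).
_DEFAULT_SIZE_FACTORS = {
    "hepatocyte": 1.5,
    "cholangiocyte": 1.0,
    "HSC": 0.8,
    "macrophage": 1.2,
}

# Affine tile-feature model: value = intercept + slope * latent_severity + noise.
# Collagen-area features load positively on severity, tissue/void compactness
# negatively (fibrotic tissue is collagen-rich and porous).
_TILE_SLOPES = {
    "compactness_tissue": -0.50,
    "compactness_voids": -0.80,
    "n_voids": 0.60,
    "equivalence_radius": 0.40,
    "collagen_area": 1.00,
    "collagen_per_tissue": 0.90,
    "collagen_per_section": 0.80,
    "void_area": 0.70,
}
_TILE_INTERCEPTS = {
    "compactness_tissue": 5.0,
    "compactness_voids": 6.0,
    "n_voids": 3.0,
    "equivalence_radius": 2.0,
    "collagen_area": 4.0,
    "collagen_per_tissue": 3.0,
    "collagen_per_section": 3.5,
    "void_area": 2.5,
}

# Sub-stream identifiers so each generator draws from its own stream of the
# study seed (same seed => byte-identical output, components independent).
_STREAM_METADATA = 1
_STREAM_REFERENCE = 2
_STREAM_PROPORTIONS = 3
_STREAM_EFFECTS = 4
_STREAM_BULK = 5
_STREAM_TILES = 6

_FEMALE_FRAC_BY_STAGE = {"N": 0.90, "F0": 0.71, "F1": 0.67, "F2": 0.70, "F3": 0.50, "F4": 0.58}
_MEAN_AGE_BY_STAGE = {"N": 43.7, "F0": 45.1, "F1": 44.4, "F2": 44.0, "F3": 50.4, "F4": 60.8}


@dataclass
class StudyConfig:
    """Knobs of the synthetic study.

    Defaults mirror the cohort shape of the emulated study: 143 biopsies
    spread over normal histology and fibrosis stages F0-F4, four major liver
    cell types, and 5000 genes of which a fraction ``de_frac`` carry a
    stage-monotone effect.
    """

    n_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"N": 31, "F0": 35, "F1": 30, "F2": 27, "F3": 8, "F4": 12}
    )
    n_genes: int = 5000
    cell_types: Sequence[str] = _DEFAULT_CELL_TYPES
    n_subjects_ref: int = 4
    cells_per_subject_type: int = 400
    markers_per_type: int = 20
    marker_boost: float = 15.0  # archetype mean ratio of a marker over other types (floor 10)
    subject_sigma: float = 0.25  # lognormal sd of cross-subject profile jitter
    base_cell_counts: float = 2000.0  # mean library size of a size-factor-1 cell
    size_factors: Mapping[str, float] | None = None
    de_frac: float = 0.04
    lfc_scale: float = 1.0
    celltype_de_frac: float = 0.02
    celltype_lfc_scale: float = 1.0
    nb_dispersion: float = 0.1
    dirichlet_concentration: float = 200.0
    stage_proportions: Mapping[str, Sequence[float]] | None = None
    libsize_mean: float = 1e6
    libsize_sigma: float = 0.3
    tile_range: tuple[int, int] = (8, 500)
    tile_noise_sd: float = 0.3
    latent_jitter_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_per_stage) != set(STAGES):
            raise ValueError(f"n_per_stage keys must be exactly {set(STAGES)}")
        if any(v <= 0 for v in self.n_per_stage.values()):
            raise ValueError("all per-stage sample counts must be positive")
        if not 0.0 <= self.de_frac <= 1.0:
            raise ValueError("de_frac must lie in [0, 1]")
        if not 0.0 <= self.celltype_de_frac <= 1.0:
            raise ValueError("celltype_de_frac must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_subjects_ref < 3:
            raise ValueError("n_subjects_ref must be >= 3")
        if self.n_genes < len(self.cell_types) * self.markers_per_type:
            raise ValueError(
                "n_genes must be at least cell_types x markers_per_type "
                f"({len(self.cell_types)} x {self.markers_per_type})"
            )
        if self.cells_per_subject_type < 30:
            raise ValueError("cells_per_subject_type must be >= 30")
        if self.tile_range[0] < 1 or self.tile_range[1] < self.tile_range[0]:
            raise ValueError("tile_range must satisfy 1 <= min <= max")
        self.stage_proportion_table()  # raises on malformed custom tables

    # -- derived pieces -------------------------------------------------

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    def stage_proportion_table(self) -> pd.DataFrame:
        """Stage-mean cell-type proportion vectors m(stage), rows on the simplex."""
        if self.stage_proportions is not None:
            tab = pd.DataFrame(
                {s: list(self.stage_proportions[s]) for s in STAGES},
                index=list(self.cell_types),
            ).T
        elif tuple(self.cell_types) == _DEFAULT_CELL_TYPES:
            tab = pd.DataFrame(
                {s: list(_DEFAULT_STAGE_PROPORTIONS[s]) for s in STAGES},
                index=list(_DEFAULT_CELL_TYPES),
            ).T
        else:
            raise ValueError(
                "custom cell_types require an explicit stage_proportions table"
            )
        if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("stage proportion rows must sum to 1")
        return tab

    def size_factor_vector(self) -> np.ndarray:
        sf = self.size_factors or _DEFAULT_SIZE_FACTORS
        return np.array([float(sf.get(c, 1.0)) for c in self.cell_types])


@dataclass
class GeneratedStudy:
    """One fully generated synthetic study with its planted ground truth."""

    config: StudyConfig
    metadata: pd.DataFrame
    reference: ad.AnnData
    true_proportions: pd.DataFrame
    bulk_counts: pd.DataFrame
    tiles: pd.DataFrame
    truth: dict


def default_gene_names(n_genes: int) -> list[str]:
    """Gene identifiers: the published signature genes first, then SGxxxxx.

    Reserving the signature names as a prefix block lets fixture tests on the
    printed gene lists run against generated matrices.
    """
    from .signature import load_signature_gene_sets

    sets = load_signature_gene_sets()
    reserved = sorted(set(sets["signature26"]) | set(sets["signature98"]))
    names = reserved[:n_genes]
    names += [f"SG{i:05d}" for i in range(len(names), n_genes)]
    return names


def generate_metadata(config: StudyConfig) -> pd.DataFrame:
    """Sample table: ordinal stage, sex/age/batch covariates, latent severity.

    ``latent_severity`` is the hidden continuous fibrosis driving the tile
    features: the stage's numeric target plus Gaussian within-stage jitter.
    It is exported for testing only; the analysis never reads it.
    """
    config.validate()
    rng = config.rng(_STREAM_METADATA)
    rows = []
    i = 0
    for stage in STAGES:
        for _ in range(int(config.n_per_stage[stage])):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "stage": stage,
                    "sex": int(rng.random() < _FEMALE_FRAC_BY_STAGE[stage]),
                    "age": float(np.round(rng.normal(_MEAN_AGE_BY_STAGE[stage], 10.0), 1)),
                    "batch": f"b{1 + rng.integers(3)}",
                    "latent_severity": STAGE_TARGETS[stage]
                    + rng.normal(0.0, config.latent_jitter_sd),
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["stage"] = pd.Categorical(meta["stage"], categories=list(STAGES), ordered=True)
    return meta


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (gamma-Poisson).

    ``dispersion == 0`` returns the exact means: the deterministic noiseless
    mode used to reduce the generators to closed form in tests.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam).astype(float)


def _archetypes(config: StudyConfig, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Per-type archetype mean profiles with planted marker genes.

    Returns an (n_genes, n_types) positive array and the marker map. Each
    marker gene's archetype mean in its own type is ``marker_boost`` times the
    maximum over the other types (boost >= 10, the specificity floor).
    """
    G, C = config.n_genes, len(config.cell_types)
    base = rng.lognormal(mean=np.log(5.0), sigma=1.2, size=G)
    type_var = rng.lognormal(mean=0.0, sigma=0.4, size=(G, C))
    arche = base[:, None] * type_var
    n_mark = C * config.markers_per_type
    marker_idx = rng.choice(G, size=n_mark, replace=False)
    markers: dict[str, list[int]] = {}
    for ci, ctype in enumerate(config.cell_types):
        idx = marker_idx[ci * config.markers_per_type : (ci + 1) * config.markers_per_type]
        markers[ctype] = list(map(int, idx))
        others = [j for j in range(C) if j != ci]
        arche[idx, ci] = config.marker_boost * arche[np.ix_(idx, others)].max(axis=1)
    return arche, markers


def _subject_profiles(
    config: StudyConfig, arche: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Absolute per-cell mean counts theta[g, c, s].

    Each subject's profile is the archetype perturbed by lognormal jitter,
    renormalized to relative abundance, then scaled to that cell type's mean
    library size (base counts x type size factor).
    """
    G, C, S = config.n_genes, len(config.cell_types), config.n_subjects_ref
    jitter = rng.lognormal(0.0, config.subject_sigma, size=(G, C, S))
    theta = arche[:, :, None] * jitter
    theta /= theta.sum(axis=0, keepdims=True)
    libsize = config.base_cell_counts * config.size_factor_vector()
    return theta * libsize[None, :, None]


def generate_reference(config: StudyConfig) -> ad.AnnData:
    """Multi-subject single-cell reference (cells x genes, sparse counts).

    ``obs`` carries ``cell_type`` and ``subject``; ``uns['markers']`` maps each
    cell type to its planted marker genes, ``uns['theta_mean']`` holds the
    absolute per-cell mean counts used for the cells (genes x types x
    subjects) for downstream truth checks.
    """
    config.validate()
    rng = config.rng(_STREAM_REFERENCE)
    arche, markers = _archetypes(config, rng)
    theta = _subject_profiles(config, arche, rng)
    genes = default_gene_names(config.n_genes)

    blocks, obs_rows = [], []
    for si in range(config.n_subjects_ref):
        subject = f"subj{si + 1}"
        for ci, ctype in enumerate(config.cell_types):
            n = config.cells_per_subject_type
            mean = np.broadcast_to(theta[:, ci, si], (n, config.n_genes))
            counts = _nb_sample(rng, mean, config.nb_dispersion)
            blocks.append(sparse.csr_matrix(counts))
            for k in range(n):
                obs_rows.append((f"{subject}_{ctype}_{k:04d}", ctype, subject))
    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "cell_type", "subject"]).set_index(
        "cell_id"
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["markers"] = {c: [genes[i] for i in idx] for c, idx in markers.items()}
    adata.uns["theta_mean"] = theta
    adata.uns["cell_types"] = list(config.cell_types)
    return adata


def generate_proportions(metadata: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """True cell-type fractions per sample: Dirichlet around m(stage).

    An infinite ``dirichlet_concentration`` returns the stage means exactly
    (the zero-variance limit).
    """
    config.validate()
    rng = config.rng(_STREAM_PROPORTIONS)
    m = config.stage_proportion_table()
    conc = config.dirichlet_concentration
    rows = np.empty((len(metadata), len(config.cell_types)))
    for i, stage in enumerate(metadata["stage"].astype(str)):
        mean = m.loc[stage].to_numpy()
        if np.isinf(conc):
            rows[i] = mean
        else:
            rows[i] = rng.dirichlet(conc * mean)
    return pd.DataFrame(rows, index=metadata.index, columns=list(config.cell_types))


def plant_effects(config: StudyConfig, genes: Sequence[str] | None = None) -> dict:
    """Draw the planted effect truth: stage-monotone lfc and cell-type betas.

    Deterministic given the config seed, so :func:`generate_bulk` and
    :func:`generate_study` agree on the same truth. The two planted gene sets
    are disjoint: ``de_frac`` of genes get a stage-monotone log2 effect of
    magnitude ``lfc_scale`` (random sign); ``celltype_de_frac`` get a
    disease-group effect of magnitude ``celltype_lfc_scale`` in one random
    cell type (disease = stages F3/F4).
    """
    config.validate()
    if genes is None:
        genes = default_gene_names(config.n_genes)
    rng = config.rng(_STREAM_EFFECTS)
    G = len(genes)
    n_de = int(round(config.de_frac * G))
    n_ct = int(round(config.celltype_de_frac * G))
    picked = rng.choice(G, size=n_de + n_ct, replace=False)
    de_idx, ct_idx = picked[:n_de], picked[n_de:]

    lfc = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    lfc.iloc[de_idx] = config.lfc_scale * rng.choice([-1.0, 1.0], size=n_de)

    beta = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=list(config.cell_types))
    types = rng.integers(len(config.cell_types), size=n_ct)
    signs = rng.choice([-1.0, 1.0], size=n_ct)
    for gi, ti, s in zip(ct_idx, types, signs):
        beta.iloc[int(gi), int(ti)] = s * config.celltype_lfc_scale
    return {
        "de_genes": [genes[i] for i in sorted(map(int, de_idx))],
        "lfc": lfc,
        "beta": beta,
    }


def _reference_mean_profiles(reference: ad.AnnData) -> pd.DataFrame:
    """Cross-subject mean of per-(subject, type) mean counts, genes x types."""
    X = reference.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    obs = reference.obs
    types = reference.uns.get("cell_types", sorted(obs["cell_type"].unique()))
    per_subject = {}
    for (subject, ctype), idx in obs.groupby(
        ["subject", "cell_type"], observed=True
    ).indices.items():
        per_subject[(subject, ctype)] = X[idx].mean(axis=0)
    out = {}
    for ctype in types:
        cols = [v for (s, c), v in per_subject.items() if c == ctype]
        out[ctype] = np.mean(cols, axis=0)
    return pd.DataFrame(out, index=reference.var_names)


def generate_bulk(
    reference: ad.AnnData,
    true_proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    config: StudyConfig,
    effects: dict | None = None,
) -> pd.DataFrame:
    """Bulk count matrix (genes x samples) mixing the reference at known fractions.

    Expected expression of gene g in sample i is
    ``libsize_i * norm( sum_c p_ic * theta_gc * 2^(beta_gc * d_i) * 2^(lfc_g * sev_i) )``
    with ``theta_gc`` the absolute per-cell mean counts of the reference,
    ``d_i`` the advanced-disease indicator (stage F3/F4) and ``sev_i`` the
    latent severity rescaled to [0, 1] (so ``lfc_g`` reads as the log2 fold
    change between normal histology and cirrhosis). Counts are negative
    binomial; ``nb_dispersion == 0`` yields the exact means.
    """
    config.validate()
    if not true_proportions.index.equals(metadata.index):
        raise ValueError("true_proportions rows are not aligned with metadata samples")
    if list(true_proportions.columns) != list(config.cell_types):
        raise ValueError("true_proportions columns do not match config cell_types")
    if effects is None:
        effects = plant_effects(config, list(reference.var_names))
    theta = _reference_mean_profiles(reference)  # genes x types, absolute scale
    if list(theta.columns) != list(config.cell_types):
        theta = theta[list(config.cell_types)]

    rng = config.rng(_STREAM_BULK)
    lfc = effects["lfc"].reindex(theta.index).fillna(0.0).to_numpy()
    beta = effects["beta"].reindex(theta.index).fillna(0.0).to_numpy()
    disease = metadata["stage"].astype(str).isin(["F3", "F4"]).to_numpy().astype(float)
    severity = (metadata["latent_severity"].to_numpy() + 1.0) / 5.0

    if config.libsize_sigma == 0:
        libsize = np.full(len(metadata), config.libsize_mean)
    else:
        libsize = rng.lognormal(np.log(config.libsize_mean), config.libsize_sigma, len(metadata))

    P = true_proportions.to_numpy()  # samples x types
    T = theta.to_numpy()  # genes x types
    counts = np.empty((T.shape[0], len(metadata)))
    for i in range(len(metadata)):
        mix = (T * np.exp2(beta * disease[i])) @ P[i]
        mix = mix * np.exp2(lfc * severity[i])
        mean = libsize[i] * mix / mix.sum()
        counts[:, i] = _nb_sample(rng, mean, config.nb_dispersion)
    return pd.DataFrame(counts, index=theta.index, columns=metadata.index)


def generate_tiles(metadata: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Morphometric tile table: 8 features, affine in latent severity plus noise.

    Tile counts per image are uniform in ``tile_range`` (biopsy images vary
    from a handful to hundreds of tiles). Collagen-area features increase with
    severity; tissue/void compactness decrease.
    """
    config.validate()
    if "latent_severity" not in metadata:
        raise ValueError("metadata must carry latent_severity (see generate_metadata)")
    rng = config.rng(_STREAM_TILES)
    lo, hi = config.tile_range
    rows = []
    for sample_id, latent in metadata["latent_severity"].items():
        n_tiles = int(rng.integers(lo, hi + 1))
        noise = (
            rng.normal(0.0, config.tile_noise_sd, size=(n_tiles, len(TILE_FEATURES)))
            if config.tile_noise_sd > 0
            else np.zeros((n_tiles, len(TILE_FEATURES)))
        )
        base = np.array(
            [_TILE_INTERCEPTS[f] + _TILE_SLOPES[f] * latent for f in TILE_FEATURES]
        )
        vals = base[None, :] + noise
        for t in range(n_tiles):
            rows.append((sample_id, f"{sample_id}_t{t:04d}", *vals[t]))
    return pd.DataFrame(rows, columns=["image_id", "tile_id", *TILE_FEATURES])


def generate_study(config: StudyConfig | None = None) -> GeneratedStudy:
    """Generate a complete, mutually consistent synthetic study."""
    config = config or StudyConfig()
    config.validate()
    metadata = generate_metadata(config)
    reference = generate_reference(config)
    proportions = generate_proportions(metadata, config)
    effects = plant_effects(config, list(reference.var_names))
    bulk = generate_bulk(reference, proportions, metadata, config, effects=effects)
    tiles = generate_tiles(metadata, config)
    truth = {
        **effects,
        "markers": dict(reference.uns["markers"]),
        "stage_proportions": config.stage_proportion_table(),
    }
    return GeneratedStudy(
        config=config,
        metadata=metadata,
        reference=reference,
        true_proportions=proportions,
        bulk_counts=bulk,
        tiles=tiles,
        truth=truth,
    )
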