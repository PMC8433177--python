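"""End-to-end orchestration: simulate -> imagescore -> deconvolve -> ctde -> signature.

``run_all`` executes the enabled stages in order on a synthetic study (or on
user-supplied inputs loaded through :mod:`fibroscope.io`), writes each
stage's outputs under the run directory, and finishes with a manifest
recording the configuration, per-stage wall time, seeds and output checksums.
Re-running with the same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .ctde import CtdeConfig, ctassoc, select_markers
from .deconv import associate_proportions, build_design, deconvolve
from .imagescore import ImageScoreConfig, compute_imagescore
from .signature import (
    composite_score,
    fit_lasso_signature,
    fit_ordinal_per_gene,
    gene_level_score,
    score_and_validate,
    transform_expression,
)
from .syndata import StudyConfig, generate_study

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    study: StudyConfig | None = None
    imagescore: ImageScoreConfig | None = None
    ctde: CtdeConfig | None = None
    run_imagescore: bool = True
    run_deconv: bool = True
    run_ctde: bool = True
    run_signature: bool = True
    signature_top_n: int = 1000
    signature_folds: int = 10
    signature_lambda_rule: str = "min_mse"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(outdir=Path(raw.pop("outdir", "fibroscope_run")))
        if "seed" in raw:
            cfg.seed = int(raw.pop("seed"))
        if "study" in raw:
            cfg.study = StudyConfig(**raw.pop("study"))
        if "imagescore" in raw:
            cfg.imagescore = ImageScoreConfig(**raw.pop("imagescore"))
        if "ctde" in raw:
            cfg.ctde = CtdeConfig(**raw.pop("ctde"))
        for key in list(raw):
            if hasattr(cfg, key):
                setattr(cfg, key, raw.pop(key))
        cfg.extra = raw
        return cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    # stable across processes (unlike the builtin str hash)
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def run_all(config: RunConfig) -> dict:
    """Run the enabled pipeline stages and return the manifest dict.

    A stage failure raises with the stage name; the partial manifest written
    so far is still saved to ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study_cfg = config.study or StudyConfig(seed=config.seed)
    manifest: dict = {
        "seed": config.seed,
        "study_seed": study_cfg.seed,
        "stages": [],
        "timings_s": {},
        "checksums": {},
        "warnings": [],
    }

    def finish_stage(name: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"].append(name)
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        for p in outputs:
            manifest["checksums"][p.name] = _checksum(p)

    current = "simulate"
    try:
        t0 = time.perf_counter()
        study = generate_study(study_cfg)
        bulk_f = outdir / "bulk_counts.tsv"
        meta_f = outdir / "metadata.tsv"
        tiles_f = outdir / "tiles.csv"
        props_f = outdir / "true_proportions.tsv"
        fio.write_expression(study.bulk_counts, bulk_f)
        fio.write_metadata(study.metadata, meta_f)
        fio.write_tiles(study.tiles, tiles_f)
        fio.write_table(study.true_proportions, props_f, index_label="sample_id")
        truth_f = outdir / "truth.json"
        truth_f.write_text(
            json.dumps(
                {
                    "de_genes": study.truth["de_genes"],
                    "markers": study.truth["markers"],
                },
                indent=1,
            )
        )
        finish_stage("simulate", t0, [bulk_f, meta_f, tiles_f, props_f, truth_f])

        imagescore_series = None
        if config.run_imagescore:
            current = "imagescore"
            t0 = time.perf_counter()
            is_cfg = config.imagescore or ImageScoreConfig(seed=_derive_seed(config.seed, "imagescore"))
            res = compute_imagescore(study.tiles, study.metadata, is_cfg)
            imagescore_series = res.per_sample["imagescore"]
            score_f = outdir / "imagescore.tsv"
            fio.write_table(res.per_sample, score_f, index_label="sample_id")
            summary_f = outdir / "imagescore_summary.json"
            summary_f.write_text(
                json.dumps(
                    {
                        "tau_vs_stage": res.tau_vs_stage,
                        "n_reps": is_cfg.n_reps,
                        "cluster_tau_vs_stage": (
                            None
                            if res.cluster_tau_vs_stage is None
                            else {int(k): v for k, v in res.cluster_tau_vs_stage.items()}
                        ),
                    },
                    indent=1,
                )
            )
            finish_stage("imagescore", t0, [score_f, summary_f])

        proportions = None
        if config.run_deconv:
            current = "deconvolve"
            t0 = time.perf_counter()
            design = build_design(study.reference)
            est = deconvolve(study.bulk_counts, design)
            proportions = est.proportions
            props_out = outdir / "estimated_proportions.tsv"
            fio.write_table(proportions, props_out, index_label="sample_id")
            assoc = associate_proportions(proportions, study.metadata, imagescore_series)
            assoc_f = outdir / "proportion_associations.tsv"
            fio.write_table(assoc["per_type"], assoc_f, index_label="cell_type")
            finish_stage("deconvolve", t0, [props_out, assoc_f])

        if config.run_ctde and proportions is not None:
            current = "ctde"
            t0 = time.perf_counter()
            tpm = study.bulk_counts / study.bulk_counts.sum(axis=0) * 1e6
            res = ctassoc(tpm, proportions, study.metadata, config.ctde or CtdeConfig())
            ctde_f = outdir / "celltype_de.tsv"
            res.to_csv(ctde_f, sep="\t", index=False, float_format=fio.FLOAT_FMT)
            markers = select_markers(study.reference)
            markers_f = outdir / "markers.json"
            markers_f.write_text(json.dumps(markers, indent=1))
            finish_stage("ctde", t0, [ctde_f, markers_f])

        if config.run_signature:
            current = "signature"
            t0 = time.perf_counter()
            vst = transform_expression(study.bulk_counts)
            fits = fit_ordinal_per_gene(vst, study.metadata["stage"])
            scores = gene_level_score(fits, vst)
            comp = composite_score(scores, top_n=config.signature_top_n, stages=study.metadata["stage"])
            comp_f = outdir / "composite_scores.tsv"
            fio.write_table(comp.per_sample.to_frame(), comp_f, index_label="sample_id")
            sig = fit_lasso_signature(
                vst,
                comp.per_sample,
                folds=config.signature_folds,
                lambda_rule=config.signature_lambda_rule,
                seed=_derive_seed(config.seed, "signature"),
            )
            val = score_and_validate(sig, vst, stages=study.metadata["stage"], composite=comp.per_sample)
            sig_f = outdir / "signature.json"
            sig_f.write_text(
                json.dumps(
                    {
                        "lambda": sig.lambda_,
                        "intercept": sig.intercept,
                        "genes": sig.genes,
                        "weights": {g: float(w) for g, w in sig.weights.items()},
                        "tau_vs_stage": val["tau_vs_stage"],
                        "tau_vs_composite": val["tau_vs_composite"],
                        "composite_tau_vs_stage": comp.tau_vs_stage,
                    },
                    indent=1,
                )
            )
            finish_stage("signature", t0, [comp_f, sig_f])
    except Exception as err:  # noqa: BLE001 - annotate and persist before re-raising
        manifest["failed_stage"] = current
        manifest["error"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err

    manifest["n_stages"] = len(manifest["stages"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
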