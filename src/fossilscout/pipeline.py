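"""End-to-end orchestration: crop -> cluster -> select -> binarize -> score.

A single global seed deterministically derives per-stage seeds (clustering,
ensemble, permutation) via numpy SeedSequence spawning, so any stage can be
re-run in isolation with the seed recorded in the manifest. Every run writes
a manifest listing artifacts, derived seeds and SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .band_importance import (
    EnsembleConfig,
    fit_ensemble,
    importance_report,
    permutation_importance,
)
from .clustering import KMeansConfig, fit_kmeans
from .prospectivity import (
    binarize,
    classification_metrics,
    confusion_matrix,
    predictive_area_stats,
    select_predictive_cluster,
)
from .raster_io import (
    SpectralScene,
    crop_to_aoi,
    load_scene,
    read_site_catalog,
    write_raster,
)
from .spectral_profiles import (
    cluster_band_summaries,
    profile_similarity,
    profiles_long_table,
    site_band_summary,
)

log = logging.getLogger("fossilscout")


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    scene_path: str
    sites_path: str
    out_dir: str
    aoi: tuple[float, float, float, float] | None = None  # min_e, min_n, max_e, max_n
    band_order: Sequence[str] | None = None
    k: int = 8
    epsilon: float = 1e-6
    max_iter: int = 100
    n_restarts: int = 10
    standardize: bool = False
    site_filter: tuple[str, ...] | None = None
    n_trees: int = 500
    n_pixels_subsample: int | None = 20_000
    seed: int = 0


def _derive_seeds(global_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(global_seed).spawn(3)
    names = ("clustering", "ensemble", "permutation")
    return {
        name: int(child.generate_state(1, np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    artifacts: dict[str, str] = {}

    def stage(name):
        log.info("stage=%s", name)

    # ---- load & crop -------------------------------------------------
    stage("load")
    try:
        scene = load_scene(config.scene_path, band_order=config.band_order)
        catalog = read_site_catalog(config.sites_path)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    if config.aoi is not None:
        stage("crop")
        try:
            scene = crop_to_aoi(scene, *config.aoi)
        except Exception as exc:
            raise PipelineError("crop", str(exc)) from exc

    # ---- cluster -----------------------------------------------------
    stage("cluster")
    try:
        km_config = KMeansConfig(
            k=config.k,
            epsilon=config.epsilon,
            max_iter=config.max_iter,
            n_restarts=config.n_restarts,
            seed=seeds["clustering"],
            standardize=config.standardize,
        )
        model = fit_kmeans(scene, km_config)
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    label_path = out / "cluster_labels.tif"
    write_raster(model.labels, scene, label_path, nodata_value=0)
    artifacts["cluster_labels"] = str(label_path)
    model_path = out / "cluster_model.json"
    _json_dump(
        {
            "k": model.k,
            "wcss": model.wcss,
            "n_iter": model.n_iter,
            "converged": model.converged,
            "seed": model.seed_used,
            "standardized": model.standardized,
            "bands": list(model.bands),
            "centroids": model.centroids.tolist(),
            "cluster_sizes": {str(j): n for j, n in model.cluster_sizes().items()},
        },
        model_path,
    )
    artifacts["cluster_model"] = str(model_path)

    # ---- select & binarize -------------------------------------------
    stage("select")
    try:
        predictive, tally = select_predictive_cluster(
            model, catalog, scene, site_filter=config.site_filter
        )
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    pmap = binarize(model, predictive)
    binary_path = out / "prospectivity.tif"
    write_raster(pmap.grid, scene, binary_path, nodata_value=255)
    artifacts["prospectivity_map"] = str(binary_path)

    # ---- score -------------------------------------------------------
    stage("score")
    try:
        cm, excluded = confusion_matrix(pmap, catalog, scene)
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc
    metrics = classification_metrics(cm)
    area = predictive_area_stats(pmap, scene.pixel_size)
    metrics_path = out / "metrics.json"
    _json_dump(
        {
            "predictive_cluster": predictive,
            "site_tally": {str(j): n for j, n in sorted(tally.items())},
            "confusion_matrix": {
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
            },
            "excluded_records": excluded,
            "metrics": metrics.as_dict(),
            "metrics_pct": metrics.as_percentages(),
            "area": area,
        },
        metrics_path,
    )
    artifacts["metrics"] = str(metrics_path)
    cm_path = out / "confusion_matrix.csv"
    cm_path.write_text(
        "cell,count\ntp,{0.tp}\nfp,{0.fp}\nfn,{0.fn}\ntn,{0.tn}\n".format(cm)
    )
    artifacts["confusion_matrix"] = str(cm_path)

    # ---- spectral profiles -------------------------------------------
    stage("profiles")
    try:
        cluster_profiles = cluster_band_summaries(scene, model)
        site_profile = site_band_summary(scene, catalog, site_filter=config.site_filter)
        similarity = profile_similarity(site_profile, cluster_profiles)
    except Exception as exc:
        raise PipelineError("profiles", str(exc)) from exc
    profiles_path = out / "profiles.csv"
    profiles_long_table([site_profile, *cluster_profiles]).to_csv(
        profiles_path, index=False
    )
    artifacts["profiles"] = str(profiles_path)
    similarity_path = out / "profile_similarity.csv"
    similarity.to_csv(similarity_path, index=False)
    artifacts["profile_similarity"] = str(similarity_path)

    # ---- band importance ---------------------------------------------
    stage("importance")
    try:
        table, flat_idx = scene.pixel_table()
        labels_flat = model.labels.ravel()[flat_idx]
        ens_config = EnsembleConfig(
            n_trees=config.n_trees,
            seed=seeds["ensemble"],
            n_pixels_subsample=config.n_pixels_subsample,
        )
        ensemble = fit_ensemble(table, labels_flat, ens_config)
        imp = permutation_importance(
            ensemble,
            table,
            labels_flat,
            seed=seeds["permutation"],
            band_names=scene.bands,
            target_clusters=(predictive,),
        )
        report = importance_report(imp, predictive_cluster_id=predictive)
    except Exception as exc:
        raise PipelineError("importance", str(exc)) from exc
    importance_path = out / "importance.csv"
    report.to_csv(importance_path, index=False)
    artifacts["importance"] = str(importance_path)

    # ---- manifest ----------------------------------------------------
    stage("manifest")
    manifest = {
        "version": __version__,
        "global_seed": config.seed,
        "derived_seeds": seeds,
        "config": {
            "k": config.k,
            "epsilon": config.epsilon,
            "max_iter": config.max_iter,
            "n_restarts": config.n_restarts,
            "standardize": config.standardize,
            "site_filter": list(config.site_filter) if config.site_filter else None,
            "n_trees": config.n_trees,
            "n_pixels_subsample": config.n_pixels_subsample,
            "aoi": list(config.aoi) if config.aoi else None,
            "oob_error": ensemble.oob_error,
        },
        "artifacts": artifacts,
        "checksums": {k: _sha256(Path(v)) for k, v in artifacts.items()},
        "predictive_cluster": predictive,
    }
    manifest_path = out / "manifest.json"
    _json_dump(manifest, manifest_path)
    for name, path in artifacts.items():
        log.info("artifact=%s path=%s sha256=%s", name, path, manifest["checksums"][name])
    return manifest
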