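"""Permutation importance of spectral bands for the clustering.

A bagged ensemble of classification trees is fit to predict cluster labels
from band values; each tree keeps its out-of-bag (OOB) index set. A band's
importance is then measured by permuting that band among each tree's OOB
cases and recording the increase in OOB misclassification error. Per band,
the per-tree error increases are averaged and divided by their standard
error (sd / sqrt(n_trees)) — the classification analog of the %IncMSE
statistic reported by classical random-forest software, where a band
carrying no information about the labels scores approximately N(0, 1).

A class-specific variant restricts the error computation to OOB cases whose
true label is a target cluster, quantifying which bands matter for telling
that one cluster (e.g. the predictive cluster) apart from the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier


class ImportanceError(Exception):
    pass


@dataclass(frozen=True)
class EnsembleConfig:
    n_trees: int = 500
    features_per_split: int | None = None  # None -> floor(sqrt(B))
    max_depth: int | None = None
    sample_fraction: float = 1.0  # bootstrap fraction, drawn with replacement
    seed: int = 0
    n_pixels_subsample: int | None = 20_000  # stratified training cap

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ImportanceError("n_trees must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ImportanceError("sample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Ensemble:
    trees: tuple[DecisionTreeClassifier, ...]
    oob_indices: tuple[np.ndarray, ...]
    classes: np.ndarray
    oob_error: float
    config: EnsembleConfig
    n_samples: int


@dataclass(frozen=True)
class ImportanceTable:
    """Per-band permutation importance, overall and per cluster.

    ``overall`` columns: band, mean_increase, sd, normalized. ``per_cluster``
    adds a cluster column with the class-restricted variant.
    """

    overall: pd.DataFrame
    per_cluster: pd.DataFrame


def _stratified_subsample(
    labels: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    n = labels.shape[0]
    if n <= cap:
        return np.arange(n)
    keep: list[np.ndarray] = []
    classes, counts = np.unique(labels, return_counts=True)
    # proportional allocation, at least one pixel per present class
    alloc = np.maximum(1, np.round(counts / n * cap).astype(int))
    for cls, take in zip(classes, alloc):
        idx = np.flatnonzero(labels == cls)
        keep.append(rng.choice(idx, size=min(take, idx.size), replace=False))
    return np.sort(np.concatenate(keep))


def fit_ensemble(
    pixels: np.ndarray, labels: np.ndarray, config: EnsembleConfig
) -> Ensemble:
    """Fit seeded bootstrap trees on (pixels, cluster labels), tracking OOB sets."""
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    if pixels.ndim != 2 or pixels.shape[0] != labels.shape[0]:
        raise ImportanceError("pixels must be (n, B) aligned with labels")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ImportanceError("need >= 2 distinct cluster labels")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA66]))
    if config.n_pixels_subsample is not None:
        keep = _stratified_subsample(labels, config.n_pixels_subsample, rng)
        pixels, labels = pixels[keep], labels[keep]
    n, b = pixels.shape
    mtry = config.features_per_split or max(1, int(np.sqrt(b)))
    if not 1 <= mtry <= b:
        raise ImportanceError(f"features_per_split must be in 1..{b}")
    n_boot = max(1, int(round(config.sample_fraction * n)))
    trees: list[DecisionTreeClassifier] = []
    oob_sets: list[np.ndarray] = []
    # per-sample OOB votes for the ensemble-level OOB error estimate
    votes = np.zeros((n, classes.size), dtype=np.int32)
    for _ in range(config.n_trees):
        boot = rng.integers(0, n, size=n_boot)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            max_depth=config.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(pixels[boot], labels[boot])
        trees.append(tree)
        oob_sets.append(oob)
        if oob.size:
            pred_pos = np.searchsorted(classes, tree.predict(pixels[oob]))
            np.add.at(votes, (oob, pred_pos), 1)
    voted = votes.sum(axis=1) > 0
    if voted.any():
        maj = classes[np.argmax(votes[voted], axis=1)]
        oob_error = float(np.mean(maj != labels[voted]))
    else:
        oob_error = float("nan")
    return Ensemble(
        trees=tuple(trees),
        oob_indices=tuple(oob_sets),
        classes=classes,
        oob_error=oob_error,
        config=config,
        n_samples=n,
    )


def _tree_errors(
    tree: DecisionTreeClassifier,
    x: np.ndarray,
    y: np.ndarray,
    class_masks: dict[int, np.ndarray],
) -> tuple[float, dict[int, float]]:
    pred = tree.predict(x)
    wrong = pred != y
    overall = float(wrong.mean()) if y.size else float("nan")
    per_class = {
        c: (float(wrong[m].mean()) if m.any() else float("nan"))
        for c, m in class_masks.items()
    }
    return overall, per_class


def permutation_importance(
    ensemble: Ensemble,
    pixels: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    band_names: tuple[str, ...] | None = None,
    target_clusters: tuple[int, ...] | None = None,
) -> ImportanceTable:
    """OOB permutation importance per band; per-cluster restricted variant.

    For each tree and band: permute the band within the tree's OOB cases,
    take (permuted error − baseline error); average over trees and divide by
    sd/sqrt(n_trees). Note the training subsample inside ``fit_ensemble``
    re-indexes cases, so pass the same (pixels, labels) given to it — the
    subsample is re-derived here from the ensemble config.
    """
    pixels = np.asarray(pixels, dtype=float)
    labels = np.asarray(labels)
    cfg = ensemble.config
    rng_fit = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBA66]))
    if cfg.n_pixels_subsample is not None:
        keep = _stratified_subsample(labels, cfg.n_pixels_subsample, rng_fit)
        pixels, labels = pixels[keep], labels[keep]
    if pixels.shape[0] != ensemble.n_samples:
        raise ImportanceError(
            "pixels/labels do not match the data the ensemble was fitted on"
        )
    n, b = pixels.shape
    if band_names is None:
        band_names = tuple(f"band_{i + 1}" for i in range(b))
    if target_clusters is None:
        target_clusters = tuple(int(c) for c in ensemble.classes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E12]))
    zero_var = [band_names[j] for j in range(b) if np.ptp(pixels[:, j]) == 0]
    if zero_var:
        warnings.warn(
            f"band(s) {zero_var} have zero variance; importance reported as 0",
            stacklevel=2,
        )
    t = len(ensemble.trees)
    diffs = np.full((t, b), np.nan)
    class_diffs = {c: np.full((t, b), np.nan) for c in target_clusters}
    for ti, (tree, oob) in enumerate(zip(ensemble.trees, ensemble.oob_indices)):
        if oob.size == 0:
            continue
        x_oob = pixels[oob]
        y_oob = labels[oob]
        masks = {c: y_oob == c for c in target_clusters}
        base, base_cls = _tree_errors(tree, x_oob, y_oob, masks)
        for j in range(b):
            if band_names[j] in zero_var:
                diffs[ti, j] = 0.0
                for c in target_clusters:
                    class_diffs[c][ti, j] = 0.0
                continue
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[rng.permutation(oob.size), j]
            perm, perm_cls = _tree_errors(tree, x_perm, y_oob, masks)
            diffs[ti, j] = perm - base
            for c in target_clusters:
                class_diffs[c][ti, j] = perm_cls[c] - base_cls[c]

    def summarize(d: np.ndarray) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(band_names):
            col = d[:, j]
            col = col[np.isfinite(col)]
            mean = float(col.mean()) if col.size else 0.0
            sd = float(col.std(ddof=1)) if col.size > 1 else 0.0
            se = sd / np.sqrt(col.size) if col.size else 0.0
            normalized = mean / se if se > 0 else (0.0 if mean == 0 else np.inf)
            rows.append(
                {
                    "band": name,
                    "mean_increase": mean,
                    "sd": sd,
                    "normalized": normalized,
                    "n_trees": int(col.size),
                }
            )
        return pd.DataFrame(rows)

    overall = summarize(diffs)
    per_cluster = pd.concat(
        [summarize(class_diffs[c]).assign(cluster=c) for c in target_clusters],
        ignore_index=True,
    )
    return ImportanceTable(overall=overall, per_cluster=per_cluster)


def importance_report(
    table: ImportanceTable, predictive_cluster_id: int | None = None
) -> pd.DataFrame:
    """Bands ranked by normalized importance (stable order on ties).

    When a predictive cluster is given, its class-specific importance is
    joined as ``cluster{id}_normalized``.
    """
    ranked = table.overall.copy()
    ranked["_pos"] = np.arange(len(ranked))
    ranked = ranked.sort_values(
        ["normalized", "_pos"], ascending=[False, True], kind="stable"
    ).drop(columns="_pos")
    if predictive_cluster_id is not None:
        sub = table.per_cluster[table.per_cluster["cluster"] == predictive_cluster_id]
        if sub.empty:
            raise ImportanceError(
                f"no per-cluster importance for cluster {predictive_cluster_id}"
            )
        ranked = ranked.merge(
            sub[["band", "normalized"]].rename(
                columns={"normalized": f"cluster{predictive_cluster_id}_normalized"}
            ),
            on="band",
        )
    return ranked.reset_index(drop=True)
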