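"""Predictive-cluster selection, binarization and classifier-style scoring.

Clustering first and then retroactively choosing the cluster that contains the
most known fossil sites ("walking back the cat") turns an unsupervised label
map into a binary prospectivity classifier: the selected cluster is the
positive class, all other clusters the negative class. Known fossil sites and
surveyed non-localities then score the map with an ordinary confusion matrix:

    TP  fossil sites on the predictive cluster
    FP  non-localities on the predictive cluster
    FN  fossil sites on any other cluster
    TN  non-localities on any other cluster

Records flagged non-verifiable (field-recorded NA) and records outside the
scene are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import ClusterModel
from .raster_io import (
    OUTSIDE,
    SiteCatalog,
    SpectralScene,
    site_to_pixel,
)


class ProspectivityError(Exception):
    pass


#: Sentinel for metrics whose denominator is zero.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ProspectivityMap:
    """Binary map: 1 on the predictive cluster, 0 elsewhere, 0-masked nodata."""

    grid: np.ndarray
    predictive_cluster_id: int
    nodata_mask: np.ndarray

    @property
    def n_positive_pixels(self) -> int:
        return int(np.count_nonzero(self.grid[~self.nodata_mask] == 1))

    @property
    def n_total_pixels(self) -> int:
        return int(np.count_nonzero(~self.nodata_mask))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ProspectivityError("confusion-matrix cells must be >= 0")

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Five standard binary-classification metrics, NaN when undefined."""

    accuracy: float
    precision: float
    npv: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "npv": self.npv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def as_percentages(self, decimals: int = 2) -> dict[str, float]:
        """Percent-scale report rounded for display (internals stay exact)."""
        return {
            name: (round(100.0 * v, decimals) if np.isfinite(v) else UNDEFINED)
            for name, v in self.as_dict().items()
        }


def site_cluster_tally(
    model: ClusterModel,
    catalog: SiteCatalog,
    scene: SpectralScene,
    site_filter: Sequence[str] | None = None,
) -> dict[int, int]:
    """Count verifiable fossil-bearing sites per cluster (in-scene only)."""
    filtered = catalog.filter(
        categories=site_filter, fossil_bearing=True, verifiable_only=True
    )
    tally = {j: 0 for j in range(1, model.k + 1)}
    for rec in filtered.records:
        loc = site_to_pixel(rec, scene)
        if loc == OUTSIDE:
            continue
        label = int(model.labels[loc])
        if label >= 1:
            tally[label] += 1
    return tally


def select_predictive_cluster(
    model: ClusterModel,
    catalog: SiteCatalog,
    scene: SpectralScene,
    site_filter: Sequence[str] | None = None,
) -> tuple[int, dict[int, int]]:
    """Choose the cluster holding the most fossil-bearing sites.

    Ties break toward the higher centroid NIR value (NIR being the most
    fossil-indicative band), then the lower cluster id; returns
    (predictive_cluster_id, per-cluster tally).
    """
    tally = site_cluster_tally(model, catalog, scene, site_filter)
    if sum(tally.values()) == 0:
        raise ProspectivityError(
            "no verifiable fossil-bearing site falls inside the scene"
        )
    best = max(tally.values())
    tied = [j for j, c in tally.items() if c == best]
    if len(tied) == 1:
        return tied[0], tally
    if "nir" in model.bands:
        nir = model.bands.index("nir")
        tied.sort(key=lambda j: (-model.centroids[j - 1, nir], j))
    return tied[0], tally


def binarize(model: ClusterModel, predictive_cluster_id: int) -> ProspectivityMap:
    """Merge all non-predictive clusters into the negative class."""
    if not 1 <= predictive_cluster_id <= model.k:
        raise ProspectivityError(
            f"cluster id {predictive_cluster_id} outside 1..{model.k}"
        )
    nodata = model.labels == 0
    grid = (model.labels == predictive_cluster_id).astype(np.uint8)
    grid[nodata] = 0
    return ProspectivityMap(
        grid=grid, predictive_cluster_id=predictive_cluster_id, nodata_mask=nodata
    )


def confusion_matrix(
    pmap: ProspectivityMap,
    catalog: SiteCatalog,
    scene: SpectralScene,
) -> tuple[ConfusionMatrix, list[str]]:
    """Score verifiable records against the binary map.

    Returns the matrix plus the ids of records excluded for falling outside
    the scene (non-verifiable records are silently excluded by contract).
    """
    if len(catalog) == 0:
        raise ProspectivityError("empty site catalog")
    tp = fp = fn = tn = 0
    excluded: list[str] = []
    scored = 0
    for rec in catalog.records:
        if not rec.verifiable:
            continue
        loc = site_to_pixel(rec, scene)
        if loc == OUTSIDE or pmap.nodata_mask[loc]:
            excluded.append(rec.site_id)
            continue
        positive = pmap.grid[loc] == 1
        scored += 1
        if rec.fossil_bearing:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    if scored == 0:
        raise ProspectivityError("no scorable records (all NA or outside scene)")
    return ConfusionMatrix(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn)), excluded


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision (PPV), NPV, sensitivity and specificity."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else UNDEFINED

    return MetricsReport(
        accuracy=ratio(cm.tp + cm.tn, cm.n_scored),
        precision=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
    )


def predictive_area_stats(
    pmap: ProspectivityMap, pixel_size: float
) -> dict[str, float]:
    """Positive-pixel count, fraction of the mapped area, and km^2 footprint."""
    if not pixel_size > 0:
        raise ProspectivityError("pixel_size must be positive")
    n_pos = pmap.n_positive_pixels
    n_tot = pmap.n_total_pixels
    return {
        "n_positive": float(n_pos),
        "n_total": float(n_tot),
        "fraction": n_pos / n_tot if n_tot else UNDEFINED,
        "area_km2": n_pos * pixel_size**2 / 1e6,
    }
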