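"""Synthetic multispectral scenes and site catalogs with known ground truth.

Emulates the statistical structure of the study setting — a 200 x 200 grid of
30 m pixels (a 6 x 6 km area of interest, 40,000 pixels) in seven Landsat-like
bands, drawn from eight land-cover classes with distinct spectral signatures —
so every pipeline stage can be exercised and checked against planted truth.

Class signatures are Gaussian with diagonal covariance on a surface-reflectance
0-1 scale. Class 1 plays the fossiliferous role (eroded outcrop / exposed
sediment: bright, with high NIR and SWIR response) and occupies ~4.5% of the
scene by default, mirroring the footprint of the study's predictive cluster.
Fossil sites land inside that class with probability ``p_site_in_class``
(default 15/17, the study's digital-validation hit rate); non-localities are
placed uniformly over the scene. The spatial layout is either iid per pixel
or "blocky" (contiguous square patches), approximating land-cover patchiness;
no pipeline stage exploits spatial autocorrelation, so this is sufficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .raster_io import (
    DEFAULT_BANDS,
    SiteCatalog,
    SiteRecord,
    SpectralScene,
    write_raster,
    write_scene,
    write_site_catalog,
)


class SyntheticError(Exception):
    pass


# Landsat-like surface-reflectance signatures for eight land covers
# (ultrablue, blue, green, red, nir, swir1, swir2). Class 1 = eroded
# outcrop / exposed sediment, the fossiliferous role.
DEFAULT_CLASS_MEANS = np.array(
    [
        [0.13, 0.15, 0.20, 0.26, 0.45, 0.52, 0.42],  # outcrop / exposed sediment
        [0.04, 0.05, 0.08, 0.06, 0.30, 0.22, 0.12],  # miombo woodland
        [0.03, 0.04, 0.06, 0.04, 0.35, 0.16, 0.07],  # riparian forest
        [0.06, 0.08, 0.12, 0.14, 0.28, 0.30, 0.20],  # grassland / savanna
        [0.07, 0.09, 0.11, 0.12, 0.18, 0.20, 0.14],  # floodplain wet soil
        [0.06, 0.07, 0.08, 0.05, 0.03, 0.02, 0.01],  # open water
        [0.04, 0.05, 0.06, 0.07, 0.10, 0.13, 0.15],  # burned area
        [0.10, 0.12, 0.16, 0.20, 0.30, 0.38, 0.33],  # bare alluvium / sand
    ]
)

DEFAULT_CLASS_WEIGHTS = np.array(
    [0.045, 0.25, 0.15, 0.20, 0.12, 0.05, 0.085, 0.10]
)

DEFAULT_BAND_SD = 0.012


@dataclass(frozen=True)
class SceneSpec:
    """Generator settings for one synthetic scene."""

    n_rows: int = 200
    n_cols: int = 200
    pixel_size: float = 30.0
    bands: tuple[str, ...] = DEFAULT_BANDS
    class_means: np.ndarray = field(default_factory=lambda: DEFAULT_CLASS_MEANS.copy())
    class_sds: np.ndarray | float = DEFAULT_BAND_SD
    class_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_WEIGHTS.copy()
    )
    layout: str = "blocky"  # {"iid", "blocky"}
    block_size: int = 10
    fossiliferous_class: int = 1
    origin_easting: float = 600_000.0
    origin_northing: float = 7_900_000.0
    crs_tag: str = "UTM zone 36S / WGS84 (synthetic)"
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.class_means, dtype=float))
        if len(np.unique(means, axis=0)) != means.shape[0]:
            raise SyntheticError("class mean vectors must be distinct")
        if means.shape[1] != len(self.bands):
            raise SyntheticError("class means do not match band count")
        sds = np.broadcast_to(
            np.asarray(self.class_sds, dtype=float), means.shape
        )
        if not (sds > 0).all():
            raise SyntheticError("class band sds (covariances) must be positive")
        weights = np.asarray(self.class_weights, dtype=float)
        if weights.shape[0] != means.shape[0] or (weights < 0).any():
            raise SyntheticError("invalid class weights")
        if not 1 <= self.fossiliferous_class <= means.shape[0]:
            raise SyntheticError("fossiliferous_class outside 1..n_classes")
        if self.layout not in ("iid", "blocky"):
            raise SyntheticError(f"unknown layout {self.layout!r}")
        object.__setattr__(self, "class_means", means)
        object.__setattr__(self, "class_sds", sds.copy())
        object.__setattr__(self, "class_weights", weights / weights.sum())

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]


@dataclass(frozen=True)
class SiteSpec:
    """Planted site-catalog settings (defaults mirror the study's catalog)."""

    n_fossil_sites: int = 17
    n_non_localities: int = 74
    p_site_in_class: float = 15.0 / 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_site_in_class <= 1:
            raise SyntheticError("p_site_in_class must be in [0, 1]")
        if min(self.n_fossil_sites, self.n_non_localities) < 0:
            raise SyntheticError("site counts must be >= 0")


def generate_scene(spec: SceneSpec) -> tuple[SpectralScene, np.ndarray]:
    """Draw a scene and its true class-label grid (1..n_classes)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5CE9]))
    shape = (spec.n_rows, spec.n_cols)
    if spec.layout == "iid":
        classes = rng.choice(spec.n_classes, size=shape, p=spec.class_weights)
    else:
        bs = spec.block_size
        br = -(-spec.n_rows // bs)
        bc = -(-spec.n_cols // bs)
        block_classes = rng.choice(spec.n_classes, size=(br, bc), p=spec.class_weights)
        classes = np.repeat(np.repeat(block_classes, bs, axis=0), bs, axis=1)
        classes = classes[: spec.n_rows, : spec.n_cols]
    noise = rng.standard_normal(shape + (len(spec.bands),))
    values = spec.class_means[classes] + noise * spec.class_sds[classes]
    scene = SpectralScene(
        values=values,
        bands=spec.bands,
        origin_easting=spec.origin_easting,
        origin_northing=spec.origin_northing,
        pixel_size=spec.pixel_size,
        crs_tag=spec.crs_tag,
    )
    return scene, classes.astype(np.int64) + 1


# category mix for planted fossil sites, cycled in order (variety as in a
# real locality register: mostly vertebrate+invertebrate localities, some
# invertebrate-only, fossil wood and single finds)
_FOSSIL_CATEGORY_CYCLE = (
    "vertebrate_invertebrate",
    "vertebrate_invertebrate",
    "invertebrate",
    "vertebrate_invertebrate",
    "fossil_wood",
    "vertebrate_invertebrate",
    "single_vertebrate",
)


def _cell_coords(
    rows: np.ndarray,
    cols: np.ndarray,
    scene_origin: tuple[float, float],
    pixel_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    # jitter strictly inside the open cell so the half-open edge rule is moot
    je = rng.uniform(1e-3, 1 - 1e-3, size=rows.shape)
    jn = rng.uniform(1e-3, 1 - 1e-3, size=rows.shape)
    easting = scene_origin[0] + (cols + je) * pixel_size
    northing = scene_origin[1] - (rows + jn) * pixel_size
    return easting, northing


def plant_sites(
    true_labels: np.ndarray,
    spec: SiteSpec,
    origin_easting: float,
    origin_northing: float,
    pixel_size: float = 30.0,
    fossiliferous_class: int = 1,
) -> SiteCatalog:
    """Plant fossil sites and non-localities with known class association.

    Each fossil site lands in a uniformly chosen fossiliferous-class pixel
    with probability ``p_site_in_class``, else in a uniformly chosen pixel of
    any other class; non-localities are uniform over all pixels. Coordinates
    are jittered inside their cell.
    """
    true_labels = np.asarray(true_labels)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x517E]))
    in_rows, in_cols = np.nonzero(true_labels == fossiliferous_class)
    out_rows, out_cols = np.nonzero(true_labels != fossiliferous_class)
    if spec.n_fossil_sites > 0:
        if in_rows.size == 0 and spec.p_site_in_class > 0:
            raise SyntheticError("fossiliferous class occupies no pixel")
        if out_rows.size == 0 and spec.p_site_in_class < 1:
            raise SyntheticError("no non-fossiliferous pixel to place misses on")
    records: list[SiteRecord] = []
    hits = rng.random(spec.n_fossil_sites) < spec.p_site_in_class
    for i, hit in enumerate(hits):
        pool_r, pool_c = (in_rows, in_cols) if hit else (out_rows, out_cols)
        pick = rng.integers(pool_r.size)
        e, n = _cell_coords(
            np.array([pool_r[pick]]),
            np.array([pool_c[pick]]),
            (origin_easting, origin_northing),
            pixel_size,
            rng,
        )
        records.append(
            SiteRecord(
                site_id=f"SYN-GPL-{i + 1}",
                easting=float(e[0]),
                northing=float(n[0]),
                category=_FOSSIL_CATEGORY_CYCLE[i % len(_FOSSIL_CATEGORY_CYCLE)],
                verifiable=True,
            )
        )
    n_rows, n_cols = true_labels.shape
    for i in range(spec.n_non_localities):
        r = rng.integers(n_rows)
        c = rng.integers(n_cols)
        e, n = _cell_coords(
            np.array([r]),
            np.array([c]),
            (origin_easting, origin_northing),
            pixel_size,
            rng,
        )
        records.append(
            SiteRecord(
                site_id=f"SYN-NEG-{i + 1}",
                easting=float(e[0]),
                northing=float(n[0]),
                category="non_locality",
                verifiable=True,
            )
        )
    return SiteCatalog(tuple(records), provenance="synthetic")


def end_to_end_fixture(
    out_dir: str | Path,
    scene_spec: SceneSpec | None = None,
    site_spec: SiteSpec | None = None,
) -> dict[str, str]:
    """Write a self-contained bundle: scene GeoTIFF, catalog CSV, truth JSON.

    Returns a dict of artifact paths. The truth JSON records the planted
    parameters and per-class pixel fractions for downstream assertions.
    """
    scene_spec = scene_spec or SceneSpec()
    site_spec = site_spec or SiteSpec(seed=scene_spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene, truth = generate_scene(scene_spec)
    catalog = plant_sites(
        truth,
        site_spec,
        scene_spec.origin_easting,
        scene_spec.origin_northing,
        scene_spec.pixel_size,
        scene_spec.fossiliferous_class,
    )
    paths = {
        "scene": str(out_dir / "scene.tif"),
        "sites": str(out_dir / "sites.csv"),
        "true_labels": str(out_dir / "true_labels.tif"),
        "truth": str(out_dir / "truth.json"),
    }
    write_scene(scene, paths["scene"])
    write_site_catalog(catalog, paths["sites"])
    write_raster(truth, scene, paths["true_labels"])
    counts = np.bincount(truth.ravel(), minlength=scene_spec.n_classes + 1)[1:]
    truth_meta = {
        "n_classes": scene_spec.n_classes,
        "fossiliferous_class": scene_spec.fossiliferous_class,
        "class_fractions": (counts / truth.size).tolist(),
        "p_site_in_class": site_spec.p_site_in_class,
        "n_fossil_sites": site_spec.n_fossil_sites,
        "n_non_localities": site_spec.n_non_localities,
        "scene_seed": scene_spec.seed,
        "site_seed": site_spec.seed,
        "layout": scene_spec.layout,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_meta, fh, indent=2)
    return paths
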