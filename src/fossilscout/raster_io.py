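"""Multiband raster and site-catalog I/O with point-in-pixel geolocation.

Scenes are north-up regular grids in a projected CRS (meters). Georeferencing
follows the GeoTIFF convention: the tie point anchors the *outer* corner of the
top-left pixel, so easting grows with column index and northing decreases with
row index. Files are plain GeoTIFFs (georeference in ModelPixelScaleTag /
ModelTiepointTag); band names, nodata value and CRS label travel in the
ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

DEFAULT_BANDS = ("ultrablue", "blue", "green", "red", "nir", "swir1", "swir2")

SITE_CATEGORIES = (
    "vertebrate_invertebrate",
    "invertebrate",
    "fossil_wood",
    "single_vertebrate",
    "non_locality",
)
FOSSIL_BEARING_CATEGORIES = frozenset(SITE_CATEGORIES[:-1])

#: Sentinel returned by :func:`site_to_pixel` for points beyond the scene extent.
OUTSIDE = "OUTSIDE"

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


class RasterIOError(Exception):
    """Raised for malformed rasters, missing bands, or bad catalogs."""


@dataclass(frozen=True)
class SpectralScene:
    """A georeferenced grid of pixels with B spectral band values each.

    ``values`` has shape (n_rows, n_cols, B); ``nodata_mask`` is True where a
    pixel carries no data. ``origin_easting``/``origin_northing`` give the outer
    (north-west) corner of pixel (0, 0); ``pixel_size`` is in meters.
    """

    values: np.ndarray
    bands: tuple[str, ...]
    origin_easting: float
    origin_northing: float
    pixel_size: float = 30.0
    crs_tag: str = "unspecified"
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.shape[2] < 1:
            raise RasterIOError(
                f"scene values must be (rows, cols, bands), got shape {values.shape}"
            )
        if len(self.bands) != values.shape[2]:
            raise RasterIOError(
                f"{len(self.bands)} band names for {values.shape[2]} band planes"
            )
        if not self.pixel_size > 0:
            raise RasterIOError("pixel_size must be positive")
        mask = self.nodata_mask
        if mask is None:
            mask = np.zeros(values.shape[:2], dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != values.shape[:2]:
                raise RasterIOError("nodata_mask shape does not match grid")
        if not np.isfinite(values[~mask]).all():
            raise RasterIOError("non-finite band values outside the nodata mask")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "nodata_mask", mask)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_easting, min_northing, max_easting, max_northing)."""
        return (
            self.origin_easting,
            self.origin_northing - self.n_rows * self.pixel_size,
            self.origin_easting + self.n_cols * self.pixel_size,
            self.origin_northing,
        )

    def pixel_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Unmasked pixels as an (n, B) array plus their flat grid indices."""
        flat_mask = ~self.nodata_mask.ravel()
        table = self.values.reshape(-1, self.n_bands)[flat_mask]
        return table, np.flatnonzero(flat_mask)


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    easting: float
    northing: float
    category: str
    verifiable: bool = True

    def __post_init__(self) -> None:
        if self.category not in SITE_CATEGORIES:
            raise RasterIOError(
                f"unknown site category {self.category!r}; "
                f"allowed: {', '.join(SITE_CATEGORIES)}"
            )

    @property
    def fossil_bearing(self) -> bool:
        return self.category in FOSSIL_BEARING_CATEGORIES


@dataclass(frozen=True)
class SiteCatalog:
    records: tuple[SiteRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.site_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RasterIOError(f"duplicate site_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def filter(
        self,
        categories: Sequence[str] | None = None,
        fossil_bearing: bool | None = None,
        verifiable_only: bool = False,
    ) -> "SiteCatalog":
        recs = self.records
        if categories is not None:
            allowed = set(categories)
            unknown = allowed - set(SITE_CATEGORIES)
            if unknown:
                raise RasterIOError(f"unknown categories in filter: {sorted(unknown)}")
            recs = tuple(r for r in recs if r.category in allowed)
        if fossil_bearing is not None:
            recs = tuple(r for r in recs if r.fossil_bearing == fossil_bearing)
        if verifiable_only:
            recs = tuple(r for r in recs if r.verifiable)
        return SiteCatalog(recs, provenance=self.provenance)


def _scene_description(scene: SpectralScene, nodata_value: float) -> str:
    return json.dumps(
        {
            "bands": list(scene.bands),
            "crs": scene.crs_tag,
            "nodata": nodata_value,
        }
    )


def _geotiff_extratags(
    origin_easting: float, origin_northing: float, pixel_size: float
) -> list[tuple]:
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (pixel_size, pixel_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, origin_easting, origin_northing, 0.0),
        ),
    ]


def write_scene(scene: SpectralScene, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write a multiband georeferenced GeoTIFF readable by :func:`load_scene`."""
    data = np.moveaxis(scene.values.astype(np.float64), 2, 0).copy()
    data[:, scene.nodata_mask] = nodata_value
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=_scene_description(scene, nodata_value),
        extratags=_geotiff_extratags(
            scene.origin_easting, scene.origin_northing, scene.pixel_size
        ),
    )


def write_raster(
    grid: np.ndarray,
    scene: SpectralScene,
    path: str | Path,
    nodata_value: int | float = 0,
) -> None:
    """Write a single-band grid (e.g. labels, binary map) on a scene's grid."""
    grid = np.asarray(grid)
    if grid.shape != (scene.n_rows, scene.n_cols):
        raise RasterIOError("grid shape does not match scene grid")
    out = grid.copy()
    out[scene.nodata_mask] = nodata_value
    tifffile.imwrite(
        str(path),
        out,
        photometric="minisblack",
        description=json.dumps(
            {"bands": ["value"], "crs": scene.crs_tag, "nodata": nodata_value}
        ),
        extratags=_geotiff_extratags(
            scene.origin_easting, scene.origin_northing, scene.pixel_size
        ),
    )


def _read_georeference(page: "tifffile.TiffPage") -> tuple[float, float, float]:
    tags = page.tags
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise RasterIOError("raster has no GeoTIFF georeference tags")
    scale = tags[_TAG_MODEL_PIXEL_SCALE].value
    tie = tags[_TAG_MODEL_TIEPOINT].value
    sx, sy = float(scale[0]), float(scale[1])
    if sx <= 0 or sy <= 0 or not math.isclose(sx, sy, rel_tol=1e-9):
        raise RasterIOError(f"unsupported non-square pixel scale {scale[:2]}")
    i, j = float(tie[0]), float(tie[1])
    # Tie point may anchor any raster position; shift to the (0, 0) corner.
    origin_e = float(tie[3]) - j * sx
    origin_n = float(tie[4]) + i * sy
    return origin_e, origin_n, sx


def load_scene(
    path: str | Path, band_order: Sequence[str] | None = None
) -> SpectralScene:
    """Read a multiband GeoTIFF, optionally selecting/reordering bands by name.

    Band names come from the file's JSON ImageDescription if present, else
    default to ``band_1..band_B``. A requested name absent from the file raises
    a named-band error; a missing georeference raises.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        origin_e, origin_n, pix = _read_georeference(page)
        data = tif.asarray()
        meta: dict = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    if data.ndim != 3:
        raise RasterIOError(f"unsupported raster dimensionality {data.ndim}")
    # Accept both planar (B, rows, cols) and interleaved (rows, cols, B) layouts;
    # band-name metadata disambiguates, else planar (this module's format) is assumed.
    meta_bands = meta.get("bands")
    if meta_bands is not None:
        if data.shape[0] != len(meta_bands) and data.shape[2] == len(meta_bands):
            data = np.moveaxis(data, 2, 0)
    elif data.shape[0] > data.shape[2] and data.shape[2] <= 16:
        data = np.moveaxis(data, 2, 0)
    n_bands = data.shape[0]
    file_bands = meta_bands or [f"band_{i + 1}" for i in range(n_bands)]
    if len(file_bands) != n_bands:
        raise RasterIOError("band-name metadata does not match band count")
    nodata = meta.get("nodata")
    values = np.moveaxis(data, 0, 2).astype(float)
    if band_order is not None:
        missing = [b for b in band_order if b not in file_bands]
        if missing:
            raise RasterIOError(
                f"band(s) {missing} not present in {path.name}; has {file_bands}"
            )
        idx = [file_bands.index(b) for b in band_order]
        values = values[:, :, idx]
        file_bands = list(band_order)
    mask = np.zeros(values.shape[:2], dtype=bool)
    if nodata is not None:
        mask |= np.any(values == nodata, axis=2)
    mask |= ~np.isfinite(values).all(axis=2)
    values = values.copy()
    values[mask] = 0.0
    return SpectralScene(
        values=values,
        bands=tuple(file_bands),
        origin_easting=origin_e,
        origin_northing=origin_n,
        pixel_size=pix,
        crs_tag=str(meta.get("crs", "unspecified")),
        nodata_mask=mask,
    )


def load_label_grid(path: str | Path) -> np.ndarray:
    """Read back a single-band raster written by :func:`write_raster`."""
    scene = load_scene(path)
    return scene.values[:, :, 0]


def crop_to_aoi(
    scene: SpectralScene,
    min_easting: float,
    min_northing: float,
    max_easting: float,
    max_northing: float,
) -> SpectralScene:
    """Crop to every pixel whose cell has positive-area overlap with the AOI."""
    if min_easting >= max_easting or min_northing >= max_northing:
        raise RasterIOError("degenerate AOI rectangle")
    s = scene.pixel_size
    oe, on = scene.origin_easting, scene.origin_northing
    # cell c spans [oe + c*s, oe + (c+1)*s); keep cells overlapping the AOI interior
    c0 = max(0, math.floor((min_easting - oe) / s))
    c1 = min(scene.n_cols, math.ceil((max_easting - oe) / s))
    r0 = max(0, math.floor((on - max_northing) / s))
    r1 = min(scene.n_rows, math.ceil((on - min_northing) / s))
    if c0 >= c1 or r0 >= r1:
        raise RasterIOError("AOI does not intersect the scene extent")
    return replace(
        scene,
        values=scene.values[r0:r1, c0:c1].copy(),
        nodata_mask=scene.nodata_mask[r0:r1, c0:c1].copy(),
        origin_easting=oe + c0 * s,
        origin_northing=on - r0 * s,
    )


def site_to_pixel(
    site: SiteRecord | tuple[float, float], scene: SpectralScene
) -> tuple[int, int] | str:
    """Locate the grid cell containing a point; ``OUTSIDE`` beyond the extent.

    Half-open cells: (r, c) covers [oe + c*s, oe + (c+1)*s) in easting and
    (on - (r+1)*s, on - r*s] in northing, so a point on a shared edge belongs
    to the cell to its east/south.
    """
    if isinstance(site, SiteRecord):
        e, n = site.easting, site.northing
    else:
        e, n = site
    s = scene.pixel_size
    col = math.floor((e - scene.origin_easting) / s)
    row = math.floor((scene.origin_northing - n) / s)
    if 0 <= row < scene.n_rows and 0 <= col < scene.n_cols:
        return int(row), int(col)
    return OUTSIDE


def read_site_catalog(path: str | Path) -> SiteCatalog:
    """Read a site catalog CSV (site_id, easting, northing, category, verifiable)."""
    df = pd.read_csv(path)
    required = {"site_id", "easting", "northing", "category", "verifiable"}
    missing = required - set(df.columns)
    if missing:
        raise RasterIOError(f"site catalog missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        verifiable = row.verifiable
        if isinstance(verifiable, str):
            verifiable = verifiable.strip().lower() in ("true", "1", "yes")
        records.append(
            SiteRecord(
                site_id=str(row.site_id),
                easting=float(row.easting),
                northing=float(row.northing),
                category=str(row.category),
                verifiable=bool(verifiable),
            )
        )
    return SiteCatalog(tuple(records), provenance=str(path))


def write_site_catalog(catalog: SiteCatalog, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "easting": r.easting,
                "northing": r.northing,
                "category": r.category,
                "verifiable": r.verifiable,
            }
            for r in catalog.records
        ]
    ).to_csv(path, index=False)
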