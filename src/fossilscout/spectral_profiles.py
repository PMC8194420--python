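"""Per-cluster spectral summaries and comparison against fossil-site pixels.

Summarizes each cluster's per-band brightness distribution (the data behind a
violin/box display) and computes the same summary for the pixels containing
known fossil sites, so "which cluster looks most like the fossil sites" can
be answered by a scalar discrepancy instead of by eye. The discrepancy used
is the median across bands of the absolute difference of per-band medians —
a robust formalization of the visual comparison; it is an artifact of this
package, not a field-standard statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .raster_io import OUTSIDE, SiteCatalog, SpectralScene, site_to_pixel


class ProfileError(Exception):
    pass


_STATS = ("min", "q1", "median", "q3", "max", "mean")


@dataclass(frozen=True)
class BandSummary:
    """Order statistics and mean per band for one group of pixels.

    ``group`` is a cluster id (int) or the string "fossil_sites"; ``table``
    is indexed by band with columns min, q1, median, q3, max, mean; ``n`` is
    the number of pixels summarized. Quantiles use linear interpolation
    between order statistics (numpy default, type 7).
    """

    group: int | str
    table: pd.DataFrame
    n: int


def _summarize(values: np.ndarray, bands: Sequence[str], group) -> BandSummary:
    if values.shape[0] == 0:
        raise ProfileError(f"no pixels to summarize for group {group!r}")
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    table = pd.DataFrame(
        {
            "min": q[0],
            "q1": q[1],
            "median": q[2],
            "q3": q[3],
            "max": q[4],
            "mean": values.mean(axis=0),
        },
        index=pd.Index(bands, name="band"),
    )
    return BandSummary(group=group, table=table, n=values.shape[0])


def cluster_band_summaries(
    scene: SpectralScene, model: ClusterModel
) -> list[BandSummary]:
    """One summary per non-empty cluster over its unmasked member pixels."""
    out = []
    for j in range(1, model.k + 1):
        member = (model.labels == j) & ~scene.nodata_mask
        if not member.any():
            warnings.warn(f"cluster {j} is empty; omitted from profiles", stacklevel=2)
            continue
        out.append(_summarize(scene.values[member], scene.bands, j))
    return out


def site_band_summary(
    scene: SpectralScene,
    catalog: SiteCatalog,
    site_filter: Sequence[str] | None = None,
) -> BandSummary:
    """Summary over the band values of pixels containing filtered fossil sites."""
    filtered = catalog.filter(
        categories=site_filter, fossil_bearing=True, verifiable_only=False
    )
    rows = []
    for rec in filtered.records:
        loc = site_to_pixel(rec, scene)
        if loc == OUTSIDE or scene.nodata_mask[loc]:
            continue
        rows.append(scene.values[loc])
    if not rows:
        raise ProfileError("no in-scene fossil sites after filtering")
    return _summarize(np.asarray(rows), scene.bands, "fossil_sites")


def profile_similarity(
    site_summary: BandSummary, cluster_summaries: Sequence[BandSummary]
) -> pd.DataFrame:
    """Rank clusters by median absolute difference of per-band medians.

    Lowest discrepancy first; exact ties break toward the lower cluster id.
    Returns a frame with cluster, discrepancy, rank, plus one column of
    absolute median differences per band.
    """
    site_bands = tuple(site_summary.table.index)
    rows = []
    for cs in cluster_summaries:
        if tuple(cs.table.index) != site_bands:
            raise ProfileError(
                f"band list of cluster {cs.group} does not match site summary"
            )
        diffs = (cs.table["median"] - site_summary.table["median"]).abs()
        rows.append(
            {
                "cluster": cs.group,
                "discrepancy": float(diffs.median()),
                **{f"absdiff_{b}": float(diffs[b]) for b in site_bands},
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["discrepancy", "cluster"], kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def profiles_long_table(
    summaries: Sequence[BandSummary],
) -> pd.DataFrame:
    """Long-format export: group, band, statistic, value (plot-ready)."""
    rows = []
    for s in summaries:
        for band, rec in s.table.iterrows():
            for stat in _STATS:
                rows.append(
                    {
                        "group": s.group,
                        "band": band,
                        "statistic": stat,
                        "value": float(rec[stat]),
                    }
                )
    return pd.DataFrame(rows)
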