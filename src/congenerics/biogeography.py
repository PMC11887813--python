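"""Biogeographic clustering and habitat summaries of occurrence records.

Georeferenced genus detections are clustered with DBSCAN under the
great-circle metric: with ``min_pts=1`` (the default, so no record is left
as noise) the clusters are exactly the connected components of the graph
joining sites at most ``d_max_km`` apart.  Typical radii are 300 km for a
global view and 25 km for regional detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "cluster_sites",
    "summarize_clusters",
    "habitat_frequencies",
    "summarize_physicochemical",
    "HabitatSummary",
    "PhysicoSummary",
]


def _check_coords(lat: float, lon: float) -> None:
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} outside [-180, 180]")


def great_circle_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points
    in degrees, on a sphere of radius 6371.0088 km (IUGG mean)."""
    _check_coords(*a)
    _check_coords(*b)
    lat1, lon1, lat2, lon2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    s = (math.sin((lat2 - lat1) / 2.0) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def cluster_sites(records: pd.DataFrame, d_max_km: float,
                  min_pts: int = 1) -> pd.DataFrame:
    """Cluster sites by DBSCAN under the great-circle metric.

    ``records`` needs columns site_id, latitude, longitude (several
    occurrence rows may share a site_id; clustering operates on the
    distinct sites).  Returns a frame with columns site_id and
    cluster_label.  With ``min_pts=1`` every site is a core point, labels
    are contiguous from 0 and equal the connected components of the
    <= d_max_km adjacency graph; with larger ``min_pts`` noise sites get
    label -1.  Cluster labels are ordered by ascending (min latitude,
    min longitude) of their members for determinism.
    """
    if d_max_km <= 0:
        raise ValueError("d_max_km must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if records.empty:
        return pd.DataFrame(columns=["site_id", "cluster_label"])

    sites = records.drop_duplicates("site_id")[
        ["site_id", "latitude", "longitude"]].reset_index(drop=True)
    for lat, lon in zip(sites["latitude"], sites["longitude"]):
        _check_coords(lat, lon)

    coords = np.radians(sites[["latitude", "longitude"]].to_numpy(float))
    labels = DBSCAN(eps=d_max_km / EARTH_RADIUS_KM, min_samples=min_pts,
                    metric="haversine").fit_predict(coords)

    out = sites.assign(cluster_label=labels)
    out["cluster_label"] = _relabel(out)
    return out[["site_id", "cluster_label"]]


def _relabel(assign: pd.DataFrame) -> np.ndarray:
    """Map raw DBSCAN labels to 0..k-1 by (min lat, min lon) of members."""
    keys = (assign[assign["cluster_label"] >= 0]
            .groupby("cluster_label")[["latitude", "longitude"]].min()
            .sort_values(["latitude", "longitude"]))
    mapping = {old: new for new, old in enumerate(keys.index)}
    mapping[-1] = -1
    return assign["cluster_label"].map(mapping).to_numpy()


def summarize_clusters(records: pd.DataFrame,
                       assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster site count, occurrence count and per-genus counts."""
    merged = records.merge(assignment, on="site_id", how="left")
    if merged["cluster_label"].isna().any():
        raise ValueError("assignment does not cover all records")
    rows = []
    for label, grp in merged.groupby("cluster_label"):
        row = {
            "cluster_label": int(label),
            "n_sites": grp["site_id"].nunique(),
            "n_occurrences": len(grp),
        }
        for genus, cnt in grp["genus"].value_counts().items():
            row[f"genus:{genus}"] = int(cnt)
        rows.append(row)
    return (pd.DataFrame(rows).fillna(0)
            .sort_values("cluster_label").reset_index(drop=True))


@dataclass
class HabitatSummary:
    frequencies: pd.DataFrame  # genus x habitat, rows sum to 1
    n_missing: pd.Series       # records lacking habitat, per genus


def habitat_frequencies(records: pd.DataFrame) -> HabitatSummary:
    """Relative habitat detection frequency per genus.

    Records with missing habitat are excluded from the frequencies but
    counted in ``n_missing``.
    """
    missing = records["habitat"].isna()
    n_missing = records.loc[missing].groupby("genus").size().reindex(
        records["genus"].unique(), fill_value=0)
    counts = (records.loc[~missing]
              .groupby(["genus", "habitat"]).size().unstack(fill_value=0))
    freq = counts.div(counts.sum(axis=1), axis=0)
    return HabitatSummary(frequencies=freq, n_missing=n_missing)


@dataclass
class PhysicoSummary:
    n: int
    quantiles: dict[str, float]  # min, q25, median, q75, max
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def summarize_physicochemical(records: pd.DataFrame,
                              parameters: list[str] | None = None,
                              bins: int = 10) -> dict[str, PhysicoSummary]:
    """Distribution summary (n, quantiles, histogram) per parameter,
    ignoring missing values; an all-missing parameter yields n=0."""
    if parameters is None:
        known = ["sulfate_mM", "salinity", "oxygen", "temperature_C"]
        parameters = [p for p in known if p in records.columns]
    out: dict[str, PhysicoSummary] = {}
    for param in parameters:
        vals = pd.to_numeric(records[param], errors="coerce").dropna().to_numpy()
        if vals.size == 0:
            out[param] = PhysicoSummary(0, {}, np.array([]), np.array([]))
            continue
        q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
        counts, edges = np.histogram(vals, bins=bins)
        out[param] = PhysicoSummary(
            n=int(vals.size),
            quantiles={"min": q[0], "q25": q[1], "median": q[2],
                       "q75": q[3], "max": q[4]},
            hist_counts=counts, hist_edges=edges,
        )
    return out
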