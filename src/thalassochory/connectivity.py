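"""Inter-island connectivity from surface-drifter trajectories.

The estimator treats satellite-tracked surface drifters as proxies for
passively floating propagules. Around every coastal point of interest an
initial search circle (default radius 0.5 degrees) collects the local mean
flow <u> and mean retention time <T> of passing buoys; their product
Lxy = <u> * <T> per direction sets the final search area. Search areas are
pooled per island, buoys visiting each island are matched by ID across
islands, and two pairwise matrices result: the dispersal probability
(fraction of a source island's buoys that later reach the destination) and
the minimum observed transit time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geo import KM_PER_DEG, degree_distance, local_km_offsets

log = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0


class Region(NamedTuple):
    """Lat/lon bounding box in degrees."""
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float


#: study region of the source analysis (Caribbean archipelagos)
CARIBBEAN_REGION = Region(10.3, 27.4, -86.3, -58.8)

DRIFTER_COLUMNS = ["id", "datetime", "lat", "lon", "ve", "vn"]


@dataclass
class SearchAreaParams:
    """Final search-area geometry around one point of interest."""

    island_id: str
    lat: float
    lon: float
    initial_radius_deg: float
    mean_u_e: float = np.nan       # m/s
    mean_u_n: float = np.nan       # m/s
    mean_retention_days: float = np.nan
    n_buoys: int = 0
    lx_km: float = np.nan          # east-west half-extent
    ly_km: float = np.nan          # north-south half-extent
    covered: bool = False
    shape: str = "ellipse"

    def contains(self, lat, lon) -> np.ndarray:
        """Membership of fixes in the final area (axis-aligned ellipse or rectangle)."""
        dx, dy = local_km_offsets(lat, lon, self.lat, self.lon)
        if self.shape == "rectangle":
            return (np.abs(dx) <= self.lx_km) & (np.abs(dy) <= self.ly_km)
        return (dx / self.lx_km) ** 2 + (dy / self.ly_km) ** 2 <= 1.0


@dataclass
class DispersalSummary:
    """Pairwise dispersal probability and transit-time summaries."""

    islands: list
    probability: pd.DataFrame            # [0,1], diagonal NaN
    transit_times: dict                  # (src, dst) -> list of day-binned transits
    min_time: pd.DataFrame               # days, NaN where no shared buoys
    n_buoys_per_island: pd.Series

    def transit_frame(self) -> pd.DataFrame:
        rows = [(s, d, t) for (s, d), ts in self.transit_times.items() for t in ts]
        return pd.DataFrame(rows, columns=["source", "destination", "transit_days"])


def read_drifter_records(path, region: Region | None = None,
                         column_map: dict | None = None,
                         velocity_unit: str = "m/s",
                         delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited drifter table into the canonical tidy layout.

    Expected columns ``id, datetime, lat, lon, ve, vn`` (override names with
    ``column_map``, e.g. to adapt a Global Drifter Program 6-hourly export).
    Velocities may be in m/s or cm/s. Rows with unparseable coordinates or
    timestamps are skipped with a logged count; fixes outside ``region`` are
    dropped; per-buoy time ordering is enforced.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in DRIFTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drifter file missing columns: {missing}")
    df = df[DRIFTER_COLUMNS].copy()
    n_raw = len(df)
    df["datetime"] = pd.to_datetime(df["datetime"], errors="coerce")
    for c in ("lat", "lon", "ve", "vn"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=["datetime", "lat", "lon"])
    bad = df[(df["lat"] < -90) | (df["lat"] > 90)]
    df = df.drop(bad.index)
    n_malformed = n_raw - len(df)
    if n_malformed:
        log.warning("skipped %d malformed drifter rows", n_malformed)
    if velocity_unit == "cm/s":
        df[["ve", "vn"]] = df[["ve", "vn"]] / 100.0
    elif velocity_unit != "m/s":
        raise ValueError("velocity_unit must be 'm/s' or 'cm/s'")
    if region is not None:
        inside = ((df["lat"] >= region.lat_min) & (df["lat"] <= region.lat_max)
                  & (df["lon"] >= region.lon_min) & (df["lon"] <= region.lon_max))
        df = df[inside]
    df = df.sort_values(["id", "datetime"]).drop_duplicates(["id", "datetime"])
    if not len(df):
        raise ValueError("no drifter fixes remain after filtering")
    log.info("read %d fixes from %d distinct buoys", len(df), df["id"].nunique())
    return df.reset_index(drop=True)


def read_island_points(path, delimiter: str = ",") -> pd.DataFrame:
    """Read points of interest: columns ``island_id, lat, lon``."""
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in ("island_id", "lat", "lon") if c not in df.columns]
    if missing:
        raise ValueError(f"island points file missing columns: {missing}")
    return df


def initial_area_stats(trajectories: pd.DataFrame, lat: float, lon: float,
                       initial_radius_deg: float = 0.5) -> dict:
    """Mean flow and mean retention time inside the initial search circle.

    <u_e>, <u_n> average the velocities of every in-area fix (fix-level
    averaging). <T> averages, over buoys, the duration of each buoy's first
    traversal: first in-area fix to the last fix of that contiguous in-area
    run (a traversal still open at track end uses the last in-area fix).
    """
    if initial_radius_deg <= 0:
        raise ValueError("initial_radius_deg must be > 0")
    d = degree_distance(trajectories["lat"].to_numpy(), trajectories["lon"].to_numpy(), lat, lon)
    inside = d <= initial_radius_deg
    if not inside.any():
        return {"mean_u_e": np.nan, "mean_u_n": np.nan,
                "mean_retention_days": np.nan, "n_buoys": 0, "covered": False}
    sub = trajectories[inside]
    mean_u_e = float(sub["ve"].mean())
    mean_u_n = float(sub["vn"].mean())

    retentions = []
    for _, g in trajectories.assign(_in=inside).groupby("id", sort=False):
        flags = g["_in"].to_numpy()
        if not flags.any():
            continue
        start = int(np.argmax(flags))
        exits = np.nonzero(~flags[start:])[0]
        end = start + (int(exits[0]) - 1 if len(exits) else len(flags) - start - 1)
        t = g["datetime"].to_numpy()
        retentions.append((t[end] - t[start]) / np.timedelta64(1, "s") / SECONDS_PER_DAY)
    return {"mean_u_e": mean_u_e, "mean_u_n": mean_u_n,
            "mean_retention_days": float(np.mean(retentions)),
            "n_buoys": len(retentions), "covered": True}


def final_search_area(island_id: str, lat: float, lon: float, stats: dict,
                      initial_radius_deg: float = 0.5,
                      shape: str = "ellipse") -> SearchAreaParams:
    """Turn initial-area statistics into the final search-area geometry.

    Half-extents Lx = |<u_e>| * <T> and Ly = |<u_n>| * <T>, converted to km,
    floored at the initial radius (km per degree of longitude at the point's
    latitude for Lx, per degree of latitude for Ly) so weak-mean-flow points
    keep a non-degenerate area. An uncovered point (no intersecting buoys)
    propagates with ``covered=False``.
    """
    area = SearchAreaParams(island_id=island_id, lat=lat, lon=lon,
                            initial_radius_deg=initial_radius_deg, shape=shape,
                            mean_u_e=stats["mean_u_e"], mean_u_n=stats["mean_u_n"],
                            mean_retention_days=stats["mean_retention_days"],
                            n_buoys=stats["n_buoys"], covered=stats["covered"])
    if not stats["covered"]:
        return area
    floor_x = initial_radius_deg * KM_PER_DEG * math.cos(math.radians(lat))
    floor_y = initial_radius_deg * KM_PER_DEG
    t_sec = stats["mean_retention_days"] * SECONDS_PER_DAY
    area.lx_km = max(abs(stats["mean_u_e"]) * t_sec / 1000.0, floor_x)
    area.ly_km = max(abs(stats["mean_u_n"]) * t_sec / 1000.0, floor_y)
    return area


def build_search_areas(trajectories: pd.DataFrame, points: pd.DataFrame,
                       initial_radius_deg: float = 0.5,
                       shape: str = "ellipse") -> list[SearchAreaParams]:
    """Compute final search areas for every point of interest."""
    areas = []
    for _, row in points.iterrows():
        stats = initial_area_stats(trajectories, row["lat"], row["lon"], initial_radius_deg)
        if not stats["covered"]:
            log.warning("point of interest at (%.3f, %.3f) on %s has no buoy coverage",
                        row["lat"], row["lon"], row["island_id"])
        areas.append(final_search_area(row["island_id"], row["lat"], row["lon"],
                                       stats, initial_radius_deg, shape))
    return areas


def detect_island_visits(trajectories: pd.DataFrame,
                         areas: list[SearchAreaParams]) -> pd.DataFrame:
    """First entry time of every buoy into every island's pooled search areas.

    A buoy visits an island if any of its fixes falls inside any of the
    island's covered final areas; repeat visits are ignored. Returns a tidy
    frame ``buoy_id, island_id, first_entry_time`` (one row per pair).
    """
    lat = trajectories["lat"].to_numpy()
    lon = trajectories["lon"].to_numpy()
    by_island: dict[str, np.ndarray] = {}
    for a in areas:
        if not a.covered:
            continue
        m = a.contains(lat, lon)
        if a.island_id in by_island:
            by_island[a.island_id] |= m
        else:
            by_island[a.island_id] = m
    rows = []
    for island, mask in by_island.items():
        if not mask.any():
            continue
        firsts = trajectories.loc[mask].groupby("id")["datetime"].min()
        for buoy, t in firsts.items():
            rows.append({"buoy_id": buoy, "island_id": island, "first_entry_time": t})
    visits = pd.DataFrame(rows, columns=["buoy_id", "island_id", "first_entry_time"])
    return visits


def filter_low_coverage(visits: pd.DataFrame, islands: list[str],
                        min_buoys: int = 10) -> tuple[list[str], list[str]]:
    """Drop islands visited by fewer than ``min_buoys`` distinct buoys.

    Returns ``(retained, dropped)`` preserving the input island order.
    """
    counts = visits.groupby("island_id")["buoy_id"].nunique()
    retained = [i for i in islands if counts.get(i, 0) >= min_buoys]
    dropped = [i for i in islands if i not in retained]
    if not retained:
        raise ValueError("every island fell below the minimum buoy coverage")
    if dropped:
        log.info("dropped %d low-coverage islands: %s", len(dropped), dropped)
    return retained, dropped


def transit_days(delta: pd.Timedelta | float) -> int:
    """Day-bin a transit interval: floor of elapsed days, minimum 1."""
    if isinstance(delta, pd.Timedelta):
        days = delta.total_seconds() / SECONDS_PER_DAY
    else:
        days = float(delta)
    return max(1, int(math.floor(days)))


def dispersal_probability_matrix(visits: pd.DataFrame,
                                 islands: list[str]) -> DispersalSummary:
    """Pairwise dispersal probabilities and transit-time distributions.

    For an ordered island pair (i, j): the numerator counts distinct buoys
    whose first entry at j is strictly later than at i; the denominator is
    the number of distinct buoys visiting i. Each qualifying buoy contributes
    one transit time, the difference of first entries binned to whole days
    (floor, minimum 1). The diagonal is undefined (NaN).
    """
    wide = visits.pivot_table(index="buoy_id", columns="island_id",
                              values="first_entry_time", aggfunc="min")
    wide = wide.reindex(columns=islands)
    n = len(islands)
    prob = pd.DataFrame(np.full((n, n), np.nan), index=islands, columns=islands)
    mint = pd.DataFrame(np.full((n, n), np.nan), index=islands, columns=islands)
    transits: dict = {}
    n_buoys = wide.notna().sum(axis=0).reindex(islands).fillna(0).astype(int)
    cols = {i: pd.to_datetime(wide[i]).to_numpy() for i in islands}
    for i in islands:
        ti = cols[i]
        denom = int((~np.isnat(ti)).sum())
        for j in islands:
            if i == j:
                continue
            if denom == 0:
                prob.loc[i, j] = 0.0
                transits[(i, j)] = []
                continue
            tj = cols[j]
            both = ~np.isnat(ti) & ~np.isnat(tj)
            qual = both & (tj > ti)  # NaT comparisons are False
            ts = sorted(transit_days(pd.Timedelta(d))
                        for d in (tj[qual] - ti[qual]))
            transits[(i, j)] = ts
            prob.loc[i, j] = qual.sum() / denom
            if ts:
                mint.loc[i, j] = ts[0]
    return DispersalSummary(islands=list(islands), probability=prob,
                            transit_times=transits, min_time=mint,
                            n_buoys_per_island=n_buoys)


def minimum_dispersal_time(transit_times: dict, islands: list[str]) -> pd.DataFrame:
    """Entrywise minimum of each pair's transit-time distribution (NaN if empty)."""
    mint = pd.DataFrame(np.full((len(islands),) * 2, np.nan),
                        index=islands, columns=islands)
    for (i, j), ts in transit_times.items():
        if ts:
            mint.loc[i, j] = min(ts)
    return mint
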