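"""Synthetic data with known ground truth.

Three generators cover the raw inputs of the pipeline:

* drifter trajectories in the 6-hourly interpolated surface-drifter layout
  (columns ``id, datetime, lat, lon, ve, vn``), with an Ornstein-Uhlenbeck
  velocity process around a prescribed mean flow so tracks meander like buoys
  in an eddy field;
* fruit-flotation trials following the tank protocol — daily float checks,
  weekly removal of 10% of floaters for tetrazolium viability testing, with
  the fewer-than-five-fruits suspension rule;
* island presence/absence matrices sampled from a connectivity matrix so the
  matrix-correlation statistics can be power-tested against a known signal.

Every generator is deterministic under a fixed seed and returns its
generative parameters alongside the data for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import M_PER_DEG

SECONDS_PER_FIX = 6 * 3600  # 6-hourly cadence


@dataclass(frozen=True)
class FlowFieldSpec:
    """Mean flow plus eddy statistics over a lat/lon box.

    Parameters
    ----------
    mean_u, mean_v : float
        Mean eastward / northward velocity, m/s.
    eddy_sigma : float
        Standard deviation of the velocity fluctuations, m/s.
    decorrelation_time : float
        e-folding time of the velocity autocorrelation, hours.
    lat_min, lat_max, lon_min, lon_max : float
        Region bounds in degrees.
    """

    mean_u: float
    mean_v: float
    eddy_sigma: float
    decorrelation_time: float
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if self.eddy_sigma < 0:
            raise ValueError("eddy_sigma must be >= 0")
        if self.decorrelation_time <= 0:
            raise ValueError("decorrelation_time must be > 0")
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("region must have positive extent")


@dataclass(frozen=True)
class TrialSimSpec:
    """Ground-truth parameters for a simulated flotation trial.

    ``sink_distribution`` is one of ``exponential`` (param: ``scale`` days),
    ``lognormal`` (``mu``, ``sigma`` of log-days), ``weibull`` (``shape``,
    ``scale``), or ``degenerate`` (``day``). ``viability_halflife`` is the
    half-life in days of seed viability while afloat; ``inf`` means seeds
    never lose viability.
    """

    n_fruits_per_species: int
    sink_distribution: str
    sink_params: dict
    viability_halflife: float
    removal_fraction: float = 0.10
    horizon: int = 90

    def __post_init__(self):
        if not 0.0 <= self.removal_fraction <= 1.0:
            raise ValueError("removal_fraction must be in [0, 1]")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.n_fruits_per_species < 5:
            raise ValueError("need at least 5 fruits per species")
        if self.sink_distribution not in {"exponential", "lognormal", "weibull", "degenerate"}:
            raise ValueError(f"unknown sink distribution {self.sink_distribution!r}")


def _sample_sink_days(spec: TrialSimSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_fruits_per_species
    p = spec.sink_params
    if spec.sink_distribution == "exponential":
        t = rng.exponential(p["scale"], n)
    elif spec.sink_distribution == "lognormal":
        t = rng.lognormal(p["mu"], p["sigma"], n)
    elif spec.sink_distribution == "weibull":
        t = p["scale"] * rng.weibull(p["shape"], n)
    else:  # degenerate
        t = np.full(n, float(p["day"]))
    # a fruit observed sunk during day d gets sink_day d (daily census)
    return np.ceil(t).astype(int)


def simulate_drifter_tracks(spec: FlowFieldSpec, n_buoys: int, seed: int,
                            start_time: str = "2000-01-01",
                            max_fixes: int = 2000,
                            start_points: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate surface-drifter tracks on a 6-hour cadence.

    Velocity follows a first-order autoregressive (discretised
    Ornstein-Uhlenbeck) process per component:

        v[t+1] = mean + a * (v[t] - mean) + sigma * sqrt(1 - a^2) * eps,

    with ``a = exp(-dt / tau)``, which has stationary standard deviation
    ``eddy_sigma`` and autocorrelation ``exp(-lag / tau)``. Positions
    integrate velocity with local metres-per-degree conversion. A buoy's
    record ends with its first fix outside the region (the exit fix is kept).

    Returns a tidy frame with columns ``id, datetime, lat, lon, ve, vn``.
    """
    if n_buoys < 1:
        raise ValueError("n_buoys must be >= 1")
    rng = np.random.default_rng(seed)
    dt = float(SECONDS_PER_FIX)
    a = math.exp(-dt / (spec.decorrelation_time * 3600.0))
    innov = spec.eddy_sigma * math.sqrt(max(0.0, 1.0 - a * a))
    t0 = pd.Timestamp(start_time)

    if start_points is None:
        lat0 = rng.uniform(spec.lat_min, spec.lat_max, n_buoys)
        lon0 = rng.uniform(spec.lon_min, spec.lon_max, n_buoys)
    else:
        start_points = np.asarray(start_points, dtype=float)
        lat0, lon0 = start_points[:, 0], start_points[:, 1]

    frames = []
    for b in range(n_buoys):
        lat, lon = float(lat0[b]), float(lon0[b])
        ve = spec.mean_u + spec.eddy_sigma * rng.standard_normal()
        vn = spec.mean_v + spec.eddy_sigma * rng.standard_normal()
        rows = []
        for k in range(max_fixes):
            rows.append((lat, lon, ve, vn))
            inside = (spec.lat_min <= lat <= spec.lat_max
                      and spec.lon_min <= lon <= spec.lon_max)
            if not inside:
                break  # exit fix recorded; track ends
            lat = lat + vn * dt / M_PER_DEG
            lon = lon + ve * dt / (M_PER_DEG * math.cos(math.radians(lat)))
            ve = spec.mean_u + a * (ve - spec.mean_u) + innov * rng.standard_normal()
            vn = spec.mean_v + a * (vn - spec.mean_v) + innov * rng.standard_normal()
        arr = np.array(rows)
        frames.append(pd.DataFrame({
            "id": f"B{b:05d}",
            "datetime": t0 + pd.to_timedelta(np.arange(len(rows)) * SECONDS_PER_FIX, unit="s"),
            "lat": arr[:, 0], "lon": arr[:, 1],
            "ve": arr[:, 2], "vn": arr[:, 3],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_flotation_trial(spec: TrialSimSpec, seed: int,
                             species: str = "synthetic_sp",
                             method: str = "tank"):
    """Simulate one species' flotation trial under the weekly-removal protocol.

    Day loop, for d = 1..horizon:

    1. fruits whose true sink day is d are recorded as sunk;
    2. on multiples of 7, if at least five fruits float, ``ceil(removal_fraction
       * n_floating)`` floaters are removed uniformly at random and tetrazolium
       tested; the first week with fewer than five floaters suspends removals
       for two weeks, after which all remaining floaters are tested and removed;
    3. at the horizon any untested floaters are tested (end-of-study check).

    A removed seed tests viable iff its latent viability-loss day (exponential
    with the specified half-life) exceeds the test day.

    Returns ``(records, tz_results, truth)`` where records/tz_results are tidy
    frames matching the trial reader layout and ``truth`` holds the generative
    sink days and viability-loss days.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_fruits_per_species
    sink_day = _sample_sink_days(spec, rng)
    if math.isinf(spec.viability_halflife):
        loss_day = np.full(n, np.inf)
    else:
        loss_day = rng.exponential(spec.viability_halflife / math.log(2.0), n)

    floating = set(range(n))
    removed_on = {}     # fruit -> day
    sunk_on = {}
    tz_rows = []
    final_test_day = None   # scheduled all-remaining test after <5 rule fires

    def _test(fruit: int, day: int):
        tz_rows.append({"species": species, "fruit_id": f"{species}_{fruit:04d}",
                        "test_day": day, "viable": bool(loss_day[fruit] > day)})

    # day-0 sinkers (never floated)
    for f in [f for f in floating if sink_day[f] <= 0]:
        floating.discard(f)
        sunk_on[f] = 0

    for d in range(1, spec.horizon + 1):
        for f in [f for f in floating if sink_day[f] <= d]:
            floating.discard(f)
            sunk_on[f] = d
        if final_test_day is not None and d == final_test_day:
            for f in sorted(floating):
                _test(f, d)
                removed_on[f] = d
            floating.clear()
        elif final_test_day is None and d % 7 == 0 and floating:
            if len(floating) >= 5:
                k = math.ceil(spec.removal_fraction * len(floating))
                chosen = rng.choice(sorted(floating), size=k, replace=False)
                for f in chosen:
                    f = int(f)
                    floating.discard(f)
                    removed_on[f] = d
                    _test(f, d)
            else:
                final_test_day = d + 14
        # conservation: every fruit is floating, sunk, or removed
        assert len(floating) + len(sunk_on) + len(removed_on) == n

    for f in sorted(floating):  # end-of-study check of survivors
        _test(f, spec.horizon)

    rec_rows = []
    for f in range(n):
        rec_rows.append({
            "species": species, "fruit_id": f"{species}_{f:04d}", "method": method,
            "sink_day": sunk_on.get(f, pd.NA),
            "removal_day": removed_on.get(f, pd.NA),
            "end_of_study_day": spec.horizon,
        })
    records = pd.DataFrame(rec_rows)
    tz_results = pd.DataFrame(tz_rows, columns=["species", "fruit_id", "test_day", "viable"])
    truth = {"sink_day": sink_day, "viability_loss_day": loss_day, "spec": spec}
    return records, tz_results, truth


def simulate_presence_from_connectivity(connectivity: pd.DataFrame,
                                        colonization_scale: float,
                                        seed: int,
                                        source_island: str | None = None):
    """Sample island occupancy from a connectivity matrix.

    A seeded source island is always occupied; every other island ``j`` is
    occupied independently with probability ``1 - exp(-colonization_scale *
    C[source, j])``, which increases monotonically in connectivity, is 0 when
    the scale tends to 0, and tends to 1 for every reachable island as the
    scale grows.

    Returns ``(presence, truth)``: a 0/1 Series indexed by island and the
    generative parameters.
    """
    if connectivity.size == 0:
        raise ValueError("empty connectivity matrix")
    vals = connectivity.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("connectivity entries must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    islands = list(connectivity.index)
    if source_island is None:
        source_island = islands[int(rng.integers(len(islands)))]
    row = connectivity.loc[source_island].fillna(0.0)
    p_occ = 1.0 - np.exp(-colonization_scale * row.to_numpy(dtype=float))
    occupied = (rng.random(len(islands)) < p_occ).astype(int)
    presence = pd.Series(occupied, index=islands, name="presence")
    presence[source_island] = 1
    truth = {"source_island": source_island, "colonization_scale": colonization_scale,
             "occupancy_probability": pd.Series(p_occ, index=islands)}
    return presence, truth
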