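"""End-to-end orchestration: drifters -> connectivity -> survival -> statistics.

A :class:`PipelineConfig` names the input files and tuning parameters; a
single root seed drives every stochastic step (Mantel permutations, demo
simulation), so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biogeo import (distribution_matrix, fit_range_size_model,
                     geographic_distance_matrix, meng_z, sorensen_matrix,
                     spearman_mantel, split_floaters)
from .connectivity import (CARIBBEAN_REGION, Region, build_search_areas,
                           detect_island_visits, dispersal_probability_matrix,
                           filter_low_coverage, read_drifter_records,
                           read_island_points)
from .datasets import traits_with_human_use
from .flotation import estimate_survival, logrank_compare
from .io import (read_matrix, read_tetrazolium, read_trial_records,
                 write_matrix, write_table)
from .species_connectivity import connectivity_for_species_set
from .synthetic import (FlowFieldSpec, TrialSimSpec,
                        simulate_drifter_tracks, simulate_flotation_trial,
                        simulate_presence_from_connectivity)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    drifter_path: str
    island_points_path: str
    trial_records_path: str
    tetrazolium_path: str
    presence_path: str | None = None
    traits_path: str | None = None       # None -> packaged 14-species fixture
    region: tuple = CARIBBEAN_REGION
    initial_radius_deg: float = 0.5
    area_shape: str = "ellipse"
    min_buoys: int = 10
    horizon: int = 90
    n_perm: int = 9999
    seed: int = 0
    out_dir: str = "thalassochory_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _slug(name: str) -> str:
    return name.replace(" ", "_")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all tables under ``config.out_dir``.

    Returns a report dict with the key results (dispersal summary, survival
    summaries, Mantel table, model fit) for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    run_log = {"version": __version__, "python": platform.python_version(),
               "seed": config.seed, "config": {k: (list(v) if isinstance(v, tuple) else v)
                                               for k, v in asdict(config).items()}}

    # ---- stage 1: drifter connectivity
    try:
        region = Region(*config.region)
        traj = read_drifter_records(config.drifter_path, region)
        points = read_island_points(config.island_points_path)
        areas = build_search_areas(traj, points, config.initial_radius_deg, config.area_shape)
        visits = detect_island_visits(traj, areas)
        islands_all = list(dict.fromkeys(points["island_id"]))
        retained, dropped = filter_low_coverage(visits, islands_all, config.min_buoys)
        summary = dispersal_probability_matrix(visits[visits["island_id"].isin(retained)], retained)
        write_matrix(summary.probability, out / "dispersal_probability.csv")
        write_matrix(summary.min_time, out / "min_dispersal_time.csv")
        write_table(summary.transit_frame(), out / "transit_times.csv")
        run_log["n_buoys"] = int(traj["id"].nunique())
        run_log["dropped_islands"] = dropped
        report["dispersal"] = summary
    except Exception as exc:
        raise StageError("drifter_connectivity", exc) from exc

    # ---- stage 2: flotation-viability survival
    try:
        records = read_trial_records(config.trial_records_path)
        tz = read_tetrazolium(config.tetrazolium_path)
        species = sorted(records["species"].unique())
        survivals = {sp: estimate_survival(records, tz, sp, config.horizon) for sp in species}
        curves = pd.concat([sv.to_frame() for sv in survivals.values()], ignore_index=True)
        write_table(curves, out / "survival_curves.csv")
        summ = pd.DataFrame([{"species": sp, "max_viability_day": sv.max_viability_day,
                              "p95_viability_day": sv.p95_viability_day}
                             for sp, sv in survivals.items()])
        write_table(summ, out / "survival_summary.csv")
        if len(species) >= 2:
            chi2, df_, p = logrank_compare(records, tz)
            report["logrank"] = {"chi2": chi2, "df": df_, "p": p}
        report["survivals"] = survivals
    except Exception as exc:
        raise StageError("flotation_viability", exc) from exc

    # ---- stage 3: species connectivity
    try:
        conn = connectivity_for_species_set(report["dispersal"], survivals, config.horizon)
        for sp, cm in conn.items():
            write_matrix(cm.value, out / f"connectivity_{_slug(sp)}.csv")
        report["connectivity"] = conn
    except Exception as exc:
        raise StageError("species_connectivity", exc) from exc

    # ---- stage 4: biogeographic statistics
    try:
        rng = np.random.default_rng(config.seed)
        geo = geographic_distance_matrix(points)
        geo = geo.loc[retained, retained]
        write_matrix(geo, out / "geographic_distance.csv")

        summary = report["dispersal"]
        mantel_rows = []

        def _mantel(name, A, B):
            try:
                rho, p = spearman_mantel(A, B, config.n_perm, int(rng.integers(2**31)))
            except ValueError as exc:  # degenerate matrices (constant / too few cells)
                log.warning("Mantel %s skipped: %s", name, exc)
                rho, p = np.nan, np.nan
            mantel_rows.append({"comparison": name, "rho": rho, "p": p})
            return rho

        rho_pt = _mantel("probability_vs_min_time", summary.probability, summary.min_time)
        rho_gd_t = _mantel("distance_vs_min_time", geo, summary.min_time)
        rho_gd_p = _mantel("distance_vs_probability", geo, summary.probability)
        rho_tp = rho_pt
        n_pairs = int((~summary.min_time.isna()).to_numpy()[~np.eye(len(retained), dtype=bool)].sum())
        if n_pairs > 3 and np.isfinite([rho_gd_t, rho_gd_p, rho_tp]).all():
            z, pz = meng_z(rho_gd_t, rho_gd_p, rho_tp, n_pairs)
            report["meng"] = {"z": z, "p": pz, "n": n_pairs}
            write_table(pd.DataFrame([report["meng"]]), out / "meng_z.csv")

        fit = fit_range_size_model(_load_traits(config))
        write_table(fit.coefficients, out / "range_size_model.csv")
        report["range_model"] = fit

        if config.presence_path:
            presence = read_matrix(config.presence_path)
            presence = presence.loc[:, presence.columns.intersection(retained)]
            for sp, cm in conn.items():
                if sp not in presence.index:
                    continue
                dm = distribution_matrix(presence.loc[sp])
                write_matrix(dm, out / f"distribution_{_slug(sp)}.csv")
                common = [i for i in retained if i in dm.index]
                if len(common) >= 3:
                    _mantel(f"distribution_vs_connectivity:{sp}",
                            dm.loc[common, common], cm.value.loc[common, common])
                    _mantel(f"distribution_vs_distance:{sp}",
                            dm.loc[common, common], geo.loc[common, common])
            p95 = pd.Series({sp: sv.p95_viability_day for sp, sv in survivals.items()})
            p95 = p95[p95.index.isin(presence.index)]
            if len(p95):
                good, poor, thresh = split_floaters(p95)
                report["floater_threshold_days"] = thresh
                for label, group in (("good", good), ("poor", poor)):
                    if not group:
                        continue
                    sor = sorensen_matrix(presence.loc[group])
                    write_matrix(sor, out / f"sorensen_{label}_floaters.csv")
                    common = [i for i in retained if i in sor.index]
                    if len(common) >= 3:
                        _mantel(f"sorensen_{label}_vs_probability",
                                sor.loc[common, common], summary.probability.loc[common, common])
                        _mantel(f"sorensen_{label}_vs_min_time",
                                sor.loc[common, common], summary.min_time.loc[common, common])
        mantel = pd.DataFrame(mantel_rows)
        write_table(mantel, out / "mantel_results.csv")
        report["mantel"] = mantel
    except StageError:
        raise
    except Exception as exc:
        raise StageError("biogeo_stats", exc) from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return report


def _load_traits(config: PipelineConfig) -> pd.DataFrame:
    if config.traits_path:
        return pd.read_csv(config.traits_path)
    return traits_with_human_use()


# ------------------------------------------------------------- demo dataset

DEMO_SPECIES = {
    # name -> (sink distribution, params, viability half-life days)
    "Floatia perpetua": ("exponential", {"scale": 150.0}, float("inf")),
    "Mediocris flotans": ("exponential", {"scale": 18.0}, 45.0),
    "Sinkia rapida": ("degenerate", {"day": 0}, 10.0),
}


def make_demo_dataset(out_dir, seed: int = 0, n_buoys: int = 120,
                      n_fruits: int = 80, horizon: int = 90) -> dict:
    """Write a fully synthetic demo dataset and its pipeline config.

    A westward mean flow carries buoys released upstream past a four-island
    chain; three species span the flotation range from sink-on-day-0 to
    floating beyond the study horizon. Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    flow = FlowFieldSpec(mean_u=-0.4, mean_v=0.0, eddy_sigma=0.12,
                         decorrelation_time=24.0,
                         lat_min=10.0, lat_max=20.0, lon_min=-80.0, lon_max=-60.0)
    starts = np.column_stack([rng.uniform(14.0, 16.0, n_buoys),
                              rng.uniform(-61.5, -60.2, n_buoys)])
    tracks = simulate_drifter_tracks(flow, n_buoys, seed=int(rng.integers(2**31)),
                                     start_points=starts)
    drifter_path = out / "drifters.csv"
    tracks.to_csv(drifter_path, index=False)

    centers = [(15.0, -63.0), (14.6, -65.5), (15.3, -68.0),
               (14.8, -70.5), (15.2, -73.0), (14.9, -75.5)]
    rows = []
    for k, (clat, lon) in enumerate(centers):
        for dlat in (-0.15, 0.15):
            rows.append({"island_id": f"ISL{k}", "lat": clat + dlat, "lon": lon})
    points = pd.DataFrame(rows)
    island_path = out / "island_points.csv"
    points.to_csv(island_path, index=False)

    all_records, all_tz = [], []
    for sp, (dist, params, halflife) in DEMO_SPECIES.items():
        spec = TrialSimSpec(n_fruits_per_species=n_fruits, sink_distribution=dist,
                            sink_params=params, viability_halflife=halflife,
                            horizon=horizon)
        rec, tz, _ = simulate_flotation_trial(spec, seed=int(rng.integers(2**31)), species=sp)
        all_records.append(rec)
        all_tz.append(tz)
    records = pd.concat(all_records, ignore_index=True)
    tzs = pd.concat(all_tz, ignore_index=True)
    trial_path = out / "trial_records.csv"
    tz_path = out / "tetrazolium.csv"
    records.to_csv(trial_path, index=False)
    tzs.to_csv(tz_path, index=False)

    # presence sampled from a crude per-species connectivity proxy so the
    # matrix-correlation stages have something to chew on
    islands = [f"ISL{k}" for k in range(len(centers))]
    base = pd.DataFrame(rng.uniform(0.05, 0.6, (len(islands), len(islands))),
                        index=islands, columns=islands)
    presence_rows = {}
    for sp in DEMO_SPECIES:
        pres, _ = simulate_presence_from_connectivity(
            base, colonization_scale=8.0, seed=int(rng.integers(2**31)))
        presence_rows[sp] = pres
    presence = pd.DataFrame(presence_rows).T
    presence_path = out / "presence.csv"
    presence.to_csv(presence_path, index_label="species")

    config = PipelineConfig(
        drifter_path=str(drifter_path), island_points_path=str(island_path),
        trial_records_path=str(trial_path), tetrazolium_path=str(tz_path),
        presence_path=str(presence_path),
        region=(flow.lat_min, flow.lat_max, flow.lon_min, flow.lon_max),
        min_buoys=10, horizon=horizon, n_perm=199, seed=seed,
        out_dir=str(out / "results"))
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        cfg = asdict(config)
        cfg["region"] = list(cfg["region"])
        yaml.safe_dump(cfg, fh)
    return {"config": cfg_path, "drifters": drifter_path, "islands": island_path,
            "trials": trial_path, "tetrazolium": tz_path, "presence": presence_path}
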