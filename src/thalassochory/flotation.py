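"""Floating-and-viable survival analysis of fruit flotation trials.

A fruit in a trial can end in one of three ways: it sinks (observed daily),
it is removed for destructive tetrazolium viability testing (weekly 10%
subsample), or it is still afloat at the end of the study. The quantity of
interest is the probability S(n) that a fruit is still floating *and* its
seed still viable n days after entering the water — the plant-survival term
of the species connectivity sum.

S(n) is factored as F(n) * V(n):

* F(n): Kaplan–Meier product-limit estimate of the floating curve, with sink
  as the event and removals / end-of-study as right-censoring;
* V(n): viability fraction among floaters, estimated as the cumulative
  proportion of tetrazolium-tested fruits viable to date, carried forward
  between weekly tests and made nonincreasing by a running minimum (the
  tested subsample is assumed representative of all floaters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class SpeciesSurvival:
    """Combined floating-and-viable survival curve for one species.

    ``float_curve``, ``viability_fraction`` and ``combined_curve`` are arrays
    indexed by integer day 0..horizon; ``combined_curve[n]`` is S(n).
    """

    species: str
    days: np.ndarray
    float_curve: np.ndarray
    viability_fraction: np.ndarray
    combined_curve: np.ndarray
    max_viability_day: int
    p95_viability_day: int

    def s(self, n: int) -> float:
        n = int(n)
        if n < 0:
            return 1.0
        if n >= len(self.combined_curve):
            return float(self.combined_curve[-1])
        return float(self.combined_curve[n])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species, "day": self.days,
            "floating": self.float_curve, "viable_fraction": self.viability_fraction,
            "floating_viable": self.combined_curve,
        })


def event_time(record: pd.Series, tz: pd.Series | None = None):
    """Classify one fruit's trial outcome.

    Returns ``(event_day, status)`` with status one of ``sunk``, ``nonviable``
    (removed and tetrazolium-negative), or ``censored`` (removed while viable,
    or still floating at study end). A fruit tested at the end-of-study check
    uses that test day.
    """
    sink = record.get("sink_day")
    removal = record.get("removal_day")
    end = int(record["end_of_study_day"])
    has_sink = pd.notna(sink)
    has_removal = pd.notna(removal)
    if has_sink and has_removal:
        raise ValueError(f"fruit {record.get('fruit_id')}: both sink and removal recorded")
    if has_sink:
        return int(sink), "sunk"
    if has_removal:
        day = int(removal)
        if tz is None:
            return day, "censored"
        return day, ("censored" if bool(tz["viable"]) else "nonviable")
    if tz is not None:  # end-of-study viability check of a still-floating fruit
        return int(tz["test_day"]), ("censored" if bool(tz["viable"]) else "nonviable")
    return end, "censored"


def build_event_table(records: pd.DataFrame, tz_results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-fruit event days and statuses for all species in ``records``."""
    tz_by_fruit = {}
    if tz_results is not None and len(tz_results):
        for _, row in tz_results.iterrows():
            tz_by_fruit[row["fruit_id"]] = row
    rows = []
    for _, rec in records.iterrows():
        day, status = event_time(rec, tz_by_fruit.get(rec["fruit_id"]))
        rows.append({"species": rec["species"], "fruit_id": rec["fruit_id"],
                     "event_day": day, "status": status})
    return pd.DataFrame(rows)


def _km_float_curve(events: pd.DataFrame, horizon: int) -> np.ndarray:
    """Kaplan–Meier floating curve on integer days 0..horizon.

    Sinking is the event; removal (any tetrazolium outcome) and end-of-study
    are censoring — a removed fruit leaves the floating pool but did not sink.
    """
    observed = (events["status"] == "sunk").astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(events["event_day"].astype(float), event_observed=observed)
    days = np.arange(horizon + 1)
    return kmf.survival_function_at_times(days).to_numpy(dtype=float)


def _viability_fraction(tz: pd.DataFrame, horizon: int) -> np.ndarray:
    """Cumulative-to-date viable proportion, carried forward, nonincreasing."""
    v = np.ones(horizon + 1)
    if tz is None or not len(tz):
        return v
    tz = tz.sort_values("test_day")
    tested = 0
    viable = 0
    frac = 1.0
    for day, grp in tz.groupby("test_day", sort=True):
        tested += len(grp)
        viable += int(grp["viable"].sum())
        frac = min(frac, viable / tested)  # running minimum: later upticks are sampling noise
        d = int(day)
        if d <= horizon:
            v[d:] = frac
    return v


def _max_viability_day(events: pd.DataFrame, tz: pd.DataFrame | None) -> int:
    """Last day the species is known floating-and-viable.

    The last viable tetrazolium observation anchors the estimate; fruits that
    sink later than that, with no intervening nonviable observation, are
    credited as viable until sinking (seeds are assumed to keep viability
    while afloat unless a test shows otherwise).
    """
    sink_days = events.loc[events["status"] == "sunk", "event_day"]
    last_sink = int(sink_days.max()) if len(sink_days) else 0
    if tz is None or not len(tz):
        return last_sink
    viable_days = tz.loc[tz["viable"].astype(bool), "test_day"]
    d_viable = int(viable_days.max()) if len(viable_days) else 0
    nonviable_after = tz.loc[(~tz["viable"].astype(bool)) & (tz["test_day"] > d_viable), "test_day"]
    if len(nonviable_after) and last_sink >= int(nonviable_after.min()):
        return d_viable
    return max(d_viable, last_sink)


def estimate_survival(records: pd.DataFrame, tz_results: pd.DataFrame | None,
                      species: str, horizon: int = 90) -> SpeciesSurvival:
    """Estimate a species' combined floating-and-viable curve S(n) = F(n)V(n).

    ``max_viability_day`` is the last day with evidence of a floating viable
    seed; ``p95_viability_day`` is the last day strictly before S drops to or
    below 5% of its initial value (the survival-curve reading of the day by
    which 95% of fruits have sunk or lost viability).
    """
    recs = records[records["species"] == species]
    if not len(recs):
        raise ValueError(f"no trial records for species {species!r}")
    tz = None
    if tz_results is not None and len(tz_results):
        tz = tz_results[tz_results["species"] == species]
    events = build_event_table(recs, tz)

    days = np.arange(horizon + 1)
    F = _km_float_curve(events, horizon)
    V = _viability_fraction(tz, horizon)
    S = F * V

    max_day = _max_viability_day(events, tz)
    s0 = S[0]
    below = np.nonzero(S <= 0.05 * s0)[0] if s0 > 0 else np.array([0])
    p95 = int(below[0]) - 1 if len(below) else horizon
    p95 = int(np.clip(p95, 0, max_day))
    return SpeciesSurvival(species=species, days=days, float_curve=F,
                           viability_fraction=V, combined_curve=S,
                           max_viability_day=int(max_day), p95_viability_day=p95)


def logrank_compare(records: pd.DataFrame, tz_results: pd.DataFrame | None = None):
    """Log-rank test of sink-or-nonviable event times across species.

    Returns ``(chi2, df, p)`` with ``df = k - 1`` for k species. Sunk and
    tetrazolium-nonviable fruits are events; removed-viable and end-of-study
    fruits are censored.
    """
    events = build_event_table(records, tz_results)
    counts = events.groupby("species").size()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("log-rank needs >= 2 species, each with >= 1 fruit")
    observed = events["status"].isin(["sunk", "nonviable"]).astype(int)
    res = multivariate_logrank_test(events["event_day"].astype(float),
                                    events["species"], observed)
    return float(res.test_statistic), int(len(counts) - 1), float(res.p_value)


def ellipsoid_volume(diameter_mm: float, length_mm: float) -> float:
    """Fruit volume in cm^3 treating the fruit as an ellipsoid of revolution.

    V = (pi/6) * d^2 * L with d, L in mm, converted mm^3 -> cm^3.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("fruit dimensions must be positive")
    return (np.pi / 6.0) * diameter_mm**2 * length_mm / 1000.0


def fruit_density(diameter_mm: float, length_mm: float, mass_g: float) -> float:
    """Whole-fruit density in g/cm^3 from ellipsoid volume."""
    return mass_g / ellipsoid_volume(diameter_mm, length_mm)


def compare_methods_paired(metric_tank, metric_field):
    """Paired t-test of a per-species viability metric under tank vs field.

    Returns ``(t, df, p)``; df = n_pairs - 1. Raises on unpaired input or a
    zero-variance difference (t undefined).
    """
    a = np.asarray(metric_tank, dtype=float)
    b = np.asarray(metric_field, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired comparison needs two equal-length vectors")
    if len(a) < 2:
        raise ValueError("need >= 2 paired species")
    diff = a - b
    if np.allclose(diff, diff[0]) and not np.allclose(diff, 0.0):
        raise ValueError("constant nonzero paired difference: t statistic undefined")
    if np.allclose(a, b):
        return 0.0, len(a) - 1, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)
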