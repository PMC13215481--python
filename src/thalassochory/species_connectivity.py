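"""Per-species ocean-dispersal connectivity.

Combines the buoy-derived transit-time distributions with a species'
floating-and-viable survival curve:

    connectivity(i, j) = sum_{n=1..horizon} S(n) * f_ij(n)

where f_ij(n) is the fraction of the source island's buoys whose day-binned
transit from i to j equals n, and S(n) the probability a fruit is still
floating and viable on day n. The result is bounded above by the
within-horizon dispersal probability for every pair and species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import DispersalSummary
from .flotation import SpeciesSurvival

DEFAULT_HORIZON = 90  # days; the study's flotation-trial time scale


def daily_dispersal_fractions(transits: list[int], n_source_buoys: int,
                              horizon: int = DEFAULT_HORIZON) -> np.ndarray:
    """Daily arrival fractions f(n), n = 1..horizon (index 0 unused).

    f(n) = (# buoys with day-binned transit n) / n_source_buoys. Transits
    beyond the horizon are excluded, so sum(f) <= dispersal probability.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if n_source_buoys <= 0:
        raise ValueError("n_source_buoys must be positive")
    f = np.zeros(horizon + 1)
    for t in transits:
        if 1 <= t <= horizon:
            f[int(t)] += 1.0
    return f / n_source_buoys


@dataclass
class ConnectivityMatrix:
    species: str
    islands: list
    value: pd.DataFrame
    horizon: int


def species_connectivity(summary: DispersalSummary, survival: SpeciesSurvival,
                         horizon: int = DEFAULT_HORIZON) -> ConnectivityMatrix:
    """Connectivity matrix for one species: sum_n S(n) * f(n) per island pair.

    S(n) is evaluated at integer days from the step survival curve, aligned
    with the day binning of the transit times (floor, minimum 1). Pairs with
    no shared buoys within the horizon get 0; the diagonal stays NaN.
    """
    if survival is None:
        raise ValueError("missing survival curve")
    islands = summary.islands
    s = np.array([survival.s(n) for n in range(horizon + 1)])
    n = len(islands)
    value = pd.DataFrame(np.zeros((n, n)), index=islands, columns=islands)
    np.fill_diagonal(value.values, np.nan)
    for (i, j), transits in summary.transit_times.items():
        denom = int(summary.n_buoys_per_island[i])
        if denom == 0:
            continue
        f = daily_dispersal_fractions(transits, denom, horizon)
        value.loc[i, j] = float(np.dot(s[1:], f[1:]))
    return ConnectivityMatrix(species=survival.species, islands=list(islands),
                              value=value, horizon=horizon)


def connectivity_for_species_set(summary: DispersalSummary,
                                 survivals: dict[str, SpeciesSurvival],
                                 horizon: int = DEFAULT_HORIZON) -> dict[str, ConnectivityMatrix]:
    """Connectivity matrices for every species with positive maximum viability.

    Species whose fruits never float viably (max_viability_day = 0) carry no
    ocean-dispersal signal and are skipped, mirroring the analysis of only
    the positive-viability species.
    """
    return {sp: species_connectivity(summary, sv, horizon)
            for sp, sv in survivals.items() if sv.max_viability_day > 0}
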