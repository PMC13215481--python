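"""Packaged study fixtures.

``species_traits.csv`` holds the 14-species trait table: fruit dimensions and
mass (means over >= 10 specimens from a Caribbean fleshy-fruit trait
database), trial fruit counts, floating / viability summary days, and the
number of study islands each species is recorded on. A maximum floating day
of ``90+`` marks a species still afloat at the 90-day study end and is
ingested as right-censored at 90 days.

``human_use.csv`` is an *illustrative synthetic* genus-level count of human
usage categories in the style of ethnobotanical-use compilations; the study's
actual per-genus counts are not published, so these values stand in for
format and plumbing only.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .flotation import ellipsoid_volume


def _data_path(name: str):
    return resources.files("thalassochory.data").joinpath(name)


def load_species_traits() -> pd.DataFrame:
    """Load the 14-species trait/range fixture with derived geometry.

    Adds ``floating_censored`` (True where the printed value was "90+"),
    numeric ``max_floating_day``, ellipsoid ``volume_cm3`` and
    ``density_g_cm3``, and the genus extracted from the binomial.
    """
    with resources.as_file(_data_path("species_traits.csv")) as p:
        df = pd.read_csv(p)
    df = df.rename(columns={"max_viable_day": "max_viability_day",
                            "p95_viable_day": "p95_viability_day"})
    raw = df["max_floating_day"].astype(str)
    df["floating_censored"] = raw.str.endswith("+")
    df["max_floating_day"] = raw.str.rstrip("+").astype(int)
    df["volume_cm3"] = [ellipsoid_volume(d, l) for d, l in
                        zip(df["mean_diameter_mm"], df["mean_length_mm"])]
    df["density_g_cm3"] = df["mean_mass_g"] / df["volume_cm3"]
    df["genus"] = df["species"].str.split().str[0]
    return df


def load_human_use() -> pd.DataFrame:
    """Illustrative genus-level human-usage category counts (synthetic)."""
    with resources.as_file(_data_path("human_use.csv")) as p:
        return pd.read_csv(p)


def traits_with_human_use() -> pd.DataFrame:
    """Species traits joined with the genus-level human-use counts."""
    traits = load_species_traits()
    use = load_human_use()
    out = traits.merge(use, on="genus", how="left")
    out["n_use_categories"] = out["n_use_categories"].fillna(0).astype(int)
    return out
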