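"""Kongsfjorden study-system preset.

Colony coordinates (0.01° precision), breeding-pair counts, survey years and
recorded foraging-trip counts for the five black-legged kittiwake colonies
of the Kongsfjorden region, Svalbard (chick-rearing 2017).  These printed
values are inputs to the arithmetic/geometry checks and seed the
Kongsfjorden-like synthetic scenario; the glacier-front geometry itself is
not published at coordinate level and is generated synthetically.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import SimConfig

#: colony id -> (lon, lat) degrees
KONGSFJORDEN_COLONIES: dict[str, tuple[float, float]] = {
    "BLM": (12.11, 78.99),  # Blomstrand
    "FGL": (10.47, 78.89),  # Fuglehuken
    "KRY": (12.18, 78.89),  # Krykkjefjellet
    "OBS": (12.28, 78.93),  # Observasjonsholmen
    "OSS": (12.44, 78.92),  # Ossian Sarsfjellet
}

#: per-colony tracking summary: trips by sex (individuals in parentheses in
#: the field report), colony size in breeding pairs, survey year
KONGSFJORDEN_TABLE = pd.DataFrame(
    [
        ("BLM", 8, 2, 17, 3, 25, 5, 908, 2011),
        ("FGL", 11, 8, 7, 5, 18, 13, 4286, 2011),
        ("KRY", 13, 4, 23, 5, 36, 9, 318, 2016),
        ("OBS", 35, 6, 48, 7, 83, 13, 141, 2017),
        ("OSS", 26, 5, 17, 3, 43, 8, 1936, 2011),
    ],
    columns=[
        "colony",
        "trips_male",
        "ind_male",
        "trips_female",
        "ind_female",
        "trips_total",
        "ind_total",
        "size_pairs",
        "survey_year",
    ],
)


def kongsfjorden_config(seed: int = 0, **overrides) -> SimConfig:
    """A SimConfig pinned to the real colony layout and sizes.

    Fronts and land are still generated (seeded); movement and front-choice
    parameters keep the study defaults unless overridden.
    """
    ids = list(KONGSFJORDEN_COLONIES)
    kwargs = dict(
        seed=seed,
        n_colonies=len(ids),
        colony_positions=tuple(KONGSFJORDEN_COLONIES[c] for c in ids),
        colony_sizes=tuple(
            int(KONGSFJORDEN_TABLE.set_index("colony").loc[c, "size_pairs"])
            for c in ids
        ),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
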