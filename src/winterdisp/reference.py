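"""Published reference values used as analysis inputs.

Deployment summaries from the 2017 Martillo Island (Beagle Channel) winter
geolocator season, bivalve isotope baselines for the Patagonian Shelf, and
the blood trophic discrimination factors for Magellanic penguins.  These are
small printed tables, carried here so summaries and worked examples can be
recomputed without the raw tag archives.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DEPLOYMENTS_2017",
    "Baseline",
    "TDF",
    "NORTHERN_PATAGONIA",
    "SOUTHERN_PATAGONIA",
    "BAHIA_FRANKLIN",
    "DEFAULT_TDF",
    "COLONY_LAT",
    "COLONY_LON",
]

COLONY_LAT = -54.9
COLONY_LON = -67.3

#: (tag id, sex, departure DD/MM/YYYY, arrival DD/MM/YYYY, latitudinal range km)
DEPLOYMENTS_2017: list[tuple[str, str, str, str, float]] = [
    ("3482", "female", "16/03/2017", "18/09/2017", 578.3),
    ("3488", "female", "16/03/2017", "25/09/2017", 1514.9),
    ("3494", "female", "22/03/2017", "02/10/2017", 1486.5),
    ("3509", "female", "03/04/2017", "21/09/2017", 1407.9),
    ("3514", "female", "29/03/2017", "21/09/2017", 1385.4),
    ("3497", "male", "31/03/2017", "20/09/2017", 1327.7),
    ("3499", "male", "29/03/2017", "16/09/2017", 1588.3),
    ("3503", "male", "29/03/2017", "23/09/2017", 1672.5),
    ("3510", "male", "31/03/2017", "14/09/2017", 1303.5),
]


@dataclass(frozen=True)
class Baseline:
    """A bivalve isotope baseline of assumed trophic position 2."""

    name: str
    d15n_mean: float
    d15n_sd: float
    d13c_mean: float
    d13c_sd: float
    sampling_year: int
    assumed_tp: float = 2.0

    def __post_init__(self) -> None:
        if self.d15n_sd < 0 or self.d13c_sd < 0:
            raise ValueError("baseline SDs must be non-negative")
        if self.assumed_tp != 2.0:
            raise ValueError("baselines are defined at trophic position 2")


@dataclass(frozen=True)
class TDF:
    """Trophic discrimination factors (‰ enrichment per trophic step)."""

    d15n_mean: float = 2.8
    d15n_sd: float = 0.2
    d13c_mean: float = 0.9
    d13c_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.d15n_mean <= 0 or self.d13c_mean <= 0:
            raise ValueError("TDF means must be positive")
        if self.d15n_sd < 0 or self.d13c_sd < 0:
            raise ValueError("TDF SDs must be non-negative")


#: Aulacomya atra, northern Patagonian Shelf (40–44°S), sampled 2009.
NORTHERN_PATAGONIA = Baseline("Northern Patagonia", 11.6, 0.1, -18.7, 0.5, 2009)
#: Aulacomya atra, southern Patagonian Shelf (48–52°S), sampled 2009.
SOUTHERN_PATAGONIA = Baseline("Southern Patagonia", 12.7, 0.5, -15.8, 0.5, 2009)
#: Mytilus chilensis, Bahía Franklin, Isla de los Estados.
BAHIA_FRANKLIN = Baseline("Bahia Franklin", 10.8, 0.5, -14.7, 0.3, 2009)

DEFAULT_TDF = TDF()
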