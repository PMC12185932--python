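"""Published sampling design of the nine-population European tawny owl survey.

These constants summarise the field design that the synthetic-data module
emulates: how many feathers and individuals were collected per population,
how many individuals were successfully genotyped with the eight-marker
microsatellite panel, the observed proportion of grey-morph owls, and the
collection years.  They are study inputs, not quantities this package
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PopulationDesign:
    """Per-population sampling summary."""

    name: str
    dorsal_feathers: int
    ventral_feathers: int
    n_individuals: int
    n_amplified: int
    prop_grey: float
    years: tuple[int, ...]


#: Per-population sampling design of the nine-population survey.
POPULATIONS: tuple[PopulationDesign, ...] = (
    PopulationDesign("Czech Republic", 189, 189, 52, 25, 0.39, (2021,)),
    PopulationDesign("Finland", 51, 51, 24, 16, 0.55, (2021, 2020)),
    PopulationDesign("Italy", 52, 50, 18, 12, 0.62, (2024, 2023, 2022, 2021)),
    PopulationDesign("Lithuania", 136, 136, 37, 3, 0.46, (2021,)),
    PopulationDesign("Norway", 120, 129, 34, 18, 0.51, (2022, 2018)),
    PopulationDesign("Portugal", 14, 16, 9, 10, 0.47, (2024, 2023, 2022, 2021)),
    PopulationDesign("Scotland", 43, 10, 21, 8, 0.13, (2023, 2022)),
    PopulationDesign(
        "Slovenia", 49, 46, 27, 7, 0.46,
        (2023, 2021, 2020, 2019, 2018, 2017, 2016, 2015),
    ),
    PopulationDesign("Sweden", 161, 162, 43, 0, 0.33, (2022, 2021, 2019, 2020)),
)

#: Number of microsatellite loci in the genotyping panel.
N_LOCI = 8


def population_names() -> list[str]:
    return [p.name for p in POPULATIONS]


def individuals_per_population() -> list[int]:
    return [p.n_individuals for p in POPULATIONS]


def amplified_per_population() -> list[int]:
    return [p.n_amplified for p in POPULATIONS]


def total_amplified() -> int:
    """Total number of individuals successfully genotyped across populations."""
    return sum(p.n_amplified for p in POPULATIONS)
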