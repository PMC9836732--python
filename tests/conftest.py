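from __future__ import annotations

import pytest

from diagnostax.msa_io import Alignment, SpeciesMap
from diagnostax.synthetic_data import PlantedRegion, SimulationConfig


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment.from_pairs(rows.items())


def make_map(assignments: dict[str, str]) -> SpeciesMap:
    return SpeciesMap(assignments)


@pytest.fixture
def toy_alignment() -> Alignment:
    return make_alignment({"s1": "ACGT", "s2": "AC-T"})


def small_planted_config(seed: int, noise: float = 0.0, **kwargs) -> SimulationConfig:
    """3 species x 4 sequences, L=60, 2 planted regions each."""
    return SimulationConfig(
        length=60,
        counts={"A": 4, "B": 4, "C": 4},
        planted={
            "A": (
                PlantedRegion(5, 9, frozenset({7})),
                PlantedRegion(14, 16, frozenset({14, 16})),
            ),
            "B": (
                PlantedRegion(22, 26, frozenset({24})),
                PlantedRegion(31, 33, frozenset({32})),
            ),
            "C": (
                PlantedRegion(40, 45, frozenset({42, 44})),
                PlantedRegion(50, 52, frozenset({51})),
            ),
        },
        seed=seed,
        intraspecific_noise=noise,
        **kwargs,
    )


def barcode_scale_config(seed: int, noise: float = 0.02) -> SimulationConfig:
    """6 species x 6 sequences at COI barcode scale (L=660)."""
    planted: dict[str, tuple[PlantedRegion, ...]] = {}
    counts: dict[str, int] = {}
    start = 40
    for i in range(1, 7):
        regions = []
        for _ in range(3):
            end = start + 11
            regions.append(PlantedRegion(start, end, frozenset({start + 2, start + 7})))
            start = end + 20
        planted[f"sp{i}"] = tuple(regions)
        counts[f"sp{i}"] = 6
    return SimulationConfig(
        length=660,
        counts=counts,
        planted=planted,
        seed=seed,
        intraspecific_noise=noise,
    )
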