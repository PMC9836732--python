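"""Synthetic alignments with planted diagnostic structure, and synthetic
specimen morphology drawn from the published per-species ranges.

The alignment generator plants, for each species, regions whose diagnostic
columns carry a state guaranteed absent from every other species, embeds
them in an otherwise shared backbone, and forces the columns immediately
flanking each planted region to vary within every species so that the
planted regions are exactly the maximal invariant runs.  With at least
three species and zero intraspecific noise, diagnosis extraction recovers
the planted truth exactly; intraspecific noise (applied only at
non-diagnostic columns by default) can shrink region context but never
removes planted diagnostic columns from the recovered strict sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .diagnostics import Diagnosis, Region
from .morphology import (
    BranchiaeObservation,
    MGStain,
    SpecimenMorphology,
    UncinusMeasurement,
)
from .msa_io import AlignedSequence, Alignment, SpeciesMap

__all__ = [
    "PlantedRegion",
    "SimulationConfig",
    "TruthSet",
    "SimulationConfigError",
    "generate_alignment",
    "generate_specimens",
    "load_morphology_ranges",
]

BASES = np.array(list("ACGT"))


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRegion:
    start: int
    end: int
    diagnostic_positions: frozenset[int]

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SimulationConfigError(f"bad planted span {self.start}-{self.end}")
        if not self.diagnostic_positions:
            raise SimulationConfigError("planted region needs >=1 diagnostic position")
        if not all(self.start <= p <= self.end for p in self.diagnostic_positions):
            raise SimulationConfigError("diagnostic positions outside planted span")


@dataclass(frozen=True)
class SimulationConfig:
    """Recipe for a synthetic labeled alignment.  ``seed`` is mandatory."""

    length: int
    counts: Mapping[str, int]                       # species -> sequence count
    planted: Mapping[str, tuple[PlantedRegion, ...]]  # species -> regions
    seed: int
    intraspecific_noise: float = 0.0
    interspecific_divergence: float = 0.0
    adversarial: bool = False  # also mutate diagnostic columns (failure paths)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimulationConfigError("length must be positive")
        if not self.counts:
            raise SimulationConfigError("at least one species required")
        if any(n < 1 for n in self.counts.values()):
            raise SimulationConfigError("per-species counts must be >= 1")
        for p in (self.intraspecific_noise, self.interspecific_divergence):
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError("probabilities must lie in [0, 1]")
        claimed: dict[int, str] = {}
        extended: list[tuple[str, int, int]] = []
        for species, regions in self.planted.items():
            if species not in self.counts:
                raise SimulationConfigError(f"planted species {species!r} has no count")
            for region in regions:
                if region.end > self.length:
                    raise SimulationConfigError(
                        f"planted span {region.start}-{region.end} exceeds length {self.length}"
                    )
                for col in region.diagnostic_positions:
                    if col in claimed and claimed[col] != species:
                        raise SimulationConfigError(
                            f"diagnostic column {col} claimed by both "
                            f"{claimed[col]!r} and {species!r}"
                        )
                    claimed[col] = species
                extended.append((species, region.start - 1, region.end + 1))
        # flank-extended spans must be pairwise disjoint, or the invariant-run
        # structure of one region would bleed into a neighbouring one
        extended.sort(key=lambda t: t[1])
        for (sp_a, _, end_a), (sp_b, start_b, _) in zip(extended, extended[1:]):
            if start_b <= end_a:
                raise SimulationConfigError(
                    "flank-extended planted spans overlap "
                    f"({sp_a!r} vs {sp_b!r}); keep at least two free columns "
                    "between planted regions"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.counts)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        doc = yaml.safe_load(text)
        planted = {
            species: tuple(
                PlantedRegion(
                    start=int(e["start"]),
                    end=int(e["end"]),
                    diagnostic_positions=frozenset(
                        int(p) for p in e["diagnostic_positions"]
                    ),
                )
                for e in entries
            )
            for species, entries in doc.get("planted", {}).items()
        }
        return cls(
            length=int(doc["length"]),
            counts={str(k): int(v) for k, v in doc["counts"].items()},
            planted=planted,
            seed=int(doc["seed"]),
            intraspecific_noise=float(doc.get("intraspecific_noise", 0.0)),
            interspecific_divergence=float(doc.get("interspecific_divergence", 0.0)),
            adversarial=bool(doc.get("adversarial", False)),
        )


@dataclass(frozen=True)
class TruthSet:
    """Planted diagnoses and the species partition they belong to."""

    diagnoses: Mapping[str, Diagnosis]
    partition: Mapping[str, tuple[str, ...]]  # species -> sequence ids


def _mutate(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_alignment(
    config: SimulationConfig,
) -> tuple[Alignment, SpeciesMap, TruthSet]:
    """Generate a labeled alignment with known diagnostic truth.

    Fully reproducible from ``config.seed``: identical configs give
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    L = config.length
    ancestral = BASES[rng.integers(0, 4, size=L)]

    diagnostic_cols: set[int] = set()
    planted_span_cols: set[int] = set()
    for regions in config.planted.values():
        for region in regions:
            diagnostic_cols.update(region.diagnostic_positions)
            planted_span_cols.update(range(region.start, region.end + 1))

    # species backbones: ancestral + optional interspecific divergence at
    # free columns; diagnostic columns handled explicitly afterwards
    backbones: dict[str, np.ndarray] = {}
    for species in config.species:
        backbone = ancestral.copy()
        if config.interspecific_divergence > 0:
            for col in range(1, L + 1):
                if col in planted_span_cols:
                    continue
                if rng.random() < config.interspecific_divergence:
                    backbone[col - 1] = _mutate(rng, str(backbone[col - 1]))
        backbones[species] = backbone

    # each species gets a private state at each of its diagnostic columns;
    # every other species keeps the ancestral state there
    for species in config.species:
        for region in config.planted.get(species, ()):
            for col in sorted(region.diagnostic_positions):
                shared = str(ancestral[col - 1])
                private = _mutate(rng, shared)
                backbones[species][col - 1] = private
                for other in config.species:
                    if other != species:
                        backbones[other][col - 1] = shared

    # flanking columns become within-species variable so each planted
    # region is delimited by a broken run on both sides
    boundary_cols: set[int] = set()
    for regions in config.planted.values():
        for region in regions:
            for col in (region.start - 1, region.end + 1):
                if 1 <= col <= L and col not in diagnostic_cols:
                    boundary_cols.add(col)

    sequences: list[AlignedSequence] = []
    assignments: dict[str, str] = {}
    partition: dict[str, tuple[str, ...]] = {}
    for species_index, species in enumerate(config.species):
        count = config.counts[species]
        ids = []
        boundary_states: dict[int, tuple[str, str]] = {}
        for col in sorted(boundary_cols):
            base = str(backbones[species][col - 1])
            boundary_states[col] = (base, _mutate(rng, base))
        for i in range(count):
            row = backbones[species].copy().astype(object)
            for col, (base, alt) in boundary_states.items():
                if count == 1:
                    row[col - 1] = "-"  # single sequence: a gap breaks the run
                else:
                    row[col - 1] = alt if i == 0 else base
            if config.intraspecific_noise > 0:
                for col in range(1, L + 1):
                    if col in boundary_cols:
                        continue
                    if col in diagnostic_cols and not config.adversarial:
                        continue
                    if rng.random() < config.intraspecific_noise:
                        row[col - 1] = _mutate(rng, str(row[col - 1]))
            seq_id = f"sp{species_index + 1}_seq{i + 1}"
            ids.append(seq_id)
            sequences.append(AlignedSequence(seq_id, "".join(row)))
            assignments[seq_id] = species
        partition[species] = tuple(ids)

    truth = {
        species: Diagnosis(
            species=species,
            regions=tuple(
                Region(
                    start=r.start,
                    end=r.end,
                    motif="".join(
                        str(backbones[species][c - 1]) for c in range(r.start, r.end + 1)
                    ),
                    diagnostic_positions=r.diagnostic_positions,
                )
                for r in sorted(config.planted.get(species, ()), key=lambda r: r.start)
            ),
            source="computed",
            provenance=f"synthetic(seed={config.seed})",
        )
        for species in config.species
    }
    return (
        Alignment(tuple(sequences)),
        SpeciesMap(assignments),
        TruthSet(diagnoses=truth, partition=partition),
    )


# ---------------------------------------------------------------------------
# Specimens


def load_morphology_ranges(path: str | None = None) -> dict:
    """Bundled per-species morphology parameter table."""
    if path is None:
        text = (
            importlib_resources.files("diagnostax")
            .joinpath("resources", "morphology_ranges.yaml")
            .read_text()
        )
    else:
        with open(path) as handle:
            text = handle.read()
    return yaml.safe_load(text)


_MG_BUILDERS = {
    1: ("solid",) * 6 + ("striped",) * 8 + ("none",) * 4,
    2: ("solid",) * 5 + ("white",) + ("striped",) * 8 + ("none",) * 4,
    9: ("solid",) * 6 + ("striped",) * 8 + ("none",) * 4,
}

# fusion-fraction sampling windows per branchiae type, chosen strictly
# inside the classifier thresholds
_FUSION_WINDOWS = {1: (0.85, 1.0), 2: (0.35, 0.65), 3: (0.16, 0.28), 4: (0.0, 0.12)}

_THORACIC_BUILDERS = {
    1: (2.0, 1.0, (2, 3), "large", 1),
    3: (1.0, 1.0, (4, 5), "mid", 1),
    4: (1.0, 1.0, (5, 7), "small", 2),
}

_ABDOMINAL_BUILDERS = {
    "1A": (1.0, 0.7, (3, 5), "large", 2),
    "2": (1.0, 0.9, (4, 5), "mid", 1),
}


def generate_specimens(
    n: int,
    seed: int,
    species: Iterable[str] | None = None,
    ranges: Mapping[str, Mapping] | None = None,
    length_count_coupling: float = 0.7,
) -> list[SpecimenMorphology]:
    """Draw ``n`` specimens per species from the published ranges.

    Continuous and integer characters are sampled uniformly within their
    printed min-max ranges; categorical characters are fixed to the
    species' printed states.  Body length and abdominal chaetiger count are
    positively coupled with Pearson correlation approximately
    ``length_count_coupling``.  Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= length_count_coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    table = dict(ranges) if ranges is not None else load_morphology_ranges()
    labels = list(species) if species is not None else list(table)
    missing = [s for s in labels if s not in table]
    if missing:
        raise KeyError(f"no morphology ranges for species {missing}")

    rng = np.random.default_rng(seed)
    rho = length_count_coupling
    out: list[SpecimenMorphology] = []
    for label in labels:
        row = table[label]
        lmin, lmax = row["body_length_mm"]
        cmin, cmax = row["abdominal_chaetigers"]
        fmin, fmax = _FUSION_WINDOWS[row["branchiae_type"]]
        t_rost, t_cap, t_teeth, t_size, t_rows = _THORACIC_BUILDERS[row["thoracic_type"]]
        a_rost, a_cap, a_teeth, a_size, a_rows = _ABDOMINAL_BUILDERS[row["abdominal_type"]]
        states = _MG_BUILDERS[row["mg_pattern"]]
        for _ in range(n):
            u = rng.random()
            u2 = rng.random()
            length = lmin + u * (lmax - lmin)
            v = 0.5 + rho * (u - 0.5) + np.sqrt(1 - rho * rho) * (u2 - 0.5)
            v = float(np.clip(v, 0.0, 1.0))
            count = int(round(cmin + v * (cmax - cmin)))
            out.append(
                SpecimenMorphology(
                    species=label,
                    body_length_mm=round(float(length), 2),
                    complete=bool(row["complete"]),
                    abdominal_chaetiger_count=count,
                    white_venter_chaetigers=frozenset(row["white_venter"]),
                    geniculate_chaetigers=frozenset(row["geniculate"]),
                    ciliated_papilla_present=bool(row["ciliated_papilla"]),
                    papillae_on_lamellae=False,
                    branchiae=BranchiaeObservation(
                        fusion_fraction=round(float(fmin + rng.random() * (fmax - fmin)), 3),
                        reduced_lobes=row["branchiae_type"] == 4,
                        lamellae_count=int(rng.integers(row["lamellae"][0], row["lamellae"][1] + 1)),
                        ventral_filament_length_um=round(
                            float(
                                row["ventral_filament_um"][0]
                                + rng.random()
                                * (row["ventral_filament_um"][1] - row["ventral_filament_um"][0])
                            ),
                            1,
                        ),
                        fifth_lobe_present=bool(row["fifth_lobe"]),
                    ),
                    thoracic_uncinus=UncinusMeasurement(
                        rostrum_length=t_rost,
                        capitium_length=t_cap,
                        first_row_tooth_count=int(rng.integers(t_teeth[0], t_teeth[1] + 1)),
                        first_row_tooth_size=t_size,
                        capitium_row_count=t_rows,
                    ),
                    abdominal_uncinus=UncinusMeasurement(
                        rostrum_length=a_rost,
                        capitium_length=a_cap,
                        first_row_tooth_count=int(rng.integers(a_teeth[0], a_teeth[1] + 1)),
                        first_row_tooth_size=a_size,
                        capitium_row_count=a_rows,
                    ),
                    mg=MGStain(
                        segment_states=states,
                        j_region_segments=frozenset(row["mg_j_segments"]),
                    ),
                    depth_m=round(
                        float(
                            row["depth_m"][0]
                            + rng.random() * (row["depth_m"][1] - row["depth_m"][0])
                        ),
                        1,
                    ),
                    notochaetae_tc1_relative=row["notochaetae_tc1"],
                    glandular_region_tc3=row["glandular_tc3"],
                    ciliary_tufts_present=bool(row["ciliary_tufts"]),
                    upper_lip_elongated=False,
                )
            )
    return out
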