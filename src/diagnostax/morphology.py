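"""Morphological typologies, character-matrix identification and the
dichotomous key engine.

The verbal typologies (uncini, branchial lobe fusion, Methyl-Green staining)
are made operational through numeric thresholds collected in
:class:`Thresholds`; the defaults are calibrated so that the nominal
published values (rostrum:capitium 2:1 / 1:1 / 1:0.7 / 1:0.9, lobes fused
"~50%") classify to their nominal types.  All classifiers are total: every
valid observation maps to a type or to ``"unknown"``/``"other"``, never an
exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Any, Callable, Iterable, Mapping, Sequence

import yaml
from scipy import stats as _scipy_stats

__all__ = [
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "UncinusMeasurement",
    "BranchiaeObservation",
    "MGStain",
    "SpecimenMorphology",
    "CharacterMatrix",
    "Lead",
    "Key",
    "KeyConfigurationError",
    "KeyReport",
    "classify_thoracic_uncinus",
    "classify_abdominal_uncinus",
    "classify_branchiae",
    "classify_mg_pattern",
    "derive_characters",
    "matrix_identify",
    "key_traverse",
    "key_consistency_check",
    "abdominal_vs_length_stats",
    "load_character_matrix",
    "load_key",
]

UNKNOWN = "unknown"

#: characters whose key predicates are not morphological (couplet-18 style
#: bathymetric / geographic discrimination)
NON_MORPHOLOGICAL_CHARS = frozenset({"depth_m", "latitude", "longitude"})


@dataclass(frozen=True)
class Thresholds:
    """Numeric cut-offs backing the verbal typologies (all configurable)."""

    branchiae_reduced_fusion: float = 0.15  # below this + reduced lobes -> type 4
    branchiae_full_fusion: float = 0.8      # at/above -> type 1
    branchiae_half_fusion: float = 0.3      # at/above -> type 2, else type 3
    thoracic_rvc_large: float = 1.5         # rostrum/capitium at/above -> type-1 ratio
    abdominal_cr_split: float = 0.8         # capitium/rostrum at/below -> type 1A
    size_small_below_mm: float = 20.0
    size_large_above_mm: float = 40.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class UncinusMeasurement:
    """Rostrum/capitium geometry and first-row tooth profile of an uncinus."""

    rostrum_length: float
    capitium_length: float
    first_row_tooth_count: int
    first_row_tooth_size: str  # "large" | "mid" | "small"
    capitium_row_count: int = 1

    def __post_init__(self) -> None:
        if self.rostrum_length <= 0 or self.capitium_length <= 0:
            raise ValueError("uncinus lengths must be positive")
        if self.first_row_tooth_count < 1:
            raise ValueError("tooth count must be >= 1")
        if self.capitium_row_count < 1:
            raise ValueError("capitium row count must be >= 1")


@dataclass(frozen=True)
class BranchiaeObservation:
    fusion_fraction: float
    reduced_lobes: bool = False
    lamellae_count: int = 0
    ventral_filament_length_um: float | None = None
    fifth_lobe_present: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fusion_fraction <= 1.0:
            raise ValueError("fusion_fraction must lie in [0, 1]")
        if self.lamellae_count < 0:
            raise ValueError("lamellae_count must be >= 0")


@dataclass(frozen=True)
class MGStain:
    """Per-segment Methyl-Green staining states, SG 1..18."""

    segment_states: tuple[str, ...]
    j_region_segments: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.segment_states) != 18:
            raise ValueError("segment_states must cover SG 1..18")
        bad = set(self.segment_states) - {"solid", "striped", "white", "none"}
        if bad:
            raise ValueError(f"unknown staining states: {sorted(bad)}")


@dataclass(frozen=True)
class SpecimenMorphology:
    """One specimen's observable character states; ``None`` means unknown."""

    species: str | None = None
    body_length_mm: float | None = None
    complete: bool | None = None
    abdominal_chaetiger_count: int | None = None
    white_venter_chaetigers: frozenset[int] | None = None
    geniculate_chaetigers: frozenset[int] | None = None
    ciliated_papilla_present: bool | None = None
    papillae_on_lamellae: bool | None = None
    branchiae: BranchiaeObservation | None = None
    thoracic_uncinus: UncinusMeasurement | None = None
    abdominal_uncinus: UncinusMeasurement | None = None
    mg: MGStain | None = None
    depth_m: float | None = None
    notochaetae_tc1_relative: str | None = None  # similar|longer|shorter|absent
    glandular_region_tc3: str | None = None      # round|oval|J_shaped|absent
    glandular_tc3_mg_stain: str | None = None    # white|blue
    ciliary_tufts_present: bool | None = None
    upper_lip_elongated: bool | None = None


def classify_thoracic_uncinus(
    m: UncinusMeasurement, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> int | str:
    """Type the thoracic uncinus as 1, 3, 4 or ``"unknown"``.

    Type 1: rostrum at least 1.5x the capitium, 2-3 large first-row teeth.
    Type 3: 4-5 mid-sized first-row teeth.  Type 4: 5-7 small first-row
    teeth in at least two rows.  Conflicting counts are resolved by the
    tooth-size class.
    """
    rvc = m.rostrum_length / m.capitium_length
    if m.first_row_tooth_size == "large" and m.first_row_tooth_count in (2, 3):
        if rvc >= thresholds.thoracic_rvc_large:
            return 1
        return UNKNOWN
    if m.first_row_tooth_size == "mid" and m.first_row_tooth_count in (4, 5):
        return 3
    if (
        m.first_row_tooth_size == "small"
        and m.first_row_tooth_count in (5, 6, 7)
        and m.capitium_row_count >= 2
    ):
        return 4
    return UNKNOWN


def classify_abdominal_uncinus(
    m: UncinusMeasurement, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """Type the abdominal uncinus as ``"1A"``, ``"2"`` or ``"unknown"``.

    Type 1A: capitium at most 0.8x the rostrum with 3-5 large first-row
    teeth (the 0.8 boundary itself is assigned to 1A).  Type 2: capitium
    above 0.8x the rostrum with 4-5 first-row teeth.
    """
    cr = m.capitium_length / m.rostrum_length
    if (
        cr <= thresholds.abdominal_cr_split
        and m.first_row_tooth_size == "large"
        and m.first_row_tooth_count in (3, 4, 5)
    ):
        return "1A"
    if cr > thresholds.abdominal_cr_split and m.first_row_tooth_count in (4, 5):
        return "2"
    return UNKNOWN


def classify_branchiae(
    b: BranchiaeObservation, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> int:
    """Type the branchiae 1-4 from lobe fusion and lobe reduction."""
    if b.reduced_lobes and b.fusion_fraction < thresholds.branchiae_reduced_fusion:
        return 4
    if b.fusion_fraction >= thresholds.branchiae_full_fusion:
        return 1
    if b.fusion_fraction >= thresholds.branchiae_half_fusion:
        return 2
    return 3


# MG templates compare the solid/white/striped classes of SG 1-14 only;
# SG 15-18 behaviour ("fading") is not discriminating.
_MG_TEMPLATES: dict[int, tuple[tuple[str, ...], bool]] = {
    9: (("solid",) * 6 + ("striped",) * 8, True),
    1: (("solid",) * 6 + ("striped",) * 8, False),
    2: (("solid",) * 5 + ("white",) + ("striped",) * 8, False),
}


def classify_mg_pattern(s: MGStain) -> int | str:
    """Assign Methyl-Green pattern 1, 2, 9 or ``"other"``.

    A J-shaped glandular region is required for pattern 9 and forbidden for
    patterns 1 and 2.
    """
    has_j = bool(s.j_region_segments)
    front = s.segment_states[:14]
    for pattern, (template, wants_j) in _MG_TEMPLATES.items():
        if wants_j == has_j and front == template:
            return pattern
    return "other"


# ---------------------------------------------------------------------------
# Derived character states


def _derive_white_venter(chaetigers: frozenset[int] | None) -> str | None:
    if chaetigers is None:
        return None
    if not chaetigers:
        return "none"
    if chaetigers == {4}:
        return "TC4"
    if chaetigers == {1, 2, 3, 4}:
        return "TC1-4"
    return "other"


def _derive_size_class(length: float | None, t: Thresholds) -> str | None:
    if length is None:
        return None
    if length < t.size_small_below_mm:
        return "small"
    if length > t.size_large_above_mm:
        return "large"
    return "medium"


def _derive_geniculate(chaetigers: frozenset[int] | None) -> str | None:
    if chaetigers is None:
        return None
    if chaetigers == {6}:
        return "TC6"
    if chaetigers == {5, 6}:
        return "TC5-6"
    return "other"


def derive_characters(
    specimen: SpecimenMorphology, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> dict[str, Any]:
    """Flatten a specimen into the character states the matrix and key use.

    ``None`` marks characters that cannot be derived from the observation.
    """
    unk = lambda v: None if v == UNKNOWN else v
    return {
        "branchiae_type": (
            classify_branchiae(specimen.branchiae, thresholds)
            if specimen.branchiae is not None
            else None
        ),
        "thoracic_type": (
            unk(classify_thoracic_uncinus(specimen.thoracic_uncinus, thresholds))
            if specimen.thoracic_uncinus is not None
            else None
        ),
        "abdominal_type": (
            unk(classify_abdominal_uncinus(specimen.abdominal_uncinus, thresholds))
            if specimen.abdominal_uncinus is not None
            else None
        ),
        "abdominal_cr": (
            specimen.abdominal_uncinus.capitium_length
            / specimen.abdominal_uncinus.rostrum_length
            if specimen.abdominal_uncinus is not None
            else None
        ),
        "mg_pattern": (
            classify_mg_pattern(specimen.mg) if specimen.mg is not None else None
        ),
        "ciliated_papilla": specimen.ciliated_papilla_present,
        "white_venter": _derive_white_venter(specimen.white_venter_chaetigers),
        "papillae_on_lamellae": specimen.papillae_on_lamellae,
        "size_class": _derive_size_class(specimen.body_length_mm, thresholds),
        "fifth_lobe": (
            specimen.branchiae.fifth_lobe_present
            if specimen.branchiae is not None
            else None
        ),
        "notochaetae_tc1": specimen.notochaetae_tc1_relative,
        "geniculate": _derive_geniculate(specimen.geniculate_chaetigers),
        "glandular_tc3": specimen.glandular_region_tc3,
        "glandular_tc3_mg_stain": specimen.glandular_tc3_mg_stain,
        "ciliary_tufts": specimen.ciliary_tufts_present,
        "upper_lip_elongated": specimen.upper_lip_elongated,
        "depth_m": specimen.depth_m,
    }


# ---------------------------------------------------------------------------
# Character matrix


class MatrixConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxon x character state table; ``"unknown"`` states match anything."""

    characters: tuple[tuple[str, tuple[Any, ...]], ...]
    states: Mapping[str, Mapping[str, Any]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.characters]
        for taxon, row in self.states.items():
            missing = set(names) - set(row)
            if missing:
                raise MatrixConfigurationError(
                    f"taxon {taxon!r} lacks states for {sorted(missing)}"
                )
            for name, domain in self.characters:
                value = row[name]
                if value != UNKNOWN and value not in domain:
                    raise MatrixConfigurationError(
                        f"state {value!r} of {taxon!r}/{name} outside domain {domain}"
                    )

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.states)


def load_character_matrix(path: str | None = None) -> CharacterMatrix:
    """Load the bundled (or a user-supplied) character matrix."""
    if path is None:
        text = (
            importlib_resources.files("diagnostax")
            .joinpath("resources", "character_matrix.yaml")
            .read_text()
        )
    else:
        with open(path) as handle:
            text = handle.read()
    doc = yaml.safe_load(text)
    characters = tuple(
        (entry["name"], tuple(entry["domain"])) for entry in doc["characters"]
    )
    return CharacterMatrix(characters=characters, states=doc["taxa"])


def matrix_identify(
    specimen: SpecimenMorphology,
    matrix: CharacterMatrix,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[str, ...]:
    """All taxa whose matrix states are consistent with the specimen.

    Unknown states on either side match anything.  A matrix character with
    no derivation rule is a configuration error.
    """
    derived = derive_characters(specimen, thresholds)
    for name, _ in matrix.characters:
        if name not in derived:
            raise MatrixConfigurationError(f"no derivation rule for character {name!r}")
    hits = []
    for taxon in matrix.taxa:
        row = matrix.states[taxon]
        consistent = True
        for name, _ in matrix.characters:
            observed = derived[name]
            expected = row[name]
            if observed is None or expected == UNKNOWN:
                continue
            if observed != expected:
                consistent = False
                break
        if consistent:
            hits.append(taxon)
    return tuple(hits)


# ---------------------------------------------------------------------------
# Dichotomous key


class KeyConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Lead:
    """One of the two alternatives of a couplet."""

    predicates: tuple[tuple[str, str, Any], ...]  # (character, op, value)
    goto: int | None = None
    taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.goto is None) == (not self.taxa):
            raise KeyConfigurationError("lead must target a couplet xor a taxon set")


_OPS: dict[str, Callable[[Any, Any], bool]] = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "in": lambda a, b: a in b,
    "not_in": lambda a, b: a not in b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}


@dataclass(frozen=True)
class Key:
    """Numbered couplets, two leads each, rooted at couplet 1."""

    couplets: Mapping[int, tuple[Lead, Lead]]

    def __post_init__(self) -> None:
        if 1 not in self.couplets:
            raise KeyConfigurationError("key must contain couplet 1")
        for number, leads in self.couplets.items():
            for lead in leads:
                if lead.goto is not None and lead.goto not in self.couplets:
                    raise KeyConfigurationError(
                        f"couplet {number} points to missing couplet {lead.goto}"
                    )
        self._check_acyclic_and_reachable()

    def _check_acyclic_and_reachable(self) -> None:
        color: dict[int, int] = {}

        def visit(node: int, trail: tuple[int, ...]) -> None:
            if color.get(node) == 1:
                raise KeyConfigurationError(f"cycle through couplets {trail + (node,)}")
            if color.get(node) == 2:
                return
            color[node] = 1
            for lead in self.couplets[node]:
                if lead.goto is not None:
                    visit(lead.goto, trail + (node,))
            color[node] = 2

        visit(1, ())
        unreachable = set(self.couplets) - set(color)
        if unreachable:
            raise KeyConfigurationError(
                f"couplets unreachable from couplet 1: {sorted(unreachable)}"
            )

    def reachable_taxa(self, start: int = 1) -> frozenset[str]:
        out: set[str] = set()
        stack = [start]
        seen: set[int] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            for lead in self.couplets[node]:
                if lead.goto is not None:
                    stack.append(lead.goto)
                else:
                    out.update(lead.taxa)
        return frozenset(out)


def load_key(path: str | None = None) -> Key:
    """Load the bundled (or a user-supplied) dichotomous key."""
    if path is None:
        text = (
            importlib_resources.files("diagnostax")
            .joinpath("resources", "identification_key.yaml")
            .read_text()
        )
    else:
        with open(path) as handle:
            text = handle.read()
    doc = yaml.safe_load(text)
    couplets: dict[int, tuple[Lead, Lead]] = {}
    for number, leads in doc["couplets"].items():
        if len(leads) != 2:
            raise KeyConfigurationError(f"couplet {number} must have exactly two leads")
        built = []
        for lead in leads:
            predicates = tuple(
                (p["char"], p["op"], tuple(p["value"]) if isinstance(p["value"], list) else p["value"])
                for p in lead.get("predicates", [])
            )
            for _, op, _ in predicates:
                if op not in _OPS:
                    raise KeyConfigurationError(f"unknown predicate op {op!r}")
            built.append(
                Lead(
                    predicates=predicates,
                    goto=lead.get("goto"),
                    taxa=tuple(lead.get("taxa", [])),
                )
            )
        couplets[int(number)] = (built[0], built[1])
    return Key(couplets=couplets)


def _lead_status(lead: Lead, derived: Mapping[str, Any]) -> bool | None:
    """True = satisfied, False = contradicted, None = undecidable."""
    saw_unknown = False
    for char, op, value in lead.predicates:
        observed = derived.get(char)
        if observed is None:
            saw_unknown = True
            continue
        if not _OPS[op](observed, value):
            return False
    return None if saw_unknown else True


def key_traverse(
    specimen: SpecimenMorphology | Mapping[str, Any],
    key: Key,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[tuple[str, ...], list[tuple[int, int]]]:
    """Run a specimen through the key from couplet 1.

    At each couplet the satisfied lead is followed; when one lead is
    contradicted the other is followed (dichotomy), and when neither or
    both remain decidable the traversal stops, returning the union of all
    taxa reachable from the current couplet together with the partial path
    of ``(couplet, lead index)`` choices.
    """
    derived = (
        dict(specimen)
        if isinstance(specimen, Mapping)
        else derive_characters(specimen, thresholds)
    )
    path: list[tuple[int, int]] = []
    node = 1
    while True:
        first, second = key.couplets[node]
        statuses = (_lead_status(first, derived), _lead_status(second, derived))
        if statuses[0] is True and statuses[1] in (False, None):
            chosen = 0
        elif statuses[1] is True and statuses[0] in (False, None):
            chosen = 1
        elif statuses[0] is False and statuses[1] is None:
            chosen = 1
        elif statuses[1] is False and statuses[0] is None:
            chosen = 0
        else:  # both true, both false, or both unknown
            return tuple(sorted(key.reachable_taxa(node))), path
        path.append((node, chosen))
        lead = key.couplets[node][chosen]
        if lead.taxa:
            return lead.taxa, path
        node = lead.goto  # type: ignore[assignment]


@dataclass
class KeyReport:
    reachable_taxa: tuple[str, ...]
    failures: list[str] = field(default_factory=list)
    multi_taxon_terminals: list[tuple[int, int, tuple[str, ...]]] = field(default_factory=list)
    non_morphological_terminals: list[tuple[int, int, tuple[str, ...]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def key_consistency_check(key: Key, matrix: CharacterMatrix | None = None) -> KeyReport:
    """Cross-check the key structure (and optionally the matrix taxa).

    Reports taxa of the matrix missing from the key, terminals naming more
    than one taxon, and terminals decided by non-morphological characters
    (bathymetry / geography).
    """
    reachable = key.reachable_taxa()
    report = KeyReport(reachable_taxa=tuple(sorted(reachable)))
    if matrix is not None:
        for taxon in matrix.taxa:
            if taxon not in reachable:
                report.failures.append(f"taxon {taxon!r} unreachable in the key")
    for number, leads in sorted(key.couplets.items()):
        for idx, lead in enumerate(leads):
            if len(lead.taxa) > 1:
                report.multi_taxon_terminals.append((number, idx, lead.taxa))
            if lead.taxa and any(
                char in NON_MORPHOLOGICAL_CHARS for char, _, _ in lead.predicates
            ):
                report.non_morphological_terminals.append((number, idx, lead.taxa))
    return report


# ---------------------------------------------------------------------------
# Abdominal chaetiger count vs body length


@dataclass(frozen=True)
class LengthCountStats:
    per_species: Mapping[str, Mapping[str, Any]]
    correlation: float | None
    n_points: int
    note: str = ""


def abdominal_vs_length_stats(
    by_species: Mapping[str, Sequence[SpecimenMorphology]],
    exempt_incomplete: Iterable[str] = ("T. irinae",),
) -> LengthCountStats:
    """Per-species ranges and the overall Pearson length-count correlation.

    Incomplete specimens are excluded except for species in
    ``exempt_incomplete`` (whose counts are reported as observed minima).
    With fewer than 3 usable points, or zero variance in either variable,
    the correlation is reported as missing.
    """
    exempt = set(exempt_incomplete)
    lengths: list[float] = []
    counts: list[int] = []
    per_species: dict[str, dict[str, Any]] = {}
    for species, specimens in by_species.items():
        usable = [
            s
            for s in specimens
            if s.body_length_mm is not None
            and s.abdominal_chaetiger_count is not None
            and (s.complete or species in exempt)
        ]
        if usable:
            ls = [s.body_length_mm for s in usable]
            cs = [s.abdominal_chaetiger_count for s in usable]
            per_species[species] = {
                "length_range": (min(ls), max(ls)),
                "chaetiger_range": (min(cs), max(cs)),
                "n": len(usable),
            }
            lengths.extend(ls)
            counts.extend(cs)
        else:
            per_species[species] = {"length_range": None, "chaetiger_range": None, "n": 0}

    if len(lengths) < 3:
        return LengthCountStats(per_species, None, len(lengths), "fewer than 3 usable points")
    if len(set(lengths)) == 1 or len(set(counts)) == 1:
        return LengthCountStats(per_species, None, len(lengths), "zero variance")
    r, _ = _scipy_stats.pearsonr(lengths, counts)
    return LengthCountStats(per_species, float(r), len(lengths))
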