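"""Extraction, verification and formatting of diagnostic nucleotide combinations.

A column is *focal-invariant* for a species when every sequence of that
species carries the same concrete nucleotide (``A/C/G/T``) there — gaps and
ambiguity codes disqualify the column.  A focal-invariant column is
*strictly diagnostic* when no sequence of any other species could carry the
focal state: a background ambiguity code compatible with the focal state
counts as a potential match and disqualifies; a background gap never
matches and never disqualifies.

Diagnoses group consecutive focal-invariant columns into regions: each
region is a maximal run of focal-invariant columns containing at least one
strictly diagnostic column, and the motif is the focal states over the run.
The plain-text dialect for a diagnosis is a comma-separated list of
``start–end: MOTIF`` entries (``pos: X`` for single columns).
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .msa_io import IUPAC_EXPANSION, Alignment, SpeciesMap, SpeciesMapError

__all__ = [
    "Region",
    "Diagnosis",
    "ValidationReport",
    "DiagnosisFormatError",
    "compute_focal_invariant_columns",
    "compute_strict_diagnostic_columns",
    "assemble_diagnosis",
    "verify_combination",
    "minimal_combination",
    "parse_diagnosis_block",
    "format_diagnosis_block",
    "profiles_to_yaml",
    "profiles_from_yaml",
]

logger = logging.getLogger(__name__)

CONCRETE = frozenset("ACGT")

# Per-region validator flags
SPAN_LENGTH_MISMATCH = "span_length_mismatch"
COORDINATE_MISSING = "coordinate_missing"
NON_MONOTONIC = "non_monotonic"
ALPHABET_VIOLATION = "alphabet_violation"


class DiagnosisFormatError(ValueError):
    """Unparseable diagnosis block."""


def states_compatible(background: str, focal: str) -> bool:
    """True when a background symbol could stand for the focal nucleotide.

    ``R`` is compatible with ``A`` (R = A/G); a gap is compatible with
    nothing.
    """
    return focal in IUPAC_EXPANSION.get(background, frozenset())


@dataclass(frozen=True)
class Region:
    """A contiguous diagnostic region in 1-based inclusive coordinates."""

    start: int
    end: int
    motif: str
    diagnostic_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad region coordinates {self.start}-{self.end}")
        if not self.diagnostic_positions:
            raise ValueError("diagnostic_positions must be nonempty")
        if not all(self.start <= p <= self.end for p in self.diagnostic_positions):
            raise ValueError("diagnostic positions outside region span")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)

    def motif_at(self, column: int) -> str:
        """Motif character at an absolute alignment column."""
        return self.motif[column - self.start]


@dataclass(frozen=True)
class Diagnosis:
    """Per-species collection of diagnostic regions."""

    species: str
    regions: tuple[Region, ...]
    source: str = "computed"  # "computed" | "parsed"
    provenance: str | None = None

    @property
    def diagnostic_positions(self) -> frozenset[int]:
        out: set[int] = set()
        for region in self.regions:
            out |= region.diagnostic_positions
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class ValidationReport:
    """Outcome of structural and exclusivity checks on a diagnosis."""

    species: str
    #: per-region flag lists, parallel to the diagnosis' regions
    region_flags: list[list[str]] = field(default_factory=list)
    #: background id -> (region index, column) witnessing its exclusion
    exclusion_evidence: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: background ids not excluded by any region
    unexcluded: list[str] = field(default_factory=list)
    #: (focal id, region index, column) triples where a focal sequence
    #: deviates from the motif
    focal_failures: list[tuple[str, int, int]] = field(default_factory=list)
    #: species with a single supporting sequence get a low-support note
    notes: list[str] = field(default_factory=list)
    verdict: str = "pass"  # "pass" | "fail" | "malformed"

    @property
    def flagged(self) -> bool:
        return any(self.region_flags)


def _fingerprint(alignment: Alignment) -> str:
    digest = hashlib.sha256()
    for seq in alignment:
        digest.update(seq.id.encode())
        digest.update(b"\x00")
        digest.update(seq.residues.encode())
        digest.update(b"\x01")
    return f"n={len(alignment)};L={alignment.length};sha256={digest.hexdigest()[:16]}"


def _split_rows(
    alignment: Alignment, species_map: SpeciesMap, species: str
) -> tuple[list[str], list[tuple[str, str]]]:
    """Focal residue strings and (id, residues) background rows."""
    focal: list[str] = []
    background: list[tuple[str, str]] = []
    for seq in alignment:
        if species_map.assignments.get(seq.id) == species:
            focal.append(seq.residues)
        else:
            background.append((seq.id, seq.residues))
    if not focal:
        raise SpeciesMapError(f"species {species!r} has no sequences in the alignment")
    return focal, background


def compute_focal_invariant_columns(
    alignment: Alignment, species_map: SpeciesMap, species: str
) -> dict[int, str]:
    """Columns where every focal sequence carries the same ``A/C/G/T`` state.

    Returns a mapping of 1-based column to the shared state.  A gap or
    ambiguity code in any focal sequence disqualifies the column.
    """
    focal, _ = _split_rows(alignment, species_map, species)
    out: dict[int, str] = {}
    for col in range(1, alignment.length + 1):
        states = {row[col - 1] for row in focal}
        if len(states) == 1:
            state = next(iter(states))
            if state in CONCRETE:
                out[col] = state
    return out


def compute_strict_diagnostic_columns(
    alignment: Alignment, species_map: SpeciesMap, species: str
) -> dict[int, str]:
    """Focal-invariant columns whose state no background sequence can match."""
    _, background = _split_rows(alignment, species_map, species)
    if not background:
        raise SpeciesMapError(
            f"species {species!r} has no background sequences to be diagnosed against"
        )
    invariant = compute_focal_invariant_columns(alignment, species_map, species)
    return {
        col: state
        for col, state in invariant.items()
        if not any(states_compatible(row[col - 1], state) for _, row in background)
    }


def assemble_diagnosis(
    alignment: Alignment, species_map: SpeciesMap, species: str
) -> Diagnosis:
    """Build the diagnosis of ``species`` against all other sequences.

    Regions are maximal runs of consecutive focal-invariant columns that
    contain at least one strictly diagnostic column; the motif records the
    focal states over the run.  An empty strict set yields a diagnosis with
    zero regions (logged as a warning, not an error).
    """
    invariant = compute_focal_invariant_columns(alignment, species_map, species)
    strict = compute_strict_diagnostic_columns(alignment, species_map, species)
    regions: list[Region] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        diagnostic = frozenset(c for c in run if c in strict)
        if diagnostic:
            regions.append(
                Region(
                    start=run[0],
                    end=run[-1],
                    motif="".join(invariant[c] for c in run),
                    diagnostic_positions=diagnostic,
                )
            )

    for col in sorted(invariant):
        if run and col == run[-1] + 1:
            run.append(col)
        else:
            if run:
                flush(run)
            run = [col]
    if run:
        flush(run)

    if not regions:
        logger.warning("species %r has no strictly diagnostic columns", species)
    return Diagnosis(
        species=species,
        regions=tuple(regions),
        source="computed",
        provenance=_fingerprint(alignment),
    )


def verify_combination(
    diagnosis: Diagnosis, alignment: Alignment, species_map: SpeciesMap
) -> ValidationReport:
    """Check a diagnosis against a labeled alignment.

    Passes iff (a) every focal sequence matches every region motif exactly
    over its span, and (b) every background sequence fails at least one
    region at a diagnostic column.  Regions outside the alignment make the
    report ``malformed``.
    """
    report = ValidationReport(species=diagnosis.species)
    report.region_flags = [_structural_flags(diagnosis.regions, i) for i in range(len(diagnosis.regions))]
    if report.flagged:
        report.verdict = "malformed"
        return report

    for region in diagnosis.regions:
        if region.end > alignment.length:
            report.verdict = "malformed"
            report.notes.append(
                f"region {region.start}-{region.end} exceeds alignment length {alignment.length}"
            )
            return report

    focal_ids = [
        s.id for s in alignment if species_map.assignments.get(s.id) == diagnosis.species
    ]
    if not focal_ids:
        raise SpeciesMapError(
            f"species {diagnosis.species!r} has no sequences in the alignment"
        )
    if len(focal_ids) == 1:
        report.notes.append("low support: species represented by a single sequence")

    for seq in alignment:
        is_focal = species_map.assignments.get(seq.id) == diagnosis.species
        if is_focal:
            for ridx, region in enumerate(diagnosis.regions):
                for col in region.columns:
                    if seq.residues[col - 1] != region.motif_at(col):
                        report.focal_failures.append((seq.id, ridx, col))
        else:
            evidence = None
            for ridx, region in enumerate(diagnosis.regions):
                for col in sorted(region.diagnostic_positions):
                    if not states_compatible(seq.residues[col - 1], region.motif_at(col)):
                        evidence = (ridx, col)
                        break
                if evidence:
                    break
            if evidence:
                report.exclusion_evidence[seq.id] = evidence
            else:
                report.unexcluded.append(seq.id)

    if report.focal_failures or report.unexcluded or not diagnosis.regions:
        report.verdict = "fail"
    return report


def _structural_flags(regions: Sequence[Region], index: int) -> list[str]:
    region = regions[index]
    flags: list[str] = []
    if len(region.motif) != region.span:
        flags.append(SPAN_LENGTH_MISMATCH)
    if index > 0 and region.start < regions[index - 1].start:
        flags.append(NON_MONOTONIC)
    if any(c not in CONCRETE for c in region.motif):
        flags.append(ALPHABET_VIOLATION)
    return flags


def minimal_combination(
    diagnosis: Diagnosis, alignment: Alignment, species_map: SpeciesMap
) -> Diagnosis:
    """Greedy reduction of a verified diagnosis to a covering subset of regions.

    Regions are retained in order of how many not-yet-excluded background
    sequences they exclude (ties broken by smaller start), until every
    background sequence is excluded by at least one retained region.
    Requires the input to pass :func:`verify_combination`.
    """
    report = verify_combination(diagnosis, alignment, species_map)
    if report.verdict != "pass":
        raise ValueError(
            f"cannot minimize a diagnosis that does not verify (verdict={report.verdict})"
        )

    background = [
        (s.id, s.residues)
        for s in alignment
        if species_map.assignments.get(s.id) != diagnosis.species
    ]
    exclusion_sets: list[set[str]] = []
    for region in diagnosis.regions:
        excluded = {
            seq_id
            for seq_id, row in background
            if any(
                not states_compatible(row[col - 1], region.motif_at(col))
                for col in region.diagnostic_positions
            )
        }
        exclusion_sets.append(excluded)

    uncovered = {seq_id for seq_id, _ in background}
    retained: list[int] = []
    while uncovered:
        best = max(
            range(len(diagnosis.regions)),
            key=lambda i: (len(exclusion_sets[i] & uncovered), -diagnosis.regions[i].start),
        )
        gain = exclusion_sets[best] & uncovered
        if not gain:  # unreachable for verified input, defensive
            break
        retained.append(best)
        uncovered -= gain

    regions = tuple(diagnosis.regions[i] for i in sorted(retained))
    return Diagnosis(
        species=diagnosis.species,
        regions=regions,
        source=diagnosis.source,
        provenance=diagnosis.provenance,
    )


# Entry dialect: "78–99: TCAACC...", "306: C"; en/em dash, hyphen or minus
# accepted, arbitrary whitespace tolerated (the printed "288– 292" case).
_ENTRY_RE = re.compile(
    r"(\d+)\s*(?:[–—−-]\s*(\d+))?\s*:\s*([ACGTUacgtu]+)"
)


def parse_diagnosis_block(text: str, species: str = "") -> tuple[Diagnosis, ValidationReport]:
    """Parse a printed plain-text diagnosis block.

    Tolerant-but-flagging: entries whose motif length disagrees with the
    coordinate span are kept and flagged (``span_length_mismatch``), a
    multi-nucleotide motif under a single coordinate is flagged
    ``coordinate_missing``, and out-of-order starts are flagged
    ``non_monotonic``.  Coordinates are never silently repaired.  Parsed
    regions treat the whole span as candidate-diagnostic (which nucleotides
    were underlined in print is not machine-readable).
    """
    if not text.strip():
        raise DiagnosisFormatError("empty diagnosis block")
    matches = _ENTRY_RE.findall(text)
    if not matches:
        raise DiagnosisFormatError(f"no parseable 'start-end: MOTIF' entry in {text!r}")

    regions: list[Region] = []
    all_flags: list[list[str]] = []
    prev_start = 0
    for start_s, end_s, motif in matches:
        start = int(start_s)
        motif = motif.upper().replace("U", "T")
        flags: list[str] = []
        if end_s:
            end = int(end_s)
            if end < start:
                flags.append(NON_MONOTONIC)
                end = start  # keep a representable span; flag records the defect
            if end - start + 1 != len(motif):
                flags.append(SPAN_LENGTH_MISMATCH)
        else:
            end = start
            if len(motif) != 1:
                flags.append(COORDINATE_MISSING)
                flags.append(SPAN_LENGTH_MISMATCH)
        if start < prev_start:
            flags.append(NON_MONOTONIC)
        prev_start = start
        regions.append(
            Region(
                start=start,
                end=end,
                motif=motif,
                diagnostic_positions=frozenset(range(start, end + 1)),
            )
        )
        all_flags.append(flags)

    diagnosis = Diagnosis(
        species=species, regions=tuple(regions), source="parsed", provenance="text"
    )
    report = ValidationReport(
        species=species,
        region_flags=all_flags,
        verdict="malformed" if any(all_flags) else "pass",
    )
    return diagnosis, report


def format_diagnosis_block(diagnosis: Diagnosis) -> str:
    """Render a diagnosis in the plain-text dialect.

    ``parse_diagnosis_block(format_diagnosis_block(d))`` reproduces the
    coordinates and motifs of ``d`` exactly.  An empty diagnosis renders as
    the empty string (with a warning).
    """
    if not diagnosis.regions:
        logger.warning("formatting an empty diagnosis for %r", diagnosis.species)
        return ""
    entries = []
    for region in diagnosis.regions:
        if region.start == region.end:
            entries.append(f"{region.start}: {region.motif}")
        else:
            entries.append(f"{region.start}–{region.end}: {region.motif}")
    return ", ".join(entries)


def profiles_to_yaml(profiles: Iterable[Diagnosis]) -> str:
    """Serialize diagnosis profiles to a YAML document keyed by species."""
    doc: dict[str, list[dict]] = {}
    for diagnosis in profiles:
        doc[diagnosis.species] = [
            {
                "start": r.start,
                "end": r.end,
                "motif": r.motif,
                "diagnostic_positions": sorted(r.diagnostic_positions),
            }
            for r in diagnosis.regions
        ]
    return yaml.safe_dump(doc, sort_keys=True)


def profiles_from_yaml(text: str) -> list[Diagnosis]:
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise DiagnosisFormatError("profile document must map species to region lists")
    profiles = []
    for species, entries in doc.items():
        regions = tuple(
            Region(
                start=int(e["start"]),
                end=int(e["end"]),
                motif=str(e["motif"]),
                diagnostic_positions=frozenset(int(p) for p in e["diagnostic_positions"]),
            )
            for e in entries
        )
        profiles.append(Diagnosis(species=species, regions=regions, source="parsed"))
    return profiles
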