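"""Reading and writing aligned sequences and species labels.

Conventions used throughout the package:

* alignment columns are **1-based inclusive** (``78-99`` means columns 78
  through 99, both ends included);
* residues are uppercase over ``{A, C, G, T, -}`` plus IUPAC ambiguity
  codes; ``U`` is normalised to ``T`` on input and lowercase is raised;
* IUPAC codes are retained verbatim at I/O time — their semantics are a
  concern of the diagnostics layer, not of ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "IUPAC_EXPANSION",
    "ALLOWED_SYMBOLS",
    "AlignedSequence",
    "Alignment",
    "SpeciesMap",
    "AlignmentShapeError",
    "AlignmentFormatError",
    "SpeciesMapError",
    "normalize_residues",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_species_map",
    "write_species_map",
]

#: Expansion of every accepted residue symbol into the set of concrete
#: nucleotides it may stand for.  Gaps expand to the empty set.
IUPAC_EXPANSION: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

ALLOWED_SYMBOLS = frozenset(IUPAC_EXPANSION)


class AlignmentFormatError(ValueError):
    """Malformed FASTA input (empty file, illegal symbol...)."""


class AlignmentShapeError(AlignmentFormatError):
    """Sequences of unequal length where an alignment was expected."""


class SpeciesMapError(ValueError):
    """Malformed or self-contradictory species map."""


def normalize_residues(residues: str) -> str:
    """Uppercase ``residues`` and map ``U`` to ``T``.

    Idempotent; does not validate symbols (see :func:`read_fasta_alignment`).
    """
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class AlignedSequence:
    """A single row of an alignment."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentFormatError("sequence id must be nonempty")

    def ungapped(self) -> str:
        """Residues with gap characters removed."""
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length sequences."""

    sequences: tuple[AlignedSequence, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentShapeError("alignment must contain at least one sequence")
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) != 1:
            offenders = sorted({s.id for s in self.sequences})
            raise AlignmentShapeError(
                f"ragged alignment: sequences of lengths {sorted(lengths)} "
                f"among ids {offenders}"
            )
        if lengths == {0}:
            raise AlignmentShapeError("alignment length must be positive")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence ids: {dupes}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple(AlignedSequence(i, normalize_residues(r)) for i, r in pairs))

    @property
    def length(self) -> int:
        """Number of columns (L)."""
        return len(self.sequences[0].residues)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.sequences)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def column(self, col: int) -> str:
        """States of 1-based column ``col``, one character per sequence."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside [1, {self.length}]")
        return "".join(s.residues[col - 1] for s in self.sequences)


@dataclass(frozen=True)
class SpeciesMap:
    """Mapping of sequence id to species label."""

    assignments: Mapping[str, str] = field(default_factory=dict)

    def species_of(self, seq_id: str) -> str:
        try:
            return self.assignments[seq_id]
        except KeyError:
            raise SpeciesMapError(f"no species assignment for sequence {seq_id!r}")

    @property
    def species(self) -> tuple[str, ...]:
        """Distinct species labels, in first-seen order."""
        return tuple(dict.fromkeys(self.assignments.values()))

    def members(self, species: str) -> tuple[str, ...]:
        return tuple(i for i, sp in self.assignments.items() if sp == species)

    def __len__(self) -> int:
        return len(self.assignments)


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Residues are uppercased and ``U`` is mapped to ``T``.  Record order is
    preserved.  Raises :class:`AlignmentShapeError` on ragged input and
    :class:`AlignmentFormatError` on empty files or illegal symbols (the
    error message names the offending id and 1-based position).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    sequences = []
    for rec in records:
        residues = normalize_residues(str(rec.seq))
        for pos, symbol in enumerate(residues, start=1):
            if symbol not in ALLOWED_SYMBOLS:
                raise AlignmentFormatError(
                    f"illegal symbol {symbol!r} at position {pos} of record {rec.id!r}"
                )
        sequences.append(AlignedSequence(rec.id, residues))
    return Alignment(tuple(sequences))


def write_fasta_alignment(alignment: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write ``alignment`` as FASTA, line-wrapped at ``wrap`` columns.

    ``read_fasta_alignment(write_fasta_alignment(a))`` reproduces ``a``
    exactly (ids, order and residues).
    """
    with open(path, "w") as handle:
        for seq in alignment:
            handle.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), wrap):
                handle.write(seq.residues[start : start + wrap] + "\n")


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a two-column, tab-separated ``sequence-id<TAB>species`` file.

    Lines starting with ``#`` and blank lines are skipped.  Duplicate rows
    are deduplicated; a duplicate id with a *conflicting* species raises
    :class:`SpeciesMapError`.
    """
    assignments: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise SpeciesMapError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
                )
            seq_id, species = parts[0].strip(), parts[1].strip()
            if seq_id in assignments and assignments[seq_id] != species:
                raise SpeciesMapError(
                    f"{path}:{lineno}: conflicting species for id {seq_id!r}: "
                    f"{assignments[seq_id]!r} vs {species!r}"
                )
            assignments[seq_id] = species
    return SpeciesMap(assignments)


def write_species_map(species_map: SpeciesMap, path: str | Path) -> None:
    with open(path, "w") as handle:
        for seq_id, species in species_map.assignments.items():
            handle.write(f"{seq_id}\t{species}\n")
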