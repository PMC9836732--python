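"""Parsing of museum specimen listings and occurrence summaries.

Listings follow the style ``<region> (CODE1, CODE2, ...); <region> (...)``
with museum prefixes ``ZMBN``, ``GNM`` and ``NTNU-VM`` (en dash tolerated);
a bare number inside a code group inherits the prefix of the preceding
code.  Unless stated otherwise, one registration code holds one specimen.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SpecimenRecord",
    "RegistryFormatError",
    "parse_material_examined",
    "parse_holotype_measurements",
    "depth_fraction",
    "DepthSummary",
]


class RegistryFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SpecimenRecord:
    code: str
    museum: str
    region: str = ""
    role: str = "non_type"  # holotype | paratype | non_type
    count: int = 1
    depth_m: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    body_length_mm: float | None = None
    body_width_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.code:
            raise RegistryFormatError("registration code must be nonempty")
        if self.count < 1:
            raise RegistryFormatError("specimen count must be >= 1")


_PREFIX_RE = r"(?:ZMBN|GNM|NTNU\s*[–—-]?\s*VM)"
_CODE_RE = re.compile(rf"^({_PREFIX_RE})\s*(\d+)$")
_BARE_RE = re.compile(r"^\d+$")
_GROUP_RE = re.compile(r"([^();]*)\(([^()]*)\)")
_STATED_RE = re.compile(r"(\d+)\s+specimens")
_HOLOTYPE_RE = re.compile(rf"Holotype\s*:?\s*({_PREFIX_RE}\s*\d+)", re.IGNORECASE)


def _normalize_prefix(prefix: str) -> str:
    prefix = re.sub(r"[–—\s-]", "", prefix.upper())
    return "NTNU-VM" if prefix == "NTNUVM" else prefix


def parse_material_examined(text: str) -> list[SpecimenRecord]:
    """Extract one record per registration code from a printed listing.

    Records appear in listing order.  Bare numbers inherit the prefix of
    the previous code in the same parenthetical group.  A stated specimen
    count disagreeing with the number of parsed codes triggers a warning
    (the discrepancy is reported, never reconciled).  Raises
    :class:`RegistryFormatError` when no code at all is found.
    """
    if not text.strip():
        raise RegistryFormatError("empty material-examined text")

    records: list[SpecimenRecord] = []

    holotype_match = _HOLOTYPE_RE.search(text)
    holotype_code = None
    if holotype_match:
        prefix, number = _CODE_RE.match(holotype_match.group(1).strip()).groups()
        museum = _normalize_prefix(prefix)
        holotype_code = f"{museum}{number}"
        records.append(
            SpecimenRecord(code=holotype_code, museum=museum, region="", role="holotype")
        )

    paratype_offset = text.find("Paratype")

    for match in _GROUP_RE.finditer(text):
        label = match.group(1)
        region = label.strip().strip(".,;:").split(";")[-1].split(":")[-1].strip()
        role = (
            "paratype"
            if paratype_offset != -1 and match.start() > paratype_offset
            else "non_type"
        )
        last_museum: str | None = None
        for chunk in match.group(2).split(","):
            chunk = chunk.strip()
            code_match = _CODE_RE.match(chunk)
            if code_match:
                prefix, number = code_match.groups()
                last_museum = _normalize_prefix(prefix)
                records.append(
                    SpecimenRecord(
                        code=f"{last_museum}{number}",
                        museum=last_museum,
                        region=region,
                        role=role,
                    )
                )
            elif _BARE_RE.match(chunk) and last_museum is not None:
                records.append(
                    SpecimenRecord(
                        code=f"{last_museum}{chunk}",
                        museum=last_museum,
                        region=region,
                        role=role,
                    )
                )
            # anything else ("Suppl. material S1", "16 specimens") is not a code

    if not records:
        raise RegistryFormatError(f"no registration codes found in {text!r}")

    stated = _STATED_RE.search(text)
    if stated:
        stated_count = int(stated.group(1))
        parsed = sum(r.count for r in records if r.code != holotype_code)
        if parsed != stated_count:
            warnings.warn(
                f"listing states {stated_count} specimens but {parsed} codes were "
                "parsed (excluding any holotype); counts are reported, not reconciled",
                stacklevel=2,
            )
    return records


_LENGTH_RE = re.compile(r"([\d.]+)\s*(mm|cm|m)\s+long", re.IGNORECASE)
_WIDTH_RE = re.compile(r"([\d.]+)\s*(mm|cm|m)\s+wide", re.IGNORECASE)
_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def parse_holotype_measurements(text: str) -> tuple[float | None, float | None]:
    """Extract ``(length_mm, width_mm)`` from a holotype description.

    Units are normalised to millimetres.  A missing width (or length)
    yields ``None`` for that slot; neither present raises
    :class:`RegistryFormatError`.
    """
    length_match = _LENGTH_RE.search(text)
    width_match = _WIDTH_RE.search(text)
    if length_match is None and width_match is None:
        raise RegistryFormatError(f"no length/width measurement found in {text!r}")
    length = (
        float(length_match.group(1)) * _TO_MM[length_match.group(2).lower()]
        if length_match
        else None
    )
    width = (
        float(width_match.group(1)) * _TO_MM[width_match.group(2).lower()]
        if width_match
        else None
    )
    return length, width


@dataclass(frozen=True)
class DepthSummary:
    """Specimen-weighted fractions either side of a depth cutoff.

    ``fraction_above`` counts depths shallower than the cutoff (above it in
    the water column), ``fraction_below`` depths at or beyond it; both are
    reported to sidestep ambiguous above/below phrasing.
    """

    fraction_above: float
    fraction_below: float
    n_with_depth: int
    n_without_depth: int


def depth_fraction(records: Sequence[SpecimenRecord], cutoff_m: float) -> DepthSummary:
    """Fractions of specimens shallower than / at-or-beyond ``cutoff_m``.

    Weighted by specimen count; records without a depth are excluded and
    reported in the coverage note.  Raises when no record carries a depth.
    """
    shallow = deep = 0
    without = 0
    for record in records:
        if record.depth_m is None:
            without += record.count
        elif record.depth_m < cutoff_m:
            shallow += record.count
        else:
            deep += record.count
    total = shallow + deep
    if total == 0:
        raise RegistryFormatError("no depth-bearing records; statistic undefined")
    return DepthSummary(
        fraction_above=shallow / total,
        fraction_below=deep / total,
        n_with_depth=total,
        n_without_depth=without,
    )
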