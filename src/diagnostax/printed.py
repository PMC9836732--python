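"""Access to the bundled printed fixtures (diagnosis blocks, specimen
listings, holotype description) shipped under ``resources/printed``."""

from __future__ import annotations

from importlib import resources as importlib_resources

__all__ = [
    "FOCAL_SPECIES",
    "SPECIES_LABELS",
    "printed_diagnosis_block",
    "printed_material_examined",
    "printed_holotype_description",
]

#: short slugs of the six focal species, in presentation order
FOCAL_SPECIES = (
    "shetlandica",
    "lavesquei",
    "atlantis",
    "irinae",
    "williamsae",
    "gracilis",
)

#: slug -> label used by the character matrix / key / range table
SPECIES_LABELS = {slug: f"T. {slug}" for slug in FOCAL_SPECIES}


def _read(name: str) -> str:
    return (
        importlib_resources.files("diagnostax")
        .joinpath("resources", "printed", name)
        .read_text()
    )


def printed_diagnosis_block(slug: str) -> str:
    """Plain text of a species' printed nucleotide-diagnosis block."""
    return _read(f"diagnosis_{slug}.txt")


def printed_material_examined(slug: str) -> str:
    """Plain text of a species' printed material-examined listing."""
    return _read(f"material_{slug}.txt")


def printed_holotype_description() -> str:
    """Printed holotype measurement sentence of the newly described species."""
    return _read("holotype_lavesquei.txt")
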