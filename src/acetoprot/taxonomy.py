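"""Organism extraction from UniProt-style description lines.

Protein-group exports built against UniProt databases carry the source
organism inside the description, e.g.::

    Alcohol dehydrogenase OS=Komagataeibacter europaeus OX=33995 GN=adhA

``parse_organism`` pulls the ``OS=`` field out of such a line and reduces it
to (genus, binomial species, family). The family is resolved through a
genus -> family lookup; the bundled table covers the Acetobacteraceae genera
commonly reported from vinegar microbiotas plus frequent acidophilic
co-occurring genera. Anything unrecognised degrades gracefully to an
"unassigned" organism rather than raising — taxonomic profiling counts those
in a separate bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

__all__ = ["Organism", "UNKNOWN_ORGANISM", "parse_organism", "load_family_lookup", "DEFAULT_FAMILY_LOOKUP"]

# Genera of the family Acetobacteraceae reported from submerged vinegar
# fermentations (acetic acid bacteria plus acidophilic relatives).
DEFAULT_FAMILY_LOOKUP: dict[str, str] = {
    "Komagataeibacter": "Acetobacteraceae",
    "Acetobacter": "Acetobacteraceae",
    "Gluconacetobacter": "Acetobacteraceae",
    "Gluconobacter": "Acetobacteraceae",
    "Asaia": "Acetobacteraceae",
    "Bombella": "Acetobacteraceae",
    "Swaminathania": "Acetobacteraceae",
    "Swingsia": "Acetobacteraceae",
    "Tanticharoenia": "Acetobacteraceae",
    "Acidocella": "Acetobacteraceae",
    "Acidiphilium": "Acetobacteraceae",
    "Acidomonas": "Acetobacteraceae",
    "Oleomonas": "Acetobacteraceae",
    "Rhodovarius": "Acetobacteraceae",
    "Roseomonas": "Acetobacteraceae",
    "Neoasaia": "Acetobacteraceae",
    "Kozakia": "Acetobacteraceae",
    "Granulibacter": "Acetobacteraceae",
}


@dataclass(frozen=True)
class Organism:
    """Taxonomic assignment of one protein group.

    ``genus``/``species``/``family`` are ``None`` when unknown; ``species``
    is the full binomial ("Genus epithet"), never the epithet alone.
    """

    genus: str | None = None
    species: str | None = None
    family: str | None = None

    @property
    def is_unknown(self) -> bool:
        return self.genus is None

    def label(self, rank: str) -> str:
        """Display label at ``rank`` (genus/species/family); 'unassigned' if unknown."""
        value = getattr(self, rank)
        return value if value is not None else "unassigned"


UNKNOWN_ORGANISM = Organism()

# OS= runs up to the next KEY= token (OX, GN, PE, SV, ...) or end of line.
_OS_RE = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")
# Epithets are lowercase latin; rejects "sp.", strain codes, "subsp." etc.
_EPITHET_RE = re.compile(r"^[a-z][a-z-]+$")


def parse_organism(
    description: str,
    family_lookup: dict[str, str] | None = None,
) -> Organism:
    """Extract (genus, species, family) from a description line.

    Total and deterministic: returns :data:`UNKNOWN_ORGANISM` for anything
    without a parseable ``OS=`` field. Trailing qualifiers such as
    ``subsp. ...`` or strain designations are dropped from the binomial;
    ``OS=Genus sp. XYZ`` yields a genus but no species.
    """
    if family_lookup is None:
        family_lookup = DEFAULT_FAMILY_LOOKUP
    if not description:
        return UNKNOWN_ORGANISM
    match = _OS_RE.search(description)
    if match is None:
        return UNKNOWN_ORGANISM
    tokens = match.group(1).split()
    if not tokens or not tokens[0][0].isupper() or not tokens[0].isalpha():
        return UNKNOWN_ORGANISM
    genus = tokens[0]
    species = None
    if len(tokens) > 1 and _EPITHET_RE.match(tokens[1]) and tokens[1] not in ("sp", "spp"):
        species = f"{genus} {tokens[1]}"
    return Organism(genus=genus, species=species, family=family_lookup.get(genus))


def load_family_lookup(path: str | Path) -> dict[str, str]:
    """Read a two-column (genus, family) TSV into a lookup dict."""
    lookup: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 2 and fields[0].lower() != "genus":
            lookup[fields[0]] = fields[1]
    return lookup
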