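"""Qualitative metaproteomics: taxon and GO-term frequency profiles.

Profiles are counting exercises over detection, not quantification: a
protein contributes to a scope group's profile when it is detected there
under the same >=50%-of-replicates rule used for filtering (configurable to
"any replicate"). Taxon frequency is the number of proteins of each taxon
out of the total proteins in scope; GO frequency is reported against the
number of proteins annotated in the aspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError
from .model import ProteinTable, canonical_aspect, format_group

__all__ = [
    "TaxonProfile",
    "GoProfile",
    "taxon_frequency",
    "go_frequency",
    "export_accession_list",
    "profiles_to_frame",
]

RANKS = ("genus", "species", "family")


@dataclass
class TaxonProfile:
    """Taxon breakdown of the proteins detected in one scope group.

    Entries are (taxon, protein count, frequency %) sorted by descending
    frequency; unparseable organisms appear in the 'unassigned' bin so the
    frequencies always total 100%.
    """

    scope_label: str
    rank: str
    entries: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.entries)

    def frequency(self, taxon: str) -> float:
        for name, _, freq in self.entries:
            if name == taxon:
                return freq
        return 0.0

    def main_taxa(self, threshold_pct: float = 1.0) -> list[tuple[str, int, float]]:
        """Entries above the main-taxon threshold (excluding 'unassigned')."""
        return [e for e in self.entries if e[2] > threshold_pct and e[0] != "unassigned"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["taxon", "count", "frequency"]) \
            .assign(scope=self.scope_label, rank=self.rank)


@dataclass
class GoProfile:
    """GO-term breakdown of the annotated proteins in one scope group."""

    scope_label: str
    aspect: str
    entries: list[tuple[str, int, float]] = field(default_factory=list)
    n_annotated: int = 0
    n_unannotated: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["go_id", "count", "frequency"]) \
            .assign(scope=self.scope_label, aspect=self.aspect)


def _scope_accessions(
    table: ProteinTable,
    scope: tuple[str, ...] | None,
    min_frac: float,
    detection: str,
) -> dict[str, list[str]]:
    """Accessions to profile per scope label ('all' when scope is None)."""
    if scope is None:
        return {"all": table.accessions}
    if detection not in ("replicate_fraction", "any"):
        raise ConfigurationError(f"unknown detection rule {detection!r}")
    groups, counts = table.detection_counts(scope)
    out: dict[str, list[str]] = {}
    for key, members in groups.items():
        threshold = 1 if detection == "any" else min_frac * len(members) - 1e-12
        out[format_group(key)] = [
            r.accession for r in table.records if counts[r.accession][key] >= threshold
        ]
    return out


def taxon_frequency(
    table: ProteinTable,
    rank: str = "genus",
    scope: tuple[str, ...] | None = ("profile", "phase"),
    min_frac: float = 0.5,
    detection: str = "replicate_fraction",
) -> list[TaxonProfile]:
    """Per-scope taxon counts and frequencies (% of total proteins in scope).

    ``rank`` is genus, species or family. With ``scope=None`` a single
    global profile over every record in the table is returned. Species
    frequencies use the same all-proteins denominator as genus frequencies,
    so a genus frequency equals the sum of its species frequencies plus its
    epithet-less fraction.
    """
    if rank not in RANKS:
        raise ConfigurationError(f"rank must be one of {RANKS}, got {rank!r}")
    by_acc = {r.accession: r for r in table.records}
    profiles = []
    for label, accessions in _scope_accessions(table, scope, min_frac, detection).items():
        tally: dict[str, int] = {}
        for acc in accessions:
            taxon = by_acc[acc].organism.label(rank)
            tally[taxon] = tally.get(taxon, 0) + 1
        total = len(accessions)
        entries = [
            (taxon, n, 100.0 * n / total if total else 0.0)
            for taxon, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        profiles.append(TaxonProfile(scope_label=label, rank=rank, entries=entries))
    return profiles


def go_frequency(
    table: ProteinTable,
    aspect: str,
    annotations: Mapping[str, set[tuple[str, str]]] | None = None,
    scope: tuple[str, ...] | None = ("profile", "phase"),
    min_frac: float = 0.5,
    detection: str = "replicate_fraction",
) -> list[GoProfile]:
    """Per-scope GO-term protein counts and frequencies.

    Frequency is the number of distinct proteins carrying the term out of
    the proteins annotated in the aspect within the scope group (a protein
    with several terms counts once per term, so frequencies need not total
    100%). Unannotated proteins are reported in ``n_unannotated``.
    Annotations default to the terms attached to the records.
    """
    aspect = canonical_aspect(aspect)
    by_acc = {r.accession: r for r in table.records}

    def terms_of(acc: str) -> set[str]:
        pairs = annotations.get(acc, set()) if annotations is not None else by_acc[acc].go_terms
        return {t for t, a in pairs if canonical_aspect(a) == aspect}

    profiles = []
    for label, accessions in _scope_accessions(table, scope, min_frac, detection).items():
        term_members: dict[str, set[str]] = {}
        annotated = 0
        for acc in accessions:
            terms = terms_of(acc)
            if terms:
                annotated += 1
                for t in terms:
                    term_members.setdefault(t, set()).add(acc)
        entries = [
            (term, len(members), 100.0 * len(members) / annotated)
            for term, members in sorted(term_members.items(),
                                        key=lambda kv: (-len(kv[1]), kv[0]))
        ]
        profiles.append(GoProfile(
            scope_label=label, aspect=aspect, entries=entries,
            n_annotated=annotated, n_unannotated=len(accessions) - annotated,
        ))
    return profiles


def export_accession_list(accessions: Iterable[str], path: str | Path) -> None:
    """One accession per line in stable sorted order (e.g. for STRING upload)."""
    Path(path).write_text("".join(f"{acc}\n" for acc in sorted(accessions)))


def profiles_to_frame(profiles: list[TaxonProfile] | list[GoProfile]) -> pd.DataFrame:
    """Concatenate profiles into one tidy frame for TSV export."""
    if not profiles:
        return pd.DataFrame()
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
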