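"""Core domain types: protein records, study designs, protein tables.

A :class:`ProteinTable` is the central container of the pipeline: a list of
:class:`ProteinRecord` (one per protein group from the search-engine export)
bound to a :class:`StudyDesign` that maps every sample column to an
acetification profile, a cycle phase and a biological replicate number.
Abundance values are non-negative reals; a value of ``None`` means the
protein was not detected in that sample ("not detected" rather than zero —
the downstream presence rules reason about detection, never about zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, ValidationError
from .taxonomy import Organism, UNKNOWN_ORGANISM

__all__ = [
    "CONFIDENCE_LEVELS",
    "GO_ASPECTS",
    "DEFAULT_PHASES",
    "canonical_aspect",
    "ProteinRecord",
    "Sample",
    "StudyDesign",
    "ProteinTable",
]

CONFIDENCE_LEVELS = ("high", "medium", "low")

GO_ASPECTS = ("molecular_function", "biological_process", "cellular_component")

_ASPECT_ALIASES = {
    "molecular_function": "molecular_function",
    "biological_process": "biological_process",
    "cellular_component": "cellular_component",
    "mf": "molecular_function",
    "bp": "biological_process",
    "cc": "cellular_component",
    "f": "molecular_function",
    "p": "biological_process",
    "c": "cellular_component",
}

# Semicontinuous acetification sampling times: end of fast loading, end of
# discontinuous loading, end of loading (natural raw materials), and just
# before unloading.
DEFAULT_PHASES = ("FL", "DL", "EL", "UL")


def canonical_aspect(label: str) -> str:
    """Normalise a GO aspect label; raises :class:`ValidationError` if unknown."""
    key = label.strip().lower().replace(" ", "_")
    if key not in _ASPECT_ALIASES:
        raise ValidationError(
            f"unknown GO aspect {label!r}; expected one of {', '.join(GO_ASPECTS)}"
        )
    return _ASPECT_ALIASES[key]


@dataclass
class ProteinRecord:
    """One protein group with identification metadata and per-sample abundances.

    ``abundances`` maps sample id -> abundance, with ``None`` for samples in
    which the protein was not detected. ``go_terms`` is a set of
    (term id, aspect) pairs with aspects in :data:`GO_ASPECTS`.
    """

    accession: str
    description: str = ""
    organism: Organism = UNKNOWN_ORGANISM
    score: float = 0.0
    num_peptides: int = 0
    fdr_confidence: str = "high"
    go_terms: set[tuple[str, str]] = field(default_factory=set)
    abundances: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise IntegrityError("protein record with empty accession")
        if self.score < 0:
            raise ValidationError(f"{self.accession}: negative score {self.score}")
        if self.num_peptides < 0:
            raise ValidationError(
                f"{self.accession}: negative peptide count {self.num_peptides}"
            )
        if self.fdr_confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"{self.accession}: unknown FDR confidence {self.fdr_confidence!r}; "
                f"expected one of {', '.join(CONFIDENCE_LEVELS)}"
            )

    def detected_in(self, sample_id: str) -> bool:
        """Detection = present with a positive abundance."""
        value = self.abundances.get(sample_id)
        return value is not None and value > 0


@dataclass(frozen=True)
class Sample:
    sample_id: str
    profile: str
    phase: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id}: replicate must be positive, got {self.replicate}"
            )


@dataclass
class StudyDesign:
    """Sample -> (acetification profile, cycle phase, replicate) mapping."""

    samples: list[Sample]
    allowed_phases: tuple[str, ...] = DEFAULT_PHASES

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise IntegrityError(f"duplicate sample ids in design: {sorted(dupes)}")
        for s in self.samples:
            if s.phase not in self.allowed_phases:
                raise ValidationError(
                    f"sample {s.sample_id}: unknown phase {s.phase!r}; allowed "
                    f"phases are {', '.join(self.allowed_phases)} "
                    "(extendable via the design's allowed_phases)"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def group_key(self, sample: Sample, scope: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(str(getattr(sample, f)) for f in scope)

    def groups(self, scope: tuple[str, ...] = ("profile", "phase")) -> dict[tuple[str, ...], list[str]]:
        """Sample ids grouped by the scope fields, in design order.

        ``scope`` is a tuple of Sample field names, e.g. ``("profile", "phase")``
        groups by sampling time within each acetification profile.
        """
        for f in scope:
            if f not in ("profile", "phase", "replicate", "sample_id"):
                raise ConfigurationError(f"unknown scope field {f!r}")
        out: dict[tuple[str, ...], list[str]] = {}
        for s in self.samples:
            out.setdefault(self.group_key(s, scope), []).append(s.sample_id)
        for key, members in out.items():
            if not members:
                raise ConfigurationError(f"group {key} has no samples")
        return out

    def validate_replicates(self, min_replicates: int = 2,
                            scope: tuple[str, ...] = ("profile", "phase")) -> None:
        """Check each scope group carries enough replicates for statistics."""
        for key, members in self.groups(scope).items():
            if len(members) < min_replicates:
                raise ConfigurationError(
                    f"group {'/'.join(key)} has {len(members)} replicate(s); "
                    f"at least {min_replicates} required"
                )


def format_group(key: tuple[str, ...]) -> str:
    return "/".join(key)


@dataclass
class ProteinTable:
    """Protein records bound to a study design, with an operation provenance trail."""

    records: list[ProteinRecord]
    design: StudyDesign
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.accession in seen:
                raise IntegrityError(f"duplicate accession {r.accession!r}")
            seen.add(r.accession)
        sample_set = set(self.design.sample_ids)
        for r in self.records:
            unknown = set(r.abundances) - sample_set
            if unknown:
                raise IntegrityError(
                    f"{r.accession}: abundance keys not in design: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def get(self, accession: str) -> ProteinRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)

    def subset(self, accessions: Iterable[str], step: str | None = None) -> "ProteinTable":
        """New table restricted to ``accessions`` (input order preserved)."""
        keep = set(accessions)
        table = ProteinTable(
            records=[r for r in self.records if r.accession in keep],
            design=self.design,
            provenance=list(self.provenance),
        )
        if step:
            table.provenance.append(step)
        return table

    def sorted_by_accession(self) -> "ProteinTable":
        return ProteinTable(
            records=sorted(self.records, key=lambda r: r.accession),
            design=self.design,
            provenance=list(self.provenance),
        )

    def with_provenance(self, step: str) -> "ProteinTable":
        return ProteinTable(self.records, self.design, [*self.provenance, step])

    def to_frame(self) -> pd.DataFrame:
        """Abundance matrix as a DataFrame (rows accessions, columns samples, NaN = missing)."""
        cols = self.design.sample_ids
        data = np.full((len(self.records), len(cols)), np.nan)
        for i, r in enumerate(self.records):
            for j, sid in enumerate(cols):
                v = r.abundances.get(sid)
                if v is not None:
                    data[i, j] = v
        return pd.DataFrame(data, index=self.accessions, columns=cols)

    def attach_go(self, annotations: Mapping[str, set[tuple[str, str]]]) -> None:
        """Attach GO annotations (accession -> {(term, aspect)}) in place."""
        for r in self.records:
            if r.accession in annotations:
                r.go_terms = set(annotations[r.accession])

    def detection_counts(
        self, scope: tuple[str, ...] = ("profile", "phase")
    ) -> tuple[dict[tuple[str, ...], list[str]], dict[str, dict[tuple[str, ...], int]]]:
        """(groups, counts) where counts[accession][group] = detected replicates."""
        groups = self.design.groups(scope)
        counts: dict[str, dict[tuple[str, ...], int]] = {}
        for r in self.records:
            counts[r.accession] = {
                key: sum(r.detected_in(s) for s in members)
                for key, members in groups.items()
            }
        return groups, counts
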