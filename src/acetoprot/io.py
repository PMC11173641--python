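"""Readers and writers for protein-group tables, design files and annotations.

All files are tab-separated with a header row. Protein-table column names
follow a Proteome Discoverer-style layout by default and are renamable
through a :class:`Dialect`, loadable from a YAML config. Written tables
carry the table's provenance as leading ``#``-prefixed comment lines, which
the reader skips, so a write -> read round trip is the identity on record
fields and abundances (missing preserved as missing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError, IntegrityError, ValidationError
from .model import (
    DEFAULT_PHASES,
    ProteinRecord,
    ProteinTable,
    Sample,
    StudyDesign,
    canonical_aspect,
)
from .taxonomy import DEFAULT_FAMILY_LOOKUP, load_family_lookup, parse_organism

__all__ = [
    "Dialect",
    "read_protein_table",
    "write_table",
    "read_design",
    "write_design",
    "read_go_annotations",
]


@dataclass
class Dialect:
    """Column naming and missing-value conventions of a protein-table export.

    ``abundance_pattern`` is a regex whose first group captures the sample id
    from an abundance column header. With ``confidence_is_qvalue`` the
    confidence column holds a numeric protein-level FDR and is mapped to the
    categorical levels: high iff value < ``confidence_high_threshold``,
    medium iff value < 0.05, low otherwise.
    """

    accession: str = "Accession"
    description: str = "Description"
    score: str = "Score"
    peptides: str = "Peptides"
    confidence: str = "Confidence"
    abundance_pattern: str = r"Abundance:\s*(.+)"
    zero_is_missing: bool = True
    confidence_is_qvalue: bool = False
    confidence_high_threshold: float = 0.01
    organism_column: str | None = None
    family_lookup_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        section = raw.get("dialect", raw)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(section) - known
        if unknown:
            raise ValidationError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**section)

    def family_lookup(self) -> dict[str, str]:
        if self.family_lookup_path:
            return load_family_lookup(self.family_lookup_path)
        return DEFAULT_FAMILY_LOOKUP


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV, skipping the leading provenance comment block."""
    path = Path(path)
    skip = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
            else:
                break
    try:
        return pd.read_csv(path, sep="\t", skiprows=skip, dtype=str,
                           keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def _categorical_confidence(raw: str, dialect: Dialect) -> str:
    if dialect.confidence_is_qvalue:
        try:
            q = float(raw)
        except ValueError as exc:
            raise FormatError(f"non-numeric confidence q-value {raw!r}") from exc
        if q < dialect.confidence_high_threshold:
            return "high"
        return "medium" if q < 0.05 else "low"
    return raw.strip().lower()


def read_protein_table(
    path: str | Path,
    dialect: Dialect | None = None,
    design: StudyDesign | None = None,
) -> ProteinTable:
    """Parse a protein-group export into a :class:`ProteinTable`.

    Abundance columns are discovered with the dialect's pattern; blank cells
    (and zeros, unless ``zero_is_missing`` is off) become missing. When no
    ``design`` is given a flat one-profile design is derived from the
    abundance column names so the table is immediately usable; pass the real
    design to bind profiles/phases/replicates.
    """
    dialect = dialect or Dialect()
    df = _read_tsv(path)

    for col in (dialect.accession, dialect.description, dialect.score,
                dialect.peptides, dialect.confidence):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    pattern = re.compile(dialect.abundance_pattern)
    abundance_cols: dict[str, str] = {}
    for col in df.columns:
        m = pattern.fullmatch(col.strip())
        if m:
            abundance_cols[col] = m.group(1).strip()

    if design is None:
        design = StudyDesign(
            samples=[Sample(sid, "default", "FL", i + 1)
                     for i, sid in enumerate(abundance_cols.values())]
        )
    else:
        missing = set(abundance_cols.values()) - set(design.sample_ids)
        if missing:
            raise IntegrityError(
                f"{path}: abundance columns not in design: {sorted(missing)}"
            )

    family_lookup = dialect.family_lookup()
    records: list[ProteinRecord] = []
    for _, row in df.iterrows():
        description = row[dialect.description]
        if dialect.organism_column and dialect.organism_column in df.columns \
                and row[dialect.organism_column].strip():
            organism = parse_organism(f"OS={row[dialect.organism_column]}", family_lookup)
        else:
            organism = parse_organism(description, family_lookup)
        abundances: dict[str, float | None] = {}
        for col, sid in abundance_cols.items():
            cell = row[col].strip()
            if cell == "" or cell.lower() in ("na", "nan"):
                abundances[sid] = None
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric abundance {cell!r} in {col!r}") from exc
            if value < 0:
                raise FormatError(f"{path}: negative abundance {value} in {col!r}")
            abundances[sid] = None if (value == 0 and dialect.zero_is_missing) else value
        try:
            score = float(row[dialect.score])
            peptides = int(float(row[dialect.peptides]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric score/peptide cell: {exc}") from exc
        records.append(
            ProteinRecord(
                accession=row[dialect.accession].strip(),
                description=description,
                organism=organism,
                score=score,
                num_peptides=peptides,
                fdr_confidence=_categorical_confidence(row[dialect.confidence], dialect),
                abundances=abundances,
            )
        )
    return ProteinTable(records=records, design=design,
                        provenance=[f"read_protein_table:{Path(path).name}"])


def write_table(table: ProteinTable, path: str | Path,
                dialect: Dialect | None = None) -> None:
    """Write a table as TSV with its provenance as leading comment lines."""
    dialect = dialect or Dialect()
    path = Path(path)
    cols = table.design.sample_ids
    header = [dialect.accession, dialect.description, dialect.score,
              dialect.peptides, dialect.confidence] + [f"Abundance: {sid}" for sid in cols]
    lines = [f"# provenance: {step}" for step in table.provenance]
    lines.append("\t".join(header))
    for r in table.records:
        row = [r.accession, r.description, repr(r.score), str(r.num_peptides),
               r.fdr_confidence]
        for sid in cols:
            v = r.abundances.get(sid)
            row.append("" if v is None else repr(v))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_design(path: str | Path,
                allowed_phases: tuple[str, ...] = DEFAULT_PHASES) -> StudyDesign:
    """Read a design TSV with columns sample_id, profile, phase, replicate."""
    df = _read_tsv(path)
    for col in ("sample_id", "profile", "phase", "replicate"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    samples = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer replicate {row['replicate']!r}") from exc
        samples.append(Sample(row["sample_id"].strip(), row["profile"].strip(),
                              row["phase"].strip(), rep))
    return StudyDesign(samples=samples, allowed_phases=allowed_phases)


def write_design(design: StudyDesign, path: str | Path) -> None:
    lines = ["sample_id\tprofile\tphase\treplicate"]
    for s in design.samples:
        lines.append(f"{s.sample_id}\t{s.profile}\t{s.phase}\t{s.replicate}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_go_annotations(path: str | Path) -> dict[str, set[tuple[str, str]]]:
    """Read accession -> {(GO id, aspect)} from a TSV with header accession, go_id, aspect."""
    df = _read_tsv(path)
    for col in ("accession", "go_id", "aspect"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    out: dict[str, set[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        aspect = canonical_aspect(row["aspect"])
        out.setdefault(row["accession"].strip(), set()).add((row["go_id"].strip(), aspect))
    return out
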