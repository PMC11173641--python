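"""Shared fixtures: small designs, table builders, random-table generators."""

from __future__ import annotations

import numpy as np
import pytest

from acetoprot.model import ProteinRecord, ProteinTable, Sample, StudyDesign
from acetoprot.taxonomy import parse_organism


def make_design(phases: dict[str, int] | None = None, profile: str = "SY") -> StudyDesign:
    phases = phases or {"FL": 3, "DL": 3, "UL": 3}
    samples = [
        Sample(f"{profile}_{ph}_{r + 1}", profile, ph, r + 1)
        for ph, n in phases.items()
        for r in range(n)
    ]
    return StudyDesign(samples=samples)


def make_record(
    accession: str,
    abundances: dict[str, float | None],
    score: float = 10.0,
    num_peptides: int = 5,
    fdr_confidence: str = "high",
    description: str = "",
) -> ProteinRecord:
    return ProteinRecord(
        accession=accession,
        description=description,
        organism=parse_organism(description),
        score=score,
        num_peptides=num_peptides,
        fdr_confidence=fdr_confidence,
        abundances=abundances,
    )


def make_table(
    abundances: dict[str, dict[str, float | None]],
    design: StudyDesign,
    **record_kwargs,
) -> ProteinTable:
    """Table from {accession: {sample_id: value-or-None}}; absent samples = missing."""
    records = [
        make_record(acc, dict(vals), **record_kwargs) for acc, vals in abundances.items()
    ]
    return ProteinTable(records=records, design=design)


def random_table(rng: np.random.Generator, max_proteins: int = 50,
                 max_samples: int = 12) -> ProteinTable:
    """Random table with random detection patterns and quality metadata."""
    n_prot = int(rng.integers(1, max_proteins + 1))
    phase_pool = ["FL", "DL", "UL"]
    profiles = ["A"] if rng.random() < 0.5 else ["A", "B"]
    phases = list(rng.choice(phase_pool, size=int(rng.integers(1, 4)), replace=False))
    samples = []
    for prof in profiles:
        for ph in phases:
            for r in range(int(rng.integers(2, 5))):
                samples.append(Sample(f"{prof}_{ph}_{r + 1}", prof, ph, r + 1))
    samples = samples[:max_samples]
    design = StudyDesign(samples=samples)
    records = []
    for i in range(n_prot):
        abundances = {
            s.sample_id: float(rng.lognormal(10, 1)) if rng.random() < 0.6 else None
            for s in samples
        }
        records.append(ProteinRecord(
            accession=f"P{i:03d}",
            description=f"protein {i}",
            score=float(rng.uniform(0, 10)),
            num_peptides=int(rng.integers(0, 10)),
            fdr_confidence=str(rng.choice(["high", "high", "medium", "low"])),
            abundances=abundances,
        ))
    return ProteinTable(records=records, design=design)


@pytest.fixture
def design9() -> StudyDesign:
    """FL/DL/UL with three biological replicates each (nine samples)."""
    return make_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240529)
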