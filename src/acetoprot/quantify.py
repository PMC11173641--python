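"""Global-sample-intensity normalization and group summarization.

Label-free protein quantification values are corrected for between-run
loading differences by a global-intensity factor: each value is divided by
the overall (summed) intensity of its sample and multiplied by the mean
overall intensity across samples,

    q'_ij = q_ij / S_j * (1/m) * sum_k S_k,    S_j = sum over detected i of q_ij.

Missing values stay missing — they contribute nothing to S_j and are never
imputed. After correction every sample's total over detected entries equals
the mean of the original totals, and within-sample ratios and rank order
are preserved exactly (each column is scaled by one positive factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import ProteinTable, StudyDesign, format_group

__all__ = ["AbundanceMatrix", "normalize_global_intensity", "summarize_by_group"]


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance matrix (NaN = not detected)."""

    values: pd.DataFrame
    normalized: bool = False
    provenance: list[str] = field(default_factory=list)

    @classmethod
    def from_table(cls, table: ProteinTable) -> "AbundanceMatrix":
        return cls(values=table.to_frame(), provenance=list(table.provenance))

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_global_intensity(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale every sample to the mean overall sample intensity.

    Raises if a sample has no detected value (its overall intensity would be
    zero) or if the matrix is already normalized.
    """
    if matrix.normalized:
        raise ValidationError("matrix is already normalized")
    values = matrix.values
    totals = values.sum(axis=0, skipna=True)
    dead = [str(c) for c in values.columns if values[c].notna().sum() == 0]
    if dead:
        raise ValidationError(
            f"cannot normalize: sample(s) with no detected values: {dead}"
        )
    factors = totals.mean() / totals
    out = values.mul(factors, axis=1)
    return AbundanceMatrix(
        values=out,
        normalized=True,
        provenance=[*matrix.provenance, "normalize_global_intensity"],
    )


def summarize_by_group(
    matrix: AbundanceMatrix,
    design: StudyDesign,
    scope: tuple[str, ...] = ("profile", "phase"),
) -> pd.DataFrame:
    """Per-protein mean over detected replicates for each scope group.

    A protein missing in every replicate of a group gets NaN for that group.
    Column labels join the scope fields with '/', e.g. 'SY/FL'.
    """
    groups = design.groups(scope)
    out = {}
    for key, members in groups.items():
        cols = [c for c in members if c in matrix.values.columns]
        if not cols:
            raise ValidationError(f"group {format_group(key)} has no columns in matrix")
        out[format_group(key)] = matrix.values[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=matrix.values.index)
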