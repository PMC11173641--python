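"""Identification-quality and replicate-presence filters.

The pipeline retains protein groups that (i) carry high protein-level FDR
confidence (<0.01), a search-engine score of at least 2 and at least 3
identified peptides, and (ii) were detected in at least half of the
biological replicates of at least one sampling time. A further pairwise
rule flags "exclusive" proteins: detected in >=50% of one group's replicates
and in no replicate of the compared group; such proteins are reported
separately so pairwise totals can omit them.

All filters are record-wise predicates: abundances are never modified, and
the two filters commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .model import ProteinTable, format_group

__all__ = [
    "FilterReport",
    "filter_identification",
    "filter_replicate_presence",
    "exclusive_proteins",
    "presence_sets",
]


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass.

    A removed record is attributed to the first rule that removes it, in the
    order confidence, score, peptides, presence, so the per-rule counts sum
    exactly to ``n_input - n_output``.
    """

    n_input: int = 0
    n_removed_confidence: int = 0
    n_removed_score: int = 0
    n_removed_peptides: int = 0
    n_removed_presence: int = 0
    removed_accessions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return (self.n_removed_confidence + self.n_removed_score
                + self.n_removed_peptides + self.n_removed_presence)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    def _record(self, rule: str, accession: str) -> None:
        self.removed_accessions.setdefault(rule, []).append(accession)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_removed_confidence": self.n_removed_confidence,
            "n_removed_score": self.n_removed_score,
            "n_removed_peptides": self.n_removed_peptides,
            "n_removed_presence": self.n_removed_presence,
            "removed_accessions": {k: sorted(v) for k, v in self.removed_accessions.items()},
        }


def filter_identification(
    table: ProteinTable,
    min_score: float = 2.0,
    min_peptides: int = 3,
    confidence: str = "high",
    rule: str = "or",
) -> tuple[ProteinTable, FilterReport]:
    """Drop low-confidence, low-score and low-peptide-count identifications.

    With ``rule="or"`` (default) a record is removed if its score falls below
    ``min_score`` or its peptide count below ``min_peptides`` — two
    independent quality gates. ``rule="and"`` removes only records failing
    both thresholds at once (the literal conjunctive reading); such removals
    are attributed to the score rule. The confidence gate always applies.
    """
    if rule not in ("or", "and"):
        raise ConfigurationError(f"rule must be 'or' or 'and', got {rule!r}")
    report = FilterReport(n_input=len(table))
    kept = []
    for r in table.records:
        if r.fdr_confidence != confidence:
            report.n_removed_confidence += 1
            report._record("confidence", r.accession)
            continue
        low_score = r.score < min_score
        low_peptides = r.num_peptides < min_peptides
        if rule == "or":
            if low_score:
                report.n_removed_score += 1
                report._record("score", r.accession)
                continue
            if low_peptides:
                report.n_removed_peptides += 1
                report._record("peptides", r.accession)
                continue
        else:
            if low_score and low_peptides:
                report.n_removed_score += 1
                report._record("score", r.accession)
                continue
        kept.append(r.accession)
    out = table.subset(
        kept,
        step=(f"filter_identification:confidence={confidence},"
              f"min_score={min_score},min_peptides={min_peptides},rule={rule}"),
    )
    return out, report


def _passes_presence(counts: dict, groups: dict, min_frac: float) -> bool:
    return any(counts[key] >= min_frac * len(members) - 1e-12
               for key, members in groups.items())


def filter_replicate_presence(
    table: ProteinTable,
    min_frac: float = 0.5,
    scope: tuple[str, ...] = ("profile", "phase"),
) -> tuple[ProteinTable, FilterReport]:
    """Retain proteins detected in >= ``min_frac`` of the replicates of at
    least one scope group (sampling time by default). Comparison is
    inclusive: 2 of 4 and 2 of 3 both pass at 0.5."""
    if not 0 < min_frac <= 1:
        raise ConfigurationError(f"min_frac must be in (0, 1], got {min_frac}")
    groups, counts = table.detection_counts(scope)
    report = FilterReport(n_input=len(table))
    kept = []
    for r in table.records:
        if _passes_presence(counts[r.accession], groups, min_frac):
            kept.append(r.accession)
        else:
            report.n_removed_presence += 1
            report._record("presence", r.accession)
    out = table.subset(
        kept, step=f"filter_replicate_presence:min_frac={min_frac},scope={'+'.join(scope)}"
    )
    return out, report


def _resolve_group(group, groups: dict) -> tuple:
    key = (group,) if isinstance(group, str) else tuple(group)
    if key not in groups:
        raise ConfigurationError(
            f"group {format_group(key)} not in design; available: "
            f"{[format_group(k) for k in groups]}"
        )
    return key


def exclusive_proteins(
    table: ProteinTable,
    group_a,
    group_b,
    scope: tuple[str, ...] = ("profile", "phase"),
    min_frac: float = 0.5,
) -> tuple[set[str], set[str]]:
    """Pairwise exclusivity rule.

    Exclusive-to-A = detected in >= ``min_frac`` of A's replicates and in no
    replicate of B (and symmetrically for B). The returned accessions are
    the ones a pairwise comparison excludes from its shared total.
    """
    groups = table.design.groups(scope)
    key_a = _resolve_group(group_a, groups)
    key_b = _resolve_group(group_b, groups)
    if set(groups[key_a]) & set(groups[key_b]):
        raise ConfigurationError(
            f"groups {format_group(key_a)} and {format_group(key_b)} share samples"
        )
    only_a: set[str] = set()
    only_b: set[str] = set()
    for r in table.records:
        in_a = sum(r.detected_in(s) for s in groups[key_a])
        in_b = sum(r.detected_in(s) for s in groups[key_b])
        if in_a >= min_frac * len(groups[key_a]) - 1e-12 and in_b == 0:
            only_a.add(r.accession)
        if in_b >= min_frac * len(groups[key_b]) - 1e-12 and in_a == 0:
            only_b.add(r.accession)
    return only_a, only_b


def presence_sets(
    table: ProteinTable,
    scope: tuple[str, ...] = ("profile", "phase"),
    min_frac: float = 0.5,
) -> dict[tuple[str, ...], set[str]]:
    """Accessions detected in >= ``min_frac`` of replicates, per scope group.

    These named sets feed the intersection (UpSet-style) analysis.
    """
    groups, counts = table.detection_counts(scope)
    return {
        key: {
            r.accession
            for r in table.records
            if counts[r.accession][key] >= min_frac * len(members) - 1e-12
        }
        for key, members in groups.items()
    }
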