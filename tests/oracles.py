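"""Independent brute-force oracles used by unit and acceptance tests.

Each function re-derives an expected result with the most literal loop
possible, sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def naive_identification(table, min_score=2.0, min_peptides=3,
                         confidence="high", rule="or") -> list[str]:
    kept = []
    for r in table.records:
        if r.fdr_confidence != confidence:
            continue
        if rule == "or":
            if r.score < min_score or r.num_peptides < min_peptides:
                continue
        else:
            if r.score < min_score and r.num_peptides < min_peptides:
                continue
        kept.append(r.accession)
    return kept


def _detected(record, sample_id) -> bool:
    v = record.abundances.get(sample_id)
    return v is not None and v > 0


def naive_presence_retained(table, min_frac=0.5, scope=("profile", "phase")) -> list[str]:
    groups = table.design.groups(scope)
    kept = []
    for r in table.records:
        ok = False
        for members in groups.values():
            n_det = sum(1 for s in members if _detected(r, s))
            if n_det / len(members) >= min_frac - 1e-12:
                ok = True
        if ok:
            kept.append(r.accession)
    return kept


def naive_presence_sets(table, min_frac=0.5, scope=("profile", "phase")):
    groups = table.design.groups(scope)
    out = {}
    for key, members in groups.items():
        acc = set()
        for r in table.records:
            n_det = sum(1 for s in members if _detected(r, s))
            if n_det / len(members) >= min_frac - 1e-12:
                acc.add(r.accession)
        out[key] = acc
    return out


def naive_exclusive(table, key_a, key_b, scope=("profile", "phase"), min_frac=0.5):
    groups = table.design.groups(scope)
    only_a, only_b = set(), set()
    for r in table.records:
        det_a = [s for s in groups[key_a] if _detected(r, s)]
        det_b = [s for s in groups[key_b] if _detected(r, s)]
        if len(det_a) / len(groups[key_a]) >= min_frac - 1e-12 and not det_b:
            only_a.add(r.accession)
        if len(det_b) / len(groups[key_b]) >= min_frac - 1e-12 and not det_a:
            only_b.add(r.accession)
    return only_a, only_b


def naive_complete_linkage(d: np.ndarray):
    """Set-based complete-linkage agglomeration with the lexicographic
    minimum-leaf-pair tie-break; returns (merge heights, partitions at every k).

    Partitions are frozensets of frozensets of leaf indices.
    """
    n = d.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights = []
    partitions = {n: frozenset(frozenset(c) for c in clusters)}
    while len(clusters) > 1:
        best = None
        best_h = None
        best_key = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                key = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                if best_h is None or h < best_h or (h == best_h and key < best_key):
                    best, best_h, best_key = (i, j), h, key
        i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        heights.append(best_h)
        partitions[len(clusters)] = frozenset(frozenset(c) for c in clusters)
    return heights, partitions


def naive_group_means(table, scope=("profile", "phase")):
    """Per-protein detected-replicate means per group; None if none detected."""
    groups = table.design.groups(scope)
    out = {}
    for r in table.records:
        row = {}
        for key, members in groups.items():
            vals = [r.abundances[s] for s in members
                    if r.abundances.get(s) is not None]
            row[key] = sum(vals) / len(vals) if vals else None
        out[r.accession] = row
    return out


def naive_taxon_tally(records, rank):
    tally = {}
    for r in records:
        name = getattr(r.organism, rank) or "unassigned"
        tally[name] = tally.get(name, 0) + 1
    return tally
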