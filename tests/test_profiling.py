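"""Taxon and GO-term frequency profiles."""

import numpy as np
import pytest

from acetoprot.errors import ValidationError
from acetoprot.profiling import (
    export_accession_list,
    go_frequency,
    taxon_frequency,
)
from acetoprot.quantify import AbundanceMatrix, normalize_global_intensity

from conftest import make_design, make_table

OS = {
    "A": "x OS=Komagataeibacter europaeus",
    "A2": "x OS=Komagataeibacter oboediens",
    "B": "x OS=Acetobacter aceti",
    "none": "hypothetical protein",
}


def test_simple_proportions(design9):
    table = make_table(
        {
            "P1": {"SY_FL_1": 1.0}, "P2": {"SY_FL_1": 1.0}, "P3": {"SY_FL_1": 1.0},
            "P4": {"SY_FL_1": 1.0},
        },
        design9,
    )
    for i, r in enumerate(table.records):
        r.description = OS["A"] if i < 3 else OS["B"]
        from acetoprot.taxonomy import parse_organism
        r.organism = parse_organism(r.description)
    [profile] = taxon_frequency(table, "genus", scope=None)
    assert profile.entries[0] == ("Komagataeibacter", 3, 75.0)
    assert profile.frequency("Acetobacter") == 25.0


def test_single_genus_degenerate(design9):
    table = make_table({"P1": {}, "P2": {}}, design9, description=OS["A"])
    [profile] = taxon_frequency(table, "genus", scope=None)
    assert profile.entries == [("Komagataeibacter", 2, 100.0)]


def test_frequencies_sum_to_100_with_unassigned(rng, design9):
    keys = list(OS)
    abundances = {f"P{i:02d}": {"SY_FL_1": 1.0} for i in range(30)}
    table = make_table(abundances, design9)
    from acetoprot.taxonomy import parse_organism
    for r in table.records:
        r.description = OS[keys[int(rng.integers(len(keys)))]]
        r.organism = parse_organism(r.description)
    for rank in ("genus", "species", "family"):
        [profile] = taxon_frequency(table, rank, scope=None)
        assert sum(f for _, _, f in profile.entries) == pytest.approx(100.0, abs=1e-9)
        assert profile.total == 30


def test_genus_equals_sum_of_its_species(rng, design9):
    """Same denominator at both ranks, so species frequencies add up."""
    keys = ["A", "A2", "B"]
    abundances = {f"P{i:02d}": {"SY_FL_1": 1.0} for i in range(40)}
    table = make_table(abundances, design9)
    from acetoprot.taxonomy import parse_organism
    for r in table.records:
        r.description = OS[keys[int(rng.integers(3))]]
        r.organism = parse_organism(r.description)
    [genus] = taxon_frequency(table, "genus", scope=None)
    [species] = taxon_frequency(table, "species", scope=None)
    komagataeibacter_species = sum(
        f for name, _, f in species.entries if name.startswith("Komagataeibacter")
    )
    assert genus.frequency("Komagataeibacter") == pytest.approx(komagataeibacter_species)


def test_planted_weights_recovered_by_independent_tally(rng, design9):
    """Frequencies equal exact multinomial count arithmetic from a naive tally."""
    from oracles import naive_taxon_tally
    keys = list(OS)
    weights = [0.9, 0.05, 0.03, 0.02]
    abundances = {f"P{i:02d}": {"SY_FL_1": 1.0} for i in range(50)}
    table = make_table(abundances, design9)
    from acetoprot.taxonomy import parse_organism
    draws = rng.choice(len(keys), size=50, p=weights)
    for r, k in zip(table.records, draws):
        r.description = OS[keys[k]]
        r.organism = parse_organism(r.description)
    [profile] = taxon_frequency(table, "genus", scope=None)
    tally = naive_taxon_tally(table.records, "genus")
    for taxon, count in tally.items():
        assert profile.frequency(taxon) == pytest.approx(100.0 * count / 50)


def test_scope_uses_detection_rule(design9):
    table = make_table(
        {
            "P1": {"SY_FL_1": 1.0, "SY_FL_2": 1.0},   # 2/3 in FL: counted there
            "P2": {"SY_FL_1": 1.0},                    # 1/3: not counted
        },
        design9, description=OS["A"],
    )
    profiles = {p.scope_label: p for p in taxon_frequency(table, "genus")}
    assert profiles["SY/FL"].total == 1
    assert profiles["SY/DL"].total == 0
    any_prof = {p.scope_label: p
                for p in taxon_frequency(table, "genus", detection="any")}
    assert any_prof["SY/FL"].total == 2


def test_profile_invariant_under_normalization(design9):
    abundances = {
        "P1": {s: float(i + 1) for i, s in enumerate(design9.sample_ids)},
        "P2": {"SY_FL_1": 2.0, "SY_FL_2": 1.0},
    }
    table = make_table(abundances, design9, description=OS["A"])
    before = taxon_frequency(table, "genus")
    matrix = normalize_global_intensity(AbundanceMatrix.from_table(table))
    for r in table.records:
        r.abundances = {
            s: (None if np.isnan(matrix.values.loc[r.accession, s])
                else float(matrix.values.loc[r.accession, s]))
            for s in design9.sample_ids
        }
    after = taxon_frequency(table, "genus")
    assert [(p.scope_label, p.entries) for p in before] == \
           [(p.scope_label, p.entries) for p in after]


def test_go_counts_and_denominator(design9):
    table = make_table({"P1": {}, "P2": {}, "P3": {}}, design9)
    ann = {
        "P1": {("T1", "molecular_function")},
        "P2": {("T1", "molecular_function"), ("T2", "molecular_function")},
    }
    [profile] = go_frequency(table, "molecular_function", ann, scope=None)
    assert profile.n_annotated == 2 and profile.n_unannotated == 1
    entries = dict((t, (n, f)) for t, n, f in profile.entries)
    assert entries["T1"] == (2, 100.0)
    assert entries["T2"] == (1, 50.0)


def test_go_empty_annotations(design9):
    table = make_table({"P1": {}, "P2": {}}, design9)
    [profile] = go_frequency(table, "biological_process", {}, scope=None)
    assert profile.entries == [] and profile.n_unannotated == 2
    with pytest.raises(ValidationError):
        go_frequency(table, "nonsense", {}, scope=None)


def test_go_matches_independent_membership_count(rng, design9):
    terms = [f"GO:{i}" for i in range(6)]
    table = make_table({f"P{i:02d}": {} for i in range(30)}, design9)
    ann = {}
    for r in table.records:
        chosen = [t for t in terms if rng.random() < 0.3]
        if chosen:
            ann[r.accession] = {(t, "biological_process") for t in chosen}
    [profile] = go_frequency(table, "biological_process", ann, scope=None)
    # naive per-term membership count
    expected_members = {t: {a for a, pairs in ann.items()
                            if (t, "biological_process") in pairs} for t in terms}
    annotated = {a for a in ann}
    for term, n, freq in profile.entries:
        assert n == len(expected_members[term])
        assert freq == pytest.approx(100.0 * n / len(annotated))


def test_accession_export_roundtrip(tmp_path, design9):
    table = make_table({f"P{i}": {} for i in range(5)}, design9)
    path = tmp_path / "acc.txt"
    export_accession_list(table.accessions, path)
    lines = path.read_text().splitlines()
    assert lines == sorted(table.accessions)
    sub = table.subset(lines)
    assert sub.accessions == sorted(table.accessions)
    export_accession_list([], path)
    assert path.read_text() == ""
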