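"""Scaling, Pearson-distance clustering, ANOVA/Tukey and q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from acetoprot.diffquant import (
    anova_tukey,
    cluster_complete,
    cut_clusters,
    intersections,
    pearson_distance,
    qvalues,
    zscore_rows,
)
from acetoprot.errors import ConfigurationError, ValidationError
from acetoprot.quantify import AbundanceMatrix

from conftest import make_design, make_table
from oracles import naive_complete_linkage

# ---------------------------------------------------------------- z-scoring


def test_zscore_simple_row():
    df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"], columns=list("abc"))
    z, dropped = zscore_rows(df)
    assert np.allclose(z.loc["P1"], [-1.0, 0.0, 1.0])
    assert dropped == []


def test_zscore_drops_constant_rows():
    df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]], index=["P1", "P2"],
                      columns=list("abc"))
    z, dropped = zscore_rows(df)
    assert dropped == ["P1"]
    assert list(z.index) == ["P2"]


def test_zscore_moments(rng):
    x = rng.normal(size=(20, 4))
    z, dropped = zscore_rows(pd.DataFrame(x))
    assert not dropped
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)


# ----------------------------------------------------------- Pearson distance


def test_distance_endpoints():
    df = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]],
                      index=["a", "b", "c"])
    d = pearson_distance(df)
    assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
    assert d.loc["a", "c"] == pytest.approx(2.0)
    assert np.all(np.diag(d.to_numpy()) == 0)


def test_distance_matches_covariance_definition(rng):
    x = rng.normal(size=(10, 4))
    d = pearson_distance(pd.DataFrame(x)).to_numpy()
    for i in range(10):
        for j in range(10):
            xi, xj = x[i], x[j]
            r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
            )
            assert d[i, j] == pytest.approx(1.0 - r, abs=1e-9)


def test_distance_insufficient_shared_columns():
    df = pd.DataFrame([[1.0, np.nan, 2.0, np.nan], [np.nan, 1.0, np.nan, 2.0]],
                      index=["a", "b"])
    with pytest.raises(ConfigurationError, match="'a' and 'b'"):
        pearson_distance(df)


# ------------------------------------------------------------------ clustering


def test_cut_at_n_gives_singletons():
    d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
    dend = cluster_complete(d, labels=["x", "y", "z"])
    assert sorted(cut_clusters(dend, 3).tolist()) == [1, 2, 3]
    with pytest.raises(ValidationError):
        cut_clusters(dend, 0)


def test_two_well_separated_pairs():
    # within-pair distance 0.1, between-pair 1.9 -> k=2 recovers the pairs
    d = np.full((4, 4), 1.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[2, 3] = d[3, 2] = 0.1
    dend = cluster_complete(d, labels=list("abcd"))
    clusters = cut_clusters(dend, 2)
    assert clusters["a"] == clusters["b"] != clusters["c"]
    assert clusters["c"] == clusters["d"]


def test_merge_heights_non_decreasing(rng):
    for _ in range(10):
        n = int(rng.integers(3, 12))
        x = rng.random((n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = cluster_complete(d)
        heights = [h for _, _, h in dend.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


def test_agreement_with_naive_cubic_oracle(rng):
    """Heights and partitions at every k match a set-based agglomeration."""
    for _ in range(25):
        n = int(rng.integers(2, 16))
        x = rng.random((n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = cluster_complete(d)
        heights, partitions = naive_complete_linkage(d)
        assert np.allclose([h for _, _, h in dend.merges], heights)
        for k in range(1, n + 1):
            got = cut_clusters(dend, k)
            got_partition = frozenset(
                frozenset(int(lbl) for lbl in got.index[got == c])
                for c in got.unique()
            )
            assert got_partition == partitions[k]


def test_agreement_with_scipy_linkage(rng):
    """Cross-check against scipy's complete linkage (ties a.s. absent)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    for _ in range(10):
        n = int(rng.integers(3, 15))
        x = rng.random((n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = cluster_complete(d)
        z = linkage(squareform(d, checks=False), method="complete")
        assert np.allclose(sorted(h for _, _, h in dend.merges), sorted(z[:, 2]))
        for k in (1, 2, n // 2 or 1, n):
            ours = cut_clusters(dend, k).to_numpy()
            theirs = fcluster(z, t=k, criterion="maxclust")
            # same partition up to label permutation
            assert len(set(zip(ours, theirs))) == len(set(ours)) == len(set(theirs))


def test_leaf_order_and_newick(rng):
    n = 8
    x = rng.random((n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"P{i}" for i in range(n)]
    dend = cluster_complete(d, labels=labels)
    order = dend.leaf_order()
    assert sorted(order) == sorted(labels)
    newick = dend.to_newick()
    assert newick.endswith(";") and all(lbl in newick for lbl in labels)
    # adjacent leaves in the final merge stay adjacent in the order
    linkage_matrix = dend.to_linkage_matrix()
    assert linkage_matrix.shape == (n - 1, 4)
    assert linkage_matrix[-1, 3] == n


# ----------------------------------------------------------------- ANOVA/Tukey


def anova_matrix(design, values_by_group):
    """Matrix with one protein whose replicate values are given per phase."""
    data = {}
    for (ph, vals) in values_by_group.items():
        for r, v in enumerate(vals):
            data[f"SY_{ph}_{r + 1}"] = v
    df = pd.DataFrame(data, index=["P1"]).reindex(columns=design.sample_ids)
    return AbundanceMatrix(values=df, normalized=True)


def test_equal_group_means_give_f_zero(design9):
    m = anova_matrix(design9, {"FL": [1, 2, 3], "DL": [1, 2, 3], "UL": [1, 2, 3]})
    result = anova_tukey(m, design9)
    assert result.stats.loc["P1", "F"] == pytest.approx(0.0)
    assert result.stats.loc["P1", "p"] == pytest.approx(1.0)


def test_two_groups_tukey_equals_anova_p():
    design = make_design({"FL": 3, "UL": 3})
    m = anova_matrix(design, {"FL": [10, 11, 12], "UL": [20, 21, 22]})
    result = anova_tukey(m, design)
    assert result.tukey["p_adj"].iloc[0] == pytest.approx(
        result.stats.loc["P1", "p"], rel=1e-9
    )


def test_f_equals_t_squared_for_two_groups(rng):
    design = make_design({"FL": 4, "UL": 4})
    for _ in range(10):
        a, b = rng.normal(size=4), rng.normal(2, 1, size=4)
        m = anova_matrix(design, {"FL": a, "UL": b})
        result = anova_tukey(m, design)
        t, p = sps.ttest_ind(a, b)
        assert result.stats.loc["P1", "F"] == pytest.approx(t ** 2, rel=1e-9)
        assert result.stats.loc["P1", "p"] == pytest.approx(p, rel=1e-9)


def test_fixture_matches_scipy_f_oneway_and_tukey(design9):
    groups = {
        "FL": [12.1, 10.9, 11.8, 12.4],
        "DL": [13.9, 14.4, 13.1, 14.8],
        "UL": [11.0, 11.7, 10.2, 11.1],
    }
    design = make_design({k: 4 for k in groups})
    m = anova_matrix(design, groups)
    result = anova_tukey(m, design)
    f_ref, p_ref = sps.f_oneway(*groups.values())
    assert result.stats.loc["P1", "F"] == pytest.approx(f_ref, rel=1e-9)
    assert result.stats.loc["P1", "p"] == pytest.approx(p_ref, rel=1e-9)
    ref = sps.tukey_hsd(*groups.values())
    names = list(groups)
    for _, row in result.tukey.iterrows():
        i = names.index(row["group_a"].split("/")[1])
        j = names.index(row["group_b"].split("/")[1])
        assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)


def test_untestable_proteins_reported(design9):
    # one detected replicate per phase: cannot form two groups of two
    m = anova_matrix(design9, {"FL": [1.0, np.nan, np.nan],
                               "DL": [2.0, np.nan, np.nan],
                               "UL": [3.0, np.nan, np.nan]})
    result = anova_tukey(m, design9)
    assert result.untestable == ["P1"]
    assert result.stats.empty


# ------------------------------------------------------------------- q-values


def test_qvalue_trivial_and_hand_computed():
    assert qvalues([0.03]) == pytest.approx([0.03])
    # BH by hand: min over tails of p * m / rank
    assert qvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert qvalues([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])


def test_qvalues_match_statsmodels_bh(rng):
    for _ in range(10):
        p = rng.uniform(size=50)  # m < 100 -> pi0 = 1 -> exact BH
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(qvalues(p), expected)


def test_qvalues_monotone_and_bounded(rng):
    p = rng.uniform(size=500) ** 2
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert q.max() <= 1.0
    # never below the BH baseline when pi0 = 1
    assert np.all(qvalues(p, method="bh") >= q - 1e-12)


def test_qvalue_validation():
    with pytest.raises(ValidationError):
        qvalues([0.5, 1.5])
    with pytest.raises(ValidationError):
        qvalues([0.1], method="banana")
    assert qvalues([]).size == 0


def test_pi0_estimate_on_uniform_pvalues(rng):
    p = rng.uniform(size=1000)
    q = qvalues(p)
    # back out pi0 = q_max-rank / BH at that rank; uniform family -> near 1
    bh = qvalues(p, method="bh")
    ratio = q[bh > 0] / bh[bh > 0]
    pi0 = ratio[0]
    assert np.allclose(ratio, pi0)
    assert 0.8 <= pi0 <= 1.0


def test_null_fdr_control_monte_carlo(rng):
    """Average FDP at q < 0.05 over pure-null families stays below 5%."""
    fdp = []
    for _ in range(100):
        p = rng.uniform(size=1000)
        rejected = (qvalues(p) < 0.05).sum()
        fdp.append(1.0 if rejected else 0.0)
    assert np.mean(fdp) <= 0.05 + 0.02


# --------------------------------------------------------------- intersections


def test_intersections_three_element_example():
    s = intersections({"A": {"x", "y"}, "B": {"y", "z"}})
    assert s.counts == {("A",): 1, ("B",): 1, ("A", "B"): 1}
    assert s.union_size == 3


def test_intersections_identical_sets():
    s = intersections({"A": {"x", "y"}, "B": {"x", "y"}})
    assert s.counts == {("A", "B"): 2}


def test_intersections_match_exhaustive_tally(rng):
    universe = [f"e{i}" for i in range(40)]
    sets = {name: {e for e in universe if rng.random() < 0.4}
            for name in ("S1", "S2", "S3")}
    summary = intersections(sets)
    for element in set().union(*sets.values()):
        combo = tuple(n for n in ("S1", "S2", "S3") if element in sets[n])
        assert element in summary.members[combo]
    assert summary.union_size == len(set().union(*sets.values()))
    frame = summary.to_frame()
    assert frame["count"].sum() == summary.union_size
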