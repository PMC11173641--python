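"""Quantitative proteomics: clustering and differential quantification.

Clustering operates on per-sampling-time mean quantification values,
row-wise z-scored (sample standard deviation, n-1), with the Pearson
correlation distance d = 1 - r and complete-linkage agglomeration. The
agglomeration is implemented here rather than delegated, because the
deterministic tie-break (merge the pair whose smallest member indices are
lexicographically least) is part of the contract; with n in the hundreds
the O(n^3) scan is immaterial.

Differential quantification runs a per-protein one-way ANOVA across
sampling-time groups on normalized replicate-level abundances, followed by
Tukey's HSD (Tukey-Kramer standard errors for unequal group sizes) and a
Storey q-value multiple-testing correction across proteins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .model import StudyDesign, format_group
from .quantify import AbundanceMatrix

__all__ = [
    "Dendrogram",
    "DiffQuantResult",
    "IntersectionSummary",
    "zscore_rows",
    "pearson_distance",
    "cluster_complete",
    "cut_clusters",
    "anova_tukey",
    "qvalues",
    "intersections",
]


# ---------------------------------------------------------------------------
# scaling and distances


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center and scale each row to mean 0, sd 1 (sd with denominator n-1).

    Rows with fewer than two non-missing values or zero standard deviation
    cannot be scaled; they are dropped and returned in the second element.
    Missing entries stay missing.
    """
    dropped: list[str] = []
    rows = {}
    for acc, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        mask = ~np.isnan(x)
        if mask.sum() < 2:
            dropped.append(str(acc))
            continue
        sd = np.std(x[mask], ddof=1)
        if sd == 0:
            dropped.append(str(acc))
            continue
        rows[acc] = (x - np.mean(x[mask])) / sd
    out = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns) \
        if rows else pd.DataFrame(columns=matrix.columns)
    return out, dropped


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation distance d(i,j) = 1 - r(i,j).

    Correlations use pairwise-complete columns; a pair of rows sharing fewer
    than two columns is an error. d lies in [0, 2] and d(i,i) = 0.
    """
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    if not np.isnan(x).any():
        r = np.corrcoef(x) if n > 1 else np.ones((1, 1))
        d = 1.0 - r
    else:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mask = ~np.isnan(x[i]) & ~np.isnan(x[j])
                if mask.sum() < 2:
                    raise ConfigurationError(
                        f"rows {matrix.index[i]!r} and {matrix.index[j]!r} share "
                        f"{int(mask.sum())} column(s); at least 2 required"
                    )
                xi, xj = x[i, mask], x[j, mask]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    raise ConfigurationError(
                        f"rows {matrix.index[i]!r} and {matrix.index[j]!r} are "
                        "constant on their shared columns"
                    )
                r = np.corrcoef(xi, xj)[0, 1]
                d[i, j] = d[j, i] = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# complete-linkage agglomeration


@dataclass
class Dendrogram:
    """Agglomeration history over ``labels``.

    Nodes follow the usual linkage numbering: leaves are 0..n-1, the cluster
    formed by merge i is node n+i. ``merges`` lists (left, right, height)
    with non-decreasing heights (guaranteed by complete linkage); the left
    child is the one containing the smallest leaf index.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self) -> dict[int, tuple[int, int]]:
        return {self.n_leaves + i: (l, r) for i, (l, r, _) in enumerate(self.merges)}

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree (heat-map row order)."""
        if not self.merges:
            return list(self.labels)
        children = self._children()
        merged = {c for pair in children.values() for c in pair}
        roots = [node for node in
                 list(range(self.n_leaves)) + list(children)
                 if node not in merged]
        order: list[int] = []

        def walk(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = children[node]
                walk(left)
                walk(right)

        for root in roots:
            walk(root)
        return [self.labels[i] for i in order]

    def to_linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage matrix (for plotting/interop)."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        out = np.zeros((len(self.merges), 4))
        for i, (l, r, h) in enumerate(self.merges):
            size = sizes[l] + sizes[r]
            sizes[self.n_leaves + i] = size
            out[i] = (l, r, h, size)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        children = self._children()
        heights = {self.n_leaves + i: h for i, (_, _, h) in enumerate(self.merges)}

        def height(node: int) -> float:
            return heights.get(node, 0.0)

        def render(node: int, parent_height: float) -> str:
            length = max(parent_height - height(node), 0.0)
            if node < self.n_leaves:
                return f"{self.labels[node]}:{length:.6g}"
            left, right = children[node]
            h = height(node)
            return f"({render(left, h)},{render(right, h)}):{length:.6g}"

        if not self.merges:
            return "(" + ",".join(f"{l}:0" for l in self.labels) + ");"
        root = self.n_leaves + len(self.merges) - 1
        return render(root, height(root)) + ";"


def cluster_complete(distance: pd.DataFrame | np.ndarray,
                     labels: list[str] | None = None) -> Dendrogram:
    """Complete-linkage hierarchical clustering of a distance matrix.

    Repeatedly merges the pair of clusters with the minimal maximum
    inter-point distance. Ties are broken deterministically in favour of
    the pair whose (smallest-member, smallest-member) leaf-index pair is
    lexicographically least.
    """
    if isinstance(distance, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in distance.index]
        d = distance.to_numpy(dtype=float).copy()
    else:
        d = np.asarray(distance, dtype=float).copy()
        if labels is None:
            labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be square and symmetric")
    if n == 0:
        raise ValidationError("empty distance matrix")

    # clusters live in matrix slots; inactive slots are masked with inf
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    minleaf = np.arange(n)           # smallest leaf index per slot
    node_id = np.arange(n)           # current dendrogram node id per slot
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        height = float(np.min(d))
        ii, jj = np.nonzero(d == height)
        # candidates as (min-leaf, min-leaf) pairs; pick lexicographic least
        best = None
        best_key = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            key = tuple(sorted((int(minleaf[a]), int(minleaf[b]))))
            if best_key is None or key < best_key:
                best_key, best = key, (int(a), int(b))
        assert best is not None
        a, b = best
        left, right = (node_id[a], node_id[b]) if minleaf[a] < minleaf[b] \
            else (node_id[b], node_id[a])
        merges.append((int(left), int(right), height))
        # complete linkage: distance to the merged cluster is the max
        row = np.maximum(d[a], d[b])
        d[a, :] = row
        d[:, a] = row
        d[a, a] = np.inf
        d[b, :] = np.inf
        d[:, b] = np.inf
        active[b] = False
        minleaf[a] = min(minleaf[a], minleaf[b])
        node_id[a] = n + step
    return Dendrogram(labels=labels, merges=merges)


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cluster assignments from cutting the dendrogram into ``k`` clusters.

    Undoes the last k-1 merges; clusters are numbered 1..k by their
    smallest member's position in the label order.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    node_leaf = {i: i for i in range(n)}  # representative leaf per node id
    for step, (l, r, _) in enumerate(dendrogram.merges[: n - k]):
        ra, rb = find(node_leaf[l]), find(node_leaf[r])
        parent[rb] = ra
        node_leaf[n + step] = ra
    # every merge node needs a representative for later lookups
    for step, (l, r, _) in enumerate(dendrogram.merges):
        node_leaf.setdefault(n + step, node_leaf[l])
    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    ordered = sorted(roots.values(), key=min)
    assignment = {}
    for cluster_id, leaves in enumerate(ordered, start=1):
        for leaf in leaves:
            assignment[dendrogram.labels[leaf]] = cluster_id
    return pd.Series(assignment, name="cluster").loc[dendrogram.labels]


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD + q-values


@dataclass
class DiffQuantResult:
    """Per-protein differential-quantification statistics.

    ``stats``: DataFrame indexed by accession with columns F, p, q (and
    'cluster' once assigned). ``tukey``: long DataFrame of per-pair Tukey
    results (accession, group_a, group_b, mean_diff, p_adj). ``untestable``
    lists proteins lacking two groups with two detected replicates.
    """

    stats: pd.DataFrame
    tukey: pd.DataFrame
    untestable: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.stats.index[self.stats["q"] < alpha])


def _anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, float, int]:
    """(F, p, MS_within, df_within) from textbook sums of squares."""
    g = len(groups)
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    n_total = all_values.size
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups)
    df_between = g - 1
    df_within = n_total - g
    ms_within = ss_within / df_within
    if ss_within == 0:
        if ss_between <= 1e-300:
            return 0.0, 1.0, 0.0, df_within
        return np.inf, 0.0, 0.0, df_within
    f_stat = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p, float(ms_within), df_within


def _tukey_pairs(
    group_names: list[str], groups: list[np.ndarray], ms_within: float, df_within: int
) -> list[tuple[str, str, float, float]]:
    """Tukey-Kramer adjusted p per pair via the studentized-range distribution."""
    g = len(groups)
    out = []
    for (i, j) in itertools.combinations(range(g), 2):
        xi, xj = groups[i], groups[j]
        diff = xi.mean() - xj.mean()
        se = np.sqrt(ms_within / 2.0 * (1.0 / len(xi) + 1.0 / len(xj)))
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q_stat = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_stat, g, df_within))
        out.append((group_names[i], group_names[j], float(diff), min(max(p_adj, 0.0), 1.0)))
    return out


def anova_tukey(
    matrix: AbundanceMatrix,
    design: StudyDesign,
    scope: tuple[str, ...] = ("profile", "phase"),
    min_replicates: int = 2,
    qvalue_method: str = "smoother",
) -> DiffQuantResult:
    """Per-protein one-way ANOVA across scope groups, with Tukey HSD post hoc.

    Operates on normalized replicate-level abundances. For each protein,
    groups with fewer than ``min_replicates`` detected values are dropped;
    proteins with fewer than two usable groups are reported as untestable.
    q-values are computed across the tested proteins.
    """
    groups = design.groups(scope)
    group_names = [format_group(k) for k in groups]
    values = matrix.values
    rows = []
    tukey_rows = []
    untestable: list[str] = []
    for acc in values.index:
        usable_names: list[str] = []
        usable: list[np.ndarray] = []
        for key, members in groups.items():
            cols = [c for c in members if c in values.columns]
            x = values.loc[acc, cols].to_numpy(dtype=float)
            x = x[~np.isnan(x)]
            if x.size >= min_replicates:
                usable_names.append(format_group(key))
                usable.append(x)
        if len(usable) < 2:
            untestable.append(str(acc))
            continue
        f_stat, p, ms_within, df_within = _anova_oneway(usable)
        rows.append((acc, f_stat, p))
        for a, b, diff, p_adj in _tukey_pairs(usable_names, usable, ms_within, df_within):
            tukey_rows.append((acc, a, b, diff, p_adj))
    stats_df = pd.DataFrame(rows, columns=["accession", "F", "p"]).set_index("accession") \
        if rows else pd.DataFrame(columns=["F", "p"])
    if len(stats_df):
        stats_df["q"] = qvalues(stats_df["p"].to_numpy(), method=qvalue_method)
    else:
        stats_df["q"] = pd.Series(dtype=float)
    tukey_df = pd.DataFrame(
        tukey_rows, columns=["accession", "group_a", "group_b", "mean_diff", "p_adj"]
    )
    _ = group_names  # full group list retained for future per-pair completeness checks
    return DiffQuantResult(stats=stats_df, tukey=tukey_df, untestable=untestable)


def qvalues(pvalues: np.ndarray | list[float], method: str = "smoother") -> np.ndarray:
    """False-discovery-rate q-values for a family of p-values.

    Storey's estimator: q_(i) = min over j >= i of pi0 * m * p_(j) / j, with
    pi0 estimated by a smoother over the grid lambda = 0.05, 0.10, ..., 0.95
    (a cubic fit to pi0(lambda) evaluated at the largest lambda). For fewer
    than 100 tests, or with ``method="bh"``, pi0 is fixed at 1, which gives
    Benjamini-Hochberg adjusted p-values. Output is monotone in p rank and
    never exceeds 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    m = p.size
    if m == 0:
        return np.array([])
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("smoother", "bh"):
        raise ValidationError(f"unknown q-value method {method!r}")
    if method == "bh" or m < 100:
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coeffs, lam[-1]))
        pi0 = min(pi0, 1.0)
        if pi0 <= 0:
            # pathological family (essentially all p tiny): fall back to the
            # most conservative estimate rather than zeroing every q-value
            pi0 = 1.0 / m
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ordered = pi0 * m * ranked / np.arange(1, m + 1)
    q_ordered = np.minimum.accumulate(q_ordered[::-1])[::-1]
    q_ordered = np.clip(q_ordered, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_ordered
    return q


# ---------------------------------------------------------------------------
# intersection analysis


@dataclass
class IntersectionSummary:
    """Exact-combination (UpSet-style) counts over named accession sets.

    ``counts`` maps each non-empty membership combination (a sorted tuple of
    set names) to the number of elements belonging to exactly those sets;
    the counts partition the union of all sets.
    """

    set_names: list[str]
    counts: dict[tuple[str, ...], int]
    members: dict[tuple[str, ...], set[str]]

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for combo in sorted(self.counts, key=lambda c: (-len(c), c)):
            mask = "".join("1" if name in combo else "0" for name in self.set_names)
            rows.append(("&".join(combo), mask, self.counts[combo]))
        return pd.DataFrame(rows, columns=["combination", "mask", "count"])


def intersections(sets: dict[str, set[str]]) -> IntersectionSummary:
    """Exact-combination counts for every non-empty membership pattern."""
    if not sets:
        raise ValidationError("at least one named set is required")
    names = list(sets)
    membership: dict[str, tuple[str, ...]] = {}
    for element in set().union(*sets.values()):
        combo = tuple(name for name in names if element in sets[name])
        membership[element] = combo
    counts: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], set[str]] = {}
    for element, combo in membership.items():
        counts[combo] = counts.get(combo, 0) + 1
        members.setdefault(combo, set()).add(element)
    return IntersectionSummary(set_names=names, counts=counts, members=members)
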