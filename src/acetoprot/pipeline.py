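"""End-to-end orchestration: filter -> normalize -> summarize -> profile ->
cluster/diffquant -> intersect.

Every output file is a TSV carrying the provenance trail as leading ``#``
comment lines, plus a JSON run manifest. All outputs are sorted by
accession (or a stated key), so results are independent of input row order
and byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import io as apio
from .diffquant import (
    anova_tukey,
    cluster_complete,
    cut_clusters,
    intersections,
    pearson_distance,
    zscore_rows,
)
from .errors import ValidationError
from .filtering import filter_identification, filter_replicate_presence, presence_sets
from .model import ProteinTable, format_group
from .profiling import export_accession_list, profiles_to_frame, taxon_frequency, go_frequency
from .quantify import AbundanceMatrix, normalize_global_intensity, summarize_by_group

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

STAGES = ("filter", "normalize", "summarize", "profile", "diffquant", "intersect")


@dataclass
class PipelineConfig:
    """Thresholds and scopes of one pipeline run.

    Paths may be left unset when a :class:`ProteinTable` is passed to
    :func:`run_all` directly (the library-use path); the CLI fills them in.
    """

    out_dir: str = "acetoprot_out"
    table_path: str | None = None
    design_path: str | None = None
    go_path: str | None = None
    dialect_path: str | None = None
    min_score: float = 2.0
    min_peptides: int = 3
    confidence: str = "high"
    identification_rule: str = "or"
    min_replicate_frac: float = 0.5
    scope: tuple[str, ...] = ("profile", "phase")
    k_clusters: int = 3
    alpha: float = 0.05
    qvalue_method: str = "smoother"
    main_taxon_threshold: float = 1.0

    def validate(self) -> None:
        if not 0 < self.min_replicate_frac <= 1:
            raise ValidationError(
                f"min_replicate_frac must be in (0, 1], got {self.min_replicate_frac}"
            )
        if self.min_score < 0 or self.min_peptides < 0:
            raise ValidationError("min_score and min_peptides must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k_clusters < 1:
            raise ValidationError(f"k_clusters must be positive, got {self.k_clusters}")
        if self.main_taxon_threshold < 0 or self.main_taxon_threshold > 100:
            raise ValidationError("main_taxon_threshold must be a percentage in [0, 100]")


@dataclass
class PipelineResult:
    """In-memory handles to everything :func:`run_all` computed."""

    filtered: ProteinTable
    normalized: AbundanceMatrix
    group_means: pd.DataFrame
    taxon_profiles: list
    go_profiles: list
    zscores: pd.DataFrame
    unclustered: list[str]
    dendrogram: object
    clusters: pd.Series
    diff: object
    intersection: object
    out_dir: Path


def _write_tsv(df: pd.DataFrame, path: Path, provenance: list[str],
               index_label: str | None = None) -> None:
    with path.open("w") as fh:
        for step in provenance:
            fh.write(f"# provenance: {step}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, lineterminator="\n")


def run_all(
    config: PipelineConfig,
    table: ProteinTable | None = None,
    annotations: dict | None = None,
) -> PipelineResult:
    """Run the full post-processing pipeline and write all outputs.

    Stages, in order: identification filter, replicate-presence filter,
    global-intensity normalization, per-sampling-time summarization, taxon
    and GO profiling, z-score + Pearson/complete clustering + per-protein
    ANOVA/Tukey/q-values, and intersection analysis.
    """
    config.validate()

    if table is None:
        if not config.table_path or not config.design_path:
            raise ValidationError("table_path and design_path (or a table) are required")
        dialect = apio.Dialect.from_yaml(config.dialect_path) if config.dialect_path \
            else apio.Dialect()
        design = apio.read_design(config.design_path)
        table = apio.read_protein_table(config.table_path, dialect, design)
    if annotations is None and config.go_path:
        annotations = apio.read_go_annotations(config.go_path)
    if annotations:
        table.attach_go(annotations)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # row order of the input file must not matter
    table = table.sorted_by_accession()

    # -- filter ------------------------------------------------------------
    table1, report_id = filter_identification(
        table, config.min_score, config.min_peptides, config.confidence,
        config.identification_rule,
    )
    table2, report_pres = filter_replicate_presence(
        table1, config.min_replicate_frac, config.scope
    )
    apio.write_table(table2, out_dir / "filtered.tsv")
    (out_dir / "filter_report.json").write_text(json.dumps({
        "identification": report_id.to_dict(),
        "presence": report_pres.to_dict(),
    }, indent=2, sort_keys=True) + "\n")

    # -- normalize ----------------------------------------------------------
    matrix = normalize_global_intensity(AbundanceMatrix.from_table(table2))
    _write_tsv(matrix.values, out_dir / "normalized.tsv", matrix.provenance,
               index_label="accession")

    # -- summarize ----------------------------------------------------------
    means = summarize_by_group(matrix, table2.design, config.scope)
    prov = [*matrix.provenance, f"summarize_by_group:scope={'+'.join(config.scope)}"]
    _write_tsv(means, out_dir / "group_means.tsv", prov, index_label="accession")

    # -- profiles -----------------------------------------------------------
    taxon_profiles = []
    for rank in ("genus", "species"):
        taxon_profiles += taxon_frequency(
            table2, rank=rank, scope=config.scope, min_frac=config.min_replicate_frac
        )
    _write_tsv(profiles_to_frame(taxon_profiles), out_dir / "taxon_profiles.tsv",
               [*table2.provenance, "taxon_frequency"])
    go_profiles = []
    if any(r.go_terms for r in table2.records):
        for aspect in ("molecular_function", "biological_process", "cellular_component"):
            go_profiles += go_frequency(
                table2, aspect, scope=config.scope, min_frac=config.min_replicate_frac
            )
        _write_tsv(profiles_to_frame(go_profiles), out_dir / "go_profiles.tsv",
                   [*table2.provenance, "go_frequency"])
    export_accession_list(table2.accessions, out_dir / "accessions.txt")

    # -- diffquant ----------------------------------------------------------
    # cluster rows need >= 3 group means for a meaningful Pearson distance
    clusterable = means[means.notna().sum(axis=1) >= 3]
    too_sparse = [a for a in means.index if a not in clusterable.index]
    zscores, degenerate = zscore_rows(clusterable)
    unclustered = sorted(too_sparse + degenerate)
    diff = anova_tukey(matrix, table2.design, config.scope,
                       qvalue_method=config.qvalue_method)
    if len(zscores) >= 2:
        dist = pearson_distance(zscores)
        dendrogram = cluster_complete(dist)
        k = min(config.k_clusters, len(zscores))
        clusters = cut_clusters(dendrogram, k)
        leaf_order = dendrogram.leaf_order()
        _write_tsv(zscores.loc[leaf_order], out_dir / "heatmap_matrix.tsv",
                   [*prov, "zscore_rows", "cluster_complete:leaf_order"],
                   index_label="accession")
        (out_dir / "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")
    else:
        dendrogram = None
        clusters = pd.Series(dtype=int, name="cluster")

    stats = diff.stats.copy()
    stats["cluster"] = clusters.reindex(stats.index).fillna(0).astype(int)
    stats = stats.sort_index()
    _write_tsv(stats, out_dir / "diffquant.tsv",
               [*prov, "anova_tukey", f"qvalues:{config.qvalue_method}"],
               index_label="accession")
    _write_tsv(diff.tukey.sort_values(["accession", "group_a", "group_b"])
               .reset_index(drop=True),
               out_dir / "tukey.tsv", [*prov, "anova_tukey"])
    if unclustered:
        (out_dir / "unclustered.txt").write_text("".join(f"{a}\n" for a in unclustered))

    # -- intersect ----------------------------------------------------------
    sets = presence_sets(table2, config.scope, config.min_replicate_frac)
    summary = intersections({format_group(k): v for k, v in sets.items()})
    _write_tsv(summary.to_frame(), out_dir / "intersections.tsv",
               [*table2.provenance, "intersections"])

    # manifest records thresholds and scopes, not machine-local paths, so
    # identical inputs give identical manifests wherever they live on disk
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if not (k == "out_dir" or k.endswith("_path"))},
        "stages": list(STAGES),
        "n_input": len(table),
        "n_filtered": len(table2),
        "n_tested": int(len(diff.stats)),
        "n_clustered": int(len(clusters)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        filtered=table2, normalized=matrix, group_means=means,
        taxon_profiles=taxon_profiles, go_profiles=go_profiles,
        zscores=zscores, unclustered=unclustered, dendrogram=dendrogram,
        clusters=clusters, diff=diff, intersection=summary, out_dir=out_dir,
    )
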