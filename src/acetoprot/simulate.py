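"""Synthetic protein-group tables with known ground truth.

The generator emulates the statistical structure of a label-free
metaproteomic export from a semicontinuous vinegar acetification:

* a multi-genus Acetobacteraceae community dominated by one species
  (default *Komagataeibacter europaeus* at weight 0.75), sampled
  multinomially per protein;
* three sampling times (FL, DL, UL) with three biological replicates each;
* log-normal abundances: per-protein base level drawn from a wide
  between-protein distribution, replicate noise on the log scale
  (sdlog 0.3, i.e. a coefficient of variation of roughly 30%);
* a planted fraction of differential proteins organised into clusters,
  each cluster up-shifted in one phase by a multiple of the replicate
  log-sd;
* intensity-dependent (MNAR) missingness: the probability of detection is
  a logistic function of log-abundance, so faint proteins drop out more —
  MCAR and no-missingness modes exist for unit tests;
* a planted fraction of low-quality identifications (low score, too few
  peptides, or sub-high FDR confidence) that the identification filter
  should remove.

Ground truth records every planted property so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .diffquant import DiffQuantResult
from .errors import IntegrityError, ValidationError
from .model import ProteinRecord, ProteinTable, Sample, StudyDesign
from .profiling import TaxonProfile
from .taxonomy import parse_organism

__all__ = ["SimConfig", "simulate", "recovery_report"]

#: Species mix of a synthetic-medium acetification: one dominant species and
#: a tail of Acetobacteraceae relatives.
DEFAULT_TAXA: tuple[tuple[str, str, float], ...] = (
    ("Komagataeibacter", "Komagataeibacter europaeus", 0.75),
    ("Komagataeibacter", "Komagataeibacter oboediens", 0.10),
    ("Acetobacter", "Acetobacter pasteurianus", 0.06),
    ("Acetobacter", "Acetobacter aceti", 0.03),
    ("Gluconacetobacter", "Gluconacetobacter entanii", 0.03),
    ("Gluconobacter", "Gluconobacter oxydans", 0.02),
    ("Asaia", "Asaia krungthepensis", 0.01),
)


@dataclass
class SimConfig:
    """Parameters of one simulated acetification profile.

    Defaults describe the study conditions the pipeline is designed for:
    FL/DL/UL sampling times with three biological replicates, a dominant
    species, log-normal abundances and intensity-driven missingness.
    """

    n_proteins: int = 300
    taxa: Sequence[tuple[str, str, float]] = DEFAULT_TAXA
    profile: str = "SY"
    phases: dict[str, int] = field(default_factory=lambda: {"FL": 3, "DL": 3, "UL": 3})
    #: between-protein base log-abundance ~ Normal(loc, scale)
    meanlog_loc: float = 13.0
    meanlog_scale: float = 1.5
    #: replicate noise on the log scale (CV ~ sdlog for small sdlog)
    sdlog: float = 0.3
    #: fraction of proteins planted as differential, split across clusters
    differential_fraction: float = 0.2
    n_clusters: int = 3
    #: log-scale effect = effect_sdlog_multiple * sdlog in the up phase
    effect_sdlog_multiple: float = 4.0
    #: missingness: "mnar" (logistic in log-abundance), "mcar", or "none"
    missingness: str = "mnar"
    mnar_slope: float = 1.0
    #: logistic midpoint, in sds of the base distribution below its mean
    mnar_center_sds: float = 2.0
    mcar_detect_prob: float = 0.9
    #: fraction of records planted with an identification-quality defect
    low_quality_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        weights = [w for _, _, w in self.taxa]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValidationError("taxa weights must be non-negative and sum to 1")
        if self.n_proteins <= 0 or any(n <= 0 for n in self.phases.values()):
            raise ValidationError("n_proteins and replicate counts must be positive")
        if not 0 <= self.differential_fraction <= 1:
            raise ValidationError("differential_fraction must be in [0, 1]")
        if not 0 <= self.low_quality_fraction <= 1:
            raise ValidationError("low_quality_fraction must be in [0, 1]")
        if self.missingness not in ("mnar", "mcar", "none"):
            raise ValidationError(f"unknown missingness mode {self.missingness!r}")
        if not 0 <= self.mcar_detect_prob <= 1:
            raise ValidationError("mcar_detect_prob must be in [0, 1]")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be positive")


def _detection_probability(logq: np.ndarray, config: SimConfig) -> np.ndarray:
    if config.missingness == "none":
        return np.ones_like(logq)
    if config.missingness == "mcar":
        return np.full_like(logq, config.mcar_detect_prob)
    center = config.meanlog_loc - config.mnar_center_sds * config.meanlog_scale
    return 1.0 / (1.0 + np.exp(-config.mnar_slope * (logq - center)))


def simulate(config: SimConfig | None = None) -> tuple[ProteinTable, pd.DataFrame]:
    """Generate a protein table and its ground truth.

    Ground truth columns: accession, genus, species, differential, cluster
    (1-based; 0 for non-differential), low_quality, lq_defect, meanlog, one
    ``effect_<phase>`` log-shift column per phase, and
    ``passes_identification`` (whether the identification filter should keep
    the record). Byte-identical output for a fixed seed.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    phases = list(config.phases)
    samples = [
        Sample(f"{config.profile}_{ph}_{r + 1}", config.profile, ph, r + 1)
        for ph in phases
        for r in range((config.phases[ph]))
    ]
    design = StudyDesign(samples=samples)

    n = config.n_proteins
    weights = np.array([w for _, _, w in config.taxa], dtype=float)
    taxon_idx = rng.choice(len(config.taxa), size=n, p=weights)
    meanlog = rng.normal(config.meanlog_loc, config.meanlog_scale, size=n)

    n_diff = int(round(config.differential_fraction * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    cluster = np.zeros(n, dtype=int)
    effects = np.zeros((n, len(phases)))
    delta = config.effect_sdlog_multiple * config.sdlog
    for rank, i in enumerate(np.sort(diff_idx)):
        c = rank % config.n_clusters
        cluster[i] = c + 1
        effects[i, c % len(phases)] = delta

    n_lq = int(round(config.low_quality_fraction * n))
    lq_idx = set(rng.choice(n, size=n_lq, replace=False).tolist())
    defect_kinds = ("score", "peptides", "confidence")

    records: list[ProteinRecord] = []
    truth_rows = []
    for i in range(n):
        accession = f"P{i + 1:04d}"
        genus, species, _ = config.taxa[taxon_idx[i]]
        description = f"Simulated protein {i + 1} OS={species} OX=0"
        if i in lq_idx:
            defect = defect_kinds[int(rng.integers(len(defect_kinds)))]
        else:
            defect = ""
        score = float(2.0 + rng.gamma(2.0, 20.0))
        peptides = int(3 + rng.poisson(8.0))
        confidence = "high"
        if defect == "score":
            score = float(rng.uniform(0.0, 2.0 - 1e-9))
        elif defect == "peptides":
            peptides = int(rng.integers(1, 3))
        elif defect == "confidence":
            confidence = "medium" if rng.random() < 0.5 else "low"

        abundances: dict[str, float | None] = {}
        for j, ph in enumerate(phases):
            for r in range(config.phases[ph]):
                sid = f"{config.profile}_{ph}_{r + 1}"
                logq = meanlog[i] + effects[i, j] + rng.normal(0.0, config.sdlog)
                detected = rng.random() < _detection_probability(
                    np.array(logq), config
                )
                abundances[sid] = math.exp(logq) if detected else None
        records.append(
            ProteinRecord(
                accession=accession,
                description=description,
                organism=parse_organism(description),
                score=score,
                num_peptides=peptides,
                fdr_confidence=confidence,
                abundances=abundances,
            )
        )
        truth_rows.append({
            "accession": accession,
            "genus": genus,
            "species": species,
            "differential": bool(cluster[i]),
            "cluster": int(cluster[i]),
            "low_quality": i in lq_idx,
            "lq_defect": defect,
            "meanlog": float(meanlog[i]),
            **{f"effect_{ph}": float(effects[i, j]) for j, ph in enumerate(phases)},
            "passes_identification": defect == "",
        })
    table = ProteinTable(records=records, design=design,
                         provenance=[f"simulate:seed={config.seed}"])
    truth = pd.DataFrame(truth_rows).set_index("accession")
    return table, truth


def recovery_report(
    truth: pd.DataFrame,
    taxon_profile: TaxonProfile | None = None,
    profiled_accessions: Sequence[str] | None = None,
    diff_result: DiffQuantResult | None = None,
    cluster_assignments: pd.Series | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Score pipeline outputs against the planted ground truth.

    Returns (keys present only for supplied outputs):

    * ``taxon_max_abs_error`` — max absolute difference (%) between a genus
      frequency in ``taxon_profile`` and the exact multinomial count
      frequency among ``profiled_accessions`` (the accessions the profile
      was computed over);
    * ``sensitivity`` / ``fdr`` — recovery of planted differential proteins
      at q < ``alpha`` among tested proteins;
    * ``ari`` — adjusted Rand index between planted and recovered clusters
      over planted-differential proteins with a recovered assignment.
    """
    metrics: dict[str, float] = {}
    if taxon_profile is not None:
        if profiled_accessions is None:
            raise ValidationError("profiled_accessions required with taxon_profile")
        unknown = set(profiled_accessions) - set(truth.index)
        if unknown:
            raise IntegrityError(f"accessions not in ground truth: {sorted(unknown)[:5]}")
        sub = truth.loc[list(profiled_accessions)]
        expected = sub["genus"].value_counts(normalize=True) * 100.0
        genera = set(expected.index) | {e[0] for e in taxon_profile.entries}
        metrics["taxon_max_abs_error"] = max(
            abs(float(expected.get(g, 0.0)) - taxon_profile.frequency(g)) for g in genera
        )
    if diff_result is not None:
        tested = [a for a in diff_result.stats.index if a in truth.index]
        unknown = set(diff_result.stats.index) - set(truth.index)
        if unknown:
            raise IntegrityError(f"accessions not in ground truth: {sorted(unknown)[:5]}")
        called = set(diff_result.significant(alpha)) & set(tested)
        planted = set(truth.index[truth["differential"]]) & set(tested)
        tp = len(called & planted)
        metrics["sensitivity"] = tp / len(planted) if planted else float("nan")
        metrics["fdr"] = (len(called) - tp) / len(called) if called else 0.0
        metrics["n_tested"] = float(len(tested))
        metrics["n_called"] = float(len(called))
    if cluster_assignments is not None:
        unknown = set(cluster_assignments.index) - set(truth.index)
        if unknown:
            raise IntegrityError(f"accessions not in ground truth: {sorted(unknown)[:5]}")
        common = [a for a in cluster_assignments.index
                  if truth.loc[a, "cluster"] > 0]
        if common:
            metrics["ari"] = float(adjusted_rand_score(
                truth.loc[common, "cluster"].to_numpy(),
                cluster_assignments.loc[common].to_numpy(),
            ))
    return metrics
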