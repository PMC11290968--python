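"""End-to-end orchestration: one configured run of the full analysis.

``run_full`` sequences the stages — perturbation profiles → consensus
drug signature → subgroup disease signatures → discordance response
scores → patient clustering → quartile survival — writing each stage's
table to a run directory together with a manifest (config hash, seed,
package version).  Inputs are either read from the configured paths or,
when paths are absent, simulated with planted ground truth, which makes
the default configuration a self-contained demonstration of the whole
signature-discordance workflow.

Determinism: one master seed; every stochastic stage draws from a
stream forked by stage name, so adding or removing a stage never
perturbs the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import build_consensus, collapse_cell_lines, top_genes
from .disease import subgroup_log2fc, subgroup_markers
from .errors import DiscosigError, ValidationError
from .io_formats import read_cohort, read_gct
from .scoring import discordance_score
from .survival import cluster_patients, q4_vs_q1_survival
from .synthetic import (
    CohortSimSpec,
    PerturbationSimSpec,
    simulate_cohort,
    simulate_perturbation_set,
)

logger = logging.getLogger(__name__)


class PipelineStageError(DiscosigError):
    """A stage failed; the message names the stage, earlier outputs stay."""


@dataclass
class RunConfig:
    """Complete parameterisation of one pipeline run."""

    # inputs; any path left None is simulated instead
    perturbation_gct: str | None = None
    cohort_expr: str | None = None
    cohort_meta: str | None = None
    # consensus signature
    timepoint: str = "24 h"
    tau: float = 0.30
    z_min: float = 2.0
    top_k: int = 20
    # disease signature
    disease_method: str = "median"  # median | mean
    expression_scale: str = "log2"
    eps: float = 1.0
    # response scoring
    n_permutations: int = 10_000
    # clustering
    cluster_k: int = 2
    cluster_distance: str = "euclidean"
    cluster_linkage: str = "complete"
    # survival (None -> use the consensus signature genes as the set)
    survival_geneset: list[str] | None = None
    # simulation overrides (field name -> value) applied when simulating
    sim_perturbation: dict = field(default_factory=dict)
    sim_cohort: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disease_method not in ("median", "mean"):
            raise ValidationError(f"disease_method must be median|mean, got {self.disease_method}")
        if not 0 < self.tau <= 1:
            raise ValidationError(f"tau out of (0,1]: {self.tau}")
        if self.z_min <= 0:
            raise ValidationError(f"z_min must be > 0: {self.z_min}")
        if self.top_k < 1:
            raise ValidationError(f"top_k must be >= 1: {self.top_k}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, forked from the master seed."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _float_fmt(v: float) -> str:
    return repr(float(v))


def run_full(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and return the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    # ---- inputs ----------------------------------------------------------
    name = stage("load_perturbation")
    try:
        if config.perturbation_gct is not None:
            profiles = read_gct(config.perturbation_gct)
        else:
            pspec = PerturbationSimSpec(
                **{"seed": stage_seed(config.seed, "perturbation"), **config.sim_perturbation}
            )
            profiles, _ = simulate_perturbation_set(pspec)
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- consensus signature --------------------------------------------
    name = stage("consensus_signature")
    try:
        by_line = collapse_cell_lines(profiles, config.timepoint)
        full_sig = build_consensus(
            by_line, tau=config.tau, z_min=config.z_min, timepoint=config.timepoint
        )
        sig = top_genes(full_sig, config.top_k)
        sig_df = pd.DataFrame(
            {
                "gene": sig.genes,
                "consensus_z": [sig.entries[g].consensus_z for g in sig.genes],
                "direction": [sig.entries[g].direction for g in sig.genes],
                "agreement": [sig.entries[g].agreement for g in sig.genes],
            }
        ).sort_values(["gene"]).reset_index(drop=True)
        sig_df.to_csv(out / "consensus_signature.tsv", sep="\t", index=False)
        (out / "signature_params.json").write_text(
            json.dumps(
                {"tau": config.tau, "z_min": config.z_min, "timepoint": config.timepoint,
                 "top_k": config.top_k, "n_retained_before_topk": len(full_sig)},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- cohort -----------------------------------------------------------
    name = stage("load_cohort")
    try:
        if config.cohort_expr is not None and config.cohort_meta is not None:
            cohort = read_cohort(
                config.cohort_expr, config.cohort_meta, scale=config.expression_scale
            )
        else:
            cspec_kwargs = {
                "seed": stage_seed(config.seed, "cohort"),
                "discordant_subgroup": "G3",
                **config.sim_cohort,
            }
            cspec = CohortSimSpec(**cspec_kwargs)
            cohort, _ = simulate_cohort(cspec, drug_signature=sig)
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- disease signatures ------------------------------------------------
    name = stage("disease_signature")
    try:
        builder = subgroup_log2fc if config.disease_method == "median" else subgroup_markers
        disease = builder(cohort, eps=config.eps)
        genes_sorted = sorted(disease.genes)
        wide = pd.DataFrame(
            {s: [disease.per_subgroup[s][g] for g in genes_sorted] for s in sorted(disease.subgroups)},
            index=pd.Index(genes_sorted, name="gene"),
        )
        wide.to_csv(out / "disease_signature.tsv", sep="\t")
        for s in sorted(disease.subgroups):
            wide[[s]].rename(columns={s: "log2fc"}).to_csv(
                out / f"disease_signature_{s}.tsv", sep="\t"
            )
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- response scores ----------------------------------------------------
    name = stage("response_score")
    try:
        score = discordance_score(
            sig,
            disease,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "permutation"),
        )
        rows = []
        for s in sorted(score.per_subgroup):
            r = score.per_subgroup[s]
            rows.append(
                {
                    "subgroup": s,
                    "rho": r.rho,
                    "n_genes": r.n_genes,
                    "perm_p": r.perm_p if r.perm_p is not None else "",
                    "predicted_responsive": r.predicted_responsive,
                }
            )
        pd.DataFrame(rows).to_csv(out / "response_scores.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- clustering ----------------------------------------------------------
    name = stage("cluster")
    try:
        clust = cluster_patients(
            cohort,
            sig.genes,
            k=config.cluster_k,
            distance=config.cluster_distance,
            linkage=config.cluster_linkage,
        )
        labels = clust.labels_at_k[config.cluster_k]
        pd.DataFrame(
            {
                "patient": sorted(labels),
                "cluster": [labels[p] for p in sorted(labels)],
                "subgroup": [cohort.subgroup[p] for p in sorted(labels)],
            }
        ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
        (out / "cluster_tree.json").write_text(
            json.dumps(
                {
                    "distance": clust.distance,
                    "linkage": clust.linkage,
                    "genes_used": clust.genes_used,
                    "merges": clust.linkage_tree.tolist(),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- survival ---------------------------------------------------------------
    name = stage("survival")
    try:
        if cohort.has_survival():
            geneset = config.survival_geneset or sig.genes
            strat = q4_vs_q1_survival(cohort, geneset)
            (out / "survival.json").write_text(
                json.dumps(
                    {
                        "logrank_chi2": strat.logrank_chi2,
                        "logrank_p": strat.logrank_p,
                        "n_q1": strat.n_q1,
                        "n_q4": strat.n_q4,
                        "geneset_size": len(geneset),
                    },
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
        else:
            logger.info("cohort lacks survival data; skipping survival stage")
    except Exception as e:
        raise PipelineStageError(f"stage {name!r} failed: {e}") from e

    # ---- manifest -----------------------------------------------------------------
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "version": __version__,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return out
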