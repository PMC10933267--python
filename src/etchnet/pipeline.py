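"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in dependency order: contaminant repository -> interaction
scoring -> compound HCI filter -> downstream analytics (interactome
matrix, correlation clustering, shared-prey hubs). Every intermediate is
a plain-text TSV/JSON/Newick file, so two runs with the same
configuration and seed are byte-identical and diffable. A SAINT-format
scoring file may be injected to skip the internal scorer; downstream
stages see the same contract either way.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as etio
from .filtering import FilterPolicy, apply_filter, summarize_hcis
from .network import build_matrix, correlation_cluster, prey_sharing
from .repository import build_repository, qc_filter_runs
from .scoring import ScoringParams, compute_bfdr, score_all_baits
from .simulate import SimulationConfig, generate_runs

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    #: demo mode: generate all inputs synthetically
    simulation: SimulationConfig | None = None
    runs_path: Path | None = None
    #: injected external SAINT-format scoring file (skips the scorer)
    scores_path: Path | None = None
    qc_min_proteins: int = 1000
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    scoring_params: ScoringParams = field(default_factory=ScoringParams)
    run_analytics: bool = True

    def validate(self) -> None:
        if self.simulation is None and self.runs_path is None:
            raise ValueError(
                "missing dependency: either a simulation config (demo mode) "
                "or runs_path must be provided")
        for attr in ("runs_path", "scores_path"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ValueError(f"missing dependency: {attr} {path} "
                                 "does not exist")


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = config.simulation
            runs, truth = generate_runs(sim)
            etio.write_runs(runs, out / "runs.tsv")
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            manifest["inputs"]["mode"] = "demo"
        else:
            runs = etio.read_runs(config.runs_path)
            manifest["inputs"]["mode"] = "files"
            manifest["inputs"]["runs"] = _checksum(config.runs_path)
        manifest["stages"]["inputs"] = {"rows": int(len(runs))}

        stage = "repository"
        controls = runs[runs["is_control"]]
        passing, rejected = qc_filter_runs(controls, config.qc_min_proteins)
        repo = build_repository(passing, assay=config.policy.assay,
                                qc_min_proteins=config.qc_min_proteins)
        etio.write_repository(repo, out / "repository.tsv")
        manifest["stages"]["repository"] = {
            "rows": int(len(repo.table)),
            "n_runs": repo.n_runs,
            "rejected_runs": rejected,
        }

        stage = "scoring"
        if config.scores_path is not None:
            scored = etio.read_scores(config.scores_path)
            if "bfdr" not in scored.columns:
                scored = compute_bfdr(scored)
            manifest["stages"]["scoring"] = {
                "rows": int(len(scored)), "source": "injected",
            }
            manifest["inputs"]["scores"] = _checksum(config.scores_path)
        else:
            scored = score_all_baits(runs, config.scoring_params)
            manifest["stages"]["scoring"] = {
                "rows": int(len(scored)), "source": "internal",
            }
        etio.write_scores(scored, out / "scores.tsv")

        stage = "filter"
        result = apply_filter(scored, repo, config.policy)
        etio.write_scores(result.hcis, out / "hcis.tsv")
        result.log.to_csv(out / "decision_log.tsv", sep="\t", index=False,
                          float_format="%.6g")
        summary = summarize_hcis(result.hcis)
        etio.write_json(summary, out / "hci_summary.json")
        manifest["stages"]["filter"] = {
            "rows": int(len(result.hcis)),
            "total_hcis": summary["total_hcis"],
            "unique_preys": summary["unique_preys"],
        }

        if config.run_analytics:
            stage = "analytics"
            matrix = build_matrix(result.hcis)
            matrix.to_csv(out / "matrix.tsv", sep="\t", float_format="%.6g")
            if matrix.shape[0] >= 2:
                clustering = correlation_cluster(matrix)
                clustering.correlation.to_csv(
                    out / "correlation.tsv", sep="\t", float_format="%.6g")
                (out / "dendrogram.nwk").write_text(clustering.newick + "\n")
            hci_sets = {b: set(g["prey_id"])
                        for b, g in result.hcis.groupby("bait_id")}
            if hci_sets:
                hubs = prey_sharing(hci_sets)
                hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
                manifest["stages"]["analytics"] = {
                    "baits": int(matrix.shape[0]),
                    "preys": int(matrix.shape[1]),
                    "max_shared_baits": int(hubs["n_baits"].max()),
                }
    except Exception as exc:  # noqa: BLE001 - abort names the stage
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    etio.write_json(manifest, out / "manifest.json")
    return manifest
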