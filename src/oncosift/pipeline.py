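"""End-to-end orchestration: select-genes → score → train → predict → cnv-correct.

A :class:`PipelineConfig` collects every stage's parameters plus paths and a
single seed; :func:`run_pipeline` executes the stages in order, skipping
signature derivation when a GMT is supplied, and writes every artifact
(signatures, model, scores, labels, reports) with a run manifest. All
randomness flows from the one configured seed via stable per-stage child
seeds so stages can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cnv import ProofreadConfig
from .data import (
    read_expression,
    read_gene_positions,
    read_gmt,
    write_gmt,
)
from .errors import ConfigurationError, OncosiftError
from .model import SignatureClassifier
from .scoring import ScoringConfig
from .signatures import ConsolidationConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (below 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_KNOWN_KEYS = {
    "training_paths", "predict_path", "positions_path", "gmt_path", "out_dir",
    "label_column", "tumor_class", "normal_classes",
    "n_top", "p_adj_threshold", "max_rank_fraction",
    "q0", "decay", "change_tol", "max_iter", "k", "n_pcs",
    "flip_probability", "gene_selection_cutoff", "cnv_window", "apply_cnv_correction",
    "seed", "log_level",
}


@dataclass
class PipelineConfig:
    training_paths: list[str] = field(default_factory=list)
    predict_path: str | None = None
    positions_path: str | None = None
    gmt_path: str | None = None  # supply signatures, skip derivation
    out_dir: str = "oncosift_run"

    label_column: str = "cell_type"
    tumor_class: str = "Tumor"
    normal_classes: list[str] = field(default_factory=lambda: ["Normal"])

    n_top: int = 300
    p_adj_threshold: float = 0.1
    max_rank_fraction: float = 0.05

    q0: float = 0.9
    decay: float = 0.25
    change_tol: float = 0.001
    max_iter: int = 50
    k: int = 30
    n_pcs: int = 50

    flip_probability: float = 0.9
    gene_selection_cutoff: float = 0.1
    cnv_window: int = 101
    apply_cnv_correction: bool = False

    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        # sub-config validation happens in the dedicated config classes
        self.consolidation = ConsolidationConfig(self.n_top, self.p_adj_threshold)
        self.scoring = ScoringConfig(self.max_rank_fraction)
        self.proofread = ProofreadConfig(self.gene_selection_cutoff, self.flip_probability)
        if not self.training_paths and not self.gmt_path:
            raise ConfigurationError("need training datasets or a signature GMT")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        payload = {k: v for k, v in asdict(self).items()}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        import oncosift

        return {"config": payload, "config_hash": digest,
                "version": oncosift.__version__, "seed": self.seed}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2))
    artifacts["manifest"] = str(out / "manifest.json")

    def stage(name):
        logger.info("stage: %s", name)

    try:
        training = [
            read_expression(p, [config.label_column]) for p in config.training_paths
        ]
        signatures = None
        if config.gmt_path:
            stage("load signatures (derivation skipped)")
            sigs = {s.name: s for s in read_gmt(config.gmt_path)}
            if not {"tumor", "normal"} <= set(sigs):
                raise ConfigurationError("GMT must contain 'tumor' and 'normal' sets")
            signatures = (sigs["tumor"], sigs["normal"])

        stage("fit (signatures + score classifier)")
        model = SignatureClassifier(
            training, label_column=config.label_column,
            tumor_class=config.tumor_class, normal_classes=config.normal_classes,
            signatures=signatures, consolidation=config.consolidation,
            scoring=config.scoring,
        )
        results = model.fit()
        write_gmt([results.tumor_signature, results.normal_signature],
                  out / "signatures.gmt")
        artifacts["signatures"] = str(out / "signatures.gmt")
        if results.audit_table is not None:
            results.audit_table.to_csv(out / "signature_audit.csv", index=False)
            artifacts["signature_audit"] = str(out / "signature_audit.csv")
        results.classifier.to_json(out / "model.json")
        artifacts["model"] = str(out / "model.json")
        results.training_scores.to_csv(out / "training_scores.csv",
                                       index_label="cell_id")
        artifacts["training_scores"] = str(out / "training_scores.csv")
        (out / "summary.txt").write_text(results.summary() + "\n")
        artifacts["summary"] = str(out / "summary.txt")

        if config.predict_path:
            stage("predict (score -> classify -> propagate)")
            target = read_expression(config.predict_path, [])
            pred = results.predict(
                target, q0=config.q0, decay=config.decay,
                change_tol=config.change_tol, max_iter=config.max_iter,
                k=config.k, n_pcs=config.n_pcs,
            )
            pred.to_csv(out / "labels.csv")
            artifacts["labels"] = str(out / "labels.csv")
            pred.scores.scores.to_csv(out / "scores.csv", index_label="cell_id")
            artifacts["scores"] = str(out / "scores.csv")
            logger.info(
                "propagation: N0=%.4f, %d iteration(s), final changed_fraction=%.5f",
                pred.propagation.initial_threshold, pred.propagation.n_iterations,
                pred.propagation.history[-1].changed_fraction if pred.propagation.history else 0.0,
            )

            if config.apply_cnv_correction:
                if not config.positions_path:
                    raise ConfigurationError("CNV correction needs positions_path")
                stage("cnv-correct (proofreading)")
                positions = read_gene_positions(config.positions_path)
                corrected, report, profile = results.proofread(
                    target, pred, positions, config=config.proofread,
                    window=config.cnv_window,
                )
                corrected_df = pred.table.copy()
                corrected_df["label"] = np.where(corrected, "tumor", "normal")
                corrected_df.to_csv(out / "labels_corrected.csv", index_label="cell_id")
                report.to_csv(out / "flip_report.csv", index=False)
                from .cnv import cnv_summary

                cnv_summary(profile).to_csv(out / "cnv_summary.csv",
                                            index_label="cell_id")
                artifacts["labels_corrected"] = str(out / "labels_corrected.csv")
                artifacts["flip_report"] = str(out / "flip_report.csv")
                artifacts["cnv_summary"] = str(out / "cnv_summary.csv")
    except OncosiftError:
        logger.error("pipeline aborted; partial artifacts retained in %s", out)
        raise
    return artifacts
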