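"""The two-step classification model and its fitted results.

Usage follows the fit/predict idiom of statistical modelling packages::

    model = SignatureClassifier(train_datasets, label_column="cell_type",
                                tumor_class="Tumor", normal_classes=["Normal"])
    results = model.fit()          # derives signatures, trains the classifier
    print(results.summary())
    pred = results.predict(new_dataset)          # score -> classify -> propagate
    corrected = results.proofread(new_dataset, pred, positions)   # CNV step

Fitting performs step one of the method: per-dataset differential
expression, cross-dataset consolidation into a tumor and a normal gene
signature, rank-based scoring of the training cells, and a logistic fit on
the two scores. Prediction performs step two on any dataset: score the
signatures, evaluate the logistic model, then refine the per-cell
probabilities by network propagation over a signature-gene cell–cell graph.
Signature derivation is optional — pre-computed signatures can be supplied,
in which case fit() only scores and trains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from .classifier import ScoreClassifier, balanced_accuracy
from .cnv import CNVProfile, ProofreadConfig
from .data import ExpressionDataset, GenePositionTable, GeneSignature
from .errors import ConfigurationError, ValidationError
from .propagation import CellGraph, PropagationResult, build_cell_graph, propagate
from .scoring import ScoringConfig, SignatureScores, score_matrix
from .signatures import ConsolidationConfig, derive_signatures

logger = logging.getLogger(__name__)

__all__ = ["SignatureClassifier", "SignatureClassifierResults", "CellPredictions"]


@dataclass
class CellPredictions:
    """Per-cell output of a prediction run."""

    table: pd.DataFrame  # cell_id index; tumor_prob, normal_prob, label
    scores: SignatureScores
    propagation: PropagationResult

    @property
    def labels(self) -> np.ndarray:
        """Boolean tumor calls."""
        return (self.table["label"] == "tumor").to_numpy()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["n_iterations"] = self.propagation.n_iterations
        out.to_csv(path, index_label="cell_id")


class SignatureClassifier:
    """Two-step tumor-cell model built from annotated training datasets."""

    def __init__(
        self,
        datasets: Sequence[ExpressionDataset],
        label_column: str,
        tumor_class: str = "Tumor",
        normal_classes: Sequence[str] = ("Normal",),
        signatures: tuple[GeneSignature, GeneSignature] | None = None,
        consolidation: ConsolidationConfig = ConsolidationConfig(),
        scoring: ScoringConfig = ScoringConfig(),
    ):
        if not datasets and signatures is None:
            raise ConfigurationError(
                "need training datasets, or pre-computed signatures plus "
                "datasets for classifier training"
            )
        if not datasets:
            raise ConfigurationError("need at least one dataset to train the classifier")
        self.datasets = list(datasets)
        self.label_column = label_column
        self.tumor_class = tumor_class
        self.normal_classes = list(normal_classes)
        self.signatures = signatures
        self.consolidation = consolidation
        self.scoring = scoring

    def fit(self) -> "SignatureClassifierResults":
        if self.signatures is not None:
            tumor_sig, normal_sig = self.signatures
            audit = None
            logger.info("using provided signatures; derivation skipped")
        else:
            tumor_sig, normal_sig, audit = derive_signatures(
                self.datasets, self.label_column, self.tumor_class,
                self.normal_classes, self.consolidation,
            )
        # independent within-sample scoring per dataset, then concatenation;
        # scores are ranks within each cell, so no cross-dataset normalization
        score_frames, label_arrays = [], []
        for d in self.datasets:
            s = score_matrix(d, tumor_sig, normal_sig, self.scoring)
            score_frames.append(s.scores)
            label_arrays.append((d.labels(self.label_column) == self.tumor_class).to_numpy())
        train_scores = pd.concat(score_frames)
        train_labels = np.concatenate(label_arrays)

        clf = ScoreClassifier().fit(train_scores[["tumor_score", "normal_score"]].to_numpy(),
                                    train_labels)
        clf.training_metadata["datasets"] = [d.dataset_name for d in self.datasets]
        train_acc = balanced_accuracy(train_labels, clf.predict(
            train_scores[["tumor_score", "normal_score"]].to_numpy()))
        return SignatureClassifierResults(
            model=self,
            tumor_signature=tumor_sig,
            normal_signature=normal_sig,
            classifier=clf,
            training_scores=train_scores,
            training_labels=train_labels,
            training_balanced_accuracy=train_acc,
            audit_table=audit,
        )


@dataclass
class SignatureClassifierResults:
    """Fitted signatures, logistic coefficients and training diagnostics."""

    model: SignatureClassifier
    tumor_signature: GeneSignature
    normal_signature: GeneSignature
    classifier: ScoreClassifier
    training_scores: pd.DataFrame
    training_labels: np.ndarray
    training_balanced_accuracy: float
    audit_table: pd.DataFrame | None = None

    @property
    def tumor_class(self) -> str:
        return self.model.tumor_class

    # -- step two: prediction ------------------------------------------
    def predict(
        self,
        dataset: ExpressionDataset,
        tumor_signature: GeneSignature | None = None,
        normal_signature: GeneSignature | None = None,
        q0: float = 0.9,
        decay: float = 0.25,
        change_tol: float = 0.001,
        max_iter: int = 50,
        k: int = 30,
        n_pcs: int = 50,
        propagate_labels: bool = True,
    ) -> CellPredictions:
        """Score, classify and (optionally) propagate labels on a dataset."""
        tsig = tumor_signature or self.tumor_signature
        nsig = normal_signature or self.normal_signature
        scores = score_matrix(dataset, tsig, nsig, self.model.scoring)
        probs = self.classifier.predict_proba(scores.as_features())
        if propagate_labels:
            k_eff = min(k, dataset.n_cells - 1)
            graph = build_cell_graph(dataset, tsig, nsig, k=k_eff, n_pcs=n_pcs)
            prop = propagate(probs, scores, graph, q0=q0, decay=decay,
                             change_tol=change_tol, max_iter=max_iter)
        else:
            prop = PropagationResult(
                labels=probs[:, 1] > probs[:, 0], probabilities=probs,
                n_iterations=0, initial_threshold=float("nan"), history=[],
            )
        table = pd.DataFrame(
            {
                "tumor_prob": prop.probabilities[:, 1],
                "normal_prob": prop.probabilities[:, 0],
                "label": np.where(prop.labels, "tumor", "normal"),
            },
            index=dataset.cell_ids,
        )
        return CellPredictions(table=table, scores=scores, propagation=prop)

    # -- CNV proofreading ----------------------------------------------
    def proofread(
        self,
        dataset: ExpressionDataset,
        predictions: CellPredictions,
        positions: GenePositionTable,
        config: ProofreadConfig = ProofreadConfig(),
        window: int = 101,
        reference: np.ndarray | None = None,
    ) -> tuple[np.ndarray, pd.DataFrame, CNVProfile]:
        """CNV-based correction of a prediction's labels.

        Reference cells for profile centering default to the cells the
        pipeline itself labelled normal (self-supervised mode); pass an
        explicit boolean mask for expert-labelled references (harness mode).
        Returns (corrected boolean labels, flip report, CNV profile).
        """
        labels = predictions.labels
        if reference is None:
            reference = ~labels
            logger.info("CNV reference: %d pseudo-labelled normal cells", reference.sum())
        profile = cnv_mod.infer_cnv_profile(
            dataset, positions, reference, window=window,
            cutoff=config.gene_selection_cutoff,
        )
        corrected, report = cnv_mod.cnv_proofread(profile, labels, config)
        return corrected, report, profile

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary."""
        clf = self.classifier
        md = clf.training_metadata
        lines = [
            "Two-step tumor-cell classification — fit summary",
            "=" * 52,
            f"Training datasets : {', '.join(md.get('datasets', []))}",
            f"Cells (tumor/normal): {md.get('n_tumor')}/{md.get('n_normal')}",
            f"Tumor signature   : {len(self.tumor_signature)} genes",
            f"Normal signature  : {len(self.normal_signature)} genes",
            "",
            "Logistic model on (tumor_score, normal_score):",
            f"  coef tumor_score  : {clf.coefficients[0]:+.4f}",
            f"  coef normal_score : {clf.coefficients[1]:+.4f}",
            f"  intercept         : {clf.intercept:+.4f}",
            f"  L2 inverse strength C = {clf.C}",
            "",
            f"Training balanced accuracy: {self.training_balanced_accuracy:.4f}",
        ]
        return "\n".join(lines)
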