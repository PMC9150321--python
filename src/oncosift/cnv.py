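"""Expression-inferred copy-number profiles and self-supervised label proofreading.

Chromosomal gains and losses leave a footprint in expression: the averaged
signal of genomically adjacent genes rises or falls over the affected
segment. The profile computed here is the smoothed relative-expression core
of that idea: genes are ordered along the genome, lowly expressed genes are
dropped, counts are library-size normalized and log-transformed, the mean
profile of a reference (normal) cell population is subtracted, values are
clipped to ±3 and smoothed with a centered moving average that never crosses
a chromosome boundary, and finally each cell is re-centered on its median.
No hidden-Markov state calling or subclustering is performed — the
continuous profile is consumed directly by a logistic proofreading model.

Proofreading is self-supervised: a logistic regression is trained on the
profiles against the pipeline's own predicted labels (pseudo-labels), then
applied to the same cells; a cell whose CNV-based probability for the
*opposite* class is very high has its label flipped. Since tumor cells carry
CNVs and normal cells do not, this preferentially removes false-positive
tumor calls on CNV-flat cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .classifier import balanced_accuracy
from .data import ExpressionDataset, GenePositionTable
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CNVProfile",
    "ProofreadConfig",
    "infer_cnv_profile",
    "cnv_summary",
    "cnv_proofread",
    "train_cnv_baseline",
]


@dataclass(frozen=True)
class ProofreadConfig:
    gene_selection_cutoff: float = 0.1  # minimum mean raw count for a gene to enter
    flip_probability: float = 0.9  # "highly probable" discordance threshold
    C: float = 1.0  # inverse L2 strength of the CNV logistic model

    def __post_init__(self):
        if not (0.5 < self.flip_probability < 1):
            raise ConfigurationError("flip_probability must be in (0.5, 1)")


@dataclass
class CNVProfile:
    """Per-cell smoothed relative expression over genome-ordered genes."""

    matrix: np.ndarray  # cells x ordered genes
    gene_order: pd.DataFrame  # columns gene, chromosome, start, end (genome-sorted)
    cell_ids: pd.Index
    window: int
    reference_cells: pd.Index

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


def _moving_average_by_chrom(
    values: np.ndarray, chromosomes: np.ndarray, window: int
) -> np.ndarray:
    """Centered moving average per chromosome with edge truncation."""
    out = np.empty_like(values)
    half = window // 2
    for chrom in pd.unique(chromosomes):
        idx = np.flatnonzero(chromosomes == chrom)
        block = values[:, idx]
        n = block.shape[1]
        if n < window:
            logger.warning(
                "chromosome %s has %d genes (< window %d); using truncated windows",
                chrom, n, window,
            )
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out[:, idx] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def infer_cnv_profile(
    dataset: ExpressionDataset,
    positions: GenePositionTable,
    reference_labels: np.ndarray,
    window: int = 101,
    cutoff: float = 0.1,
) -> CNVProfile:
    """Compute the smoothed relative-expression CNV profile.

    ``reference_labels`` is a boolean mask over cells marking the baseline
    (normal) population. Pipeline: keep positioned genes with mean raw count
    ≥ ``cutoff`` → library-size normalize (to the median library size) and
    log2(x+1) → subtract the per-gene reference mean → clip to ±3 → centered
    moving average of ``window`` genes per chromosome → subtract each cell's
    median.
    """
    if dataset.raw_counts is None:
        raise ValidationError("CNV inference requires raw counts (layer 'counts')")
    if window % 2 == 0 or window < 1:
        raise ConfigurationError("window must be a positive odd integer")
    ref = np.asarray(reference_labels, dtype=bool)
    if ref.shape[0] != dataset.n_cells:
        raise ValidationError("reference_labels length must match cell count")
    if ref.sum() < 10:
        raise ValidationError(f"need >= 10 reference cells, got {int(ref.sum())}")

    # genome-ordered genes present in the dataset
    pos = positions.table[
        positions.table["gene"].isin(dataset.gene_symbols)
    ].reset_index(drop=True)
    if len(pos) < window:
        logger.warning("only %d positioned genes; windows will be truncated", len(pos))
    if len(pos) < 2:
        raise ValidationError("fewer than 2 positioned genes present in the dataset")
    cols = dataset.gene_symbols.get_indexer(pos["gene"])
    counts = np.asarray(dataset.raw_counts, dtype=float)[:, cols]

    keep = counts.mean(axis=0) >= cutoff
    pos = pos[keep].reset_index(drop=True)
    counts = counts[:, keep]
    if counts.shape[1] < 2:
        raise ValidationError("gene-selection cutoff removed nearly all genes")

    libsize = np.asarray(dataset.raw_counts, dtype=float).sum(axis=1)
    libsize[libsize == 0] = 1.0
    scale = np.median(libsize)
    norm = np.log2(1.0 + counts / libsize[:, None] * scale)

    rel = norm - norm[ref].mean(axis=0)[None, :]
    rel = np.clip(rel, -3.0, 3.0)
    smooth = _moving_average_by_chrom(rel, pos["chromosome"].to_numpy(), window)
    smooth = smooth - np.median(smooth, axis=1, keepdims=True)

    return CNVProfile(
        matrix=smooth,
        gene_order=pos,
        cell_ids=dataset.cell_ids,
        window=window,
        reference_cells=dataset.cell_ids[ref],
    )


def cnv_summary(profile: CNVProfile) -> pd.DataFrame:
    """Per-cell mean and variance of the CNV profile.

    Misclassified tumor cells typically show elevated values of both,
    which is the diagnostic motivating proofreading.
    """
    return pd.DataFrame(
        {
            "cnv_mean": profile.matrix.mean(axis=1),
            "cnv_variance": profile.matrix.var(axis=1),
        },
        index=profile.cell_ids,
    )


def cnv_proofread(
    profile: CNVProfile,
    pseudo_labels: np.ndarray,
    config: ProofreadConfig = ProofreadConfig(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip highly probable discordant labels using a CNV-trained logistic model.

    The model is trained on all cells of the same dataset with the pipeline's
    own predictions as targets, then applied to those same cells (logistic
    regression is assumed not to overfit this task). A label flips iff the
    CNV model assigns the *opposite* class a probability above
    ``flip_probability``. Returns (corrected labels, flip report).
    """
    y = np.asarray(pseudo_labels, dtype=bool)
    if y.shape[0] != profile.n_cells:
        raise ValidationError("pseudo_labels length must match profile cell count")
    empty_report = pd.DataFrame(
        columns=["cell_id", "old_label", "new_label", "opposite_class_probability"]
    )
    if y.all() or (~y).all():
        logger.warning("single-class pseudo-labels; proofreading skipped")
        return y.copy(), empty_report

    lr = LogisticRegression(C=config.C, solver="lbfgs", max_iter=1000)
    lr.fit(profile.matrix, y.astype(int))
    p_tumor = lr.predict_proba(profile.matrix)[:, list(lr.classes_).index(1)]
    p_opposite = np.where(y, 1.0 - p_tumor, p_tumor)
    flip = p_opposite > config.flip_probability

    corrected = y.copy()
    corrected[flip] = ~y[flip]
    report = pd.DataFrame(
        {
            "cell_id": profile.cell_ids[flip],
            "old_label": np.where(y[flip], "tumor", "normal"),
            "new_label": np.where(~y[flip], "tumor", "normal"),
            "opposite_class_probability": p_opposite[flip],
        }
    )
    logger.info("proofreading flipped %d/%d labels", int(flip.sum()), len(y))
    return corrected, report if flip.any() else empty_report


def train_cnv_baseline(
    profiles: list[CNVProfile],
    labels: list[np.ndarray],
    cohort_names: list[str] | None = None,
    include_merged_pair: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-cohort generalization harness for CNV-only classification.

    Trains a random-forest classifier per cohort on (profile → expert tumor
    labels) and evaluates every classifier on every cohort, returning the
    balanced-accuracy matrix (rows: training cohort, columns: test cohort).
    Optionally adds a row trained on the first two cohorts merged. CNV-only
    classifiers usually do not generalize across tumor types with disjoint
    CNV architectures; this harness measures exactly that.
    """
    if len(profiles) < 2:
        raise ConfigurationError("need >= 2 cohorts")
    if cohort_names is None:
        cohort_names = [f"cohort_{i}" for i in range(len(profiles))]

    common = set(profiles[0].gene_order["gene"])
    for p in profiles[1:]:
        common &= set(p.gene_order["gene"])
    if len(common) < 2:
        raise ValidationError("cohorts share fewer than 2 profiled genes")

    def aligned(p: CNVProfile) -> np.ndarray:
        keep = p.gene_order["gene"].isin(common).to_numpy()
        return p.matrix[:, keep]

    xs = [aligned(p) for p in profiles]
    ys = [np.asarray(l, dtype=bool) for l in labels]

    training_sets: list[tuple[str, list[int]]] = [
        (cohort_names[i], [i]) for i in range(len(profiles))
    ]
    if include_merged_pair and len(profiles) >= 2:
        training_sets.append((f"{cohort_names[0]}+{cohort_names[1]}", [0, 1]))

    rows = []
    for train_name, idx in training_sets:
        y_train = np.concatenate([ys[i] for i in idx])
        if y_train.all() or (~y_train).all():
            logger.warning("cohort %s lacks both classes; skipped", train_name)
            continue
        rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        rf.fit(np.vstack([xs[i] for i in idx]), y_train.astype(int))
        row = {"training": train_name}
        for j, test_name in enumerate(cohort_names):
            pred = rf.predict(xs[j]).astype(bool)
            row[test_name] = balanced_accuracy(ys[j], pred)
        rows.append(row)
    return pd.DataFrame(rows).set_index("training")
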