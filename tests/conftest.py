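"""Shared fixtures: tiny hand-built datasets and small simulated cohorts.

All fixtures are generated programmatically; the expensive simulated cohorts
are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oncosift import ExpressionDataset, GeneSignature, SignatureScores
from oncosift.simulate import CohortSpec, simulate_cohort


def make_dataset(
    matrix,
    labels=None,
    name="toy",
    raw_counts=None,
    gene_prefix="g",
):
    """Build an ExpressionDataset from a plain array and optional label list."""
    matrix = np.asarray(matrix, dtype=float)
    n_cells, n_genes = matrix.shape
    cells = pd.Index([f"cell{i:04d}" for i in range(n_cells)])
    genes = pd.Index([f"{gene_prefix}{j:04d}" for j in range(n_genes)])
    if labels is None:
        labels = ["Normal"] * n_cells
    ann = pd.DataFrame({"cell_type": list(labels)}, index=cells)
    return ExpressionDataset(
        matrix=matrix, cell_ids=cells, gene_symbols=genes,
        annotations=ann, dataset_name=name, raw_counts=raw_counts,
    )


def make_scores(tumor, normal):
    """Build SignatureScores directly from two per-cell arrays."""
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    idx = pd.Index([f"cell{i:04d}" for i in range(len(tumor))])
    return SignatureScores(
        scores=pd.DataFrame({"tumor_score": tumor, "normal_score": normal}, index=idx),
        coverage={"tumor": 1.0, "normal": 1.0},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Three datasets at the generator's default per-dataset scale.

    The score classifier operates on small-magnitude rank scores, so it
    needs a few thousand training cells — the regime annotated tumor
    datasets actually provide; fixtures below that scale underfit.
    """
    spec = CohortSpec(n_datasets=3, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_fitted(small_cohort):
    """Model fitted on the first two cohorts with the true planted signatures."""
    from oncosift import SignatureClassifier

    datasets, truth = small_cohort
    tumor = GeneSignature("tumor", tuple(truth.planted_up))
    normal = GeneSignature("normal", tuple(truth.planted_down), "down_in_class")
    model = SignatureClassifier(
        datasets[:2], label_column="cell_type", signatures=(tumor, normal)
    )
    return model.fit()


@pytest.fixture(scope="session")
def cnv_cohort():
    """Single 800-cell dataset with a strong contiguous gain, for CNV tests."""
    spec = CohortSpec(
        n_datasets=1, n_cells=800, n_genes=2400,
        n_planted_up=60, n_planted_down=60,
        cnv_segments=(("chr01", (0, 99), 2.0),), seed=23,
    )
    return simulate_cohort(spec)
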