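"""Label propagation over a signature-gene cell–cell graph.

Instead of clustering, cell annotations are refined iteratively: at each
step only cells whose |tumor − normal score difference| clears a stringency
threshold keep their class probabilities (the rest are masked to zero), the
surviving probabilities are diffused to neighbors by a dot product with the
graph connectivities, and labels are re-derived from the propagated
probabilities. The threshold decays exponentially, N(t) = N0 · e^(−λt), with
N0 the 90th percentile of the score difference, so confident cells seed the
process and progressively less confident cells join it. Iteration stops when
fewer than 0.1% of annotations change.

The graph restricts the expression matrix to the signature genes, reduces it
by PCA, finds k nearest neighbors (Euclidean) and symmetrizes them into
fuzzy-union connectivity weights in [0, 1] — the standard single-cell
neighbor graph, built on the signature feature space only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import ExpressionDataset, GeneSignature
from .errors import ConfigurationError, ValidationError
from .scoring import SignatureScores

logger = logging.getLogger(__name__)

__all__ = [
    "CellGraph",
    "PropagationState",
    "PropagationResult",
    "build_cell_graph",
    "initial_stringency",
    "propagate",
]


@dataclass
class CellGraph:
    """Sparse symmetric nonnegative cell–cell connectivities, zero diagonal."""

    connectivities: sp.csr_matrix
    k: int
    n_components_used: int

    def __post_init__(self):
        c = sp.csr_matrix(self.connectivities)
        c.setdiag(0.0)
        c.eliminate_zeros()
        asym = abs(c - c.T)
        if asym.nnz and asym.max() > 1e-8:
            raise ValidationError("connectivities are not symmetric")
        if c.nnz and c.min() < 0:
            raise ValidationError("connectivities contain negative weights")
        self.connectivities = c

    @property
    def n_cells(self) -> int:
        return self.connectivities.shape[0]


@dataclass
class PropagationState:
    """Snapshot of one propagation iteration (for run auditing)."""

    iteration: int
    threshold: float  # tumor-side stringency N(t)
    threshold_normal: float  # mirrored normal-side stringency
    n_masked: int
    changed_fraction: float


@dataclass
class PropagationResult:
    labels: np.ndarray  # boolean, True = tumor
    probabilities: np.ndarray  # cells x 2, (normal, tumor), rows sum to 1
    n_iterations: int
    initial_threshold: float
    history: list[PropagationState] = field(default_factory=list)
    converged: bool = True


def build_cell_graph(
    dataset: ExpressionDataset,
    tumor_signature: GeneSignature,
    normal_signature: GeneSignature,
    k: int = 30,
    n_pcs: int = 50,
) -> CellGraph:
    """PCA + k-NN + fuzzy-union connectivities on the signature-gene submatrix."""
    import scanpy as sc  # deferred: scanpy import is slow

    genes = set(tumor_signature.genes) | set(normal_signature.genes)
    cols = dataset.gene_symbols.get_indexer(sorted(genes))
    cols = cols[cols >= 0]
    if len(cols) < 2:
        raise ValidationError(
            f"only {len(cols)} signature gene(s) present in dataset; need >= 2"
        )
    if k >= dataset.n_cells:
        raise ConfigurationError(
            f"k = {k} must be smaller than the number of cells ({dataset.n_cells})"
        )
    import anndata as ad

    adata = ad.AnnData(X=dataset.matrix[:, cols].astype(np.float32))
    n_comps = int(min(n_pcs, len(cols) - 1, dataset.n_cells - 1))
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=0)
    # scanpy counts the cell itself among its n_neighbors; ask for k + 1 so
    # each cell has k true neighbors
    sc.pp.neighbors(
        adata,
        n_neighbors=min(k + 1, dataset.n_cells),
        n_pcs=n_comps,
        metric="euclidean",
        random_state=0,
    )
    conn = sp.csr_matrix(adata.obsp["connectivities"])
    conn = conn.maximum(conn.T)  # enforce exact symmetry
    return CellGraph(connectivities=conn, k=k, n_components_used=n_comps)


def initial_stringency(scores: SignatureScores, q0: float = 0.9) -> float:
    """Starting threshold N0: the q0 quantile of the tumor − normal score difference.

    The quantile uses linear interpolation between order statistics (numpy's
    default), documented for bit-reproducibility.
    """
    diff = scores.difference
    if not np.all(np.isfinite(diff)):
        raise ValidationError("score differences contain non-finite values")
    return float(np.quantile(diff, q0))


def propagate(
    probabilities: np.ndarray,
    scores: SignatureScores,
    graph: CellGraph,
    q0: float = 0.9,
    decay: float = 0.25,
    change_tol: float = 0.001,
    max_iter: int = 50,
) -> PropagationResult:
    """Iterative masked diffusion of class probabilities over the cell graph.

    Each iteration: (1) the tumor-side threshold N(t) = N0·e^(−decay·t), with
    N0 the q0 quantile of the (tumor − normal) score difference, and a
    mirrored normal-side threshold decaying identically from the q0 quantile
    of (normal − tumor); (2) cells clearing neither threshold have both class
    probabilities masked to zero, so both confident-tumor and confident-normal
    cells survive as seeds; (3) propagated = connectivities · masked
    probabilities, renormalized per cell (cells whose propagated row is all
    zero keep their previous probabilities and label); (4) labels = argmax;
    (5) stop when the fraction of changed labels drops below ``change_tol``
    or ``max_iter`` is reached.
    """
    if decay <= 0:
        raise ConfigurationError("decay constant must be positive")
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValidationError("probabilities must be cells x 2")
    if probs.shape[0] != graph.n_cells:
        raise ValidationError("probabilities and graph disagree on cell count")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1")

    n0 = initial_stringency(scores, q0)
    diff = scores.difference
    n0_normal = float(np.quantile(-diff, q0))  # mirrored threshold for normal seeds
    conn = graph.connectivities
    labels = probs[:, 1] > probs[:, 0]
    history: list[PropagationState] = []
    converged = False
    t = 0
    for t in range(max_iter):
        damp = float(np.exp(-decay * t))
        threshold = n0 * damp
        threshold_normal = n0_normal * damp
        # seeds: cells confidently tumor-like or confidently normal-like on
        # the score-difference scale; everything else is masked to zero
        seed = (diff >= threshold) | (-diff >= threshold_normal)
        below = ~seed
        masked = probs.copy()
        masked[below] = 0.0
        propagated = np.asarray(conn @ masked)
        row_sums = propagated.sum(axis=1)
        zero_rows = row_sums == 0
        propagated[~zero_rows] /= row_sums[~zero_rows, None]
        propagated[zero_rows] = probs[zero_rows]  # isolated / fully masked: keep state
        new_labels = propagated[:, 1] > propagated[:, 0]
        new_labels[zero_rows] = labels[zero_rows]
        changed = float(np.mean(new_labels != labels))
        history.append(
            PropagationState(
                iteration=t, threshold=threshold, threshold_normal=threshold_normal,
                n_masked=int(below.sum()), changed_fraction=changed,
            )
        )
        probs = propagated
        labels = new_labels
        if changed < change_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "propagation hit max_iter=%d with changed_fraction=%.4f",
            max_iter, history[-1].changed_fraction,
        )
    return PropagationResult(
        labels=labels,
        probabilities=probs,
        n_iterations=t + 1,
        initial_threshold=n0,
        history=history,
        converged=converged,
    )
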