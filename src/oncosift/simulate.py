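"""Synthetic multi-dataset scRNA-seq cohorts with planted tumor structure.

The generator emulates the statistical features the classifier relies on:

* negative-binomial counts with gene-wise base means and log-normal
  library-size variation;
* a shared set of planted tumor-marker genes (mean log2 expression shifted
  up by ``effect_size`` in tumor cells) and tumor-depleted genes (shifted
  down), common to all datasets in a cohort;
* per-dataset multiplicative batch offsets on every gene, so naive
  cross-dataset expression comparison is confounded while within-cell ranks
  are not;
* class imbalance (tumor cells are a minority, 1/8 of cells by default,
  emulating the ~7:1 normal:tumor ratio typical of annotated tumor
  datasets);
* optional contiguous copy-number segments: a fold change multiplying the
  counts of a genomically contiguous gene block in tumor cells only.

Counts are stored in a ``"counts"`` layer; the working matrix is the counts
normalized to the median library size and log2(x + 1) transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionDataset, GenePositionTable
from .errors import ConfigurationError

__all__ = ["CohortSpec", "CohortTruth", "simulate_cohort", "plant_label_noise",
           "LABEL_COLUMN", "TUMOR", "NORMAL"]

LABEL_COLUMN = "cell_type"
TUMOR = "Tumor"
NORMAL = "Normal"


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a synthetic cohort."""

    n_datasets: int = 4
    n_cells: int = 2000
    n_genes: int = 6000
    tumor_fraction: float = 0.125
    n_planted_up: int = 150
    n_planted_down: int = 150
    effect_size: float = 1.5  # mean log2 shift of planted genes in tumor cells
    batch_sd: float = 0.3  # sd of per-dataset gene-wise log2 offsets
    dispersion: float = 0.5  # NB overdispersion alpha: var = mu + alpha * mu^2
    # (chromosome, (first_gene_idx_on_chrom, last_gene_idx_on_chrom), fold)
    cnv_segments: tuple[tuple[str, tuple[int, int], float], ...] = (
        ("chr01", (0, 299), 2.0),
    )
    n_chromosomes: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.tumor_fraction < 1):
            raise ConfigurationError("tumor_fraction must be in (0, 1)")
        if min(self.n_datasets, self.n_cells, self.n_genes) < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ConfigurationError("planted genes exceed n_genes")


@dataclass
class CohortTruth:
    """Ground-truth manifest emitted alongside a simulated cohort."""

    planted_up: list[str]
    planted_down: list[str]
    cnv_genes: dict[str, list[str]]  # segment id -> genes spanned
    labels: dict[str, pd.Series]  # dataset_name -> per-cell class
    positions: GenePositionTable


def _gene_positions(spec: CohortSpec) -> GenePositionTable:
    """Uniformly spaced genes on n_chromosomes equal blocks, genome-ordered."""
    per_chrom = int(np.ceil(spec.n_genes / spec.n_chromosomes))
    rows = []
    g = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for i in range(per_chrom):
            if g >= spec.n_genes:
                break
            start = 10_000 * (i + 1)
            rows.append((f"G{g:05d}", chrom, start, start + 5_000))
            g += 1
    return GenePositionTable(pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"]))


def simulate_cohort(spec: CohortSpec) -> tuple[list[ExpressionDataset], CohortTruth]:
    """Generate the cohort's datasets plus the ground-truth manifest.

    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    positions = _gene_positions(spec)
    genes = positions.genes()  # genome order == lexicographic by construction
    gene_arr = genes.to_numpy()

    # base means on a log-normal scale, moderately expressed on average
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)

    # planted genes: choose disjoint up/down sets, avoiding CNV segments so
    # marker signal and copy-number signal stay orthogonal
    chrom_arr = positions.table["chromosome"].to_numpy()
    cnv_cols: dict[str, np.ndarray] = {}
    for chrom, (lo, hi), fold in spec.cnv_segments:
        # indices are positions within the chromosome's genome-ordered block
        chrom_idx = np.flatnonzero(chrom_arr == chrom)
        if len(chrom_idx) == 0:
            raise ConfigurationError(f"CNV segment on unknown chromosome {chrom!r}")
        seg = chrom_idx[lo:hi + 1]
        if len(seg) == 0:
            raise ConfigurationError(f"CNV segment {chrom}:{lo}-{hi} spans no genes")
        cnv_cols[f"{chrom}:{lo}-{hi}x{fold}"] = seg
    cnv_all = (
        np.unique(np.concatenate(list(cnv_cols.values())))
        if cnv_cols else np.empty(0, dtype=int)
    )
    candidates = np.setdiff1d(np.arange(spec.n_genes), cnv_all)
    if len(candidates) < spec.n_planted_up + spec.n_planted_down:
        raise ConfigurationError("not enough genes outside CNV segments to plant markers")
    chosen = rng.choice(candidates, size=spec.n_planted_up + spec.n_planted_down,
                        replace=False)
    up_cols = np.sort(chosen[: spec.n_planted_up])
    down_cols = np.sort(chosen[spec.n_planted_up:])
    # depleted genes must be expressed in normal cells to be depletable
    base_mean[down_cols] = np.maximum(base_mean[down_cols], 2.0)
    base_mean[up_cols] = np.maximum(base_mean[up_cols], 1.0)

    size = 1.0 / spec.dispersion  # NB shape parameter
    datasets: list[ExpressionDataset] = []
    labels_by_dataset: dict[str, pd.Series] = {}
    n_tumor = int(round(spec.tumor_fraction * spec.n_cells))

    for d in range(spec.n_datasets):
        name = f"cohort{d}"
        batch = 2.0 ** rng.normal(0.0, spec.batch_sd, size=spec.n_genes)
        lib = rng.lognormal(mean=0.0, sigma=0.3, size=spec.n_cells)

        is_tumor = np.zeros(spec.n_cells, dtype=bool)
        is_tumor[rng.choice(spec.n_cells, size=n_tumor, replace=False)] = True

        mu = np.outer(lib, base_mean * batch)
        fold_up = 2.0 ** spec.effect_size
        mu[np.ix_(is_tumor, up_cols)] *= fold_up
        mu[np.ix_(is_tumor, down_cols)] /= fold_up
        for seg_id, seg in cnv_cols.items():
            fold = float(seg_id.split("x")[-1])
            mu[np.ix_(is_tumor, seg)] *= fold

        shape = rng.gamma(shape=size, scale=mu / size)
        counts = rng.poisson(shape).astype(np.int64)

        total = counts.sum(axis=1).astype(float)
        total[total == 0] = 1.0
        norm = counts / total[:, None] * np.median(total)
        log2 = np.log2(1.0 + norm)

        cell_ids = pd.Index([f"{name}_cell{i:05d}" for i in range(spec.n_cells)])
        ann = pd.DataFrame(
            {LABEL_COLUMN: np.where(is_tumor, TUMOR, NORMAL)}, index=cell_ids
        )
        ds = ExpressionDataset(
            matrix=log2, cell_ids=cell_ids, gene_symbols=genes,
            annotations=ann, dataset_name=name, raw_counts=counts,
        )
        datasets.append(ds)
        labels_by_dataset[name] = ann[LABEL_COLUMN]

    truth = CohortTruth(
        planted_up=list(gene_arr[up_cols]),
        planted_down=list(gene_arr[down_cols]),
        cnv_genes={k: list(gene_arr[v]) for k, v in cnv_cols.items()},
        labels=labels_by_dataset,
        positions=positions,
    )
    return datasets, truth


def plant_label_noise(
    labels: np.ndarray, flip_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Flip an exact fraction of boolean labels, uniformly at random.

    Returns (corrupted labels, boolean mask of flipped positions).
    """
    if not (0 <= flip_fraction < 1):
        raise ConfigurationError("flip_fraction must be in [0, 1)")
    y = np.asarray(labels, dtype=bool).copy()
    n_flip = int(round(flip_fraction * len(y)))
    flipped = np.zeros(len(y), dtype=bool)
    if n_flip:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(y), size=n_flip, replace=False)
        y[idx] = ~y[idx]
        flipped[idx] = True
    return y, flipped
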