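"""Derivation of tumor-up / tumor-depleted gene signatures from annotated cohorts.

Per dataset, every gene is tested between the two classes with a t-test whose
standard error is deliberately inflated ("overestimated variance"): both
group variance terms are divided by the size of the group under test rather
than by each group's own size, which shrinks t-statistics for small target
classes and so guards against overconfident marker calls. Per-gene log2 fold
changes (group-mean differences on the log2 layer) are then averaged across
datasets, keeping only datasets where the BH-adjusted p-value clears the
threshold, the top genes are taken per comparison, and comparisons are
consolidated by intersection (up-signature) or union (depleted signature).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset, GeneSignature
from .errors import ConfigurationError, InsufficientCellsError, LabelError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConsolidationConfig",
    "DEResult",
    "differential_expression",
    "average_and_rank",
    "integrate_signatures",
    "derive_signatures",
    "crossvalidate_pairs",
    "ablate_signature",
]


@dataclass(frozen=True)
class ConsolidationConfig:
    """Knobs for turning per-dataset DE tables into signatures."""

    n_top: int = 300
    p_adj_threshold: float = 0.1

    def __post_init__(self):
        if not (0 < self.p_adj_threshold <= 1):
            raise ConfigurationError("p_adj_threshold must be in (0, 1]")
        if self.n_top < 1:
            raise ConfigurationError("n_top must be >= 1")


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one dataset/comparison."""

    table: pd.DataFrame  # index: gene; columns: t_statistic, log2fc, p_value, p_adj
    dataset_name: str
    comparison: tuple[str, str]  # (up_class, down_class)


def _overestimated_variance_ttest(
    up: np.ndarray, down: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized t-test over gene columns with the inflated-variance denominator.

    Both variance terms are divided by ``n_up`` (the size of the class under
    test), and degrees of freedom follow Welch–Satterthwaite on those same
    inflated terms.
    """
    n_up, n_down = up.shape[0], down.shape[0]
    mean_up = up.mean(axis=0)
    mean_down = down.mean(axis=0)
    var_up = up.var(axis=0, ddof=1)
    var_down = down.var(axis=0, ddof=1)

    term_up = var_up / n_up
    term_down = var_down / n_up  # shared (smaller) denominator: the inflation
    se2 = term_up + term_down
    diff = mean_up - mean_down

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        dof = se2**2 / (term_up**2 / (n_up - 1) + term_down**2 / (n_up - 1))

    # zero-variance genes: identical constant values give t = 0, p = 1;
    # constant but different means give an infinite statistic, p = 0
    zero_se = se2 == 0
    t = np.where(zero_se & (diff == 0), 0.0, t)
    t = np.where(zero_se & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    dof = np.where(zero_se | ~np.isfinite(dof), 1.0, dof)

    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), dof)
    )
    p = np.where(zero_se & (diff == 0), 1.0, p)
    return t, p, diff


def differential_expression(
    dataset: ExpressionDataset,
    up_class: str,
    down_class: str,
    label_column: str,
) -> DEResult:
    """Test every gene for differential expression between two cell classes.

    Returns one row per gene with the inflated-variance t-statistic, the
    approximate log2 fold change (difference of class means on the log2
    layer), the two-sided p-value and its Benjamini–Hochberg adjustment.
    """
    labels = dataset.labels(label_column)
    for cls in (up_class, down_class):
        if cls not in set(labels):
            raise LabelError(
                f"class {cls!r} absent from column {label_column!r} in "
                f"dataset {dataset.dataset_name!r}"
            )
    up_mask = (labels == up_class).to_numpy()
    down_mask = (labels == down_class).to_numpy()
    if up_mask.sum() < 2 or down_mask.sum() < 2:
        raise InsufficientCellsError(
            f"need >=2 cells per class; got {up_mask.sum()} {up_class!r} and "
            f"{down_mask.sum()} {down_class!r}"
        )
    t, p, log2fc = _overestimated_variance_ttest(
        dataset.matrix[up_mask], dataset.matrix[down_mask]
    )
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"t_statistic": t, "log2fc": log2fc, "p_value": p, "p_adj": p_adj},
        index=dataset.gene_symbols,
    )
    return DEResult(table=table, dataset_name=dataset.dataset_name,
                    comparison=(up_class, down_class))


def average_and_rank(
    de_results: Sequence[DEResult],
    config: ConsolidationConfig = ConsolidationConfig(),
    descending: bool = True,
) -> list[str]:
    """Average per-gene log2fc across datasets and return the top genes.

    A gene contributes from a dataset only where its adjusted p-value clears
    ``p_adj_threshold``; the average runs over the passing datasets only, and
    genes passing nowhere are dropped. Genes are sorted by average log2fc
    (descending for up-signatures, ascending for depleted ones) with
    lexicographic tie-breaking, and the top ``n_top`` returned.
    """
    if not de_results:
        raise ConfigurationError("need at least one DE result")
    comparisons = {r.comparison for r in de_results}
    if len(comparisons) > 1:
        raise ConfigurationError(f"mixed comparisons: {comparisons}")

    frames = []
    for r in de_results:
        passing = r.table.loc[r.table["p_adj"] < config.p_adj_threshold, "log2fc"]
        frames.append(passing.rename(r.dataset_name))
    merged = pd.concat(frames, axis=1)
    if merged.empty:
        logger.warning("no gene passed the p_adj filter in any dataset")
        return []
    avg = merged.mean(axis=1, skipna=True).dropna()
    order = pd.DataFrame({"avg": avg, "gene": avg.index})
    order = order.sort_values(
        ["avg", "gene"], ascending=[not descending, True], kind="stable"
    )
    return order["gene"].head(config.n_top).tolist()


def integrate_signatures(
    per_comparison_lists: Sequence[Sequence[str]],
    mode: str,
    name: str = "signature",
) -> GeneSignature | None:
    """Consolidate ranked per-comparison gene lists into one signature.

    ``mode="up"`` intersects the lists (genes must discriminate the class of
    interest from every other class); ``mode="down"`` takes the union. The
    result is ordered lexicographically. An empty consolidation (possible
    only for the intersection) logs a warning and returns ``None``.
    """
    if not per_comparison_lists:
        raise ConfigurationError("need at least one gene list")
    if mode not in ("up", "down"):
        raise ConfigurationError(f"mode must be 'up' or 'down', got {mode!r}")
    sets = [set(lst) for lst in per_comparison_lists]
    genes = set.intersection(*sets) if mode == "up" else set.union(*sets)
    if not genes:
        logger.warning("signature %r: empty %s across comparisons", name, mode)
        return None
    direction = "up_in_class" if mode == "up" else "down_in_class"
    return GeneSignature(name=name, genes=tuple(sorted(genes)), direction=direction)


def derive_signatures(
    datasets: Sequence[ExpressionDataset],
    label_column: str,
    class_of_interest: str,
    other_classes: Sequence[str],
    config: ConsolidationConfig = ConsolidationConfig(),
) -> tuple[GeneSignature, GeneSignature, pd.DataFrame]:
    """Full signature derivation across datasets and comparisons.

    For each comparison (class_of_interest vs. one other class) the per-dataset
    DE tables are averaged and ranked twice — once for genes up in the class of
    interest, once for genes depleted in it. Up-lists are intersected across
    comparisons ("tumor" signature); depleted lists are unioned ("normal"
    signature). Also returns an audit table of per-dataset statistics.
    """
    up_lists, down_lists, audit_rows = [], [], []
    for other in other_classes:
        de = [differential_expression(d, class_of_interest, other, label_column)
              for d in datasets]
        up_lists.append(average_and_rank(de, config, descending=True))
        down_lists.append(average_and_rank(de, config, descending=False))
        for r in de:
            t = r.table.copy()
            t["dataset"] = r.dataset_name
            t["comparison"] = f"{class_of_interest}_vs_{other}"
            audit_rows.append(t.reset_index(names="gene"))

    provenance = tuple(
        (d.dataset_name, f"{class_of_interest}_vs_{o}")
        for d in datasets for o in other_classes
    )
    up = integrate_signatures(up_lists, "up", "tumor")
    down = integrate_signatures(down_lists, "down", "normal")
    if up is None or down is None:
        raise ValidationError("signature derivation produced an empty gene set")
    up = GeneSignature(up.name, up.genes, up.direction, provenance)
    down = GeneSignature(down.name, down.genes, down.direction, provenance)
    audit = pd.concat(audit_rows, ignore_index=True)
    return up, down, audit


def crossvalidate_pairs(
    datasets: Sequence[ExpressionDataset],
    label_column: str,
    class_of_interest: str,
    other_classes: Sequence[str],
    config: ConsolidationConfig = ConsolidationConfig(),
    include_singles: bool = False,
    **predict_kwargs,
) -> pd.DataFrame:
    """Dataset-pair cross-validation of signature derivation + classification.

    For every unordered pair of datasets, derive signatures from the pair,
    train the score classifier on it, predict the held-out datasets, and
    report the minimum balanced accuracy across them (the worst-case
    performance). ``include_singles`` adds single-dataset training rows.
    Evaluation uses the score classifier directly (no propagation) unless
    ``propagate_labels=True`` is passed through ``predict_kwargs``.
    """
    predict_kwargs.setdefault("propagate_labels", False)
    from .model import SignatureClassifier  # local import: model builds on this module

    if len(datasets) < 3:
        raise ConfigurationError("pair cross-validation needs >= 3 datasets")
    names = [d.dataset_name for d in datasets]
    training_sets: list[tuple[int, ...]] = list(
        itertools.combinations(range(len(datasets)), 2)
    )
    if include_singles:
        training_sets += [(i,) for i in range(len(datasets))]

    rows = []
    for idx in training_sets:
        train = [datasets[i] for i in idx]
        held_out = [d for i, d in enumerate(datasets) if i not in idx]
        model = SignatureClassifier(
            train, label_column=label_column,
            tumor_class=class_of_interest, normal_classes=list(other_classes),
            consolidation=config,
        )
        res = model.fit()
        accs = {}
        from .classifier import balanced_accuracy

        for d in held_out:
            pred = res.predict(d, **predict_kwargs)
            truth = (d.labels(label_column) == class_of_interest).to_numpy()
            accs[d.dataset_name] = balanced_accuracy(truth, pred.labels)
        rows.append({
            "training": "+".join(names[i] for i in idx),
            "min_balanced_accuracy": min(accs.values()),
            **{f"acc_{k}": v for k, v in accs.items()},
        })
    return pd.DataFrame(rows)


def ablate_signature(
    results,
    dataset: ExpressionDataset,
    label_column: str,
    mode: str = "fraction",
    fraction: float | None = None,
    gene: str | None = None,
    genes: Sequence[str] | None = None,
    n_repeats: int = 25,
    seed: int = 0,
    **predict_kwargs,
) -> pd.DataFrame:
    """Robustness harness: re-run score→classify→propagate with a reduced tumor list.

    ``mode="fraction"`` removes a random fraction of the tumor signature per
    repeat; ``mode="single_gene"`` removes one named gene once;
    ``mode="genes"`` removes an explicit gene set once (e.g. every informative
    gene, to measure the floor). Predictions are not CNV-corrected. Returns a
    table of balanced accuracies per repeat.

    ``results`` is a fitted :class:`~oncosift.model.SignatureClassifierResults`.
    """
    from .classifier import balanced_accuracy

    tumor = list(results.tumor_signature.genes)
    rng = np.random.default_rng(seed)
    truth = (dataset.labels(label_column) == results.tumor_class).to_numpy()

    def run_with(genes: list[str], repeat: int) -> dict:
        if len(genes) < 1:
            raise ValidationError("ablation leaves no genes in the signature")
        reduced = GeneSignature("tumor", tuple(genes), "up_in_class")
        pred = results.predict(
            dataset, tumor_signature=reduced, **predict_kwargs
        )
        acc = balanced_accuracy(truth, pred.labels)
        return {"repeat": repeat, "n_genes": len(genes), "balanced_accuracy": acc}

    rows = []
    if mode == "fraction":
        if fraction is None or not (0 <= fraction < 1):
            raise ConfigurationError("fraction must be in [0, 1)")
        n_remove = int(round(fraction * len(tumor)))
        for rep in range(n_repeats):
            keep = list(tumor)
            if n_remove:
                drop = set(rng.choice(len(tumor), size=n_remove, replace=False))
                keep = [g for i, g in enumerate(tumor) if i not in drop]
            rows.append(run_with(keep, rep) | {"fraction_removed": fraction})
    elif mode == "single_gene":
        if gene is None:
            raise ConfigurationError("single_gene mode needs a gene")
        if gene not in tumor:
            raise ValidationError(f"gene {gene!r} is not in the signature")
        rows.append(run_with([g for g in tumor if g != gene], 0) | {"gene_removed": gene})
    elif mode == "genes":
        if not genes:
            raise ConfigurationError("genes mode needs a non-empty gene list")
        missing = [g for g in genes if g not in tumor]
        if missing:
            raise ValidationError(f"gene(s) not in the signature: {missing[:5]}")
        remove = set(genes)
        rows.append(
            run_with([g for g in tumor if g not in remove], 0)
            | {"n_genes_removed": len(remove)}
        )
    else:
        raise ConfigurationError(f"unknown ablation mode {mode!r}")
    return pd.DataFrame(rows)
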