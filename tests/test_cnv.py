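"""CNV profile inference, summary diagnostic, proofreading and the
cross-cohort baseline harness."""

import numpy as np
import pandas as pd
import pytest

import oncosift as o
from oncosift.cnv import ProofreadConfig, _moving_average_by_chrom
from oncosift.errors import ConfigurationError, ValidationError

from conftest import make_dataset


def _positions(n_genes, chroms=2):
    per = int(np.ceil(n_genes / chroms))
    rows = []
    g = 0
    for c in range(chroms):
        for i in range(per):
            if g >= n_genes:
                break
            rows.append((f"g{g:04d}", f"chr{c + 1}", 1000 * (i + 1),
                         1000 * (i + 1) + 500))
            g += 1
    return o.GenePositionTable(
        pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"]))


def _poisson_dataset(n_cells, n_genes, seed, gain_cells=None, gain_genes=None,
                     fold=2.0, mean_scale=50.0):
    """High-depth Poisson counts; optional planted gain block."""
    rng = np.random.default_rng(seed)
    gene_means = mean_scale * rng.lognormal(0, 0.3, size=n_genes)
    mu = np.tile(gene_means, (n_cells, 1))
    if gain_cells is not None:
        mu[np.ix_(gain_cells, gain_genes)] *= fold
    counts = rng.poisson(mu)
    total = counts.sum(axis=1).astype(float)
    log2 = np.log2(1 + counts / total[:, None] * np.median(total))
    labels = ["Normal"] * n_cells
    if gain_cells is not None:
        for i in gain_cells:
            labels[i] = "Tumor"
    return make_dataset(log2, labels, raw_counts=counts)


class TestMovingAverage:
    def test_matches_scalar_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(3, 40))
        chroms = np.array(["chr1"] * 25 + ["chr2"] * 15)
        window = 7
        out = _moving_average_by_chrom(values, chroms, window)
        half = window // 2
        for c in range(3):
            for block in (range(25), range(25, 40)):
                block = list(block)
                for pos, j in enumerate(block):
                    lo = max(pos - half, 0)
                    hi = min(pos + half + 1, len(block))
                    expected = np.mean([values[c, block[q]]
                                        for q in range(lo, hi)])
                    assert out[c, j] == pytest.approx(expected, abs=1e-12)

    def test_never_crosses_chromosome_boundary(self):
        values = np.zeros((1, 20))
        values[0, 10:] = 10.0  # chr2 elevated
        chroms = np.array(["chr1"] * 10 + ["chr2"] * 10)
        out = _moving_average_by_chrom(values, chroms, 5)
        assert np.allclose(out[0, :10], 0.0)
        assert np.allclose(out[0, 10:], 10.0)

    def test_preserves_per_chromosome_mean_up_to_edge_truncation(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(2, 500))
        chroms = np.array(["chr1"] * 500)
        out = _moving_average_by_chrom(values, chroms, 11)
        # interior mass is conserved; discrepancies come from the ~window
        # edge genes only
        for c in range(2):
            assert abs(out[c].mean() - values[c].mean()) < 11 / 500


class TestInferProfile:
    def test_null_data_gives_flat_profiles(self):
        # sequencing depth high enough that smoothing noise sits well
        # inside the +-0.1 band expected of a CNV-free profile
        ds = _poisson_dataset(120, 300, seed=2, mean_scale=200.0)
        profile = o.infer_cnv_profile(ds, _positions(300),
                                      np.ones(120, dtype=bool), window=51)
        assert np.abs(profile.matrix).max() < 0.1

    def test_reference_mean_profile_near_zero(self, cnv_cohort):
        datasets, truth = cnv_cohort
        ds = datasets[0]
        ref = (ds.labels("cell_type") == "Normal").to_numpy()
        profile = o.infer_cnv_profile(ds, truth.positions, ref)
        ref_rows = np.isin(np.asarray(profile.cell_ids),
                           np.asarray(profile.reference_cells))
        assert np.abs(profile.matrix[ref_rows].mean(axis=0)).max() < 0.05

    def test_planted_gain_produces_positive_plateau(self, cnv_cohort):
        datasets, truth = cnv_cohort
        ds = datasets[0]
        tumor = (ds.labels("cell_type") == "Tumor").to_numpy()
        profile = o.infer_cnv_profile(ds, truth.positions, ~tumor)
        gain_genes = set(next(iter(truth.cnv_genes.values())))
        in_gain = profile.gene_order["gene"].isin(gain_genes).to_numpy()
        assert in_gain.sum() > 50
        tumor_plateau = profile.matrix[np.ix_(tumor, in_gain)].mean()
        normal_plateau = profile.matrix[np.ix_(~tumor, in_gain)].mean()
        assert tumor_plateau > 0.3
        assert abs(normal_plateau) < 0.1

    def test_plateau_equals_brute_force_pipeline_recomputation(self):
        n_cells, n_genes = 40, 60
        gain_cells = np.arange(5)
        gain_genes = np.arange(10, 25)
        ds = _poisson_dataset(n_cells, n_genes, seed=3,
                              gain_cells=gain_cells, gain_genes=gain_genes)
        positions = _positions(n_genes, chroms=1)
        ref = np.ones(n_cells, dtype=bool)
        ref[gain_cells] = False
        window = 5
        profile = o.infer_cnv_profile(ds, positions, ref, window=window,
                                      cutoff=0.1)

        # independent scalar recomputation of every pipeline stage
        counts = ds.raw_counts.astype(float)
        keep = [j for j in range(n_genes) if counts[:, j].mean() >= 0.1]
        lib = counts.sum(axis=1)
        scale = float(np.median(lib))
        norm = np.array([[np.log2(1 + counts[i, j] / lib[i] * scale)
                          for j in keep] for i in range(n_cells)])
        ref_mean = norm[ref].mean(axis=0)
        rel = np.clip(norm - ref_mean, -3, 3)
        half = window // 2
        smooth = np.empty_like(rel)
        for i in range(n_cells):
            for p in range(len(keep)):
                lo, hi = max(p - half, 0), min(p + half + 1, len(keep))
                smooth[i, p] = rel[i, lo:hi].mean()
        smooth -= np.median(smooth, axis=1, keepdims=True)
        np.testing.assert_allclose(profile.matrix, smooth, atol=1e-10)

    def test_lowly_expressed_genes_excluded_before_smoothing(self):
        ds = _poisson_dataset(50, 80, seed=4)
        ds.raw_counts[:, 7] = 0
        ds.raw_counts[1, 7] = 2  # mean raw count 0.04 < 0.1
        profile = o.infer_cnv_profile(ds, _positions(80),
                                      np.ones(50, dtype=bool), window=5)
        assert "g0007" not in set(profile.gene_order["gene"])

    def test_gene_column_order_invariance(self):
        ds = _poisson_dataset(30, 40, seed=5)
        positions = _positions(40, chroms=1)
        rng = np.random.default_rng(6)
        perm = rng.permutation(40)
        shuffled = o.ExpressionDataset(
            matrix=ds.matrix[:, perm],
            cell_ids=ds.cell_ids,
            gene_symbols=ds.gene_symbols[perm],
            annotations=ds.annotations.copy(),
            raw_counts=ds.raw_counts[:, perm],
        )
        ref = np.ones(30, dtype=bool)
        a = o.infer_cnv_profile(ds, positions, ref, window=5)
        b = o.infer_cnv_profile(shuffled, positions, ref, window=5)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)
        assert list(a.gene_order["gene"]) == list(b.gene_order["gene"])

    def test_requires_raw_counts_and_reference(self):
        ds = make_dataset(np.ones((20, 30)))
        with pytest.raises(ValidationError):
            o.infer_cnv_profile(ds, _positions(30), np.ones(20, dtype=bool))
        ds2 = _poisson_dataset(20, 30, seed=7)
        with pytest.raises(ValidationError):
            o.infer_cnv_profile(ds2, _positions(30), np.zeros(20, dtype=bool))


class TestSummary:
    def test_all_zero_profile_gives_zero_mean_and_variance(self):
        profile = o.CNVProfile(
            matrix=np.zeros((4, 10)),
            gene_order=_positions(10).table,
            cell_ids=pd.Index([f"c{i}" for i in range(4)]),
            window=5, reference_cells=pd.Index(["c0"]),
        )
        summ = o.cnv_summary(profile)
        assert (summ["cnv_mean"] == 0).all()
        assert (summ["cnv_variance"] == 0).all()

    def test_hand_computed_four_gene_profile(self):
        m = np.array([[0.1, -0.1, 0.3, 0.5], [0.0, 0.0, 0.0, 0.4]])
        profile = o.CNVProfile(
            matrix=m, gene_order=_positions(4).table,
            cell_ids=pd.Index(["a", "b"]), window=3,
            reference_cells=pd.Index(["b"]),
        )
        summ = o.cnv_summary(profile)
        assert summ.loc["a", "cnv_mean"] == pytest.approx((0.1 - 0.1 + 0.3 + 0.5) / 4)
        assert summ.loc["a", "cnv_variance"] == pytest.approx(m[0].var())
        assert summ.loc["b", "cnv_mean"] == pytest.approx(0.1)

    def test_gain_carrying_cells_have_higher_mean_and_variance(self, cnv_cohort):
        datasets, truth = cnv_cohort
        ds = datasets[0]
        tumor = (ds.labels("cell_type") == "Tumor").to_numpy()
        profile = o.infer_cnv_profile(ds, truth.positions, ~tumor)
        summ = o.cnv_summary(profile)
        assert summ["cnv_mean"][tumor].mean() > summ["cnv_mean"][~tumor].mean()
        assert summ["cnv_variance"][tumor].mean() > summ["cnv_variance"][~tumor].mean()


class TestProofread:
    def _profile(self, matrix):
        n_cells, n_genes = matrix.shape
        return o.CNVProfile(
            matrix=matrix, gene_order=_positions(n_genes, chroms=1).table,
            cell_ids=pd.Index([f"c{i:03d}" for i in range(n_cells)]),
            window=5, reference_cells=pd.Index([]),
        )

    def test_concordant_predictions_yield_zero_flips(self):
        rng = np.random.default_rng(8)
        n = 200
        labels = np.zeros(n, dtype=bool)
        labels[:40] = True
        matrix = rng.normal(0, 0.02, size=(n, 30))
        matrix[labels, :10] += 1.0  # separable CNV structure
        profile = self._profile(matrix)
        corrected, report = o.cnv_proofread(profile, labels)
        np.testing.assert_array_equal(corrected, labels)
        assert len(report) == 0

    def test_moderately_discordant_cell_not_flipped(self):
        # flip threshold 0.9: a discordant probability of ~0.6 must not flip
        rng = np.random.default_rng(9)
        n = 100
        labels = np.zeros(n, dtype=bool)
        labels[:50] = True
        matrix = rng.normal(0, 1.0, size=(n, 5))  # nearly uninformative CNVs
        profile = self._profile(matrix)
        corrected, report = o.cnv_proofread(profile, labels)
        if len(report):
            assert (report["opposite_class_probability"] > 0.9).all()
        # weak features cannot produce confident discordance for most cells
        assert (corrected != labels).mean() < 0.1

    def test_single_class_pseudo_labels_returns_unchanged_with_warning(self, caplog):
        profile = self._profile(np.zeros((20, 10)))
        labels = np.ones(20, dtype=bool)
        with caplog.at_level("WARNING"):
            corrected, report = o.cnv_proofread(profile, labels)
        np.testing.assert_array_equal(corrected, labels)
        assert len(report) == 0
        assert any("single-class" in r.message for r in caplog.records)

    def test_flips_bounded_by_discordant_cells_and_never_concordant(self):
        rng = np.random.default_rng(10)
        n = 300
        truth = np.zeros(n, dtype=bool)
        truth[:60] = True
        matrix = rng.normal(0, 0.05, size=(n, 40))
        matrix[truth, :20] += 0.8
        pseudo = truth.copy()
        wrong = rng.choice(np.flatnonzero(~truth), size=15, replace=False)
        pseudo[wrong] = True  # false positives on flat cells
        profile = self._profile(matrix)
        corrected, report = o.cnv_proofread(profile, pseudo)
        # only planted-discordant cells may flip
        flipped = corrected != pseudo
        assert flipped.sum() <= len(wrong)
        assert set(np.flatnonzero(flipped)) <= set(wrong)

    def test_false_positive_rate_drops_without_accuracy_loss(self, cnv_cohort):
        datasets, truth = cnv_cohort
        ds = datasets[0]
        labels = (ds.labels("cell_type") == "Tumor").to_numpy()
        rng = np.random.default_rng(11)
        pseudo = labels.copy()
        fp = rng.choice(np.flatnonzero(~labels),
                        size=int(0.05 * len(labels)), replace=False)
        pseudo[fp] = True
        profile = o.infer_cnv_profile(ds, truth.positions, ~pseudo)
        corrected, _ = o.cnv_proofread(profile, pseudo)

        def fpr(pred):
            return (pred & ~labels).sum() / (~labels).sum()

        assert fpr(corrected) < fpr(pseudo)
        assert o.balanced_accuracy(labels, corrected) >= (
            o.balanced_accuracy(labels, pseudo) - 0.01
        )


class TestCnvBaseline:
    def _cohort_profile(self, seed, gain_genes):
        n_cells = 150
        gain_cells = np.arange(30)
        ds = _poisson_dataset(n_cells, 120, seed=seed,
                              gain_cells=gain_cells, gain_genes=gain_genes,
                              fold=2.0)
        ref = np.ones(n_cells, dtype=bool)
        ref[gain_cells] = False
        profile = o.infer_cnv_profile(ds, _positions(120, chroms=2), ref,
                                      window=11)
        labels = ~ref
        return profile, labels

    def test_shared_architecture_generalizes_but_disjoint_does_not(self):
        shared = np.arange(10, 40)
        pa, la = self._cohort_profile(20, shared)
        pb, lb = self._cohort_profile(21, shared)
        disjoint = np.arange(70, 100)
        pc, lc = self._cohort_profile(22, disjoint)
        table = o.train_cnv_baseline(
            [pa, pb, pc], [la, lb, lc], ["a", "b", "c"],
            include_merged_pair=False,
        )
        assert table.loc["a", "a"] > 0.95
        assert table.loc["a", "b"] > 0.9  # same planted architecture
        assert table.loc["a", "c"] < 0.7  # disjoint architecture
        assert table.loc["c", "a"] < 0.7

    def test_single_cohort_rejected(self):
        p, l = self._cohort_profile(23, np.arange(5, 20))
        with pytest.raises(ConfigurationError):
            o.train_cnv_baseline([p], [l])
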