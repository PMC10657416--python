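"""Stage-3 clustering and differential-expression validation."""

import numpy as np
import pytest
import scipy.sparse as sp

import dropgate as dg
from dropgate.expression_filter import (
    ClusterDEResult,
    cluster_de,
    cluster_shallow_deep,
    evaluate_clusters,
)


def _two_population_matrix(rng, n_per=120, n_genes=300, n_markers=20):
    """Two populations with disjoint marker blocks on a shared background."""
    base = rng.gamma(2.0, 1.0, n_genes)
    base[:2 * n_markers] = 0.01
    profiles = []
    for t in range(2):
        prof = base.copy()
        prof[t * n_markers : (t + 1) * n_markers] = base.mean() * 20
        profiles.append(prof / prof.sum())
    cols, labels = [], []
    for t, prof in enumerate(profiles):
        depth = rng.integers(1500, 2500, n_per)
        for d in depth:
            g = rng.choice(n_genes, d, p=prof)
            col = np.bincount(g, minlength=n_genes)
            cols.append(col)
            labels.append(t)
    X = sp.csr_matrix(np.array(cols).T)
    cm = dg.CountMatrix(X, [f"G{i}" for i in range(n_genes)], [f"B{i:04d}" for i in range(len(labels))])
    return cm, np.array(labels)


class TestSelectHvgs:
    def test_uniform_gene_ranked_last(self, rng):
        cm, _ = _two_population_matrix(rng)
        order = dg.select_hvgs(cm, n=cm.n_genes)
        # marker genes (0..39) dominate the top of the ranking
        top40 = set(order[:40].tolist())
        assert len(top40 & set(range(40))) >= 30

    def test_planted_marker_above_uniform(self, rng):
        cm, _ = _two_population_matrix(rng)
        order = list(dg.select_hvgs(cm, n=cm.n_genes))
        marker_ranks = [order.index(g) for g in range(20)]
        background_ranks = [order.index(g) for g in range(100, 120)]
        assert np.median(marker_ranks) < np.median(background_ranks)

    def test_deviance_nonnegative_and_top_n(self, rng):
        cm, _ = _two_population_matrix(rng)
        hv = dg.select_hvgs(cm, n=50)
        assert len(hv) == 50

    def test_all_zero_matrix_errors(self):
        cm = dg.CountMatrix(sp.csr_matrix((5, 4)), [f"G{i}" for i in range(5)], list("abcd"))
        with pytest.raises(ValueError):
            dg.select_hvgs(cm)


class TestEmbed:
    def test_separates_planted_populations(self, rng):
        from sklearn.metrics import silhouette_score

        cm, labels = _two_population_matrix(rng)
        emb = dg.embed(cm, dg.select_hvgs(cm, 200), n_components=10, seed=0)
        assert silhouette_score(emb[:, :1], labels) > 0.5

    def test_duplicated_barcode_identical_rows(self, rng):
        cm, _ = _two_population_matrix(rng, n_per=30)
        counts = sp.hstack([cm.counts, cm.counts[:, [0]]]).tocsr()
        cm2 = dg.CountMatrix(counts, cm.feature_ids, cm.barcode_ids + ["DUP"])
        emb = dg.embed(cm2, dg.select_hvgs(cm2, 200), n_components=5, seed=0)
        assert np.allclose(emb[0], emb[-1], atol=1e-8)

    def test_reproducible_for_fixed_seed(self, rng):
        cm, _ = _two_population_matrix(rng, n_per=40)
        hv = dg.select_hvgs(cm, 200)
        e1 = dg.embed(cm, hv, n_components=8, seed=5)
        e2 = dg.embed(cm, hv, n_components=8, seed=5)
        assert np.array_equal(e1, e2)


class TestClusterShallowDeep:
    def _embedding(self, rng, n_per=200, k=3):
        centers = rng.normal(0, 8, (k, 10))
        return (
            np.vstack([c + rng.normal(0, 1, (n_per, 10)) for c in centers]),
            np.repeat(np.arange(k), n_per),
        )

    def test_three_planted_populations(self, rng):
        emb, truth = self._embedding(rng)
        frame = cluster_shallow_deep(emb, seed=0)
        assert len(np.unique(frame.shallow_label)) >= 2
        assert len(np.unique(frame.deep_label)) >= 3
        # deep refines shallow: every deep cluster sits (almost) entirely
        # inside one shallow cluster, and deep is at least as fine
        assert len(np.unique(frame.deep_label)) >= len(np.unique(frame.shallow_label))
        for d in np.unique(frame.deep_label):
            members = frame.shallow_label[frame.deep_label == d]
            purity = np.max(np.bincount(members)) / members.size
            assert purity >= 0.9

    def test_identical_barcodes_single_cluster(self):
        emb = np.zeros((50, 5))
        frame = cluster_shallow_deep(emb, seed=0)
        assert len(np.unique(frame.shallow_label)) == 1
        assert np.array_equal(frame.deep_label, frame.shallow_label)

    def test_min_deep_cluster_size(self, rng):
        emb, _ = self._embedding(rng, n_per=60)
        frame = cluster_shallow_deep(emb, seed=0)
        assert np.bincount(frame.deep_label).min() >= 5

    def test_shallow_of_deep_defined_for_all(self, rng):
        emb, _ = self._embedding(rng, n_per=60)
        frame = cluster_shallow_deep(emb, seed=0)
        assert set(np.unique(frame.deep_label)) == set(frame.shallow_of_deep)


class TestClusterDe:
    def test_planted_markers_detected(self, rng):
        cm, labels = _two_population_matrix(rng)
        emb = dg.embed(cm, dg.select_hvgs(cm, 200), n_components=10, seed=0)
        frame = cluster_shallow_deep(emb, seed=0)
        # pick the deep cluster best matching population 0
        best = max(
            np.unique(frame.deep_label),
            key=lambda d: np.mean(labels[frame.deep_label == d] == 0),
        )
        if np.mean(labels[frame.deep_label == best] == 0) < 0.9:
            pytest.skip("clustering did not isolate the planted population")
        res = cluster_de(cm, frame, int(best))
        markers = set(range(20))
        top = set(res.top_markers)
        assert len(top & markers) >= 5
        pos = [np.flatnonzero(res.gene_idx == g)[0] for g in res.top_markers if g in markers]
        assert np.all(res.auc[pos] >= 0.9)
        assert np.all(res.fdr[pos] < 0.05)

    def test_null_cluster_few_significant(self, rng):
        # one population randomly split in two: DE should find ~nothing
        cm, _ = _two_population_matrix(rng, n_per=100)
        n = cm.n_barcodes
        half = rng.permutation(n) < n // 3
        frame = dg.ClusterFrame(
            shallow_label=half.astype(int),
            deep_label=half.astype(int),
            deep_resolution=0.2,
            shallow_of_deep={0: 0, 1: 1},
            embedding=np.zeros((n, 2)),
        )
        # population structure exists, but labels ignore it -> compare a random
        # subset of the same mixture against the rest
        res = cluster_de(cm, frame, 1)
        assert res.n_significant <= 0.01 * res.n_tested + 1

    def test_identical_gene_auc_half(self, rng):
        # equal depths, so normalised values of the constant gene are identical
        n = 30
        g0 = np.full(n, 3)
        g1 = rng.integers(0, 5, n)
        g2 = 10 - g1
        cm = dg.CountMatrix(
            sp.csr_matrix(np.vstack([g0, g1, g2])),
            ["G0", "G1", "G2"],
            [f"B{i:02d}" for i in range(n)],
        )
        labels = (np.arange(n) < 10).astype(int)
        frame = dg.ClusterFrame(
            shallow_label=labels, deep_label=labels, deep_resolution=0.2,
            shallow_of_deep={0: 0, 1: 1}, embedding=np.zeros((n, 2)),
        )
        res = cluster_de(cm, frame, 1)
        pos = np.flatnonzero(res.gene_idx == 0)[0]
        assert res.auc[pos] == pytest.approx(0.5)


def _mk_result(d, pct_in, pct_out, n_tested=1000, n_sig=50, min_fdr=1e-20, delta=None):
    pct_in = np.asarray(pct_in, float)
    pct_out = np.asarray(pct_out, float)
    return ClusterDEResult(
        deep_label=d,
        gene_idx=np.arange(pct_in.size),
        auc=np.linspace(0.99, 0.9, pct_in.size),
        log_fold_change=np.ones(pct_in.size),
        pct_in=pct_in,
        pct_out=pct_out,
        fdr=np.linspace(min_fdr, 1e-10, pct_in.size),
        top_markers=list(range(min(10, pct_in.size))),
        min_fdr=min_fdr,
        avg_delta_pct=float(np.mean(pct_in[:10] - pct_out[:10])) if delta is None else delta,
        n_tested=n_tested,
        n_significant=n_sig,
    )


class TestEvaluateClusters:
    def _qc(self, n):
        import pandas as pd

        return pd.DataFrame(
            {"frac_mito": np.full(n, 0.05), "frac_ribo": np.full(n, 0.2)},
            index=[f"B{i}" for i in range(n)],
        )

    def _frame(self, labels):
        labels = np.asarray(labels)
        return dg.ClusterFrame(
            shallow_label=labels, deep_label=labels, deep_resolution=1.0,
            shallow_of_deep={int(d): int(d) for d in np.unique(labels)},
            embedding=np.zeros((labels.size, 2)),
        )

    def test_ubiquitous_marker_cluster_fails(self):
        res = _mk_result(0, pct_in=np.full(10, 95.0), pct_out=np.full(10, 80.0))
        frame = self._frame([0] * 20)
        verdict = evaluate_clusters([res], self._qc(20), frame)
        assert verdict[0] == (False, "cluster_marker")  # pct_out >= 70

    def test_specific_marker_cluster_passes(self):
        res = _mk_result(0, pct_in=np.full(10, 50.0), pct_out=np.full(10, 10.0))
        frame = self._frame([0] * 20)
        verdict = evaluate_clusters([res], self._qc(20), frame)
        assert verdict[0][0]

    def test_marker_depleted_in_cluster_fails(self):
        pct_in = np.full(10, 50.0)
        pct_in[3] = 5.0  # expressed in 1pp fewer barcodes inside
        res = _mk_result(0, pct_in=pct_in, pct_out=np.full(10, 10.0))
        verdict = evaluate_clusters([res], self._qc(20), self._frame([0] * 20))
        assert verdict[0] == (False, "cluster_marker")

    def test_too_few_significant_fails(self):
        res = _mk_result(0, pct_in=np.full(10, 50.0), pct_out=np.full(10, 10.0), n_sig=5)
        verdict = evaluate_clusters([res], self._qc(20), self._frame([0] * 20))
        assert verdict[0] == (False, "cluster_significance")

    def test_high_mito_cluster_fails_fraction_rule(self):
        import pandas as pd

        labels = np.repeat([0, 1, 2, 3], 10)
        qc = pd.DataFrame(
            {
                "frac_mito": np.where(labels == 2, 0.5, 0.05 + 0.001 * labels),
                "frac_ribo": np.full(40, 0.2),
            },
            index=[f"B{i}" for i in range(40)],
        )
        results = [
            _mk_result(d, pct_in=np.full(10, 60.0), pct_out=np.full(10, 10.0))
            for d in range(4)
        ]
        verdict = evaluate_clusters(results, qc, self._frame(labels))
        assert verdict[2] == (False, "cluster_fraction")
        assert verdict[0][0] and verdict[1][0] and verdict[3][0]


class TestRunStage3Planted:
    def test_ambient_cluster_removed_cells_kept(self, staged_qc):
        qc, truth = staged_qc["qc"], staged_qc["truth"]
        tt = truth.table.loc[qc.index]
        cells = (tt["klass"] == "cell") & qc["pass_stage2"]
        empties = (tt["klass"] == "empty") & qc["pass_stage2"]
        assert qc.loc[cells[cells].index, "pass_stage3"].mean() >= 0.95
        if empties.sum() >= 10:
            assert qc.loc[empties[empties].index, "pass_stage3"].mean() <= 0.2

    def test_survivors_are_union_of_passing_clusters(self, staged_qc):
        qc = staged_qc["qc"]
        assert (qc["pass_stage3"] <= qc["pass_stage2"]).all()
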