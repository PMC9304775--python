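"""Median centering, Ward clustering with the min-size cut, and iterative
DE-driven refinement."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import scmntb
from scmntb import normalize as norm, qc as qcm
from scmntb.cluster import (
    iterative_refine,
    median_center,
    same_partition,
    ward_cluster,
)
from scmntb.de import DEThresholds
from scmntb.matrix import ExpressionMatrix, ValidationError
from scmntb.simulate import CellTypeProfile, SimulationConfig, default_config, generate_dataset


def expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])])


class TestMedianCenter:
    def test_constant_gene_becomes_zero(self):
        cm = median_center(expr(np.full((1, 5), 7.0)))
        np.testing.assert_array_equal(cm.values, 0.0)

    def test_simple_arithmetic(self):
        cm = median_center(expr([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(cm.values, [[-1.0, 0.0, 1.0]])

    def test_per_gene_median_is_zero(self, rng):
        cm = median_center(expr(rng.normal(size=(30, 11))))
        np.testing.assert_allclose(np.median(cm.values, axis=1), 0.0, atol=1e-9)

    def test_empty_gene_set_raises(self):
        with pytest.raises(ValidationError):
            median_center(expr(np.ones((3, 4))), genes=[])


def naive_ward_linkage(X):
    """O(n^3) agglomeration via the Lance-Williams update for Ward linkage."""
    n = X.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = np.sqrt(((X[i] - X[j]) ** 2).sum())

    def dist(a, b):
        return d[(min(a, b), max(a, b))]

    Z = []
    nxt = n
    while len(active) > 1:
        best = min(
            ((dist(a, b), a, b) for i, a in enumerate(active)
             for b in active[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        na, nb = sizes[a], sizes[b]
        Z.append([min(a, b), max(a, b), h, na + nb])
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            s = na + nb + nc
            new = np.sqrt(
                (na + nc) / s * dist(a, c) ** 2
                + (nb + nc) / s * dist(b, c) ** 2
                - nc / s * h ** 2
            )
            d[(min(c, nxt), max(c, nxt))] = new
        active = [c for c in active if c not in (a, b)] + [nxt]
        sizes[nxt] = na + nb
        nxt += 1
    return np.asarray(Z)


def test_linkage_heights_match_naive_ward_oracle(rng):
    X = rng.normal(size=(7, 3))
    cm = median_center(expr(X.T))
    res = ward_cluster(cm, min_cluster_size=1, n_clusters=2)
    Z_oracle = naive_ward_linkage(X)
    np.testing.assert_allclose(np.sort(res.linkage[:, 2]),
                               np.sort(Z_oracle[:, 2]), rtol=1e-9)


class TestWardCluster:
    def blobs(self, rng, centers, n_per, sd=0.3, n_genes=10):
        X, labels = [], []
        for k, c in enumerate(centers):
            X.append(c + sd * rng.standard_normal((n_per, n_genes)))
            labels += [k] * n_per
        return np.concatenate(X).T, np.array(labels)

    def test_two_separated_blobs_recovered(self, rng):
        vals, truth = self.blobs(rng, [np.zeros(10), np.full(10, 5.0)], 20)
        res = ward_cluster(median_center(expr(vals)))
        assert res.n_clusters == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_five_type_synthetic_recovery(self, default_dataset):
        ds = default_dataset
        m = ds.counts.subset_cells(
            qcm.mad_outlier_filter(qcm.compute_cell_qc(ds.counts))
        )
        mf = m.subset_genes(qcm.filter_genes(m))
        sf = norm.deconvolution_size_factors(mf)
        e = norm.log2_cpm(mf, sf)
        markers = sorted(set().union(*ds.marker_map.values()) - {"tdTomato"})
        res = ward_cluster(median_center(e, markers))
        truth = ds.true_type[m.cell_ids].to_numpy()
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_min_cluster_size_respected(self, rng):
        vals, _ = self.blobs(rng, [np.zeros(10), np.full(10, 6.0)], 30)
        res = ward_cluster(median_center(expr(vals)), min_cluster_size=5)
        assert min(res.cluster_sizes().values()) >= 5

    def test_explicit_k_honored(self, rng):
        vals, _ = self.blobs(rng, [np.zeros(10), np.full(10, 6.0), np.full(10, -6.0)], 15)
        res = ward_cluster(median_center(expr(vals)), n_clusters=3)
        assert res.n_clusters == 3

    def test_too_few_cells_single_cluster_with_warning(self, rng):
        vals = rng.normal(size=(10, 6))
        with pytest.warns(UserWarning):
            res = ward_cluster(median_center(expr(vals)), min_cluster_size=5)
        assert res.n_clusters == 1

    def test_invariant_to_cell_permutation(self, rng):
        vals, _ = self.blobs(rng, [np.zeros(8), np.full(8, 5.0)], 20, n_genes=8)
        res = ward_cluster(median_center(expr(vals)))
        perm = rng.permutation(vals.shape[1])
        e2 = ExpressionMatrix(vals[:, perm],
                              [f"g{i}" for i in range(vals.shape[0])],
                              [f"c{j}" for j in perm])
        res2 = ward_cluster(median_center(e2))
        assert same_partition(res.labels[perm], res2.labels)


class TestSamePartition:
    def test_permutation_invariant(self):
        assert same_partition([0, 0, 1, 1], [5, 5, 2, 2])
        assert not same_partition([0, 0, 1, 1], [0, 1, 0, 1])


@pytest.fixture(scope="module")
def prepared(default_dataset):
    ds = default_dataset
    m = ds.counts.subset_cells(
        qcm.mad_outlier_filter(qcm.compute_cell_qc(ds.counts))
    )
    mf = m.subset_genes(qcm.filter_genes(m))
    sf = norm.deconvolution_size_factors(mf)
    e = norm.log2_cpm(mf, sf)
    return ds, mf, sf, e


class TestIterativeRefine:
    def test_converges_fast_when_hvgs_separate_types(self, prepared):
        ds, mf, sf, e = prepared
        markers = sorted(
            (set().union(*ds.marker_map.values()) - {"tdTomato"})
            & set(mf.gene_ids)
        )
        res = iterative_refine(mf, sf, e, markers)
        assert res.converged
        assert len(res.iterations) <= 3
        truth = ds.true_type[res.cell_ids].to_numpy()
        assert adjusted_rand_score(truth, res.labels) >= 0.9

    def test_final_gene_set_covers_planted_markers(self, prepared):
        ds, mf, sf, e = prepared
        markers = sorted(
            (set().union(*ds.marker_map.values()) - {"tdTomato"})
            & set(mf.gene_ids)
        )
        res = iterative_refine(mf, sf, e, markers)
        planted = set(markers)
        assert len(set(res.genes_used) & planted) >= 0.8 * len(planted)

    def test_every_round_respects_min_size(self, prepared):
        _, mf, sf, e = prepared
        markers = [g for g in mf.gene_ids if not g.startswith("g")][:40]
        res = iterative_refine(mf, sf, e, markers, min_cluster_size=5)
        for _, labels in res.iterations:
            _, counts = np.unique(labels, return_counts=True)
            assert counts.min() >= 5 or len(counts) == 1

    def test_single_type_collapses_to_one_cluster(self):
        rng = np.random.default_rng(8)
        rates = rng.lognormal(1.0, 1.0, size=300)
        cfg = SimulationConfig(
            profiles=[CellTypeProfile("only", 60, rates)],
            gene_ids=[f"g{i}" for i in range(300)],
            nb_dispersion=0.05,
            seed=9,
        )
        ds = generate_dataset(cfg)
        m = ds.counts.subset_genes(qcm.filter_genes(ds.counts))
        sf = norm.deconvolution_size_factors(m)
        e = norm.log2_cpm(m, sf)
        with pytest.warns(UserWarning):
            res = iterative_refine(m, sf, e, list(m.gene_ids)[:50])
        assert res.n_clusters == 1
        assert res.converged

    def test_manual_exclusions_removed_before_clustering(self, prepared):
        ds, mf, sf, e = prepared
        drop = list(mf.cell_ids[:3])
        markers = sorted(
            (set().union(*ds.marker_map.values()) - {"tdTomato"})
            & set(mf.gene_ids)
        )
        res = iterative_refine(mf, sf, e, markers, exclude_cells=drop)
        assert set(drop).isdisjoint(set(res.cell_ids))
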