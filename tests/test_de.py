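"""Negative-binomial contrasts: detection rule, dispersion estimation,
likelihood-ratio calibration, fold-change conventions, and merged
one-vs-rest tables."""

import numpy as np
import pandas as pd
import pytest

from scmntb.de import (
    DEThresholds,
    detection_fraction,
    estimate_dispersion,
    nb_contrast,
    one_vs_rest_tables,
)
from scmntb.matrix import CountMatrix, SizeFactors, ValidationError
from scmntb.normalize import cpm, deconvolution_size_factors
from scmntb.stats import bh_fdr


def make_matrix(counts):
    counts = np.asarray(counts)
    return CountMatrix(counts, [f"g{i}" for i in range(counts.shape[0])],
                       [f"c{j}" for j in range(counts.shape[1])])


def unit_factors(m):
    return SizeFactors(np.ones(m.n_cells), m.cell_ids)


def nb_counts(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    lam = rng.gamma(1.0 / alpha, alpha * mu, size=size)
    return rng.poisson(lam)


def two_group_matrix(rng, n_genes=300, n_per=50, alpha=0.1, base_mu=20.0,
                     de_genes=(), fold=8.0):
    mu = np.full(n_genes, base_mu)
    a = nb_counts(rng, mu[:, None], alpha, (n_genes, n_per))
    mu_b = mu.copy()
    for g in de_genes:
        mu_b[g] *= fold
    b = nb_counts(rng, mu_b[:, None], alpha, (n_genes, n_per))
    counts = np.concatenate([a, b], axis=1)
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return make_matrix(counts), labels


class TestDetectionFraction:
    def test_zero_everywhere_gives_zero(self):
        v = np.zeros((3, 10))
        out = detection_fraction(v, ["x"] * 5 + ["y"] * 5)
        assert (out.to_numpy() == 0).all()

    def test_boundary_twenty_percent(self):
        v = np.zeros((1, 10))
        v[0, :2] = 5.0  # exactly at the CPM threshold
        out = detection_fraction(v, ["x"] * 10)
        assert out.loc[0, "x"] == 0.2

    def test_matches_naive_oracle(self, rng):
        v = rng.uniform(0, 20, size=(40, 30))
        labels = rng.choice(["a", "b", "c"], size=30)
        out = detection_fraction(v, labels)
        for lab in "abc":
            for g in range(40):
                members = labels == lab
                expect = sum(v[g, j] >= 5 for j in np.flatnonzero(members)) / members.sum()
                assert np.isclose(out.loc[g, lab], expect)

    def test_labels_must_cover_cells(self):
        with pytest.raises(ValidationError):
            detection_fraction(np.zeros((2, 4)), ["x", "x", "x"])


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self, rng):
        m, labels = two_group_matrix(rng, alpha=0.0)
        disp = estimate_dispersion(m, unit_factors(m), labels)
        assert np.median(disp.alpha) <= 0.02

    def test_nb_alpha_recovered(self, rng):
        m, labels = two_group_matrix(rng, alpha=0.2, n_per=100)
        disp = estimate_dispersion(m, unit_factors(m), labels)
        assert 0.1 <= np.median(disp.alpha) <= 0.3

    def test_constant_gene_falls_back_to_trend(self, rng):
        m, labels = two_group_matrix(rng, n_genes=50)
        counts = m.dense()
        counts[0, :] = 7  # constant gene: zero variance
        m2 = make_matrix(counts)
        disp = estimate_dispersion(m2, unit_factors(m2), labels)
        assert np.isclose(disp.alpha[0], disp.trend[0])


class TestNBContrast:
    def test_identical_groups_are_null(self, rng):
        block = nb_counts(rng, 20.0, 0.1, (100, 30))
        counts = np.concatenate([block, block], axis=1)
        m = make_matrix(counts)
        labels = np.array(["A"] * 30 + ["B"] * 30)
        tab = nb_contrast(m, unit_factors(m), labels, "A", "B").table
        np.testing.assert_allclose(tab["fold_change"], 1.0, atol=1e-9)
        assert (tab["p"] > 0.9).all()
        assert not tab["significant"].any()

    def test_antisymmetry(self, rng):
        m, labels = two_group_matrix(rng, n_genes=100, de_genes=range(5))
        sf = unit_factors(m)
        disp = estimate_dispersion(m, sf, labels)
        ab = nb_contrast(m, sf, labels, "A", "B", disp).table
        ba = nb_contrast(m, sf, labels, "B", "A", disp).table
        np.testing.assert_allclose(ab["fold_change"] * ba["fold_change"], 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-6)

    def test_type_one_error_calibrated(self, rng):
        """Null NB simulation: rejection rate at p < 0.05 within [0.03, 0.07]."""
        m, labels = two_group_matrix(rng, n_genes=1000, n_per=50, alpha=0.1)
        tab = nb_contrast(m, unit_factors(m), labels, "A", "B").table
        rate = (tab["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_markers_recalled(self, rng):
        """8-fold planted genes at n=30/group recalled >= 90% at the standard
        gates (fold >= 2, FDR <= 0.05, detection rule)."""
        de = set(range(0, 300, 10))  # 30 planted genes
        m, labels = two_group_matrix(rng, n_genes=300, n_per=30, alpha=0.1,
                                     de_genes=de, fold=8.0)
        tab = nb_contrast(m, unit_factors(m), labels, "B", "A").table
        called = set(np.flatnonzero(tab["significant"].to_numpy()))
        planted = {int(g) for g in de}
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9

    def test_zero_denominator_uses_continuity(self):
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :10] = 50   # gene 0 only in A
        counts[1, :] = 30     # keeps libraries nonzero
        m = make_matrix(counts)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        tab = nb_contrast(m, unit_factors(m), labels, "A", "B").table
        assert bool(tab["zero_denominator"].iloc[0])
        assert np.isfinite(tab["fold_change"].iloc[0])
        assert tab["fold_change"].iloc[0] > 1

    def test_detection_gate_blocks_sparse_noise(self, rng):
        # a gene present in only 1/30 cells per group fails the 20% rule
        counts = nb_counts(rng, 20.0, 0.1, (50, 60))
        counts[0, :] = 0
        counts[0, 0] = 400
        m = make_matrix(counts)
        labels = np.array(["A"] * 30 + ["B"] * 30)
        tab = nb_contrast(m, unit_factors(m), labels, "A", "B").table
        assert not tab["significant"].iloc[0]

    def test_empty_group_raises(self, rng):
        m, labels = two_group_matrix(rng, n_genes=30)
        with pytest.raises(ValidationError):
            nb_contrast(m, unit_factors(m), labels, "C", "B")


class TestOneVsRest:
    @pytest.fixture()
    def three_group(self, rng):
        mu = np.full(200, 15.0)
        blocks, labels = [], []
        for gi, (name, n, boosted) in enumerate(
            [("n1", 25, range(0, 10)), ("n2", 25, range(0, 10)),
             ("glia", 30, range(20, 30))]
        ):
            mu_g = mu.copy()
            for g in boosted:
                mu_g[g] *= 8
            blocks.append(nb_counts(rng, mu_g[:, None], 0.1, (200, n)))
            labels += [name] * n
        return make_matrix(np.concatenate(blocks, axis=1)), np.array(labels)

    def test_merged_neurons_top_table_has_pan_markers(self, three_group):
        m, labels = three_group
        tabs = one_vs_rest_tables(m, unit_factors(m), labels,
                                  merge_map={"n1": "neuron", "n2": "neuron"})
        assert set(tabs) == {"neuron", "glia"}
        neuron = tabs["neuron"].table
        top = list(neuron.index[neuron["significant"]][:15])
        pan = {f"g{i}" for i in range(10)}
        assert len(pan & set(top)) >= 9
        # tables arrive sorted by FDR
        fdr = tabs["neuron"].table["fdr"].to_numpy()
        assert (np.diff(fdr) >= -1e-12).all()

    def test_identity_merge_equals_plain_one_vs_rest(self, three_group):
        m, labels = three_group
        sf = unit_factors(m)
        tabs = one_vs_rest_tables(m, sf, labels)
        direct = nb_contrast(m, sf, labels, "glia", "rest",
                             thresholds=DEThresholds(direction="up")).table
        got = tabs["glia"].table.loc[direct.index]
        np.testing.assert_allclose(got["p"], direct["p"], rtol=1e-6)
        np.testing.assert_allclose(got["fold_change"], direct["fold_change"],
                                   rtol=1e-9)

    def test_single_group_after_merge_raises(self, three_group):
        m, labels = three_group
        with pytest.raises(ValidationError):
            one_vs_rest_tables(m, unit_factors(m), labels,
                               merge_map={"n1": "x", "n2": "x", "glia": "x"})


def test_bh_fdr_matches_brute_force_oracle(rng):
    def brute(ps):
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        adj = [None] * m
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, ps[i] * m / rank_from_top)
            adj[i] = val
            prev = val
        return np.array(adj)

    p = rng.uniform(size=5000)
    p[:50] = rng.uniform(0, 1e-4, size=50)
    np.testing.assert_allclose(bh_fdr(p), brute(list(p)), rtol=1e-12)


def test_fdr_controls_false_positives_under_global_null(rng):
    """Across >= 20 null replicates the average fraction of significant genes
    stays at or below the nominal 5% FDR."""
    rates = []
    for _ in range(20):
        m, labels = two_group_matrix(rng, n_genes=200, n_per=25, alpha=0.1)
        tab = nb_contrast(m, unit_factors(m), labels, "A", "B").table
        rates.append((tab["fdr"] <= 0.05).mean())
    assert np.mean(rates) <= 0.05
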