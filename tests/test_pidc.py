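"""Information measures, PID decomposition and PUC confidence ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from signet import pidc
from signet.pidc import (discretize, edge_confidence, joint_counts,
                         mi_from_counts, mutual_information, pid_from_joint,
                         pid_unique, puc_matrix, top_edges)


# --- independent plug-in oracles (plain loops, no shared code path) --------

def mi_oracle(table):
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pij = table[i, j] / n
            if pij > 0:
                pi = table[i, :].sum() / n
                pj = table[:, j].sum() / n
                total += pij * math.log2(pij / (pi * pj))
    return total


def wb_redundancy_oracle(p_xzy):
    """Williams-Beer redundancy by explicit outcome loops."""
    p = np.asarray(p_xzy, dtype=float)
    p = p / p.sum()
    nx, nz, ny = p.shape
    red = 0.0
    for y in range(ny):
        py = p[:, :, y].sum()
        if py == 0:
            continue
        spec = []
        for marg, ns in ((p.sum(axis=1), nx), (p.sum(axis=0), nz)):
            acc = 0.0
            for s in range(ns):
                ps = marg[s, :].sum()
                psy = marg[s, y] / py
                if psy > 0:
                    acc += psy * (math.log2(psy) - math.log2(ps))
            spec.append(acc)
        red += py * min(spec)
    return red


class TestDiscretize:
    def test_two_level_values_two_bins(self):
        disc = discretize(np.array([[0.0, 0.0, 5.0, 5.0]]), n_bins=2)
        assert disc.labels.tolist() == [[0, 0, 1, 1]]

    def test_constant_vector_flagged(self):
        disc = discretize(np.array([[3.0] * 10, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]]),
                          n_bins=3)
        assert disc.labels[0].tolist() == [0] * 10
        assert disc.zero_information.tolist() == [True, False]

    def test_uniform_values_equal_bins(self):
        disc = discretize(np.arange(1, 101, dtype=float)[None, :], n_bins=4)
        assert np.bincount(disc.labels[0]).tolist() == [25, 25, 25, 25]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((1, 4)), n_bins=1)

    def test_bayesian_blocks_separates_clusters(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(9, 10, 30)])
        disc = discretize(vals[None, :], method="bayesian_blocks")
        assert disc.n_bins[0] >= 2
        lo = np.bincount(disc.labels[0][:30]).argmax()
        hi = np.bincount(disc.labels[0][30:]).argmax()
        assert lo != hi

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 50))
        d1, d2 = discretize(x), discretize(x)
        assert np.array_equal(d1.labels, d2.labels)


class TestMutualInformation:
    def test_identical_balanced_binary(self):
        x = np.array([0, 1] * 25)
        assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_table_zero(self):
        assert mi_from_counts(np.array([[25, 25], [25, 25]])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_table(self):
        assert mi_from_counts(np.array([[4, 1], [1, 4]])) == \
            pytest.approx(mi_oracle([[4, 1], [1, 4]]), abs=1e-12)
        assert mi_from_counts(np.array([[4, 1], [1, 4]])) == \
            pytest.approx(0.278071905, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 0])

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 6, size=(3, 4))
            if t.sum() == 0:
                continue
            assert mi_from_counts(t) == pytest.approx(mi_oracle(t), abs=1e-12)


class TestPID:
    def test_fully_redundant_sources(self):
        x = np.array([0, 1] * 25)
        u, red = pid_unique(x, x, x)
        assert red == pytest.approx(1.0, abs=1e-12)
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_independent_informative_source(self):
        # exact 8-outcome joint table: X = Y, Z independent fair coin
        p = np.zeros((2, 2, 2))
        for x in (0, 1):
            for z in (0, 1):
                p[x, z, x] = 0.25
        parts = pid_from_joint(p)
        assert parts["redundancy"] == pytest.approx(0.0, abs=1e-12)
        assert parts["unique_x"] == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_source_has_zero_unique(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 60)
        y = rng.permutation(x)  # same marginal, independent of x
        z = rng.integers(0, 3, 60)
        u, red = pid_unique(x, z, y)
        i_xy = mutual_information(x, y)
        assert u <= i_xy + 1e-12

    def test_identity_and_bounds_on_random_binary_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = rng.integers(4, 61)
            x = rng.integers(0, 2, n)
            z = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            tab = joint_counts(x, z, y).astype(float)
            parts = pid_from_joint(tab)
            red = parts["redundancy"]
            assert red == pytest.approx(wb_redundancy_oracle(tab), abs=1e-12)
            assert -1e-12 <= red <= min(parts["mi_xy"], parts["mi_zy"]) + 1e-12
            # unique + redundancy reconstructs the pairwise MI exactly
            assert parts["unique_x"] + red == pytest.approx(
                parts["mi_xy"], abs=1e-12)
            assert parts["unique_z"] + red == pytest.approx(
                parts["mi_zy"], abs=1e-12)


class TestPUC:
    def _disc(self, mat):
        return discretize(np.asarray(mat, dtype=float), n_bins=2)

    def test_independent_genes_zero_matrix(self):
        rng = np.random.default_rng(2)
        # three mutually independent coins, all 8 combinations equally often
        rows = np.array(list(itertools.product([0, 1], repeat=3))).T
        mat = np.tile(rows, 8)
        puc = puc_matrix(self._disc(mat))
        assert np.allclose(puc.u.to_numpy(), 0.0, atol=1e-12)

    def test_duplicated_pair_has_largest_puc(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 200)
        others = rng.integers(0, 2, (2, 200))
        mat = np.vstack([x, x, others])
        puc = puc_matrix(self._disc(mat))
        u = puc.u.to_numpy()
        assert u[0, 1] == u.max()
        assert u[0, 1] > u[0, 2] and u[0, 1] > u[2, 3]

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        mat = rng.integers(0, 3, (5, 100)).astype(float)
        disc = discretize(mat, n_bins=3)
        puc = puc_matrix(disc).u.to_numpy()
        perm = [3, 1, 4, 0, 2]
        disc_p = discretize(mat[perm], n_bins=3)
        puc_p = puc_matrix(disc_p).u.to_numpy()
        assert np.allclose(puc_p, puc[np.ix_(perm, perm)], atol=1e-12)

    def test_constant_gene_excluded(self):
        mat = np.vstack([np.zeros(50),
                         np.random.default_rng(0).integers(0, 2, (3, 50))])
        puc = puc_matrix(discretize(mat, n_bins=2))
        assert puc.excluded_genes == ["g0"]
        assert len(puc.genes) == 3

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            puc_matrix(self._disc(np.random.default_rng(0)
                                  .integers(0, 2, (2, 30))))


class TestConfidenceAndSelection:
    def test_all_equal_puc_gives_confidence_two(self):
        idx = pd.Index(list("abcd"), name="gene")
        u = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=idx, columns=idx)
        conf = edge_confidence(pidc.PUCMatrix(u=u, mi=u))
        off = conf.confidence.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_duplicated_pair_tops_confidence(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 200)
        mat = np.vstack([x, x, rng.integers(0, 2, (2, 200))]).astype(float)
        conf = edge_confidence(puc_matrix(discretize(mat, n_bins=2)))
        top = top_edges(conf, fraction=0.2)  # ceil(0.2 * 6) = 2 edges
        assert {top.iloc[0]["gene_a"], top.iloc[0]["gene_b"]} == {"g0", "g1"}

    def test_top_edge_count_rounds_up(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(10, 60))
        conf = edge_confidence(puc_matrix(discretize(mat, n_bins=3)))
        assert len(top_edges(conf, fraction=0.10)) == 5  # ceil(4.5)
        assert len(top_edges(conf, fraction=1.0)) == 45

    def test_bad_fraction_rejected(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(4, 30))
        conf = edge_confidence(puc_matrix(discretize(mat, n_bins=2)))
        with pytest.raises(ValueError):
            top_edges(conf, fraction=0.0)
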