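"""QC filters, balancing, pseudo-bulk and the built-in NB Wald test."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from conftest import toy_table
from statsmodels.stats.multitest import multipletests

from signet import dge, simulate
from signet.dge import (PseudobulkCounts, QCThresholds, balance_cells,
                        differential_test, filter_cells, filter_genes,
                        pseudobulk, remove_batch_genes)


def _adata_from_counts(counts, genes=None, **obs_cols):
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    obs = pd.DataFrame(
        {k: (v if not np.isscalar(v) else [v] * n)
         for k, v in obs_cols.items()},
        index=[f"c{i}" for i in range(n)])
    adata = ad.AnnData(X=counts, obs=obs)
    adata.var_names = genes or [f"g{i}" for i in range(counts.shape[1])]
    return adata


class TestFilterCells:
    def _qc_adata(self, numi, ngene_target=None, mito_frac=0.0, ribo_frac=0.0):
        """One cell with controlled QC metrics over a 4-gene panel."""
        mito = int(round(numi * mito_frac / 100))
        ribo = int(round(numi * ribo_frac / 100))
        rest = numi - mito - ribo
        counts = [[rest - 1, 1, mito, ribo]]
        return _adata_from_counts(
            counts, genes=["Plain1", "Plain2", "mt-Nd1", "Rps1"],
            sample_id="s1")

    def test_boundary_numi_retained(self):
        # exactly at the threshold -> kept (strict <)
        adata = self._qc_adata(2500)
        kept, log = filter_cells(adata, QCThresholds(min_ngene=0,
                                                     min_log10_genes_per_umi=0))
        assert kept.shape[0] == 1
        kept, _ = filter_cells(self._qc_adata(2499),
                               QCThresholds(min_ngene=0,
                                            min_log10_genes_per_umi=0))
        assert kept.shape[0] == 0

    def test_high_mito_removed(self):
        adata = self._qc_adata(4000, mito_frac=5.0)
        kept, log = filter_cells(adata, QCThresholds(min_ngene=0,
                                                     min_log10_genes_per_umi=0))
        assert kept.shape[0] == 0
        assert log["pct_mito"] == 1

    def test_all_zero_input_no_crash(self):
        adata = _adata_from_counts(np.zeros((3, 4)), sample_id="s1")
        with pytest.warns(UserWarning):
            kept, log = filter_cells(adata)
        assert kept.shape[0] == 0


class TestBalanceCells:
    def _adata(self, group_sizes):
        rows, batches = [], []
        for (batch, cond), size in group_sizes.items():
            for _ in range(size):
                batches.append((batch, cond))
        n = len(batches)
        return _adata_from_counts(
            np.ones((n, 2)),
            batch=[b for b, _ in batches],
            condition=[c for _, c in batches],
            sample_id="s1")

    def test_thirty_sixty_becomes_thirty_fortyfive(self):
        adata = self._adata({("b1", "x"): 30, ("b1", "y"): 60})
        out = balance_cells(adata, group_keys=("batch", "condition"), seed=0)
        sizes = out.obs.groupby(["batch", "condition"], observed=True).size()
        assert sorted(sizes) == [30, 45]

    def test_equal_groups_unchanged(self):
        adata = self._adata({("b1", "x"): 40, ("b1", "y"): 40})
        out = balance_cells(adata, seed=0)
        assert out.shape[0] == 80

    def test_three_groups_capped_at_fifteen(self):
        adata = self._adata({("b1", "x"): 10, ("b1", "y"): 14,
                             ("b1", "z"): 16})
        out = balance_cells(adata, seed=0)
        sizes = out.obs.groupby(["batch", "condition"], observed=True).size()
        assert sorted(sizes) == [10, 14, 15]

    def test_missing_group_combination_errors(self):
        adata = self._adata({("b1", "x"): 5, ("b2", "y"): 5})
        with pytest.raises(ValueError, match="zero cells"):
            balance_cells(adata)

    def test_never_inflates_and_is_deterministic(self):
        adata = self._adata({("b1", "x"): 7, ("b1", "y"): 30})
        out1 = balance_cells(adata, seed=3)
        out2 = balance_cells(adata, seed=3)
        assert list(out1.obs_names) == list(out2.obs_names)
        sizes = out1.obs.groupby(["batch", "condition"], observed=True).size()
        assert sizes.max() <= int(7 * 1.5)


class TestPseudobulk:
    def test_sums_per_sample(self):
        adata = _adata_from_counts([[1, 2], [3, 4]], sample_id=["s1", "s1"])
        pb = pseudobulk(adata)
        assert pb.counts.loc["s1"].tolist() == [4, 6]
        assert pb.sample_meta.loc["s1", "n_cells_used"] == 2

    def test_one_cell_per_sample_identity(self):
        adata = _adata_from_counts([[5, 7], [2, 9]], sample_id=["s1", "s2"])
        pb = pseudobulk(adata)
        assert pb.counts.loc["s1"].tolist() == [5, 7]
        assert pb.counts.loc["s2"].tolist() == [2, 9]

    def test_conserves_totals(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, size=(20, 5))
        adata = _adata_from_counts(
            counts, sample_id=[f"s{i % 4}" for i in range(20)])
        pb = pseudobulk(adata)
        assert pb.counts.to_numpy().sum(axis=0).tolist() == \
            counts.sum(axis=0).tolist()


class TestFilterGenes:
    def _pb(self, columns):
        counts = pd.DataFrame(columns)
        meta = pd.DataFrame(index=counts.index)
        return PseudobulkCounts(counts=counts, sample_meta=meta)

    def test_boundary_three_in_three_kept(self):
        pb = self._pb({"keepme": [3, 3, 3, 0, 0], "dropme": [3, 3, 2, 0, 0]})
        out = filter_genes(pb)
        assert list(out.counts.columns) == ["keepme"]

    def test_mitochondrial_symbol_excluded(self):
        pb = self._pb({"mt-Nd1": [100] * 5, "Actb": [100] * 5,
                       "Rpl3": [50] * 5, "Mrps6": [50] * 5})
        out = filter_genes(pb)
        assert list(out.counts.columns) == ["Actb"]


class TestDifferentialTest:
    def test_holm_by_hand(self):
        padj = multipletests([0.01, 0.04], method="holm")[1]
        assert np.allclose(padj, [0.02, 0.04])

    def test_null_type_one_error_controlled(self):
        samples = simulate.cohort_design(["synON24M", "synOFF24M"], 6)
        cfg = simulate.SimulationConfig(
            n_genes=200, n_cells_per_sample=100, samples=samples, seed=21)
        adata, _ = simulate.simulate_counts(cfg)
        tab = differential_test(pseudobulk(adata), "synON24M_vs_synOFF24M",
                                covariates=("sex", "batch"))
        frac = (tab.data["pvalue"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 200)
        assert frac <= 0.05 + 3 * se

    def test_planted_effect_recovered(self):
        samples = simulate.cohort_design(["synON24M", "synOFF24M"], 6)
        cfg = simulate.SimulationConfig(
            n_genes=60, n_cells_per_sample=500, samples=samples,
            planted_de={"synON24M_vs_synOFF24M": [(g, 2.0) for g in range(10)]},
            seed=22)
        adata, _ = simulate.simulate_counts(cfg)
        tab = differential_test(pseudobulk(adata), "synON24M_vs_synOFF24M",
                                covariates=("sex", "batch"))
        planted = tab.data.iloc[:10]
        assert ((planted["significant"]) & (planted["log2fc"] > 0)).mean() >= 0.9
        # non-planted genes stay quiet after Holm
        assert tab.data.iloc[10:]["significant"].sum() <= 1

    def test_gene_permutation_equivariance(self):
        samples = simulate.cohort_design(["synON24M", "synOFF24M"], 3)
        cfg = simulate.SimulationConfig(
            n_genes=20, n_cells_per_sample=100, samples=samples, seed=23)
        adata, _ = simulate.simulate_counts(cfg)
        pb = pseudobulk(adata)
        perm = np.random.default_rng(5).permutation(20)
        pb_perm = PseudobulkCounts(counts=pb.counts.iloc[:, perm],
                                   sample_meta=pb.sample_meta)
        t1 = differential_test(pb, "synON24M_vs_synOFF24M")
        t2 = differential_test(pb_perm, "synON24M_vs_synOFF24M")
        joined = t1.data.join(t2.data, rsuffix="_p")
        assert np.allclose(joined["pvalue"], joined["pvalue_p"])
        assert np.allclose(joined["log2fc"], joined["log2fc_p"])

    def test_missing_arm_errors(self):
        samples = simulate.cohort_design(["synON24M", "synOFF24M"], 3)
        cfg = simulate.SimulationConfig(
            n_genes=5, n_cells_per_sample=50, samples=samples, seed=1)
        adata, _ = simulate.simulate_counts(cfg)
        with pytest.raises(ValueError, match="arm"):
            differential_test(pseudobulk(adata), "synON6M_vs_synOFF6M")


class TestRemoveBatchGenes:
    def _tables(self):
        t = toy_table("synON24M_vs_synOFF24M",
                      {"A": (True, 1), "B": (True, -1)}, universe=["C"])
        return {"synON24M_vs_synOFF24M": t}

    def test_empty_batch_table_is_noop(self):
        tables = self._tables()
        batch = toy_table("synON24M_vs_synOFF24M", {}, universe=["A", "B"])
        out, removed = remove_batch_genes(tables, batch)
        assert out["synON24M_vs_synOFF24M"].genes() == {"A", "B", "C"}
        assert removed["synON24M_vs_synOFF24M"] == []

    def test_batch_gene_removed_from_confounded_contrast(self):
        tables = self._tables()
        batch = toy_table("synON24M_vs_synOFF24M", {"A": (True, 1)})
        out, removed = remove_batch_genes(tables, batch)
        assert "A" not in out["synON24M_vs_synOFF24M"].genes()
        assert removed["synON24M_vs_synOFF24M"] == ["A"]

    def test_non_confounded_contrast_untouched(self):
        tables = self._tables()
        batch = toy_table("synON24M_vs_synOFF24M", {"A": (True, 1)})
        out, removed = remove_batch_genes(tables, batch, confounded=set())
        assert "A" in out["synON24M_vs_synOFF24M"].genes()
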