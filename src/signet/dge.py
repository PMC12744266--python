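"""Cell/gene filtering, cell-number balancing, pseudo-bulk and the
built-in differential test.

The differential stage follows the pseudo-bulk design: cells are summed
per biological sample, samples are the units of replication, and a
negative-binomial GLM with median-of-ratios size factors is fitted per
gene with a Wald test on the condition coefficient.  Raw p-values are
Holm-adjusted; significance is called at an adjusted p below 0.05.  The
test is pluggable — any externally produced table in the
``ComparisonTable`` TSV layout can be slotted into the downstream set
logic instead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._contrasts import parse_contrast
from .tables import ComparisonTable, make_table

DEFAULT_EXCLUSION_PREFIXES = ("mt-", "Rps", "Rpl", "Mrps", "Mrpl")


# ---------------------------------------------------------------------------
# QC

@dataclass
class QCThresholds:
    """Cell-removal criteria; a cell failing any one is dropped.

    Boundaries are read strictly (a cell at exactly the threshold is
    kept), and every threshold is configurable.
    """

    min_numi: float = 2500
    min_ngene: float = 1500
    max_pct_mito: float = 3.0
    max_pct_ribo: float = 1.5
    min_log10_genes_per_umi: float = 0.85


def compute_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell nUMI, nGene, mito%, ribo% and log10(nGene)/log10(nUMI)."""
    x = np.asarray(adata.X if not hasattr(adata.X, "toarray")
                   else adata.X.toarray())
    numi = x.sum(axis=1)
    ngene = (x > 0).sum(axis=1)
    names = adata.var_names.str.lower()
    mito = names.str.startswith("mt-")
    ribo = names.str.startswith(("rps", "rpl"))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(numi > 0, 100 * x[:, mito].sum(axis=1) / numi, 0.0)
        pct_ribo = np.where(numi > 0, 100 * x[:, ribo].sum(axis=1) / numi, 0.0)
        log_ratio = np.where(
            (numi > 1) & (ngene > 0),
            np.log10(np.maximum(ngene, 1)) / np.log10(np.maximum(numi, 2)),
            0.0,
        )
    return pd.DataFrame(
        {
            "numi": numi,
            "ngene": ngene,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "log10_genes_per_umi": log_ratio,
        },
        index=adata.obs_names,
    )


def filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
) -> tuple[ad.AnnData, dict[str, int]]:
    """Drop cells failing any QC criterion; returns (kept, removal log)."""
    thresholds = thresholds or QCThresholds()
    qc = compute_qc_metrics(adata)
    fails = {
        "numi": qc["numi"] < thresholds.min_numi,
        "ngene": qc["ngene"] < thresholds.min_ngene,
        "pct_mito": qc["pct_mito"] > thresholds.max_pct_mito,
        "pct_ribo": qc["pct_ribo"] > thresholds.max_pct_ribo,
        "log10_genes_per_umi":
            qc["log10_genes_per_umi"] < thresholds.min_log10_genes_per_umi,
    }
    log = {name: int(f.sum()) for name, f in fails.items()}
    keep = ~np.logical_or.reduce([f.to_numpy() for f in fails.values()])
    log["kept"] = int(keep.sum())
    if keep.sum() == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    return adata[keep].copy(), log


# ---------------------------------------------------------------------------
# balancing & pseudo-bulk

def balance_cells(
    adata: ad.AnnData,
    group_keys: tuple[str, ...] = ("batch", "condition"),
    max_fold: float = 1.5,
    seed: int = 0,
) -> ad.AnnData:
    """Cap group sizes at ``floor(min_group * max_fold)`` by uniform
    subsampling without replacement.  Groups are never inflated."""
    obs = adata.obs
    combos = list(itertools.product(
        *[sorted(obs[k].unique()) for k in group_keys]))
    sizes = obs.groupby(list(group_keys), observed=True).size()
    for combo in combos:
        key = combo if len(combo) > 1 else combo[0]
        if key not in sizes.index or sizes[key] == 0:
            raise ValueError(
                f"group {dict(zip(group_keys, combo))} has zero cells")
    cap = int(np.floor(sizes.min() * max_fold))
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for _, members in obs.groupby(list(group_keys), observed=True).groups.items():
        idx = np.asarray([obs.index.get_loc(m) for m in members])
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    return adata[keep].copy()


@dataclass
class PseudobulkCounts:
    """Sample x gene integer sums with sample-level metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            raise ValueError("counts and sample_meta must share an index")

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns


def pseudobulk(adata: ad.AnnData) -> PseudobulkCounts:
    """Sum counts per sample; carry sample-level metadata over."""
    x = np.asarray(adata.X if not hasattr(adata.X, "toarray")
                   else adata.X.toarray())
    df = pd.DataFrame(x, index=adata.obs["sample_id"].to_numpy(),
                      columns=adata.var_names)
    counts = df.groupby(level=0).sum()
    meta_cols = [c for c in ("condition", "age", "batch", "sex", "group")
                 if c in adata.obs.columns]
    meta = (adata.obs[["sample_id", *meta_cols]]
            .drop_duplicates("sample_id").set_index("sample_id"))
    meta["n_cells_used"] = adata.obs.groupby("sample_id", observed=True).size()
    meta = meta.loc[counts.index]
    meta.index.name = None
    counts.index.name = None
    return PseudobulkCounts(counts=counts.astype(np.int64), sample_meta=meta)


def filter_genes(
    pb: PseudobulkCounts,
    min_samples: int = 3,
    min_level: int = 3,
    exclusion_prefixes: tuple[str, ...] = DEFAULT_EXCLUSION_PREFIXES,
) -> PseudobulkCounts:
    """Keep genes expressed at >= min_level in >= min_samples samples and
    not matching any excluded symbol prefix (ribosomal/mitochondrial)."""
    expressed = (pb.counts >= min_level).sum(axis=0) >= min_samples
    lowered = tuple(p.lower() for p in exclusion_prefixes)
    excluded = pb.counts.columns.str.lower().str.startswith(lowered)
    keep = expressed.to_numpy() & ~excluded
    return PseudobulkCounts(counts=pb.counts.loc[:, keep],
                            sample_meta=pb.sample_meta)


# ---------------------------------------------------------------------------
# differential testing

def median_of_ratios(counts: pd.DataFrame) -> np.ndarray:
    """DESeq-style size factors; falls back to library-size ratios when
    no gene is expressed in every sample."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=0)
    if positive.sum() >= 1:
        logs = np.log(mat[:, positive])
        log_geomean = logs.mean(axis=0)
        sf = np.exp(np.median(logs - log_geomean, axis=1))
    else:
        totals = mat.sum(axis=1)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def _moment_dispersion(q: np.ndarray, groups: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion (alpha in var = mu + alpha mu^2)
    from within-group means/variances of normalized counts."""
    num = den = 0.0
    for g in np.unique(groups):
        vals = q[groups == g]
        if len(vals) < 2:
            continue
        m, v = vals.mean(), vals.var(ddof=1)
        if m > 0:
            num += (v - m) * (len(vals) - 1)
            den += m * m * (len(vals) - 1)
    if den == 0:
        return 1e-8
    return float(np.clip(num / den, 1e-8, 100.0))


def differential_test(
    pb: PseudobulkCounts,
    contrast: str,
    covariates: tuple[str, ...] = (),
    alpha: float = 0.05,
    method: str = "nbglm",
    group_col: str = "group",
) -> ComparisonTable:
    """Per-gene NB-GLM Wald test on the condition coefficient.

    ``contrast`` is ``test_vs_reference`` over the ``group_col`` values
    (or over ``condition`` when ``group_col="condition"``).  Covariates
    are sample-level columns entered as dummy-coded terms.  P-values use
    a t reference with residual degrees of freedom; multiplicity is
    controlled by Bonferroni-Holm.

    ``method="deseq2"`` delegates to pydeseq2 when installed; the
    default ``"nbglm"`` is self-contained.
    """
    test, ref = parse_contrast(contrast)
    meta = pb.sample_meta
    if group_col not in meta.columns:
        raise ValueError(f"sample metadata lacks column {group_col!r}")
    in_test = meta[group_col] == test
    in_ref = meta[group_col] == ref
    for name, mask in (("test", in_test), ("reference", in_ref)):
        if mask.sum() == 0:
            raise ValueError(f"{name} arm {test if name == 'test' else ref!r} "
                             "has no samples")
        if mask.sum() < 2:
            raise ValueError(f"{name} arm needs >= 2 samples")
    sel = in_test | in_ref
    counts = pb.counts.loc[sel]
    meta = meta.loc[sel]

    nonzero = counts.sum(axis=0) > 0
    log = {"all_zero_excluded": sorted(counts.columns[~nonzero]),
           "glm_fallback": []}
    counts = counts.loc[:, nonzero]

    if method == "deseq2":
        return _deseq2_test(counts, meta, test, ref, group_col, covariates,
                            alpha, contrast, log)
    if method != "nbglm":
        raise ValueError(f"unknown method {method!r}")

    sf = median_of_ratios(counts)
    cond = (meta[group_col] == test).astype(float).to_numpy()
    design = pd.DataFrame({"intercept": 1.0, "cond": cond}, index=meta.index)
    for cov in covariates:
        dummies = pd.get_dummies(meta[cov], prefix=cov, drop_first=True)
        design = pd.concat([design, dummies.astype(float)], axis=1)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    df_resid = max(X.shape[0] - rank, 1)
    offset = np.log(sf)
    groups = pd.factorize(design.apply(tuple, axis=1))[0]

    lfc = np.empty(counts.shape[1])
    pvals = np.empty(counts.shape[1])
    for k, gene in enumerate(counts.columns):
        y = counts[gene].to_numpy(dtype=float)
        q = y / sf
        disp = _moment_dispersion(q, groups)
        try:
            fam = (sm.families.NegativeBinomial(alpha=disp)
                   if disp > 1e-6 else sm.families.Poisson())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
            beta = res.params[1]
            se = res.bse[1]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                raise ValueError("non-finite Wald statistic")
            lfc[k] = beta / np.log(2)
            pvals[k] = 2 * stats.t.sf(abs(beta / se), df_resid)
        except Exception:
            log["glm_fallback"].append(gene)
            m_t = q[cond == 1].mean()
            m_r = q[cond == 0].mean()
            lfc[k] = np.log2((m_t + 0.5) / (m_r + 0.5))
            lq = np.log2(q + 0.5)
            pvals[k] = stats.ttest_ind(
                lq[cond == 1], lq[cond == 0], equal_var=False).pvalue
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = multipletests(pvals, method="holm")[1]
    return make_table(contrast, counts.columns, lfc, pvals, padj,
                      alpha=alpha, log=log)


def _deseq2_test(counts, meta, test, ref, group_col, covariates, alpha,
                 contrast, log):
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = meta.copy()
    meta["_cond"] = np.where(meta[group_col] == test, "test", "ref")
    factors = ["_cond", *covariates]
    dds = DeseqDataSet(counts=counts, metadata=meta,
                       design="~" + " + ".join(factors), quiet=True)
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["_cond", "test", "ref"], quiet=True)
    ds.summary()
    res = ds.results_df
    pvals = res["pvalue"].fillna(1.0).to_numpy()
    padj = multipletests(pvals, method="holm")[1]
    return make_table(contrast, res.index, res["log2FoldChange"].fillna(0.0),
                      pvals, padj, alpha=alpha, log=log)


def remove_batch_genes(
    tables: dict[str, ComparisonTable],
    batch_table: ComparisonTable,
    confounded: set[str] | None = None,
) -> tuple[dict[str, ComparisonTable], dict[str, list[str]]]:
    """Delete batch-significant genes from confounded contrasts.

    ``confounded`` names the contrasts with confounding designs; when
    None, every supplied table is cleaned.  Returns the cleaned tables
    and a per-contrast removal log.
    """
    batch_genes = batch_table.significant_genes()
    removed: dict[str, list[str]] = {}
    out: dict[str, ComparisonTable] = {}
    for label, tab in tables.items():
        if confounded is not None and tab.contrast not in confounded:
            out[label] = tab
            continue
        drop = sorted(batch_genes & tab.genes())
        removed[label] = drop
        out[label] = ComparisonTable(
            contrast=tab.contrast,
            data=tab.data.drop(index=drop),
            alpha=tab.alpha,
            log={**tab.log, "batch_genes_removed": drop},
        )
    return out, removed
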