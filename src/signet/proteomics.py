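"""Proteomics filtering, MAR/MNAR classification, imputation and
covariate-adjusted differential testing.

Intensities are on the log2 scale with explicit missing markers.
Filtering keeps proteins detected in at least two samples of both
batches and in at least 75% of replicates of some condition.  For a
two-condition comparison a protein's missingness is MNAR when one arm
is well detected (>= 75%) while the other is mostly missing (>= 75%),
MAR for any other pattern with missing values, and complete otherwise.
MAR cells are filled by k-nearest-neighbour averaging over proteins;
MNAR cells by low-intensity draws (MinProb-style: a Gaussian centred at
a low per-sample quantile of the observed intensities).  Differential
testing is an ordinary per-protein linear model with sex and batch
covariates, Holm-adjusted at 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .tables import ComparisonTable, make_table


@dataclass
class ProteinMatrix:
    """Proteins x samples log2 intensities with sample metadata."""

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.sample_meta.index):
            raise ValueError(
                "intensity columns and sample metadata index must match")
        for col in ("condition", "batch"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks {col!r}")

    def detected(self) -> pd.DataFrame:
        return self.intensities.notna()

    def drop_samples(self, sample_ids) -> "ProteinMatrix":
        """Explicit sample-exclusion hook (e.g. aberrant replicates)."""
        keep = [s for s in self.intensities.columns if s not in set(sample_ids)]
        return ProteinMatrix(self.intensities[keep],
                             self.sample_meta.loc[keep])


@dataclass
class MissingnessLabels:
    """Per-protein missingness class for one condition comparison."""

    comparison: tuple[str, str]
    labels: pd.Series  # protein -> MAR | MNAR | complete


def filter_proteins(m: ProteinMatrix) -> tuple[ProteinMatrix, dict[str, int]]:
    """Batch-detection and condition-completeness filters.

    Keeps proteins detected in >= 2 samples of every batch and in
    >= 75% of replicates of at least one condition (both thresholds
    inclusive).  Returns the filtered matrix and per-rule removal
    counts.
    """
    det = m.detected()
    batches = m.sample_meta["batch"].unique()
    conditions = m.sample_meta["condition"].unique()
    if len(batches) < 2 or len(conditions) < 2:
        raise ValueError("need at least two batches and two conditions")

    per_batch = pd.concat(
        {b: det.loc[:, m.sample_meta["batch"] == b].sum(axis=1)
         for b in batches}, axis=1)
    rule1 = (per_batch >= 2).all(axis=1)

    frac_by_cond = pd.concat(
        {c: det.loc[:, m.sample_meta["condition"] == c].mean(axis=1)
         for c in conditions}, axis=1)
    rule2 = (frac_by_cond >= 0.75).any(axis=1)

    keep = rule1 & rule2
    log = {
        "removed_batch_rule": int((~rule1).sum()),
        "removed_condition_rule": int((rule1 & ~rule2).sum()),
        "kept": int(keep.sum()),
    }
    return ProteinMatrix(m.intensities.loc[keep], m.sample_meta), log


def classify_missingness(
    m: ProteinMatrix,
    comparison: tuple[str, str],
) -> MissingnessLabels:
    """Label each protein MAR / MNAR / complete for one comparison.

    MNAR: detection >= 75% in one arm while the other arm has >= 75%
    missing values (both inclusive).  Any other pattern with missing
    values is MAR; fully observed proteins are complete.
    """
    cond_a, cond_b = comparison
    meta = m.sample_meta
    for c in comparison:
        if (meta["condition"] == c).sum() == 0:
            raise ValueError(f"condition {c!r} absent from sample metadata")
    det = m.detected()
    det_a = det.loc[:, meta["condition"] == cond_a].mean(axis=1)
    det_b = det.loc[:, meta["condition"] == cond_b].mean(axis=1)
    cols = meta.index[meta["condition"].isin(comparison)]
    any_missing = ~det[cols].all(axis=1)

    mnar = (((det_a >= 0.75) & (1 - det_b >= 0.75))
            | ((det_b >= 0.75) & (1 - det_a >= 0.75)))
    labels = pd.Series("complete", index=m.intensities.index, name="label")
    labels[any_missing] = "MAR"
    labels[any_missing & mnar] = "MNAR"
    return MissingnessLabels(comparison=comparison, labels=labels)


def impute(
    m: ProteinMatrix,
    labels: MissingnessLabels,
    knn_k: int = 10,
    minprob_quantile: float = 0.01,
    minprob_sd_scale: float = 1.0,
    seed: int = 0,
) -> ProteinMatrix:
    """Fill MAR cells by kNN over proteins, MNAR cells by MinProb draws.

    kNN: each protein's missing entries are averaged over its
    ``knn_k`` nearest proteins by Euclidean distance on the shared
    observed samples.  MinProb: MNAR cells are drawn from a Gaussian
    centred at the per-sample ``minprob_quantile`` of observed
    intensities, with standard deviation ``minprob_sd_scale`` times the
    median per-protein SD.  Observed cells are never altered;
    deterministic under ``seed``.
    """
    intens = m.intensities
    if intens.notna().sum(axis=1).eq(0).any():
        empty = intens.index[intens.notna().sum(axis=1) == 0]
        raise ValueError(
            f"proteins with no observed values (should have been filtered): "
            f"{list(empty[:5])}")
    out = intens.copy()
    observed_mask = intens.notna()
    is_mnar = labels.labels == "MNAR"

    # --- MAR: kNN over proteins (rows are the imputer's samples)
    mar_rows = intens.index[(~is_mnar) & (~observed_mask.all(axis=1))]
    if len(mar_rows):
        imputer = KNNImputer(n_neighbors=min(knn_k, max(len(intens) - 1, 1)))
        filled = pd.DataFrame(imputer.fit_transform(intens.to_numpy()),
                              index=intens.index, columns=intens.columns)
        for prot in mar_rows:
            miss = ~observed_mask.loc[prot]
            out.loc[prot, miss] = filled.loc[prot, miss]

    # --- MNAR: low-intensity Gaussian draws per sample
    mnar_rows = intens.index[is_mnar & (~observed_mask.all(axis=1))]
    if len(mnar_rows):
        rng = np.random.default_rng(seed)
        per_protein_sd = intens.std(axis=1, ddof=1)
        sd = minprob_sd_scale * float(np.nanmedian(per_protein_sd))
        centers = intens.quantile(minprob_quantile, axis=0)
        for col in intens.columns:
            miss = intens.index.isin(mnar_rows) & intens[col].isna().to_numpy()
            if miss.any():
                out.loc[miss, col] = rng.normal(
                    centers[col], sd, size=int(miss.sum()))
    assert not out.isna().any().any()
    return ProteinMatrix(out, m.sample_meta)


def differential_proteins(
    m: ProteinMatrix,
    comparison: tuple[str, str],
    covariates: tuple[str, ...] = ("sex", "batch"),
    alpha: float = 0.1,
) -> ComparisonTable:
    """Per-protein linear model with a t-test on the condition term.

    ``comparison`` is (test, reference); intensities are assumed
    imputed (log2 scale), so the condition coefficient is directly a
    log2 fold change.  Holm-adjusted significance at padj < 0.1 by
    default.
    """
    test, ref = comparison
    meta = m.sample_meta
    sel = meta["condition"].isin(comparison)
    if meta.loc[sel, "condition"].nunique() < 2:
        raise ValueError(f"both arms of {comparison} must have samples")
    y_all = m.intensities.loc[:, sel.to_numpy()]
    sub = meta.loc[sel.to_numpy()]
    if y_all.isna().any().any():
        raise ValueError("matrix must be imputed before differential testing")

    design = pd.DataFrame(
        {"intercept": 1.0,
         "cond": (sub["condition"] == test).astype(float)},
        index=sub.index)
    for cov in covariates:
        dummies = pd.get_dummies(sub[cov], prefix=cov, drop_first=True)
        design = pd.concat([design, dummies.astype(float)], axis=1)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [c for i, c in enumerate(design.columns)
                     if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: "
                         f"{collinear}")
    df_resid = X.shape[0] - X.shape[1]
    if df_resid < 1:
        raise ValueError("not enough samples for the design")

    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T
    cond_ix = list(design.columns).index("cond")
    Y = y_all.to_numpy(dtype=float).T          # samples x proteins
    beta = hat @ Y
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df_resid
    se = np.sqrt(sigma2 * xtx_inv[cond_ix, cond_ix])
    tstat = np.divide(beta[cond_ix], se, out=np.zeros_like(se),
                      where=se > 0)
    pvals = 2 * stats.t.sf(np.abs(tstat), df_resid)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = multipletests(pvals, method="holm")[1]
    return make_table(f"{test}_vs_{ref}", y_all.index, beta[cond_ix],
                      pvals, padj, alpha=alpha)
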