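"""Scoring a gene signature in an independent expression dataset.

The module score is the classic binned-control statistic: per cell,
the mean normalized expression of the signature genes minus the mean of
a pool of control genes drawn from the same average-expression bins
(so the score is centred near zero for an arbitrary gene set).  Group
differences are tested on sample-wise pseudo-bulked scores with an
exact two-sided Wilcoxon rank-sum test.  For cross-dataset comparison
of effect sizes, per-dataset log2 fold changes are rescaled to a common
[-4, 4] range and genes with an identical nonzero sign everywhere are
flagged concordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ComparisonTable


@dataclass
class ModuleScoreResult:
    """Per-cell module scores with the control pool that produced them."""

    cell_scores: pd.Series
    signature_genes: list[str]
    control_genes: list[str]
    missing_genes: list[str] = field(default_factory=list)


def module_score(
    expr: pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes=None,
) -> ModuleScoreResult:
    """Binned-control module score per cell.

    ``expr`` is a normalized genes x cells matrix.  Genes are ranked by
    average expression into ``n_bins`` equal-count bins; each signature
    gene contributes ``n_ctrl`` control genes sampled from its bin
    (signature genes excluded; with replacement when the bin is small).
    ``control_genes`` overrides the sampled pool (useful for nulls).
    Deterministic under ``seed``.
    """
    genes_present = [g for g in gene_set if g in expr.index]
    missing = [g for g in gene_set if g not in expr.index]
    if not genes_present:
        raise ValueError("no signature gene found in the expression matrix")

    if control_genes is None:
        rng = np.random.default_rng(seed)
        avg = expr.mean(axis=1)
        bins = pd.qcut(avg.rank(method="first"), q=min(n_bins, len(avg)),
                       labels=False)
        sig_set = set(genes_present)
        pool: list[str] = []
        for g in genes_present:
            candidates = avg.index[(bins == bins[g])
                                   & ~avg.index.isin(sig_set)]
            if len(candidates) == 0:
                continue
            replace = len(candidates) < n_ctrl
            pool.extend(rng.choice(candidates, size=n_ctrl, replace=replace))
        control_genes = sorted(set(pool))
        if not control_genes:
            raise ValueError("control pool is empty; too few non-signature "
                             "genes in the matrix")
    else:
        control_genes = [g for g in control_genes if g in expr.index]

    sig_mean = expr.loc[genes_present].mean(axis=0)
    ctrl_mean = expr.loc[control_genes].mean(axis=0)
    return ModuleScoreResult(
        cell_scores=(sig_mean - ctrl_mean).rename("module_score"),
        signature_genes=genes_present,
        control_genes=list(control_genes),
        missing_genes=missing,
    )


def pseudobulk_wilcoxon(
    scores: ModuleScoreResult,
    sample_meta: pd.DataFrame,
    comparison: tuple[str, str],
    exact_max_n: int = 25,
) -> float:
    """Two-sided rank-sum p on per-sample mean module scores.

    ``sample_meta`` is indexed by cell with ``sample_id`` and
    ``condition`` columns.  The test is exact for arms of up to
    ``exact_max_n`` samples, a tie-corrected normal approximation
    beyond that.
    """
    per_sample = (pd.DataFrame({"score": scores.cell_scores})
                  .join(sample_meta[["sample_id", "condition"]])
                  .groupby("sample_id", observed=True)
                  .agg(score=("score", "mean"),
                       condition=("condition", "first")))
    arm_a = per_sample.loc[per_sample["condition"] == comparison[0], "score"]
    arm_b = per_sample.loc[per_sample["condition"] == comparison[1], "score"]
    return wilcoxon_rank_sum(arm_a.to_numpy(), arm_b.to_numpy(),
                             exact_max_n=exact_max_n)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray,
                      exact_max_n: int = 25) -> float:
    """Two-sided unpaired Wilcoxon (Mann-Whitney) p-value."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both arms need at least one sample")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = ("exact"
              if max(len(a), len(b)) <= exact_max_n and not ties
              else "asymptotic")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def scale_log2fc(values, bound: float = 4.0, mode: str = "maxabs") -> np.ndarray:
    """Rescale log2 fold changes to the range [-bound, bound].

    ``mode="maxabs"`` (default) maps the most extreme value to the
    bound: x -> x * bound / max|x|, applied even when max|x| < bound so
    the output range is always calibrated.  ``mode="clip"`` truncates
    at the bound instead.  Sign-preserving; an all-zero vector is
    returned unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log2 fold changes must be finite")
    if mode == "clip":
        return np.clip(x, -bound, bound)
    if mode != "maxabs":
        raise ValueError(f"unknown scaling mode {mode!r}")
    m = np.max(np.abs(x)) if x.size else 0.0
    if m == 0.0:
        warnings.warn("all log2 fold changes are zero; nothing to scale",
                      stacklevel=2)
        return x.copy()
    # divide before multiplying so tiny maxima cannot overflow
    return (x / m) * bound


def concordant_genes(
    tables: list[ComparisonTable],
    bound: float = 4.0,
    mode: str = "maxabs",
) -> pd.DataFrame:
    """Direction-concordant genes across >= 2 datasets.

    Gene symbols are matched case-insensitively (mouse Calm3 vs human
    CALM3).  Each dataset's log2 fold changes over the shared genes are
    rescaled to [-bound, bound]; a gene is concordant when its sign is
    identical and nonzero in every dataset.  Rows are sorted by mean
    absolute scaled log2FC, descending.
    """
    if len(tables) < 2:
        raise ValueError("need at least two comparison tables")
    uppered = []
    for t in tables:
        df = t.data.copy()
        df.index = df.index.str.upper()
        if df.index.has_duplicates:
            df = df[~df.index.duplicated()]
        uppered.append(df)
    shared = uppered[0].index
    for df in uppered[1:]:
        shared = shared.intersection(df.index)
    if len(shared) == 0:
        raise ValueError("no shared genes across the supplied tables")
    shared = sorted(shared)

    out = pd.DataFrame(index=pd.Index(shared, name="gene"))
    signs = np.zeros((len(shared), len(tables)), dtype=int)
    for d, (t, df) in enumerate(zip(tables, uppered)):
        lfc = df.loc[shared, "log2fc"].to_numpy()
        out[f"scaled_log2fc_{t.contrast}"] = scale_log2fc(lfc, bound, mode)
        signs[:, d] = np.sign(lfc)
    out["concordant"] = [(row != 0).all() and len(set(row)) == 1
                         for row in signs]
    scaled_cols = [c for c in out.columns if c.startswith("scaled_")]
    out["mean_abs_scaled"] = out[scaled_cols].abs().mean(axis=1)
    return out.sort_values("mean_abs_scaled", ascending=False)


def gaba_cluster_flags(
    expr: pd.DataFrame,
    clusters: pd.Series,
    markers: tuple[str, ...] = ("GAD1", "GAD2", "SNAP25", "SYT1"),
) -> pd.Series:
    """Flag clusters with enriched expression of all GABAergic markers.

    A convenience rule for user-supplied clusterings: a cluster is
    flagged when each marker's mean expression inside the cluster
    exceeds that marker's dataset-wide median of cluster means.
    """
    present = [m for m in markers if m in expr.index]
    if len(present) < len(markers):
        raise ValueError(f"markers missing from matrix: "
                         f"{sorted(set(markers) - set(present))}")
    means = {m: expr.loc[m].groupby(clusters, observed=True).mean()
             for m in markers}
    flags = None
    for m, cm in means.items():
        enriched = cm > cm.median()
        flags = enriched if flags is None else (flags & enriched)
    return flags.rename("gabaergic")
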