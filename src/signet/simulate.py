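"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline (differential expression,
signature set logic, network inference, centrality, topic scoring,
proteomics) can be exercised on data from this module, where the truth
— which gene pairs are dependent, which genes are differential in which
contrast, which intensities are missing and why — is known exactly.

Count simulation uses a Gaussian copula: per cell, each gene receives a
standard-normal latent value; genes joined by a planted edge share a
latent factor whose weight is the coupling strength, so the pairwise
latent correlation equals the coupling.  Latents are pushed through the
negative-binomial quantile function, with per-group mean multipliers
encoding planted differential expression and batch effects.  Coupling 1
duplicates the latent factor, giving a maximally dependent pair;
coupling 0 gives exact independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from ._contrasts import (AGES, CONDITIONS, parse_contrast, require_named)
from .tables import ComparisonTable, make_table


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SampleDesign:
    sample_id: str
    condition: str
    age: str
    batch: str
    sex: str

    @property
    def group(self) -> str:
        return f"{self.condition}{self.age}"


@dataclass
class SimulationConfig:
    """Design of one synthetic single-nucleus count experiment.

    ``planted_edges`` are ``(gene_i, gene_j, coupling)`` triples with
    gene indices into the simulated gene list and coupling in [0, 1].
    ``planted_de`` maps a named contrast label to ``(gene_index,
    log2fc)`` pairs: the test arm's mean is multiplied by ``2**log2fc``.
    ``nb_dispersion`` is the negative-binomial size parameter (larger =
    closer to Poisson; variance = mu + mu**2 / size).
    """

    n_genes: int
    n_cells_per_sample: int
    samples: list[SampleDesign]
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    planted_de: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    planted_batch_de: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    nb_mean: float = 5.0
    nb_dispersion: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise InvalidConfigError(
                "nb_mean and nb_dispersion must be positive")
        if self.n_genes < 1 or self.n_cells_per_sample < 1:
            raise InvalidConfigError("n_genes and n_cells_per_sample >= 1")
        coupling_load = np.zeros(self.n_genes)
        for i, j, c in self.planted_edges:
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes) or i == j:
                raise InvalidConfigError(f"invalid planted edge ({i}, {j})")
            if not 0.0 <= c <= 1.0:
                raise InvalidConfigError(f"coupling {c} outside [0, 1]")
            coupling_load[i] += c
            coupling_load[j] += c
        if np.any(coupling_load > 1.0 + 1e-12):
            raise InvalidConfigError(
                "total coupling per gene must not exceed 1")
        for s in self.samples:
            if s.condition not in CONDITIONS or s.age not in AGES:
                raise InvalidConfigError(
                    f"sample {s.sample_id}: labels must come from "
                    f"{CONDITIONS} x {AGES}")
        for label in self.planted_de:
            parse_contrast(label)


@dataclass
class GroundTruth:
    """What the simulator planted, for scoring recovery downstream."""

    gene_names: list[str]
    true_edges: set[frozenset] = field(default_factory=set)
    true_de_by_contrast: dict[str, dict[str, int]] = field(default_factory=dict)
    true_missingness: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (p, c), lab in self.true_missingness.items():
            if lab not in {"MAR", "MNAR", "observed"}:
                raise ValueError(f"bad missingness label {lab!r} for {(p, c)}")


def default_gene_names(n_genes: int) -> list[str]:
    return [f"Gene{i:04d}" for i in range(n_genes)]


def _substream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible stream for one operation."""
    tag = int.from_bytes(label.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence((seed, tag)))


# ---------------------------------------------------------------------------
# counts

def simulate_counts(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a cells x genes integer count matrix with metadata.

    Returns an AnnData whose ``obs`` carries sample_id, condition, age,
    batch, sex and the composite group label, plus the ground truth of
    planted edges and differential genes.
    """
    config.validate()
    rng = _substream(config.seed, "counts")
    genes = default_gene_names(config.n_genes)
    n_samples = len(config.samples)
    n_cells = n_samples * config.n_cells_per_sample

    # latent Gaussian layer with shared per-edge factors
    z = rng.standard_normal((n_cells, config.n_genes))
    resid_weight = np.ones(config.n_genes)
    for i, j, c in config.planted_edges:
        resid_weight[i] -= c
        resid_weight[j] -= c
    z *= np.sqrt(np.clip(resid_weight, 0.0, None))
    for i, j, c in config.planted_edges:
        f = rng.standard_normal(n_cells)
        z[:, i] += np.sqrt(c) * f
        z[:, j] += np.sqrt(c) * f

    u = stats.norm.cdf(z)
    np.clip(u, 1e-12, 1.0 - 1e-12, out=u)

    # per-group mean multipliers from planted DE; per-batch multipliers
    log2_mult_group: dict[str, np.ndarray] = {}
    for label, effects in config.planted_de.items():
        test, _ref = parse_contrast(label)
        arr = log2_mult_group.setdefault(test, np.zeros(config.n_genes))
        for g, lfc in effects:
            arr[g] += lfc
    log2_mult_batch: dict[str, np.ndarray] = {}
    for batch, effects in config.planted_batch_de.items():
        arr = log2_mult_batch.setdefault(batch, np.zeros(config.n_genes))
        for g, lfc in effects:
            arr[g] += lfc

    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    size = config.nb_dispersion
    for s_idx, s in enumerate(config.samples):
        rows = slice(s_idx * config.n_cells_per_sample,
                     (s_idx + 1) * config.n_cells_per_sample)
        log2_mu = np.log2(config.nb_mean) * np.ones(config.n_genes)
        if s.group in log2_mult_group:
            log2_mu = log2_mu + log2_mult_group[s.group]
        if s.batch in log2_mult_batch:
            log2_mu = log2_mu + log2_mult_batch[s.batch]
        mu = 2.0 ** log2_mu
        p = size / (size + mu)  # scipy's nbinom success probability
        counts[rows] = stats.nbinom.ppf(u[rows], size, p[None, :]).astype(np.int64)

    obs = pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in config.samples],
                                   config.n_cells_per_sample),
            "condition": np.repeat([s.condition for s in config.samples],
                                   config.n_cells_per_sample),
            "age": np.repeat([s.age for s in config.samples],
                             config.n_cells_per_sample),
            "batch": np.repeat([s.batch for s in config.samples],
                               config.n_cells_per_sample),
            "sex": np.repeat([s.sex for s in config.samples],
                             config.n_cells_per_sample),
            "group": np.repeat([s.group for s in config.samples],
                               config.n_cells_per_sample),
        },
        index=pd.Index([f"cell{i:06d}" for i in range(n_cells)], name="cell"),
    )
    adata = ad.AnnData(X=counts, obs=obs)
    adata.var_names = genes
    adata.uns["seed"] = config.seed

    truth = GroundTruth(
        gene_names=genes,
        true_edges={frozenset({genes[i], genes[j]})
                    for i, j, c in config.planted_edges if c > 0},
        true_de_by_contrast={
            label: {genes[g]: int(np.sign(lfc)) for g, lfc in effects}
            for label, effects in config.planted_de.items()
        },
    )
    return adata, truth


# ---------------------------------------------------------------------------
# ready-made differential tables

def simulate_dge_tables(
    overlap_spec: dict[str, dict[str, int]],
    n_background: int = 50,
    seed: int = 0,
) -> dict[str, ComparisonTable]:
    """Construct noiseless differential tables realizing an overlap design.

    ``overlap_spec`` maps a named contrast to ``{gene: sign}``; those
    genes come out significant (Holm-adjusted p < 0.05) with the
    requested sign, every other gene in the shared universe is
    non-significant with log2FC ~ N(0, 0.1).  Signs are passed through
    verbatim, contradictions included, so downstream rules can be
    probed directly.
    """
    labels = [require_named(lab) for lab in overlap_spec]
    rng = _substream(seed, "dge_tables")
    requested = sorted({g for spec in overlap_spec.values() for g in spec})
    background = [f"Bg{i:04d}" for i in range(n_background)]
    universe = requested + background

    tables: dict[str, ComparisonTable] = {}
    for label, spec in zip(labels, overlap_spec.values()):
        for g, s in spec.items():
            if s not in (-1, 1):
                raise ValueError(f"sign for {g!r} must be +1 or -1, got {s}")
        lfc = rng.normal(0.0, 0.1, size=len(universe))
        pvals = rng.uniform(0.2, 1.0, size=len(universe))
        padj = np.ones(len(universe))
        for k, g in enumerate(universe):
            if g in spec:
                lfc[k] = spec[g] * rng.uniform(1.0, 3.0)
                pvals[k] = 1e-8
                padj[k] = 1e-6
        tables[label] = make_table(label, universe, lfc, pvals, padj)
    return tables


# ---------------------------------------------------------------------------
# interaction database

def simulate_interaction_db(
    truth: GroundTruth,
    n_decoys: int,
    score_law=("uniform", 0.0, 1.0),
    seed: int = 0,
):
    """Mock curated interaction database overlapping the planted graph.

    Every true edge is included with a score above the STRING-style
    0.600 threshold; ``n_decoys`` random non-true pairs are added with
    scores drawn from ``score_law`` (``("uniform", lo, hi)`` or any
    object with an ``rvs(size, random_state)`` method).
    """
    from .network import InteractionDatabase

    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = _substream(seed, "interaction_db")
    genes = list(truth.gene_names)
    true_pairs = {tuple(sorted(e)) for e in truth.true_edges}

    all_pairs = [(genes[i], genes[j])
                 for i in range(len(genes)) for j in range(i + 1, len(genes))]
    decoy_pool = [p for p in all_pairs if p not in true_pairs]
    if n_decoys > len(decoy_pool):
        raise ValueError(
            f"requested {n_decoys} decoys but only {len(decoy_pool)} "
            "non-true pairs exist")
    decoy_idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)

    if isinstance(score_law, tuple):
        kind, lo, hi = score_law
        if kind != "uniform":
            raise ValueError(f"unknown score law {kind!r}")
        decoy_scores = rng.uniform(lo, hi, size=n_decoys)
    else:
        decoy_scores = np.asarray(
            score_law.rvs(size=n_decoys, random_state=rng))

    rows = []
    for a, b in sorted(true_pairs):
        rows.append((a, b, float(rng.uniform(0.7, 1.0)), "mock"))
    for idx, score in zip(decoy_idx, decoy_scores):
        a, b = decoy_pool[int(idx)]
        rows.append((a, b, float(score), "mock"))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "source"])
    return InteractionDatabase.from_edges(edges)


# ---------------------------------------------------------------------------
# proteomics

@dataclass
class MissingSpec:
    """Missingness plan: a MAR rate plus MNAR-flagged (protein, condition).

    MAR cells are Bernoulli-masked independently of intensity; MNAR
    cells are left-censored below the per-condition 75th percentile of
    the protein's intensities so that the flagged condition loses at
    least 75% of its replicates.  MNAR-flagged proteins are exempt from
    MAR masking so their planted label stays unambiguous.
    """

    mar_rate: float = 0.0
    mnar: list[tuple[int, str]] = field(default_factory=list)

    def validate(self) -> None:
        if not 0.0 <= self.mar_rate <= 1.0:
            raise ValueError(f"mar_rate {self.mar_rate} outside [0, 1]")


def simulate_proteomics(
    n_proteins: int,
    conditions: list[str],
    replicates_per_condition: int = 4,
    batches: tuple[str, str] = ("B1", "B2"),
    missing_spec: MissingSpec | None = None,
    seed: int = 0,
    planted_effects: dict[str, list[tuple[int, float]]] | None = None,
    base_mean: float = 25.0,
    base_sd: float = 2.0,
    noise_sd: float = 0.3,
    batch_shift: float = 0.3,
):
    """Log-scale intensity matrix with planted shifts and missingness.

    Replicates alternate between the two batches and sexes.
    ``planted_effects`` maps a condition to ``(protein_index, log2
    shift)`` pairs added to that condition's intensities.
    Returns ``(ProteinMatrix, GroundTruth)``.
    """
    from .proteomics import ProteinMatrix

    if replicates_per_condition < 2:
        raise ValueError("need at least two replicates per condition")
    missing_spec = missing_spec or MissingSpec()
    missing_spec.validate()
    planted_effects = planted_effects or {}
    rng = _substream(seed, "proteomics")

    proteins = [f"Prot{i:04d}" for i in range(n_proteins)]
    sample_ids, meta_rows = [], []
    for cond in conditions:
        for r in range(replicates_per_condition):
            sample_ids.append(f"{cond}-{r + 1}")
            meta_rows.append({
                "condition": cond,
                "batch": batches[r % len(batches)],
                # sex alternates on a different period than batch so the
                # two covariates are never collinear
                "sex": ("F", "M")[(r // 2) % 2],
                "replicate": r + 1,
            })
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample"))

    base = rng.normal(base_mean, base_sd, size=n_proteins)
    intens = np.empty((n_proteins, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        cond = meta.at[sid, "condition"]
        shift = np.zeros(n_proteins)
        for p_idx, lfc in planted_effects.get(cond, []):
            shift[p_idx] += lfc
        b_shift = batch_shift if meta.at[sid, "batch"] == batches[-1] else 0.0
        intens[:, j] = base + shift + b_shift + rng.normal(
            0.0, noise_sd, size=n_proteins)

    df = pd.DataFrame(intens, index=pd.Index(proteins, name="protein"),
                      columns=sample_ids)
    truth_missing: dict[tuple[str, str], str] = {}

    # MNAR: left-censor below the per-(protein, condition) 75th percentile
    mnar_rows = {proteins[p] for p, _ in missing_spec.mnar}
    for p_idx, cond in missing_spec.mnar:
        prot = proteins[p_idx]
        cols = meta.index[meta["condition"] == cond]
        vals = df.loc[prot, cols]
        thr = np.quantile(vals.to_numpy(), 0.75)
        df.loc[prot, cols] = vals.where(vals >= thr)
        truth_missing[(prot, cond)] = "MNAR"

    # MAR: uniform Bernoulli masking of the remaining proteins
    if missing_spec.mar_rate > 0:
        mask = rng.random(df.shape) < missing_spec.mar_rate
        for i, prot in enumerate(proteins):
            if prot in mnar_rows:
                continue
            for j, sid in enumerate(sample_ids):
                if mask[i, j] and not pd.isna(df.iat[i, j]):
                    df.iat[i, j] = np.nan
                    truth_missing.setdefault(
                        (prot, meta.at[sid, "condition"]), "MAR")

    truth = GroundTruth(gene_names=proteins, true_missingness=truth_missing)
    return ProteinMatrix(intensities=df, sample_meta=meta), truth


# ---------------------------------------------------------------------------
# convenience cohort builders

def cohort_design(
    groups: list[str],
    n_per_group: int = 4,
    batches: tuple[str, str] = ("B1", "B2"),
) -> list[SampleDesign]:
    """Balanced animal cohort: n samples per condition-age group,
    alternating batch and sex, mirroring a 4-animals-per-arm design."""
    samples = []
    for g in groups:
        # longest suffix first: "16M"/"24M" end with "6M" too
        for age in sorted(AGES, key=len, reverse=True):
            if g.endswith(age):
                cond, a = g[: -len(age)], age
                break
        else:
            raise ValueError(f"bad group label {g!r}")
        for r in range(n_per_group):
            samples.append(SampleDesign(
                sample_id=f"{g}-{r + 1}",
                condition=cond, age=a,
                batch=batches[r % len(batches)],
                sex=("F", "M")[(r // 2) % 2],
            ))
    return samples
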