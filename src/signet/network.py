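"""Database-backed network construction and central-regulator ranking.

Expression-inferred (PIDC-selected) genes seed a graph built from
curated interaction databases: every database edge between two seed
genes is kept, and any non-seed gene bridging two seed genes through a
length-2 path is admitted as an interconnecting node (at most one
intermediate per path).  Each gene is then tested for over-connectivity
with an upper-tail hypergeometric test — drawing the constructed
graph's edges from the database's edges, how surprising is the gene's
observed degree given its database degree — followed by Holm adjustment
and deterministic ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionDatabase:
    """Weighted undirected edge store with a per-gene degree index."""

    edges: pd.DataFrame  # columns gene_a, gene_b, score, source
    _adjacency: dict[str, set[str]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "InteractionDatabase":
        df = edges.copy()
        pairs = [_norm_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
        df["gene_a"] = [p[0] for p in pairs]
        df["gene_b"] = [p[1] for p in pairs]
        if (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("self-loops are not allowed")
        # merge duplicates: keep max score, union of source tags
        df = (df.groupby(["gene_a", "gene_b"], as_index=False)
                .agg(score=("score", "max"),
                     source=("source", lambda s: ",".join(
                         sorted(set(",".join(map(str, s)).split(","))))))
              .sort_values(["gene_a", "gene_b"], kind="mergesort")
              .reset_index(drop=True))
        adj: dict[str, set[str]] = {}
        for a, b in zip(df["gene_a"], df["gene_b"]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return cls(edges=df, _adjacency=adj)

    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, gene: str) -> int:
        return len(self._adjacency.get(gene, ()))

    def neighbors(self, gene: str) -> set[str]:
        return set(self._adjacency.get(gene, ()))

    def genes(self) -> set[str]:
        return set(self._adjacency)

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adjacency.get(a, ())


STRING_COLUMNS = ["protein1", "protein2", "combined_score"]
GENERIC_COLUMNS = ["gene_a", "gene_b", "score", "source"]


def _read_edge_file(path, string_min_score: float) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:3] == STRING_COLUMNS:
        df = pd.read_csv(path, sep="\t")
        bad = df[pd.to_numeric(df["combined_score"], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable combined_score at line "
                f"{int(bad.index[0]) + 2}")
        # STRING combined scores are on a 0-999 scale
        df["score"] = df["combined_score"].astype(float) / 1000.0
        df = df[df["score"] > string_min_score]
        return pd.DataFrame({"gene_a": df["protein1"], "gene_b": df["protein2"],
                             "score": df["score"], "source": "string"})
    if header == GENERIC_COLUMNS:
        df = pd.read_csv(path, sep="\t")
        bad = df[pd.to_numeric(df["score"], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable score at line {int(bad.index[0]) + 2}")
        return df
    raise ValueError(
        f"{path}: unrecognized edge-file header {header!r}; expected "
        f"{STRING_COLUMNS} or {GENERIC_COLUMNS}")


def load_database(paths, string_min_score: float = 0.600) -> InteractionDatabase:
    """Union of edge files (generic or STRING dialect).

    STRING combined scores are divided by 1000 and filtered strictly
    above ``string_min_score``; duplicate pairs across sources are
    merged keeping the maximum score and both source tags.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = [_read_edge_file(p, string_min_score) for p in paths]
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=GENERIC_COLUMNS)
    if merged.empty:
        warnings.warn("interaction database is empty", stacklevel=2)
        merged = pd.DataFrame(columns=GENERIC_COLUMNS)
    return InteractionDatabase.from_edges(merged)


@dataclass
class InferredNetwork:
    """Seed genes plus one-intermediate bridges, with node roles."""

    nodes: dict[str, str]               # gene -> signature_gene | interconnecting_gene
    edges: pd.DataFrame                 # gene_a, gene_b, origin
    seed_genes: list[str]
    isolated_seeds: list[str] = field(default_factory=list)

    def degree(self, gene: str) -> int:
        return int(((self.edges["gene_a"] == gene)
                    | (self.edges["gene_b"] == gene)).sum())

    def n_edges(self) -> int:
        return len(self.edges)


def build_network(seed_genes, db: InteractionDatabase) -> InferredNetwork:
    """Database edges among seeds, plus single-gene bridges.

    Includes (i) every database edge between two seed genes and (ii)
    for every pair of seed genes joined by a length-2 database path,
    the intermediate gene and both its edges.  No edge ever joins two
    interconnecting genes.  Seeds with no qualifying edge stay as
    isolated nodes and are reported.
    """
    seeds = sorted(set(seed_genes))
    if not seeds:
        raise ValueError("seed gene list is empty")
    seed_set = set(seeds)
    edge_set: set[tuple[str, str]] = set()
    nodes: dict[str, str] = {g: "signature_gene" for g in seeds}

    for g in seeds:
        for nb in db.neighbors(g):
            if nb in seed_set:
                edge_set.add(_norm_pair(g, nb))

    for i, a in enumerate(seeds):
        nbrs_a = db.neighbors(a) - seed_set
        for b in seeds[i + 1:]:
            bridges = nbrs_a & (db.neighbors(b) - seed_set)
            for x in sorted(bridges):
                nodes[x] = "interconnecting_gene"
                edge_set.add(_norm_pair(a, x))
                edge_set.add(_norm_pair(b, x))

    edges = pd.DataFrame(sorted(edge_set), columns=["gene_a", "gene_b"])
    edges["origin"] = "database"
    touched = set(edges["gene_a"]) | set(edges["gene_b"])
    isolated = [g for g in seeds if g not in touched]
    return InferredNetwork(nodes=nodes, edges=edges, seed_genes=seeds,
                           isolated_seeds=isolated)


@dataclass
class CentralityResult:
    """Hypergeometric over-connectivity table and the chosen regulators."""

    table: pd.DataFrame   # k, n, K, N, p, padj, rank per gene
    central: list[str]
    warnings: list[str] = field(default_factory=list)


def hypergeom_overconnectivity(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(H >= k) for H ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def central_regulators(
    net: InferredNetwork,
    db: InteractionDatabase,
    top_k: int = 20,
) -> CentralityResult:
    """Rank network genes by over-connectivity vs their database degree.

    The gene's degree in the constructed graph (k, out of its n edges)
    is compared to its degree in the database (K, out of N edges) with
    an upper-tail hypergeometric test; Holm-adjusted p-values are
    ranked ascending with ties broken by raw p, then higher k, then
    gene name.  The top ``top_k`` genes are the central regulators.
    """
    if net.n_edges() == 0:
        raise ValueError("network has no edges")
    N = db.n_edges()
    n = net.n_edges()
    warn: list[str] = []
    deg_net: dict[str, int] = {}
    for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]):
        deg_net[a] = deg_net.get(a, 0) + 1
        deg_net[b] = deg_net.get(b, 0) + 1
    rows = []
    for gene in sorted(net.nodes):
        k = deg_net.get(gene, 0)
        K = db.degree(gene)
        if K == 0 and k > 0:
            warn.append(f"{gene}: absent from database, K set to k={k}")
            K = k
        rows.append((gene, k, n, K, N,
                     hypergeom_overconnectivity(k, K, n, N)))
    table = pd.DataFrame(rows, columns=["gene", "k", "n", "K", "N", "p"])
    table["padj"] = multipletests(table["p"], method="holm")[1]
    table = table.sort_values(
        by=["padj", "p", "k", "gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.set_index("gene")
    central = list(table.index[:top_k])
    return CentralityResult(table=table, central=central, warnings=warn)


MITO_KEYWORDS = ("mitochondrial", "respiratory chain", "respirasome",
                 "nadh", "oxidoreductase")


def collapse_mitochondria(
    genes,
    kegg_sets: dict[str, set[str]],
    go_cc_sets: dict[str, set[str]],
) -> dict[str, str]:
    """Partition genes into {"Mitochondria", "other"}.

    A gene collapses to "Mitochondria" when it belongs to the KEGG
    oxidative-phosphorylation set or to any GO cellular-component set
    whose name contains (case-insensitively) one of: mitochondrial,
    respiratory chain, respirasome, NADH, oxidoreductase.
    """
    mito_genes: set[str] = set()
    for name, members in kegg_sets.items():
        if "oxidative phosphorylation" in name.lower():
            mito_genes |= members
    for name, members in go_cc_sets.items():
        if any(kw in name.lower() for kw in MITO_KEYWORDS):
            mito_genes |= members
    return {g: ("Mitochondria" if g in mito_genes else "other")
            for g in genes}
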