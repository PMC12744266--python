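"""Topic-topic interaction scoring by label permutation.

Network genes carry curated functional topic labels (supplied as a
file, not computed).  The observed number of network edges joining two
distinct topics is compared to its null distribution under uniform
permutation of the topic assignment over genes (the label multiset is
preserved).  Upper-tail p-values use the add-one rule so the score
-log10(p) is always finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import InferredNetwork

UNASSIGNED = "Unassigned"


@dataclass
class TopicModel:
    """Observed and null inter-topic connection counts with scores."""

    assignment: dict[str, str]
    topics: list[str]
    observed: pd.DataFrame
    exceed_counts: pd.DataFrame
    p: pd.DataFrame
    score: pd.DataFrame
    n_perm: int
    seed: int
    intra_topic_edges: int = 0
    log: dict = field(default_factory=dict)


def _full_assignment(net: InferredNetwork,
                     assignment: dict[str, str]) -> tuple[dict[str, str], list[str]]:
    full, missing = {}, []
    for g in net.nodes:
        if g in assignment:
            full[g] = assignment[g]
        else:
            full[g] = UNASSIGNED
            missing.append(g)
    if missing:
        warnings.warn(f"{len(missing)} network genes lack a topic; "
                      f"labelled {UNASSIGNED!r}", stacklevel=3)
    return full, missing


def observed_topic_connections(
    net: InferredNetwork,
    assignment: dict[str, str],
) -> pd.DataFrame:
    """Symmetric topic x topic counts of inter-topic network edges.

    Intra-topic edges are excluded from the off-diagonal entries (the
    diagonal holds them, for bookkeeping)."""
    full, _ = _full_assignment(net, assignment)
    topics = sorted(set(full.values()))
    idx = {t: i for i, t in enumerate(topics)}
    mat = np.zeros((len(topics), len(topics)), dtype=np.int64)
    for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]):
        ta, tb = idx[full[a]], idx[full[b]]
        if ta == tb:
            mat[ta, ta] += 1
        else:
            mat[ta, tb] += 1
            mat[tb, ta] += 1
    return pd.DataFrame(mat, index=topics, columns=topics)


def permutation_scores(
    net: InferredNetwork,
    assignment: dict[str, str],
    n_perm: int = 10000,
    seed: int = 0,
) -> TopicModel:
    """Permutation null for inter-topic connection counts.

    p(s, t) = (1 + #{permutations with count >= observed}) / (1 + n_perm),
    one-sided toward over-connection; score = -log10 p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    full, missing = _full_assignment(net, assignment)
    genes = sorted(net.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    labels = np.array([full[g] for g in genes])
    topics = sorted(set(labels))
    t_idx = {t: i for i, t in enumerate(topics)}
    codes = np.array([t_idx[lab] for lab in labels])
    nt = len(topics)

    ea = np.array([gene_idx[a] for a in net.edges["gene_a"]])
    eb = np.array([gene_idx[b] for b in net.edges["gene_b"]])

    def pair_counts(c: np.ndarray) -> np.ndarray:
        ta, tb = c[ea], c[eb]
        inter = ta != tb
        lo = np.minimum(ta[inter], tb[inter])
        hi = np.maximum(ta[inter], tb[inter])
        flat = np.zeros(nt * nt, dtype=np.int64)
        np.add.at(flat, lo * nt + hi, 1)
        return flat

    obs_flat = pair_counts(codes)
    intra = len(ea) - int(obs_flat.sum())

    rng = np.random.default_rng(seed)
    exceed = np.zeros(nt * nt, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        exceed += pair_counts(perm) >= obs_flat

    def to_frame(flat: np.ndarray, dtype=float) -> pd.DataFrame:
        # counts live in the upper triangle only; mirror them down
        m = np.triu(flat.reshape(nt, nt).astype(dtype), 1)
        return pd.DataFrame(m + m.T, index=topics, columns=topics)

    observed = to_frame(obs_flat, np.int64)
    exceed_df = to_frame(exceed, np.int64)
    p = (1.0 + exceed_df) / (1.0 + n_perm)
    np.fill_diagonal(p.values, 1.0)
    score = -np.log10(p)
    return TopicModel(
        assignment=full, topics=topics, observed=observed,
        exceed_counts=exceed_df, p=p, score=score,
        n_perm=n_perm, seed=seed, intra_topic_edges=intra,
        log={"unassigned_genes": missing},
    )


def select_top_partners(
    model: TopicModel,
    k: int = 2,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Keep each topic's k highest-scoring partners.

    Topics with fewer than ``min_genes`` assigned genes are dropped
    first; ties break by higher observed count then partner name.  An
    edge survives when it is a top-k partner of either endpoint.
    Returns one row per surviving topic pair:
    ``topic_a topic_b observed p score kept``.
    """
    sizes = pd.Series(list(model.assignment.values())).value_counts()
    eligible = sorted(t for t in model.topics
                      if sizes.get(t, 0) >= min_genes)
    kept_pairs: set[tuple[str, str]] = set()
    for t in eligible:
        partners = [u for u in eligible if u != t]
        partners.sort(key=lambda u: (-model.score.at[t, u],
                                     -model.observed.at[t, u], u))
        for u in partners[:k]:
            kept_pairs.add(tuple(sorted((t, u))))
    rows = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1:]:
            rows.append((a, b, int(model.observed.at[a, b]),
                         float(model.p.at[a, b]),
                         float(model.score.at[a, b]),
                         (a, b) in kept_pairs))
    return pd.DataFrame(rows, columns=["topic_a", "topic_b", "observed",
                                       "p", "score", "kept"])
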