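"""Set logic deriving the PD, PD-Beginning, Aging and intersection
gene signatures from per-contrast differential tables.

The disease signatures come from a four-way intersection: genes
differential in both transgene arms (lifelong and late-induced
expression) at 16 months and again at 24 months.  Genes of that
intersection already differential at the pre-symptomatic 6-month
timepoint form the "PD Beginning"; the rest form the "PD Signature".
The aging signature collects genes differential between 24- and
6-month non-expressing animals whose direction is confirmed in at
least one intermediate aging contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tables import ComparisonTable

AGING_TRIPLE = ("synOFF24M_vs_synOFF6M", "synOFF16M_vs_synOFF6M",
                "synOFF24M_vs_synOFF16M")
PD_QUINTUPLE = ("synON16M_vs_synOFF16M", "synlateON16M_vs_synOFF16M",
                "synON24M_vs_synOFF24M", "synlateON24M_vs_synOFF24M",
                "synON6M_vs_synOFF6M")


@dataclass
class SignatureSet:
    """Named gene set with per-gene direction and provenance."""

    name: str
    members: dict[str, str] = field(default_factory=dict)  # gene -> up/down
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {d for d in self.members.values() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"invalid directions {bad}")

    def genes(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def _require(table: ComparisonTable, expected: str) -> None:
    if table.contrast != expected:
        raise ValueError(
            f"expected table for contrast {expected!r}, got {table.contrast!r}")


def _direction(sign: int) -> str:
    return "up" if sign > 0 else "down"


def aging_signature(
    t_24v6: ComparisonTable,
    t_16v6: ComparisonTable,
    t_24v16: ComparisonTable,
) -> SignatureSet:
    """Genes differential across the whole aging span (24M vs 6M) with
    direction-concordant support in an intermediate aging contrast.

    A gene qualifies when it is significant in the 24-vs-6 table and
    significant with the same log2FC sign in the 16-vs-6 or 24-vs-16
    table; significance with the opposite sign in either supporting
    table disqualifies it.  The recorded direction comes from 24-vs-6.
    """
    _require(t_24v6, AGING_TRIPLE[0])
    _require(t_16v6, AGING_TRIPLE[1])
    _require(t_24v16, AGING_TRIPLE[2])

    members: dict[str, str] = {}
    for gene in sorted(t_24v6.significant_genes()):
        s = t_24v6.sign(gene)
        if s == 0:
            continue
        support = discord = False
        for tab in (t_16v6, t_24v16):
            if gene in tab.significant_genes():
                if tab.sign(gene) == s:
                    support = True
                else:
                    discord = True
        if support and not discord:
            members[gene] = _direction(s)
    return SignatureSet(
        name="Aging_Signature",
        members=members,
        provenance={"contrasts": list(AGING_TRIPLE),
                    "rule": "significant 24v6, concordantly significant in "
                            "16v6 or 24v16, no opposite-sign support"},
    )


def pd_signatures(
    t_on16: ComparisonTable,
    t_late16: ComparisonTable,
    t_on24: ComparisonTable,
    t_late24: ComparisonTable,
    t_on6: ComparisonTable,
    sign_concordant: bool = False,
) -> tuple[SignatureSet, SignatureSet]:
    """Split the four-way symptomatic intersection by 6-month presence.

    I16 and I24 intersect the lifelong and late-induced arms at each
    symptomatic age; their intersection I is partitioned into the PD
    Signature (genes absent from the pre-symptomatic 6-month contrast)
    and PD Beginning (genes already present at 6 months).  Directions
    are recorded from the lifelong-expression 24-month table.  With
    ``sign_concordant=True`` the intersections additionally require
    equal log2FC signs across the four symptomatic tables.
    """
    expected = PD_QUINTUPLE
    for tab, exp in zip((t_on16, t_late16, t_on24, t_late24, t_on6), expected):
        _require(tab, exp)

    i16 = t_on16.significant_genes() & t_late16.significant_genes()
    i24 = t_on24.significant_genes() & t_late24.significant_genes()
    intersection = i16 & i24
    if sign_concordant:
        intersection = {
            g for g in intersection
            if len({t.sign(g) for t in (t_on16, t_late16, t_on24, t_late24)}) == 1
        }
    at_6m = t_on6.significant_genes()

    def build(name: str, genes: set[str]) -> SignatureSet:
        return SignatureSet(
            name=name,
            members={g: _direction(t_on24.sign(g)) for g in sorted(genes)},
            provenance={"contrasts": list(expected),
                        "sign_concordant": sign_concordant},
        )

    return (build("PD_Signature", intersection - at_6m),
            build("PD_Beginning", intersection & at_6m))


def intersect_signatures(a: SignatureSet, b: SignatureSet,
                         name: str) -> SignatureSet:
    """Genes shared by two signatures; directions carried from *a*."""
    shared = a.genes() & b.genes()
    return SignatureSet(
        name=name,
        members={g: a.members[g] for g in sorted(shared)},
        provenance={"parents": [a.name, b.name],
                    "direction_source": a.name},
    )
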