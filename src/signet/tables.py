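"""Per-contrast differential-result tables.

:class:`ComparisonTable` is the atomic currency of the signature logic:
one labeled contrast with per-gene log2 fold change, raw p-value,
Holm-adjusted p-value and a significance flag.  Tables can be produced
by the built-in differential test, by the simulator, or loaded from TSV
files written by any external tool (e.g. a DESeq2 run), so the set
logic downstream never depends on which test produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._contrasts import canonical_label

#: Column order of the on-disk TSV representation.
TSV_COLUMNS = ["gene", "log2fc", "pvalue", "padj", "significant"]


@dataclass
class ComparisonTable:
    """Differential expression/abundance results for one contrast.

    Parameters
    ----------
    contrast
        Label of the form ``test_vs_reference``.
    data
        DataFrame indexed by gene symbol with columns ``log2fc``,
        ``pvalue``, ``padj`` and boolean ``significant``.
    alpha
        Significance level the ``significant`` flag was computed at.
    log
        Free-form record of exclusions / fallbacks during testing.
    """

    contrast: str
    data: pd.DataFrame
    alpha: float = 0.05
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        try:
            self.contrast = canonical_label(self.contrast)
        except ValueError:
            # proteomics and external tables may use free-form arm labels
            self.contrast = self.contrast.replace(":", "_vs_")
        missing = [c for c in ("log2fc", "pvalue", "padj", "significant")
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"comparison table missing columns {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols in comparison table")

    # -- accessors used by the signature set logic -------------------------
    def significant_genes(self) -> set[str]:
        return set(self.data.index[self.data["significant"].astype(bool)])

    def sign(self, gene: str) -> int:
        """Sign of the gene's log2 fold change (+1, -1 or 0)."""
        return int(np.sign(self.data.at[gene, "log2fc"]))

    def genes(self) -> set[str]:
        return set(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.reset_index()
        out.columns = TSV_COLUMNS
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, contrast: str, alpha: float = 0.05) -> "ComparisonTable":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != TSV_COLUMNS:
            raise ValueError(
                f"{path}: expected columns {TSV_COLUMNS}, got {list(df.columns)}"
            )
        df = df.set_index("gene")
        df["significant"] = df["significant"].astype(bool)
        return cls(contrast=contrast, data=df, alpha=alpha)


def make_table(contrast: str, genes, log2fc, pvalue, padj,
               alpha: float = 0.05, log: dict | None = None) -> ComparisonTable:
    """Assemble a :class:`ComparisonTable` from parallel arrays."""
    data = pd.DataFrame(
        {
            "log2fc": np.asarray(log2fc, dtype=float),
            "pvalue": np.asarray(pvalue, dtype=float),
            "padj": np.asarray(padj, dtype=float),
        },
        index=pd.Index(genes, name="gene"),
    )
    data["significant"] = data["padj"] < alpha
    return ComparisonTable(contrast=contrast, data=data, alpha=alpha,
                           log=log or {})
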