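import numpy as np
import pandas as pd
import pytest

from signet.tables import make_table


def toy_table(contrast, spec, universe=None):
    """Build a ComparisonTable from {gene: (significant, sign)}."""
    genes = sorted(set(universe or []) | set(spec))
    lfc, p, padj = [], [], []
    for g in genes:
        sig, sign = spec.get(g, (False, 1))
        lfc.append(sign * (2.0 if sig else 0.05))
        p.append(1e-6 if sig else 0.5)
        padj.append(1e-4 if sig else 1.0)
    return make_table(contrast, genes, lfc, p, padj)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cohort():
    """One symptomatic and one control arm, 4 samples each."""
    from signet import simulate
    return simulate.cohort_design(["synON24M", "synOFF24M"], n_per_group=4)


@pytest.fixture
def protein_matrix():
    """Complete 8-protein, 2-condition, 2-batch intensity matrix."""
    from signet import simulate
    pm, truth = simulate.simulate_proteomics(
        n_proteins=8, conditions=["synON", "synOFF"],
        replicates_per_condition=4, seed=11)
    return pm, truth
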