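import numpy as np
import pandas as pd
import pytest

from nichescore.qc import QCParams, filter_cells, filter_genes, normalize
from nichescore.synthetic import worked_fixture

# QC convention for the worked fixture: its rare/edge genes put the
# gene-filter boundary at 5 cells (see worked_fixture docstring)
FIXTURE_QC = QCParams(min_cells_per_gene=5)


@pytest.fixture(scope="session")
def fixture_data():
    """The hand-written 20-gene x 30-cell dataset with its resources."""
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_filtered(fixture_data):
    """Fixture data after cell/gene QC plus the normalized matrix."""
    counts, metadata, bundle, truth = fixture_data
    counts_f, meta_f, report = filter_cells(counts, metadata, FIXTURE_QC)
    counts_f = filter_genes(counts_f, bundle.annotations.mitochondrial,
                            min_cells=FIXTURE_QC.min_cells_per_gene)
    norm = normalize(counts_f, size_factor=FIXTURE_QC.size_factor)
    return counts_f, meta_f, norm, report


def exact_wilcoxon_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes; p is the fraction of assignments whose rank-sum
    deviates from its mean at least as much as the observed one.
    Midranks are used for ties, so the oracle matches the tie convention
    of the asymptotic test it checks.
    """
    from itertools import combinations

    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    dev = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def brute_force_pairs(assignment, receptor_genes, library):
    """Independent triple-loop oracle for ligand-receptor pairing."""
    rows = []
    for subtype in sorted(assignment):
        table = assignment[subtype]
        ligands = list(table["gene"]) if isinstance(table, pd.DataFrame) else list(table)
        for ligand in ligands:
            for receptor in receptor_genes:
                if library.contains(ligand, receptor):
                    rows.append((subtype, ligand, receptor))
    return rows
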