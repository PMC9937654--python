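import numpy as np
import pandas as pd
import pytest

from ibioid.io import CountTable
from ibioid.simulate import (
    SimConfig,
    contaminant_gene_list,
    mito_gene_list,
    simulate_dataset,
)


def make_counts(rows):
    """rows: (protein, gene, bait, genotype, session, repeat, count)."""
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "gene_symbol",
            "bait",
            "genotype",
            "session",
            "repeat",
            "peptide_count",
        ],
    )


def toy_table(bait_counts, genotype="CONTROL", n_sessions=2):
    """Build a CountTable from {protein: {bait: (per-repeat counts per session)}}.

    ``bait_counts`` maps protein → {bait: tuple of repeat counts}; the same
    repeat counts are used in every session. Gene symbol defaults to the
    protein id.
    """
    rows = []
    for protein, baits in bait_counts.items():
        for bait, counts in baits.items():
            for sess in range(1, n_sessions + 1):
                for i, c in enumerate(counts):
                    rows.append(
                        (
                            protein,
                            protein,
                            bait,
                            genotype,
                            sess,
                            (sess - 1) * len(counts) + i + 1,
                            c,
                        )
                    )
    return CountTable(make_counts(rows))


@pytest.fixture(scope="session")
def sim_default():
    """One default-config control dataset plus truth and removal lists."""
    cfg = SimConfig(n_proteins=800, seed=11)
    table, truth = simulate_dataset(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def removal_lists(sim_default):
    _, _, truth = sim_default
    return mito_gene_list(truth), contaminant_gene_list()
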