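import numpy as np
import pandas as pd
import pytest

from phosphoflux import synthetic as syn
from phosphoflux.io_formats import PsiteQuantTable


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic dataset shared across tests (read-only)."""
    cfg = syn.PhosphoSimConfig(n_sites=400, n_proteins=200, n_regulated=150)
    return syn.generate_phospho_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset[2]


def make_table(values_by_key, times=(5, 30, 60), replicates=5,
               genes=None, peptides=None, loc_prob=0.99):
    """Build a PsiteQuantTable from {key: {(cond, time, rep): value}} or
    {key: array of shape (n_cols,)} following the canonical column order."""
    cols = pd.MultiIndex.from_tuples(
        [(c, t, r) for t in times for c in ("low", "high")
         for r in range(1, replicates + 1)],
        names=["condition", "time", "replicate"])
    rows = {}
    for key, vals in values_by_key.items():
        if isinstance(vals, dict):
            rows[key] = [vals.get(c, np.nan) for c in cols]
        else:
            rows[key] = list(vals)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    values.index.name = "psite"
    genes = genes or {}
    peptides = peptides or {}
    meta = pd.DataFrame({
        "protein": [k.rpartition("_")[0] for k in values.index],
        "gene": [genes.get(k, "") for k in values.index],
        "loc_prob": loc_prob,
        "peptide": [peptides.get(k, "") for k in values.index],
    }, index=values.index)
    return PsiteQuantTable(values, meta)


@pytest.fixture
def toy_table():
    """Five p-sites, one clearly regulated at every time point."""
    rng = np.random.default_rng(7)
    vals = {}
    for i in range(5):
        base = rng.normal(20, 1)
        row = {}
        for t in (5, 30, 60):
            for r in range(1, 6):
                low = base + rng.normal(0, 0.05)
                eff = 0.8 if i == 0 else 0.0
                row[("low", t, r)] = low
                row[("high", t, r)] = low + eff + rng.normal(0, 0.05)
        vals[f"SP{i:05d}_S{10 + i}"] = row
    return make_table(vals)
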