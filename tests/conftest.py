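"""Shared fixtures: models and simulations reused across test modules.

Heavy simulations are session-scoped so each is run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import methylhic as mh
from methylhic import contact_matrix as cm
from methylhic import synthetic as syn

SEED = 11


@pytest.fixture(scope="session")
def wt_model():
    """Default two-chromosome wild-type model."""
    return mh.build_genome_model(mh.SyntheticConfig(), SEED)


@pytest.fixture(scope="session")
def full_model(wt_model):
    """Model carrying WT plus the default knockout perturbation."""
    return syn.apply_perturbation(wt_model, syn.PerturbationConfig())


@pytest.fixture(scope="session")
def wt_pairs(full_model):
    """Two million wild-type contacts (coordinates only)."""
    return mh.simulate_contacts(full_model, "WT", 2_000_000, SEED + 1)


@pytest.fixture(scope="session")
def tko_pairs(full_model):
    return mh.simulate_contacts(full_model, "TKO", 2_000_000, SEED + 2)


@pytest.fixture(scope="session")
def wt_balanced50(wt_pairs, full_model):
    raw = cm.bin_pairs(wt_pairs, full_model.genome, 50_000)
    return {c: cm.balance(m) for c, m in raw.items()}


@pytest.fixture(scope="session")
def tko_balanced50(tko_pairs, full_model):
    raw = cm.bin_pairs(tko_pairs, full_model.genome, 50_000)
    return {c: cm.balance(m) for c, m in raw.items()}


@pytest.fixture(scope="session")
def wt_oe50(wt_balanced50):
    return {c: cm.oe_transform(m)[1] for c, m in wt_balanced50.items()}


@pytest.fixture(scope="session")
def tko_oe50(tko_balanced50):
    return {c: cm.oe_transform(m)[1] for c, m in tko_balanced50.items()}


@pytest.fixture(scope="session")
def dense_flat_model():
    """CpG-dense, flat-surface single-chromosome model.

    Mates carry ~12 CpGs so mate-level methylation fractions are
    informative, and the flat surface isolates the planted copula
    correlation from surface autocorrelation.
    """
    cfg = mh.SyntheticConfig(
        chrom_lengths={"chr1": 10_000_000},
        cpg_rate_prairie=0.12, cpg_rate_forest=0.12, cgi_fold=1.0,
        meth_cgi=0.5, meth_forest=0.5, meth_prairie=0.5, meth_noise_sd=0.0)
    return mh.build_genome_model(cfg, SEED)


def toeplitz_counts(rng, n=120, scale=200.0, decay=1.0, binsize=50_000):
    """Structureless raw matrix: symmetric Poisson noise around a
    distance-decay mean (no compartments, TADs or loops)."""
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = scale / np.maximum(d, 1) ** decay
    upper = rng.poisson(lam)
    vals = np.triu(upper) + np.triu(upper, k=1).T
    return cm.ContactMatrix(chrom="chrN", binsize=binsize,
                            values=vals.astype(float))
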