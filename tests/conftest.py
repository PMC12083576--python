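"""Shared fixtures and helpers for the test suite.

All randomness is seeded; fixtures build small synthetic loci so the whole
suite is deterministic and self-contained.
"""

from __future__ import annotations

import numpy as np
import pytest

from secboost import TraitDataset, simulate_locus
from secboost.sumstats import SummaryStats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trait(rng, n=60, p=8, beta=None, noise=1.0, trait_id="T1",
               rho=0.0):
    """A small standardized trait dataset with optional AR(1) genotype LD."""
    if rho:
        eps = rng.standard_normal((n, p))
        X = np.empty((n, p))
        X[:, 0] = eps[:, 0]
        for j in range(1, p):
            X[:, j] = rho * X[:, j - 1] + np.sqrt(1 - rho * rho) * eps[:, j]
    else:
        X = rng.standard_normal((n, p))
    b = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    y = X @ b + noise * rng.standard_normal(n)
    ids = [f"v{j}" for j in range(p)]
    return TraitDataset.from_raw(trait_id, y, X, ids)


def to_sumstats(ds: TraitDataset) -> SummaryStats:
    """In-sample marginal t-statistics of a trait dataset."""
    n = ds.N
    rho = ds.X.T @ ds.Y / (n - 1)
    rho = np.clip(rho, -0.999999, 0.999999)
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return SummaryStats(ds.trait_id, ds.variant_ids, t, n)


@pytest.fixture
def shared_signal_locus():
    """Two traits sharing one causal variant at 5% PVE."""
    return simulate_locus(N=600, P=120, L=2, n_causal=1, phi=0.05, seed=11)
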