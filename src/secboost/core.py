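"""Data containers and per-trait association/likelihood primitives.

Everything downstream works on standardized data: phenotypes are centered
and scaled to unit sample variance, genotype dosage columns likewise.  On
that scale the per-variant gradient of the squared-error loss, the marginal
association z-score, and the profile log-likelihood gain of a one-variable
fit all reduce to simple functions of the inner products ``X_j^T r`` and
``||r||^2``, which is what lets the boosting engine run identically on
individual-level data and on summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitDataset",
    "LDReference",
    "BoostState",
    "standardize",
    "gradient_scores",
    "delta_loglik",
]

# Floor for RSS after a one-variable fit, as a fraction of the null RSS.
# Guards the log-ratio against perfect fits on degenerate toy inputs.
_RSS_FLOOR = 1e-12


def standardize(matrix, policy: str = "drop"):
    """Center and scale columns to mean 0, sample sd 1 (N-1 denominator).

    Zero-variance columns cannot be scaled; under the default policy they
    are dropped and reported.

    Parameters
    ----------
    matrix : (N, P) array_like
        Raw dosage (or covariate) matrix, N >= 2.
    policy : {"drop", "error"}
        What to do with constant columns.

    Returns
    -------
    Z : (N, K) ndarray
        Standardized matrix over the K retained columns.
    kept : (K,) ndarray of int
        Indices of retained columns in the input.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    variable = sd > 0
    if not variable.any():
        raise ValueError("no variable columns")
    if policy == "error" and not variable.all():
        raise ValueError("constant column(s) present")
    kept = np.flatnonzero(variable)
    Z = (X[:, kept] - mu[kept]) / sd[kept]
    return Z, kept


def standardize_vector(y):
    """Standardize a phenotype vector to mean 0, sample sd 1."""
    y = np.asarray(y, dtype=float).ravel()
    sd = y.std(ddof=1)
    if sd <= 0:
        raise ValueError("phenotype has zero variance")
    return (y - y.mean()) / sd


@dataclass
class TraitDataset:
    """One trait's standardized phenotype and genotypes.

    ``Y`` is the standardized phenotype (mean 0, sd 1), ``X`` the
    column-standardized dosage matrix over ``variant_ids``.  Several traits
    measured on the same cohort may share the identical ``X`` object; the
    fitting engine exploits that to share cached cross-products.
    """

    trait_id: str
    Y: np.ndarray
    X: np.ndarray
    variant_ids: list[str]

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.variant_ids = list(self.variant_ids)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"trait {self.trait_id}: X has {self.X.shape[0]} rows "
                f"but Y has {self.Y.shape[0]} entries"
            )
        if self.X.shape[1] != len(self.variant_ids):
            raise ValueError(
                f"trait {self.trait_id}: {self.X.shape[1]} genotype columns "
                f"vs {len(self.variant_ids)} variant ids"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"trait {self.trait_id}: duplicate variant ids")

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def P(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_raw(cls, trait_id, y_raw, x_raw, variant_ids):
        """Build a dataset from raw phenotype/dosages, standardizing both."""
        Z, kept = standardize(x_raw)
        ids = [variant_ids[i] for i in kept]
        return cls(trait_id, standardize_vector(y_raw), Z, ids)


@dataclass
class LDReference:
    """Variant-by-variant Pearson correlation matrix with identifiers."""

    R: np.ndarray
    variant_ids: list[str]

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.variant_ids = list(self.variant_ids)
        p = len(self.variant_ids)
        if self.R.shape != (p, p):
            raise ValueError("LD matrix shape does not match variant ids")
        if len(set(self.variant_ids)) != p:
            raise ValueError("duplicate variant ids in LD reference")
        if not np.allclose(self.R, self.R.T, atol=1e-6, equal_nan=True):
            raise ValueError("LD matrix is not symmetric")
        diag = np.diag(self.R)
        if not np.allclose(diag[np.isfinite(diag)], 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.R)) > 1 + 1e-8:
                raise ValueError("LD entries exceed 1 in magnitude")

    @classmethod
    def from_genotypes(cls, X, variant_ids):
        Z, kept = standardize(X)
        n = Z.shape[0]
        R = (Z.T @ Z) / (n - 1)
        np.fill_diagonal(R, 1.0)
        return cls(R, [variant_ids[i] for i in kept])


@dataclass
class BoostState:
    """Per-trait boosting state for individual-level data.

    ``r = Y - X beta`` is maintained explicitly; the moment-based engine in
    :mod:`secboost.coupling` keeps the equivalent sufficient statistics
    instead, and the two agree by construction.
    """

    trait_id: str
    beta: np.ndarray
    r: np.ndarray
    loglik: float = 0.0
    round: int = 0

    @classmethod
    def initial(cls, ds: TraitDataset) -> "BoostState":
        return cls(
            trait_id=ds.trait_id,
            beta=np.zeros(ds.P),
            r=ds.Y.copy(),
            loglik=profile_loglik(ds.Y, ds.N),
            round=0,
        )


def profile_loglik(r, n: int) -> float:
    """Gaussian log-likelihood with the residual variance profiled out.

    Up to an additive constant, -(n/2) log(RSS / n).
    """
    rss = float(np.dot(r, r))
    if rss <= 0:
        raise ValueError("zero residual norm")
    return -0.5 * n * np.log(rss / n)


def gradient_scores(X, r):
    """Per-variant gradient g_j = X_j^T r / (N - 1).

    Callers take ``|g_j|`` for update magnitudes and ``sign(g_j)`` for
    update directions.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float).ravel()
    if X.shape[0] != r.shape[0]:
        raise ValueError("X and r have incompatible shapes")
    return X.T @ r / (X.shape[0] - 1)


def delta_loglik(X_j, r, n: int | None = None) -> float:
    """Profile log-likelihood drop when the effect at one variant is zeroed.

    Equivalently the gain of the one-variable least-squares fit of the
    current residual ``r`` on the standardized column ``X_j``:
    ``(n/2) log(RSS0 / RSS1)`` with ``RSS0 = ||r||^2`` and
    ``RSS1 = RSS0 - (X_j^T r)^2 / (n - 1)``.
    """
    X_j = np.asarray(X_j, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    if n is None:
        n = r.shape[0]
    rss0 = float(np.dot(r, r))
    if rss0 <= 0:
        raise ValueError("zero residual norm")
    xtr = float(np.dot(X_j, r))
    return delta_loglik_from_moments(xtr, rss0, n)


def delta_loglik_from_moments(xtr: float, rss0: float, n: int) -> float:
    """``delta_loglik`` from the sufficient statistics X_j^T r and ||r||^2."""
    if rss0 <= 0:
        raise ValueError("zero residual norm")
    rss1 = rss0 - xtr * xtr / (n - 1)
    rss1 = max(rss1, _RSS_FLOOR * rss0)
    return 0.5 * n * np.log(rss0 / rss1)
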