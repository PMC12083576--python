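"""The proximity-smoothed weak learner.

A naive boosting update at the single best-associated variant is unreliable
under linkage disequilibrium: the top marginal hit may only tag the causal
variant.  The weak learner here therefore spreads each update over the LD
proximity of the anchor variant.  Two ingredients control the spread:

* a *local association simplex* ``delta`` concentrating prior mass on LD
  proxies of the anchor that are themselves associated, via
  ``delta_j \\propto exp(LD(j, j*) * h(z_j))`` with an elastic-net shaped
  ``h``; and
* a temperature-``tau`` softmax of the gradient magnitudes relative to
  ``delta``, yielding per-variant weights ``xi`` that sum to ``1/(N-1)``.

The residual is then moved along ``d = sum_j xi_j sign(X_j^T r) X_j`` with a
shrunken exact line-search step, so every accepted update strictly reduces
the residual sum of squares while remaining a weak learner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimplexWeights",
    "UpdateRecord",
    "elastic_score",
    "local_simplex",
    "smoothed_weights",
    "weak_update",
]


def elastic_score(z, lam: float = 0.5):
    """Elastic-net shaped score of a z-score: (1-lam)|z| + (lam/2) z^2."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    z = np.asarray(z, dtype=float)
    return (1.0 - lam) * np.abs(z) + 0.5 * lam * z * z


@dataclass
class SimplexWeights:
    """Probability simplex over variants, anchored at variant ``anchor``."""

    delta: np.ndarray
    anchor: int


@dataclass
class UpdateRecord:
    """One boosting round: which traits moved, where, and by how much.

    ``xi`` holds, per updated trait, the weight vector renormalized to sum
    to 1 (i.e. ``(N-1) * xi``) stored sparsely as (support indices, values)
    in the shared variant universe.  ``gain`` is the per-trait profile
    log-likelihood gain of the round.
    """

    round: int
    mode: str
    anchor: dict[str, int]
    xi: dict[str, tuple[np.ndarray, np.ndarray]]
    signs: dict[str, np.ndarray]
    eta: dict[str, float]
    gain: dict[str, float]

    @property
    def traits(self) -> list[str]:
        return list(self.xi.keys())


def _stable_softmax(logw):
    m = np.max(logw)
    w = np.exp(logw - m)
    return w / w.sum()


def local_simplex(ld_row, z, lam: float = 0.5, anchor: int | None = None):
    """Local association simplex around an anchor variant.

    ``delta_j \\propto exp(LD(j, j*) * h(z_j))``, normalized to sum 1, with
    overflow-safe computation.  ``ld_row`` is the LD of every variant with
    the anchor; missing entries (NaN) contribute the neutral value 0.
    """
    ld_row = np.asarray(ld_row, dtype=float)
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    if anchor is None:
        anchor = int(np.argmax(np.where(np.isnan(ld_row), -np.inf, ld_row)))
    ld = np.where(np.isfinite(ld_row), ld_row, 0.0)
    logw = ld * elastic_score(z, lam)
    return SimplexWeights(delta=_stable_softmax(logw), anchor=anchor)


def smoothed_weights(delta: SimplexWeights, g, tau: float = 0.01, N: int = 2):
    """Temperature-softmax weights xi over variants.

    ``xi_j = (1/(N-1)) * delta_j exp(|g_j|/tau) / sum_j' delta_j'
    exp(|g_j'|/tau)`` where ``g_j = X_j^T r / (N-1)``; the vector sums to
    ``1/(N-1)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    g = np.asarray(g, dtype=float)
    d = np.asarray(delta.delta, dtype=float)
    with np.errstate(divide="ignore"):
        logw = np.where(d > 0, np.log(d), -np.inf) + np.abs(g) / tau
    return _stable_softmax(logw) / (N - 1)


def line_search_step(dtr: float, dtd: float, kappa: float) -> float:
    """Shrunken exact line-search step length along direction d.

    ``eta = kappa * argmin_eta ||r - eta d||^2 = kappa * (d^T r)/(d^T d)``,
    floored at 0.  For ``kappa`` in (0, 2) the residual SSE cannot increase.
    """
    if dtd <= 0:
        return 0.0
    return max(kappa * dtr / dtd, 0.0)


def weak_update(state, X, xi, signs, kappa: float = 0.3):
    """Apply one smoothed weak-learner update to an individual-level state.

    Moves ``state.beta``/``state.r`` along ``d = sum_j xi_j signs_j X_j``
    by the shrunken line-search step and returns ``(eta, gain)`` where
    ``gain`` is the profile log-likelihood improvement.  A zero direction
    is a no-op with gain 0.
    """
    X = np.asarray(X, dtype=float)
    xi = np.asarray(xi, dtype=float)
    signs = np.asarray(signs, dtype=float)
    if np.any(xi < 0):
        raise ValueError("xi must be non-negative")
    n = X.shape[0]
    coef = xi * signs
    d = X @ coef
    dtd = float(np.dot(d, d))
    if dtd == 0.0:
        return 0.0, 0.0
    dtr = float(np.dot(d, state.r))
    eta = line_search_step(dtr, dtd, kappa)
    if eta == 0.0:
        return 0.0, 0.0
    rss0 = float(np.dot(state.r, state.r))
    state.beta = state.beta + eta * coef
    state.r = state.r - eta * d
    rss1 = float(np.dot(state.r, state.r))
    gain = 0.5 * n * np.log(rss0 / rss1) if rss1 > 0 else np.inf
    state.loglik += gain
    state.round += 1
    return eta, gain
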