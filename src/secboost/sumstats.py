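"""Summary-statistics operating mode.

Because the boosting engine consumes only the sufficient statistics
``(X^T r, ||r||^2, X^T X, N)``, a trait known only through marginal
z-scores plus an LD panel can be fitted with the identical code path.
Under the standardized-data convention the reconstruction is exact:

* ``rho_j = z_j / sqrt(z_j^2 + N - 2)`` — the marginal correlation
  recovered from the t-statistic relation (not the large-N ``z/sqrt(N)``
  approximation, so toy sample sizes round-trip exactly);
* ``X^T Y = (N-1) rho``, ``Y^T Y = N-1``, ``X^T X = (N-1) R``.

Traits with non-overlapping variant sets are harmonized onto the union
universe without imputation: a variant absent from a trait simply carries
zero gradient for that trait.  Variants missing from a trait's LD panel
are retained but flagged: they never serve as anchors, and receive
proximity mass only through observed LD pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LDReference
from .coupling import _TraitWork, BoostConfig

__all__ = [
    "SummaryStats",
    "sufficient_stats",
    "harmonize",
    "ld_free_colocalize",
]


@dataclass
class SummaryStats:
    """Marginal association summary statistics for one trait."""

    trait_id: str
    variant_ids: list[str]
    z: np.ndarray
    N: int

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.variant_ids = list(self.variant_ids)
        if self.z.shape[0] != len(self.variant_ids):
            raise ValueError(
                f"trait {self.trait_id}: {self.z.shape[0]} z-scores vs "
                f"{len(self.variant_ids)} variant ids"
            )
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"trait {self.trait_id}: non-finite z-scores")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"trait {self.trait_id}: duplicate variant ids")
        if self.N < 2:
            raise ValueError(f"trait {self.trait_id}: N must be >= 2")
        self.N = int(self.N)

    @classmethod
    def from_beta_se(cls, trait_id, variant_ids, beta, se, N):
        beta = np.asarray(beta, dtype=float)
        se = np.asarray(se, dtype=float)
        if np.any(se <= 0):
            raise ValueError("standard errors must be positive")
        return cls(trait_id, variant_ids, beta / se, N)


def sufficient_stats(ss: SummaryStats, ld: LDReference):
    """Reconstruct boosting sufficient statistics from z-scores + LD.

    Returns ``(XtY, XtX, YtY)`` on the standardized scale.  Raises if a
    reconstructed marginal correlation reaches 1 in magnitude, which
    signals inconsistent z and N.
    """
    ids_ld = {v: i for i, v in enumerate(ld.variant_ids)}
    order = [ids_ld[v] for v in ss.variant_ids if v in ids_ld]
    if len(order) != len(ss.variant_ids):
        missing = [v for v in ss.variant_ids if v not in ids_ld]
        raise ValueError(
            f"trait {ss.trait_id}: {len(missing)} variants absent from the "
            f"LD panel (first: {missing[0]})"
        )
    n = ss.N
    rho = ss.z / np.sqrt(ss.z ** 2 + max(n - 2, 1))
    if np.any(np.abs(rho) >= 1):
        raise ValueError("inconsistent z and N")
    XtY = (n - 1) * rho
    XtX = (n - 1) * ld.R[np.ix_(order, order)]
    YtY = float(n - 1)
    return XtY, XtX, YtY


def harmonize(traits, ld_panels=()):
    """Align traits (and LD panels) onto the union variant universe.

    Returns ``(universe, masks)`` where ``universe`` lists variant ids in
    first-seen order and ``masks[i]`` gives, for trait i, the global index
    of each of its local variants.  Each mask is a bijection onto that
    trait's variants, so indices round-trip exactly.
    """
    traits = list(traits)
    if not traits:
        raise ValueError("need at least one trait")
    universe: list[str] = []
    pos: dict[str, int] = {}
    counts: dict[str, int] = {}
    for t in traits:
        for v in t.variant_ids:
            if v not in pos:
                pos[v] = len(universe)
                universe.append(v)
            counts[v] = counts.get(v, 0) + 1
    if len(traits) > 1 and max(counts.values()) < 2:
        raise ValueError("no variant is shared by any two traits")
    masks = [np.array([pos[v] for v in t.variant_ids], dtype=np.intp)
             for t in traits]
    return universe, masks


def _work_from_sumstats(ss: SummaryStats, panel: LDReference | None,
                        idx, cfg: BoostConfig) -> _TraitWork:
    n = ss.N
    p = len(ss.variant_ids)
    rho = ss.z / np.sqrt(ss.z ** 2 + max(n - 2, 1))
    if np.any(np.abs(rho) >= 1):
        raise ValueError("inconsistent z and N")
    xtr = (n - 1) * rho
    rss = float(n - 1)

    if panel is None:  # LD-free mode: identity LD
        def xtx_col(jl, _n=n, _p=p):
            col = np.zeros(_p)
            col[jl] = _n - 1
            return col

        missing = np.zeros(p, dtype=bool)
    else:
        ids_ld = {v: i for i, v in enumerate(panel.variant_ids)}
        panel_idx = np.array([ids_ld.get(v, -1) for v in ss.variant_ids],
                             dtype=np.intp)
        have = panel_idx >= 0
        R = panel.R
        row_bad = np.zeros(p, dtype=bool)
        if have.any():
            sub_ok = np.isfinite(R[np.ix_(panel_idx[have], panel_idx[have])])
            row_bad[have] = ~sub_ok.all(axis=1)
        missing = ~have | row_bad
        cache: dict[int, np.ndarray] = {}

        def xtx_col(jl, _R=R, _pi=panel_idx, _have=have, _n=n, _p=p, _c=cache):
            col = _c.get(jl)
            if col is None:
                col = np.full(_p, np.nan)
                if _pi[jl] >= 0:
                    col[_have] = (_n - 1) * _R[_pi[_have], _pi[jl]]
                col[jl] = _n - 1
                _c[jl] = col
            return col

    return _TraitWork(ss.trait_id, n, idx, xtr=xtr, rss=rss,
                      xtx_col=xtx_col, missing_ld=missing)


def ld_free_colocalize(traits, config: BoostConfig | None = None,
                       focal: str | None = None):
    """Colocalize from summary statistics alone, without any LD panel.

    Runs the boosting loop under the single-causal-variant assumption:
    the proximity simplex degenerates to the anchor variant, every update
    is a pure coordinate step, and at most one event is reported per trait
    configuration.

    Returns ``(events, fit)``.
    """
    from dataclasses import replace
    from .coupling import fit as _fit
    from .postprocess import assemble_events

    cfg = replace(config or BoostConfig(), ld_free=True)
    bf = _fit(list(traits), ld=None, config=cfg, focal=focal)
    events = assemble_events(bf)
    best: dict[tuple, object] = {}
    for ev in events:
        key = tuple(sorted(ev.traits))
        if key not in best or ev.gain > best[key].gain:
            best[key] = ev
    return sorted(best.values(), key=lambda e: -e.gain), bf
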