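"""Multi-trait boosting orchestration: single-effect couplers.

Each boosting round models one putative causal variant (a *single-effect
coupler*, SEC) and decides which traits to move at it:

* **Logic 1** — every trait's best single-effect variant is equivalent to
  the cross-trait best ``j*``: couple all traits at ``j*``.
* **Logic 2** — no trait is equivalent to ``j*``: either couple the
  strongest equivalence *group* of traits at that group's own best variant
  (2.1), or update singleton traits each at their own best (2.2).
* **Logic 3 (delayed SEC)** — a proper subset is equivalent to ``j*``:
  coupling is deferred until competing trait-specific signals have been
  absorbed, so that LD-induced horizontal pleiotropy does not contaminate
  the coupled update.
* **E-SEC** — in disease-prioritized mode a pre-step anchors each round on
  the focal trait's best variant while any other trait agrees with it.

The engine never touches raw data inside the loop: each trait is reduced to
the moment state ``(X^T r, ||r||^2, lazy columns of X^T X, N)``.  With
individual-level data those moments are exact; with summary statistics they
are reconstructed from z-scores and an LD panel, and the loop is oblivious
to the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .core import TraitDataset, LDReference, delta_loglik_from_moments
from .learner import UpdateRecord, elastic_score, _stable_softmax, line_search_step

__all__ = [
    "BoostConfig",
    "RoundPlan",
    "BoostFit",
    "best_joint_variant",
    "check_equivalence",
    "schedule_round",
    "fit",
    "fineboost",
]


@dataclass
class BoostConfig:
    """Tunable parameters of the boosting engine and event assembly.

    The defaults are the package's operating point; they are documented,
    with units and rationale, in the methods note.
    """

    # weak learner
    lam: float = 0.5          # elastic-net mixing weight in h(z)
    tau: float = 0.01         # softmax temperature for the xi weights
    kappa: float = 0.3        # shrinkage on the exact line-search step
    prox_min: float = 0.2     # xi support: min |LD| with the anchor.  The
                              # smoothed update distributes mass over the
                              # anchor's LD proximity; variants effectively
                              # uncorrelated with it belong to other
                              # effects and are excluded outright.
    # coupling
    epsilon: float = 0.1      # relative delta-loglik gap for equivalence
    ld_equiv: float = 0.8     # |LD| gate for equivalence of two variants
    join_frac: float = 0.5    # sub-logic 3.1: join the coupled update if
                              # delta-loglik at j* >= join_frac * own best
    join_p: float = 1e-3      # passive join: a trait that no longer drives
                              # scheduling still joins an update at anchor
                              # j* when its own |z| there is single-test
                              # significant at this level.  The anchor was
                              # chosen by the *other* traits, so no
                              # locus-wide multiplicity is paid -- this is
                              # how weak signals borrow strength from
                              # stronger traits.
    esec_patience: int = 3    # retire E-SEC after this many empty rounds
    # convergence
    tol: float = 1e-4         # relative SSE improvement over the window
    window: int = 5           # sliding window length (accepted updates)
    max_rounds: int = 500
    # trait inclusion gate: a trait enters the boosting loop only if its
    # strongest marginal association clears a Bonferroni bound alpha/P,
    # and stops updating once its residual's strongest association falls
    # back below that bound.  Traits with no detectable signal would
    # otherwise contribute pure noise updates, and greedy boosting on
    # noise does not terminate on its own.  Set to None to disable.
    gate_alpha: float | None = 0.05
    # event assembly (read by secboost.postprocess)
    coverage: float = 0.95
    purity_min: float = 0.5
    gain_rel_min: float = 0.025   # min share of a trait's total gain
    gain_event_frac: float = 0.1  # vs the trait's strongest event
    weight_power: float = 1.5     # v in the cross-trait weight combination
    cluster_sim_min: float = 0.5  # edge threshold in the SEC round graph
    merge_jaccard: float = 0.5    # "highly correlated CoS" merging
    merge_lead_ld: float = 0.8
    # operating mode
    ld_free: bool = False     # single-causal mode: no proximity smoothing
    # numerical
    xi_support_tol: float = 1e-8  # drop normalized xi entries below this


@dataclass
class RoundPlan:
    """Scheduled updates for one boosting round.

    ``updates`` maps anchor variants (global indices) to the tuple of trait
    ids updated there; a trait appears at most once per round.
    """

    mode: str
    updates: list[tuple[int, tuple[str, ...]]]

    def __post_init__(self):
        seen: set[str] = set()
        for _, traits in self.updates:
            for t in traits:
                if t in seen:
                    raise ValueError(f"trait {t} scheduled twice in one round")
                seen.add(t)


class _TraitWork:
    """Moment state of one trait inside the boosting loop."""

    def __init__(self, trait_id, n, idx, xtr, rss, xtx_col, missing_ld=None):
        self.tid = trait_id
        self.n = int(n)
        self.idx = np.asarray(idx, dtype=np.intp)  # ascending global indices
        self.xtr = np.asarray(xtr, dtype=float).copy()
        self.rss = float(rss)
        self.rss0 = float(rss)
        self._xtx_col = xtx_col  # callable: local index -> local column
        self.beta = np.zeros(self.idx.shape[0])
        self.missing_ld = (
            np.zeros(self.idx.shape[0], dtype=bool)
            if missing_ld is None
            else np.asarray(missing_ld, dtype=bool)
        )
        self.active = True
        self.converged = False
        # finishing: the residual peak fell below the locus-wide gate, so
        # the trait no longer drives scheduling but keeps polishing its
        # already-committed effects until the window criterion fires
        self.finishing = False
        self.committed: list[int] = []      # local anchors used so far
        self._finish_mask: np.ndarray | None = None
        self._upd_rss = [self.rss]
        # global -> local lookup
        self._local = {int(g): i for i, g in enumerate(self.idx)}

    def commit_anchor(self, jl: int):
        if jl not in self.committed:
            self.committed.append(jl)
            self._finish_mask = None

    def finish_mask(self, ld_min: float) -> np.ndarray:
        """Variants in tight LD (>= ld_min) with any committed anchor."""
        if self._finish_mask is None:
            mask = np.zeros(self.idx.shape[0], dtype=bool)
            for a in self.committed:
                with np.errstate(invalid="ignore"):
                    mask |= np.abs(np.nan_to_num(self.ld_row(a), nan=0.0)) \
                        >= ld_min
            self._finish_mask = mask
        return self._finish_mask

    def local(self, j_global: int) -> int | None:
        return self._local.get(int(j_global))

    def has(self, j_global: int) -> bool:
        return int(j_global) in self._local

    def ld_row(self, j_local: int) -> np.ndarray:
        """LD of every local variant with variant ``j_local`` (NaN = missing)."""
        return self._xtx_col(j_local) / (self.n - 1)

    def z(self) -> np.ndarray:
        return self.xtr / np.sqrt(self.rss)

    def best_local(self) -> int:
        a = np.abs(self.xtr)
        if self.missing_ld.any():
            a = np.where(self.missing_ld, -np.inf, a)
        return int(np.argmax(a))

    def dll(self, j_local: int) -> float:
        """Profile log-likelihood drop of zeroing the effect at one variant."""
        return delta_loglik_from_moments(float(self.xtr[j_local]), self.rss, self.n)

    @property
    def total_gain(self) -> float:
        return 0.5 * self.n * np.log(self.rss0 / self.rss)


def _work_from_dataset(ds: TraitDataset, idx, cache) -> _TraitWork:
    X, Y = ds.X, ds.Y
    key = id(X)
    col_cache = cache.setdefault(key, {})

    def xtx_col(j_local, _X=X, _c=col_cache):
        col = _c.get(j_local)
        if col is None:
            col = _X.T @ _X[:, j_local]
            _c[j_local] = col
        return col

    return _TraitWork(
        ds.trait_id,
        ds.N,
        idx,
        xtr=X.T @ Y,
        rss=float(Y @ Y),
        xtx_col=xtx_col,
    )


def best_joint_variant(residuals, datasets):
    """Cross-trait best single-effect variant.

    Maximizes the l1-aggregated absolute gradient ``sum_l |X_{l,j}^T r_l|``
    over variants j; ties break to the lowest index.  All datasets must be
    over the same variant universe (use :func:`secboost.sumstats.harmonize`
    otherwise).
    """
    total = None
    for r, ds in zip(residuals, datasets):
        s = np.abs(np.asarray(ds.X, dtype=float).T @ np.asarray(r, dtype=float))
        total = s if total is None else total + s
    return int(np.argmax(total))


def check_equivalence(j, j_star, trait: TraitDataset, ld: LDReference,
                      epsilon: float = 0.1, ld_gate: float = 0.8, r=None):
    """Are two candidate anchor variants equivalent for one trait?

    True iff the variants coincide or are in strong LD (``|r| > ld_gate``)
    *and* the trait's profile log-likelihood drop at the two variants is
    comparable: relative gap below ``epsilon``.  ``r`` is the residual the
    drops are computed on (defaults to the phenotype itself).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    j, j_star = int(j), int(j_star)
    if j != j_star and abs(float(ld.R[j, j_star])) <= ld_gate:
        return False
    if j == j_star:
        return True
    rr = trait.Y if r is None else np.asarray(r, dtype=float)
    rss = float(rr @ rr)
    n = trait.N
    d1 = delta_loglik_from_moments(float(trait.X[:, j] @ rr), rss, n)
    d2 = delta_loglik_from_moments(float(trait.X[:, j_star] @ rr), rss, n)
    return _rel_gap(d1, d2) < epsilon


def _rel_gap(d1: float, d2: float) -> float:
    return abs(d1 - d2) / max(d1, d2, 1e-12)


class _Engine:
    """Shared state for one multi-trait boosting fit."""

    def __init__(self, works, P, config, focal=None):
        self.works: list[_TraitWork] = works
        self.by_id = {w.tid: w for w in works}
        self.P = int(P)
        self.cfg = config
        self.focal = focal
        self.esec_active = focal is not None
        self.esec_streak = 0
        self.records: list[UpdateRecord] = []

    # ---- primitives -------------------------------------------------

    def _pair_ld(self, j1: int, j2: int) -> float:
        """Max |LD| between two global variants across panels that carry both."""
        if j1 == j2:
            return 1.0
        best = np.nan
        for w in self.works:
            l1, l2 = w.local(j1), w.local(j2)
            if l1 is None or l2 is None:
                continue
            v = w.ld_row(l2)[l1]
            if np.isfinite(v) and (np.isnan(best) or abs(v) > abs(best)):
                best = v
        return best

    def _equiv(self, w: _TraitWork, j: int, j_star: int) -> bool:
        """Equivalence of variants j and j* for trait w, on current residuals."""
        if j == j_star:
            return True
        lj, ls = w.local(j), w.local(j_star)
        if lj is None or ls is None:
            return False
        ld = self._pair_ld(j, j_star)
        if not np.isfinite(ld) or abs(ld) <= self.cfg.ld_equiv:
            return False
        return _rel_gap(w.dll(lj), w.dll(ls)) < self.cfg.epsilon

    def _jbest(self, w: _TraitWork) -> int:
        return int(w.idx[w.best_local()])

    def _jstar(self, works) -> int:
        agg = np.zeros(self.P)
        seen = np.zeros(self.P, dtype=bool)
        blocked = np.ones(self.P, dtype=bool)
        for w in works:
            np.add.at(agg, w.idx, np.abs(w.xtr))
            seen[w.idx] = True
            blocked[w.idx] &= w.missing_ld
        agg[~seen | blocked] = -np.inf
        return int(np.argmax(agg))

    # ---- scheduling --------------------------------------------------

    def schedule(self) -> RoundPlan | None:
        active = [w for w in self.works
                  if w.active and not w.converged and not w.finishing]
        if not active:
            return None
        if self.esec_active and self.focal is not None:
            plan = self._esec_prestep(active)
            if plan is not None:
                return plan
        return self._dynamic_coupling(active, mode_prefix="")

    def _join_z(self) -> float:
        return float(norm.isf(0.5 * self.cfg.join_p))

    def _esec_prestep(self, active) -> RoundPlan | None:
        fw = self.by_id.get(self.focal)
        if fw is None:
            self.esec_active = False
            return None
        if fw.converged or fw.rss <= 0:
            self.esec_active = False
            return None
        # the focal trait's peak anchors the round no matter how weak its
        # own evidence: corroboration -- other traits' best variants
        # independently landing in LD with it -- is what admits the
        # coupling.  This is the point of disease prioritization.
        je = self._jbest(fw)
        group = [w for w in active
                 if w.tid != self.focal and self._equiv(w, self._jbest(w), je)]
        if not group:
            self.esec_streak += 1
            if self.esec_streak >= self.cfg.esec_patience:
                self.esec_active = False
            return None
        self.esec_streak = 0
        members = group + [fw]
        j = self._jstar(members)
        # E-SEC only overrides the choice of candidate variant; which
        # traits actually update at it is still decided by the dynamic
        # coupling strategy, so delayed-SEC protection stays in force
        plan = self._dynamic_coupling(active, mode_prefix="esec-", jstar=j)
        # the focal trait couples at j* by corroboration: its own peak is
        # equivalent to the group's bests, so it joins without any
        # further evidence bar (this is the prioritization)
        planned = {t for _, traits in plan.updates for t in traits}
        if self.focal not in planned and fw.has(j) and \
                not fw.missing_ld[fw.local(j)]:
            updates = [(a, traits + (self.focal,)) if a == j else (a, traits)
                       for a, traits in plan.updates]
            if not any(a == j for a, _ in plan.updates):
                updates.append((j, (self.focal,)))
            plan = RoundPlan(plan.mode, updates)
        return plan

    def _dynamic_coupling(self, active, mode_prefix="",
                          jstar: int | None = None) -> RoundPlan:
        jb = {w.tid: self._jbest(w) for w in active}
        if jstar is None:
            jstar = self._jstar(active)
        r_star = [w for w in active if self._equiv(w, jb[w.tid], jstar)]
        r_not = [w for w in active if w not in r_star]
        if not r_not:  # Logic 1
            return RoundPlan(mode_prefix + "coupled",
                             [(jstar, tuple(w.tid for w in r_star))])
        if not r_star:  # Logic 2
            return self._logic2(active, jb)
        # Logic 3 (delayed SEC)
        m_star = min(w.dll(w.local(jstar)) for w in r_star)
        m_not = max(w.dll(w.local(jb[w.tid])) for w in r_not)
        if m_star > m_not:  # sub-logic 3.1
            z_join = self._join_z()
            joiners = []
            for w in r_not:
                ls = w.local(jstar)
                if ls is None:
                    continue
                if w.dll(ls) >= self.cfg.join_frac * w.dll(w.local(jb[w.tid])) \
                        and abs(float(w.z()[ls])) >= z_join:
                    joiners.append(w)
            members = r_star + joiners
            return RoundPlan("coupled",
                             [(jstar, tuple(w.tid for w in members))])
        # sub-logic 3.2: defer j*, update the complementary set
        return self._logic2(r_not, jb, mode_prefix="delayed-")

    def _logic2(self, subset, jb, mode_prefix="") -> RoundPlan:
        # pairwise equivalence groups among the subset's best variants
        k = len(subset)
        parent = list(range(k))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in range(k):
            for b in range(a + 1, k):
                wa, wb = subset[a], subset[b]
                ja, jbv = jb[wa.tid], jb[wb.tid]
                if self._equiv(wa, ja, jbv) and self._equiv(wb, jbv, ja):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        groups: dict[int, list[_TraitWork]] = {}
        for i, w in enumerate(subset):
            groups.setdefault(find(i), []).append(w)
        multi = [g for g in groups.values() if len(g) > 1]
        if multi:  # sub-logic 2.1: strongest equivalence group couples
            def gmax(g):
                return max(w.dll(w.local(jb[w.tid])) for w in g)
            best = max(multi, key=gmax)
            j = self._jstar(best)
            return RoundPlan(mode_prefix + "group-coupled",
                             [(j, tuple(w.tid for w in best))])
        # sub-logic 2.2: every trait updates its own unique best
        return RoundPlan(mode_prefix + "trait-specific",
                         [(jb[w.tid], (w.tid,)) for w in subset])

    # ---- updates -----------------------------------------------------

    def _update_trait(self, w: _TraitWork, j_global: int):
        """Proximity-smoothed weak update of one trait at one anchor."""
        cfg = self.cfg
        jl = w.local(j_global)
        if jl is None or w.rss <= 0:
            return None
        p = w.idx.shape[0]
        if cfg.ld_free:
            wgt = np.zeros(p)
            wgt[jl] = 1.0
            support = np.array([jl], dtype=np.intp)
        else:
            z = w.z()
            ld = np.nan_to_num(w.ld_row(jl), nan=0.0)
            logw = ld * elastic_score(z, cfg.lam)
            logw = logw + np.abs(w.xtr) / ((w.n - 1) * cfg.tau)
            logw[np.abs(ld) < cfg.prox_min] = -np.inf
            wgt = _stable_softmax(logw)
            support = np.flatnonzero(wgt > cfg.xi_support_tol)
            if support.size == 0:
                return None
        ws = wgt[support]
        ws = ws / ws.sum()
        sgn = np.sign(w.xtr[support])
        sgn[sgn == 0] = 1.0
        u = ws * sgn
        K = np.column_stack([
            np.nan_to_num(w._xtx_col(int(s)), nan=0.0) for s in support
        ])
        dtr = float(u @ w.xtr[support])
        dtd = float(u @ (K[support, :] @ u))
        eta = line_search_step(dtr, dtd, cfg.kappa)
        if eta <= 0.0:
            return None
        rss_new = w.rss - 2 * eta * dtr + eta * eta * dtd
        if rss_new <= 0 or rss_new >= w.rss:
            return None
        w.xtr -= eta * (K @ u)
        w.beta[support] += eta * u
        gain = 0.5 * w.n * np.log(w.rss / rss_new)
        w.rss = rss_new
        w._upd_rss.append(rss_new)
        w.commit_anchor(jl)
        self._check_converged(w)
        return (w.idx[support].copy(), ws, sgn, eta, gain)

    def _check_converged(self, w: _TraitWork):
        cfg = self.cfg
        W = cfg.window
        if len(w._upd_rss) > W and \
                np.log(w._upd_rss[-W - 1] / w._upd_rss[-1]) < cfg.tol:
            w.converged = True
        if cfg.gate_alpha is not None and not w.converged and not w.finishing:
            # residual peak no longer locus-wide significant: stop driving
            # the scheduler, finish polishing the committed effects
            z_stop = norm.isf(0.5 * cfg.gate_alpha / w.idx.shape[0])
            if float(np.max(np.abs(w.z()))) < z_stop:
                if w.committed:
                    w.finishing = True
                else:
                    w.converged = True

    def _augment_plan(self, plan: RoundPlan | None) -> RoundPlan | None:
        """Passive joins and finishing self-updates around the scheduled plan.

        Traits that no longer drive scheduling participate by priority:

        1. *passive join* — when any planned anchor (scheduled, or another
           trait's finishing anchor) carries a single-test-significant
           association for the trait (``join_p``), the trait joins the
           strongest such anchor.  The anchor was chosen by the other
           traits, so no locus-wide multiplicity is paid; this is how weak
           signals borrow strength from stronger traits.
        2. *finishing self-update* — otherwise a finishing trait polishes
           the tight LD proximity (>= ld_equiv) of its committed anchors
           until its convergence window fires.
        """
        updates = [] if plan is None else list(plan.updates)
        planned = {t for _, traits in updates for t in traits}

        # finishing self-anchor proposals
        fin_anchor: dict[str, int] = {}
        for w in self.works:
            if not w.finishing or w.converged or w.tid in planned:
                continue
            mask = w.finish_mask(self.cfg.ld_equiv) & ~w.missing_ld
            if not mask.any():
                w.converged = True
                continue
            jl = int(np.argmax(np.where(mask, np.abs(w.xtr), -np.inf)))
            fin_anchor[w.tid] = int(w.idx[jl])

        pool = sorted({j for j, _ in updates} | set(fin_anchor.values()))
        z_join = self._join_z()
        joins: dict[int, list[str]] = {}
        for w in self.works:
            driving = w.active and not w.converged and not w.finishing
            if w.tid in planned or driving or w.rss <= 0:
                continue
            best_j, best_z = None, z_join
            for j in pool:
                if j == fin_anchor.get(w.tid):
                    continue  # its own polish anchor is not a join
                jl = w.local(j)
                if jl is None or w.missing_ld[jl]:
                    continue
                zv = abs(float(w.z()[jl]))
                if zv >= best_z:
                    best_j, best_z = j, zv
            if best_j is not None:
                joins.setdefault(best_j, []).append(w.tid)
                planned.add(w.tid)

        # remaining finishing traits polish their own effects
        self_upd: dict[int, list[str]] = {}
        for tid, j in fin_anchor.items():
            if tid not in planned:
                self_upd.setdefault(j, []).append(tid)
                planned.add(tid)

        merged = []
        seen_anchor = set()
        for j, traits in updates:
            extra = tuple(joins.pop(j, ())) + tuple(self_upd.pop(j, ()))
            merged.append((j, tuple(traits) + extra))
            seen_anchor.add(j)
        for j in sorted(set(joins) | set(self_upd)):
            merged.append((j, tuple(joins.get(j, ())) +
                           tuple(self_upd.get(j, ()))))
        if not merged:
            return None
        return RoundPlan(plan.mode if plan is not None else "finishing",
                         merged)

    def run(self):
        cfg = self.cfg
        for k in range(cfg.max_rounds):
            plan = self.schedule()
            plan = self._augment_plan(plan)
            if plan is None:
                break
            anchors, xi, signs, eta, gain = {}, {}, {}, {}, {}
            for j_global, traits in plan.updates:
                for tid in traits:
                    work = self.by_id[tid]
                    res = self._update_trait(work, j_global)
                    if res is None:
                        # stalled: counts toward the convergence window
                        work._upd_rss.append(work.rss)
                        self._check_converged(work)
                        continue
                    idx, ws, sg, e, g = res
                    anchors[tid] = int(j_global)
                    xi[tid] = (idx, ws)
                    signs[tid] = sg
                    eta[tid] = e
                    gain[tid] = g
            if not xi:
                # nothing improved: the scheduled traits are done
                for j_global, traits in plan.updates:
                    for tid in traits:
                        self.by_id[tid].converged = True
                continue
            self.records.append(UpdateRecord(
                round=len(self.records), mode=plan.mode, anchor=anchors,
                xi=xi, signs=signs, eta=eta, gain=gain,
            ))
        return self


@dataclass
class BoostFit:
    """Full boosting trajectory plus final per-trait effect vectors."""

    trait_ids: list[str]
    variant_ids: list[str]
    records: list[UpdateRecord]
    beta: dict[str, np.ndarray]
    rss0: dict[str, float]
    rss: dict[str, float]
    n: dict[str, int]
    gated: dict[str, bool]          # True = trait entered the loop
    config: BoostConfig
    focal: str | None = None
    _works: list = field(default_factory=list, repr=False)

    @property
    def n_rounds(self) -> int:
        return len(self.records)

    def trait_gain(self, tid: str) -> float:
        """Total profile log-likelihood gain of one trait."""
        return 0.5 * self.n[tid] * np.log(self.rss0[tid] / self.rss[tid])

    def ld_submatrix(self, variants) -> np.ndarray:
        """Pairwise LD among global variants: max |LD| across panels.

        Entries no panel can supply are NaN.
        """
        variants = [int(v) for v in variants]
        m = len(variants)
        out = np.full((m, m), np.nan)
        np.fill_diagonal(out, 1.0)
        for w in self._works:
            loc = [w.local(v) for v in variants]
            for b, lb in enumerate(loc):
                if lb is None:
                    continue
                row = w.ld_row(lb)
                for a, la in enumerate(loc):
                    if la is None or a == b:
                        continue
                    v = row[la]
                    if np.isfinite(v) and (
                        np.isnan(out[a, b]) or abs(v) > abs(out[a, b])
                    ):
                        out[a, b] = v
                        out[b, a] = v
        return out


def _passes_gate(w: _TraitWork, cfg: BoostConfig) -> bool:
    if cfg.gate_alpha is None:
        return True
    p = w.idx.shape[0]
    z_gate = norm.isf(0.5 * cfg.gate_alpha / p)
    return float(np.max(np.abs(w.z()))) >= z_gate


def schedule_round(works_or_engine, config: BoostConfig | None = None,
                   focal: str | None = None) -> RoundPlan | None:
    """One scheduling decision of the dynamic coupling strategy.

    Accepts either a prepared :class:`_Engine` or a list of internal trait
    states; exposed mainly for tests that step the decision tree by hand.
    """
    if isinstance(works_or_engine, _Engine):
        return works_or_engine.schedule()
    works = list(works_or_engine)
    P = 1 + max(int(w.idx.max()) for w in works)
    return _Engine(works, P, config or BoostConfig(), focal=focal).schedule()


def fit(datasets, ld=None, config: BoostConfig | None = None,
        focal: str | None = None) -> BoostFit:
    """Run the coupled boosting loop over one locus.

    Parameters
    ----------
    datasets : list of TraitDataset and/or SummaryStats
        The traits to colocalize.  Mixed types are allowed.
    ld : LDReference, list of LDReference, or None
        LD panel(s) for summary-statistic traits.  One panel may be shared
        by all traits, or one panel supplied per trait.  Individual-level
        traits use their in-sample LD and ignore this argument.  ``None``
        requires either all-individual data or ``config.ld_free``.
    config : BoostConfig, optional
    focal : str, optional
        Trait id of the focal (disease) trait: enables the
        disease-prioritized E-SEC mode.

    Notes
    -----
    The fit is deterministic given data and configuration: there is no
    internal randomness.
    """
    from .sumstats import SummaryStats, harmonize, _work_from_sumstats

    cfg = config or BoostConfig()
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one trait")
    if focal is not None and focal not in [d.trait_id for d in datasets]:
        raise ValueError(f"focal trait {focal!r} not among datasets")
    ld_list: list[LDReference | None]
    if ld is None or isinstance(ld, LDReference):
        ld_list = [ld] * len(datasets)
    else:
        ld_list = list(ld)
        if len(ld_list) == 1:
            ld_list = ld_list * len(datasets)
        if len(ld_list) != len(datasets):
            raise ValueError("need one LD panel, or one per trait")

    universe, masks = harmonize(datasets, [l for l in ld_list if l is not None])
    cache: dict = {}
    works = []
    for ds, panel, idx in zip(datasets, ld_list, masks):
        if isinstance(ds, TraitDataset):
            works.append(_work_from_dataset(ds, idx, cache))
        elif isinstance(ds, SummaryStats):
            if panel is None and not cfg.ld_free:
                raise ValueError(
                    f"trait {ds.trait_id}: summary statistics need an LD "
                    "panel unless config.ld_free is set"
                )
            works.append(_work_from_sumstats(ds, panel, idx, cfg))
        else:
            raise TypeError(f"unsupported dataset type {type(ds)!r}")

    for w in works:
        w.active = _passes_gate(w, cfg)

    eng = _Engine(works, len(universe), cfg, focal=focal).run()

    P = len(universe)
    beta = {}
    for w in works:
        b = np.zeros(P)
        b[w.idx] = w.beta
        beta[w.tid] = b
    return BoostFit(
        trait_ids=[w.tid for w in works],
        variant_ids=universe,
        records=eng.records,
        beta=beta,
        rss0={w.tid: w.rss0 for w in works},
        rss={w.tid: w.rss for w in works},
        n={w.tid: w.n for w in works},
        gated={w.tid: w.active for w in works},
        config=cfg,
        focal=focal,
        _works=works,
    )


def fineboost(dataset, config: BoostConfig | None = None) -> BoostFit:
    """Single-trait special case: proximity-smoothed boosting fine-mapping."""
    return fit([dataset], config=config)
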