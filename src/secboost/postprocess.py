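"""Assemble boosting rounds into colocalization events.

A single causal effect is typically updated over many boosting rounds,
often at slightly different LD-proximal anchors, by design of the weak
learner.  Rounds are therefore clustered by the similarity of their
per-variant weight vectors (modularity maximization on the round graph),
and each cluster becomes a candidate colocalization event:

* per trait, per-round weights are averaged with profile log-likelihood
  gains as weights (``W_jls``);
* traits are combined into ``W_js = (prod_l W_jls)^(v/|T_s|)`` (default
  v = 1.5) so the scale is comparable across configuration sizes;
* the 95% colocalization confidence set (CoS) is the smallest set of
  variants whose normalized weights reach the coverage level;
* events are filtered on purity (minimum pairwise |LD| inside the CoS)
  and on the trait-wise likelihood contributions, and per-variant
  colocalization probabilities ``VCP_j = 1 - prod_s (1 - W_js)`` are
  reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .coupling import BoostConfig, BoostFit

__all__ = [
    "ColocEvent",
    "ColocResult",
    "cluster_sec",
    "event_weights",
    "build_cos",
    "purity_and_filters",
    "vcp_scores",
    "max_vcp",
    "assemble_events",
    "colocalize",
]


@dataclass
class ColocEvent:
    """One assembled colocalization event."""

    event_id: int
    cos: np.ndarray                  # global variant indices, weight-ordered
    cos_ids: list[str]
    w: np.ndarray                    # normalized W_js over the CoS variants
    w_full: np.ndarray               # normalized W_js over the whole locus
    traits: list[str]                # trait configuration T_s
    w_trait: dict[str, np.ndarray]   # per-trait W_jls over the locus
    trait_gain: dict[str, float]     # per-trait likelihood contribution
    purity: float
    coverage: float
    rounds: list[int]
    label: str = "primary"
    ld_flagged: bool = False         # purity computed on partial LD only

    @property
    def gain(self) -> float:
        return float(sum(self.trait_gain.values()))

    @property
    def size(self) -> int:
        return int(self.cos.shape[0])


@dataclass(frozen=True)
class SecUnit:
    """One single-effect update: a (round, anchor) pair with its traits.

    A coupled round contributes one unit; a trait-specific round updating
    several traits at different anchors contributes one unit per anchor,
    so that distinct effects touched in the same round never share a
    clustering node.
    """

    record: int
    anchor: int
    traits: tuple[str, ...]


def sec_units(records) -> list[SecUnit]:
    units = []
    for i, rec in enumerate(records):
        by_anchor: dict[int, list[str]] = {}
        for tid in rec.xi:
            by_anchor.setdefault(int(rec.anchor[tid]), []).append(tid)
        for a in sorted(by_anchor):
            units.append(SecUnit(i, a, tuple(sorted(by_anchor[a]))))
    return units


def _unit_vectors(units, records, P):
    """Per-unit dense normalized weight vectors, per trait and averaged."""
    per_trait: dict[str, dict[int, np.ndarray]] = {}
    mean_vec = np.zeros((len(units), P))
    for i, u in enumerate(units):
        for tid in u.traits:
            idx, w = records[u.record].xi[tid]
            v = np.zeros(P)
            v[idx] = w
            per_trait.setdefault(tid, {})[i] = v
            mean_vec[i] += v
        mean_vec[i] /= len(u.traits)
    return per_trait, mean_vec


def _cosine_rows(M, metric=None):
    """Pairwise cosine of rows, optionally in a bilinear |LD| metric.

    With ``metric`` A (PSD), similarity is x^T A y / sqrt(x^T A x y^T A y):
    two weight vectors concentrated on tight LD proxies of one effect are
    then similar even when their supports barely overlap, while vectors on
    uncorrelated variants stay dissimilar.
    """
    if metric is None:
        G = M @ M.T
    else:
        G = M @ metric @ M.T
    d = np.sqrt(np.clip(np.diag(G), 1e-300, None))
    return np.clip(G / np.outer(d, d), -1.0, 1.0)


def cluster_sec(records, P: int | None = None, sim_min: float = 0.5,
                ld=None):
    """Group single-effect updates into clusters, one per putative effect.

    Nodes are single-effect units (round x anchor); the edge weight
    between two units is the cosine similarity of their weight vectors,
    averaged over traits updated in both (falling back to the
    trait-averaged vectors when the units share no trait).  When ``ld``
    (a callable mapping a variant index list to an LD submatrix) is
    supplied, the cosine is taken in the |LD| metric, so that rounds
    re-anchored on tight proxies of one effect still co-cluster.  Edges
    below ``sim_min`` are removed, communities come from greedy modularity
    maximization, and units with the identical anchor variant always
    co-cluster.

    Returns a list of clusters, each a list of :class:`SecUnit`.
    """
    records = list(records)
    if not records:
        return []
    units = sec_units(records)
    if P is None:
        P = 1 + max(int(idx.max()) for rec in records
                    for idx, _ in rec.xi.values() if idx.size)
    R = len(units)
    if R == 1:
        return [[units[0]]]
    per_trait, mean_vec = _unit_vectors(units, records, P)

    metric = None
    support = None
    if ld is not None:
        support = np.asarray(sorted({int(j) for rec in records
                                     for idx, _ in rec.xi.values()
                                     for j in idx.tolist()}), dtype=np.intp)
        A = np.abs(np.asarray(ld(support.tolist()), dtype=float))
        A = np.nan_to_num(A, nan=0.0)
        np.fill_diagonal(A, 1.0)
        metric = A

    def _restrict(M):
        return M[:, support] if support is not None else M

    sim_sum = np.zeros((R, R))
    sim_cnt = np.zeros((R, R))
    for vecs in per_trait.values():
        rows = sorted(vecs)
        M = np.vstack([vecs[i] for i in rows])
        S = _cosine_rows(_restrict(M), metric)
        ix = np.asarray(rows)
        sim_sum[np.ix_(ix, ix)] += S
        sim_cnt[np.ix_(ix, ix)] += 1
    fallback = _cosine_rows(_restrict(mean_vec), metric)
    with np.errstate(invalid="ignore"):
        sim = np.where(sim_cnt > 0, sim_sum / np.maximum(sim_cnt, 1), fallback)

    G = nx.Graph()
    G.add_nodes_from(range(R))
    for a in range(R):
        for b in range(a + 1, R):
            if sim[a, b] > sim_min:
                G.add_edge(a, b, weight=float(sim[a, b]))
    comms = nx.community.greedy_modularity_communities(G, weight="weight")

    parent = {i: i for i in range(R)}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for comm in comms:
        comm = sorted(comm)
        for b in comm[1:]:
            union(comm[0], b)
    by_anchor: dict[int, int] = {}
    for i, u in enumerate(units):
        if u.anchor in by_anchor:
            union(by_anchor[u.anchor], i)
        else:
            by_anchor[u.anchor] = i

    clusters: dict[int, list[int]] = {}
    for i in range(R):
        clusters.setdefault(find(i), []).append(i)
    out = [[units[i] for i in sorted(c)] for c in clusters.values()]
    return sorted(out, key=lambda c: (c[0].record, c[0].anchor))


def event_weights(cluster, records, P: int | None = None, v: float = 1.5):
    """Per-trait and combined variant weights for one cluster.

    ``W_jls`` is the gain-weighted average of the per-round weight vectors
    (each already normalized to sum 1); ``W_js = (prod_l W_jls)^(v/|T_s|)``
    over the traits with positive aggregate gain in the cluster.

    ``cluster`` may contain :class:`SecUnit` items or plain record
    positions (in which case every trait of the record contributes).

    Returns ``(w_trait, w_js, trait_gain)``.
    """
    cluster = list(cluster)
    if not cluster:
        raise ValueError("empty cluster")
    pairs = []  # (record, trait) contributions
    for item in cluster:
        if isinstance(item, SecUnit):
            pairs.extend((item.record, tid) for tid in item.traits)
        else:
            pairs.extend((int(item), tid) for tid in records[int(item)].xi)
    if P is None:
        P = 1 + max(int(records[k].xi[t][0].max()) for k, t in pairs
                    if records[k].xi[t][0].size)
    acc: dict[str, np.ndarray] = {}
    gain: dict[str, float] = {}
    for k, tid in pairs:
        rec = records[k]
        idx, w = rec.xi[tid]
        g = rec.gain.get(tid, 0.0)
        if g <= 0:
            continue
        vec = acc.setdefault(tid, np.zeros(P))
        np.add.at(vec, idx, g * w)
        gain[tid] = gain.get(tid, 0.0) + g
    w_trait = {tid: acc[tid] / gain[tid] for tid in acc if gain[tid] > 0}
    if not w_trait:
        raise ValueError("cluster has zero total likelihood gain")
    w_js = combine_trait_weights(w_trait, v)
    return w_trait, w_js, gain


def combine_trait_weights(w_trait: dict[str, np.ndarray], v: float = 1.5):
    """Cross-trait weight combination ``(prod_l W_jls)^(v/|T|)``."""
    T = len(w_trait)
    stack = np.vstack(list(w_trait.values()))
    with np.errstate(divide="ignore"):
        logw = np.where(stack > 0, np.log(np.maximum(stack, 1e-300)), -np.inf)
    s = logw.sum(axis=0)
    out = np.zeros(stack.shape[1])
    ok = np.isfinite(s)
    out[ok] = np.exp((v / T) * s[ok])
    return out


def build_cos(w_js, alpha: float = 0.95):
    """Smallest weight-ordered variant set reaching cumulative mass alpha.

    Weights are normalized to sum 1 over the locus first; ties in the
    descending sort break to the lower variant index.
    """
    w = np.asarray(w_js, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("all-zero weights")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    wn = w / tot
    order = np.argsort(-wn, kind="stable")
    cum = np.cumsum(wn[order])
    k = int(np.searchsorted(cum, alpha - 1e-12)) + 1
    k = min(k, order.shape[0])
    if alpha == 1.0:  # exclude trailing zero-weight variants
        k = int(np.count_nonzero(wn[order] > 0))
    return order[:k]


def cos_purity(cos, ld_matrix):
    """Minimum absolute pairwise correlation within a CoS.

    ``ld_matrix`` is aligned with ``cos``; NaN pairs are skipped and the
    second return value flags whether any pair was unavailable.
    """
    m = len(cos)
    if m <= 1:
        return 1.0, False
    iu = np.triu_indices(m, k=1)
    vals = np.abs(np.asarray(ld_matrix, dtype=float)[iu])
    ok = np.isfinite(vals)
    if not ok.any():
        return 0.0, True
    return float(vals[ok].min()), bool((~ok).any())


def _prune_memberships(raw_events, fit: BoostFit):
    """Drop trait memberships with negligible likelihood contribution."""
    cfg = fit.config
    total = {tid: 0.0 for tid in fit.trait_ids}
    for rec in fit.records:
        for tid, g in rec.gain.items():
            total[tid] += g
    best = {tid: 0.0 for tid in fit.trait_ids}
    for ev in raw_events:
        for tid, g in ev["trait_gain"].items():
            best[tid] = max(best[tid], g)
    for ev in raw_events:
        keep = {}
        for tid, g in ev["trait_gain"].items():
            if total[tid] <= 0:
                continue
            if g / total[tid] < cfg.gain_rel_min:
                continue
            if g < cfg.gain_event_frac * best[tid]:
                continue
            keep[tid] = g
        ev["trait_gain"] = keep
        ev["w_trait"] = {tid: ev["w_trait"][tid] for tid in keep}
    return raw_events


def purity_and_filters(events, fit: BoostFit, config: BoostConfig | None = None):
    """Apply purity, trait-count and redundancy filters to built events.

    Drops events whose CoS purity falls below the configured minimum,
    drops events left with fewer than two traits (unless they contain the
    focal trait in disease-prioritized mode), merges highly correlated
    CoS, and labels the surviving events primary/secondary by total gain.
    """
    cfg = config or fit.config
    kept = []
    for ev in events:
        if not ev.traits:
            continue
        if len(ev.traits) < 2 and not (fit.focal and fit.focal in ev.traits):
            continue
        if ev.purity < cfg.purity_min:
            continue
        kept.append(ev)
    kept = _merge_correlated(kept, fit, cfg)
    kept.sort(key=lambda e: -e.gain)
    for i, ev in enumerate(kept):
        ev.event_id = i
        ev.label = "primary" if i == 0 else "secondary"
    return kept


def _merge_correlated(events, fit: BoostFit, cfg: BoostConfig):
    """Merge events whose CoS overlap heavily and share a lead signal."""
    events = list(events)
    merged = True
    while merged and len(events) > 1:
        merged = False
        for a in range(len(events)):
            for b in range(a + 1, len(events)):
                ea, eb = events[a], events[b]
                sa, sb = set(ea.cos.tolist()), set(eb.cos.tolist())
                jac = len(sa & sb) / len(sa | sb)
                lead = fit.ld_submatrix([int(ea.cos[0]), int(eb.cos[0])])[0, 1]
                lead_ok = np.isfinite(lead) and abs(lead) > cfg.merge_lead_ld
                # two descriptions of one effect: heavily shared variants,
                # or lead variants that are tight LD proxies (a compact CoS
                # re-anchored on a proxy has Jaccard 0 yet is the same
                # signal)
                if not (jac > cfg.merge_jaccard or lead_ok):
                    continue
                hi, lo = (ea, eb) if ea.gain >= eb.gain else (eb, ea)
                tot = hi.gain + lo.gain
                w_full = (hi.gain * hi.w_full + lo.gain * lo.w_full) / tot
                w_full = w_full / w_full.sum()
                ev = _event_from_weights(
                    w_full, hi.w_trait, dict(hi.trait_gain), fit, cfg,
                    rounds=sorted(set(hi.rounds) | set(lo.rounds)),
                )
                events = [e for k, e in enumerate(events) if k not in (a, b)]
                events.append(ev)
                merged = True
                break
            if merged:
                break
    return events


def _event_from_weights(w_full, w_trait, trait_gain, fit, cfg, rounds):
    cos = build_cos(w_full, cfg.coverage)
    ldm = fit.ld_submatrix(cos.tolist())
    purity, flagged = cos_purity(cos.tolist(), ldm)
    wn = w_full / w_full.sum()
    return ColocEvent(
        event_id=-1,
        cos=cos,
        cos_ids=[fit.variant_ids[j] for j in cos],
        w=wn[cos],
        w_full=wn,
        traits=sorted(trait_gain),
        w_trait=w_trait,
        trait_gain=trait_gain,
        purity=purity,
        coverage=cfg.coverage,
        rounds=list(rounds),
        ld_flagged=flagged,
    )


def assemble_events(fit: BoostFit, config: BoostConfig | None = None):
    """Full postprocessing pipeline: records -> retained ColocEvents."""
    cfg = config or fit.config
    if not fit.records:
        return []
    P = len(fit.variant_ids)
    clusters = cluster_sec(fit.records, P=P, sim_min=cfg.cluster_sim_min,
                           ld=fit.ld_submatrix)
    raw = []
    for cl in clusters:
        try:
            w_trait, w_js, gain = event_weights(
                cl, fit.records, P=P, v=cfg.weight_power)
        except ValueError:
            continue
        raw.append({"cluster": cl, "w_trait": w_trait, "trait_gain": gain})
    raw = _prune_memberships(raw, fit)
    events = []
    for ev in raw:
        if not ev["trait_gain"]:
            continue
        w_js = combine_trait_weights(ev["w_trait"], cfg.weight_power)
        if w_js.sum() <= 0:
            continue
        events.append(_event_from_weights(
            w_js / w_js.sum(), ev["w_trait"], ev["trait_gain"],
            fit, cfg,
            rounds=sorted({u.record for u in ev["cluster"]}),
        ))
    return purity_and_filters(events, fit, cfg)


@dataclass
class ColocResult:
    """Events, per-variant scores, and the underlying boosting fit."""

    fit: BoostFit
    events: list[ColocEvent]

    @property
    def vcp(self) -> np.ndarray:
        return vcp_scores(self.events, len(self.fit.variant_ids))

    @property
    def variant_ids(self) -> list[str]:
        return self.fit.variant_ids


def colocalize(datasets, ld=None, config: BoostConfig | None = None,
               focal: str | None = None) -> ColocResult:
    """Fit the coupled boosting model and assemble colocalization events.

    The one-call entry point: runs :func:`secboost.coupling.fit` and the
    full postprocessing pipeline.  ``focal`` switches to the
    disease-prioritized mode.
    """
    from .coupling import fit as _fit

    bf = _fit(datasets, ld=ld, config=config, focal=focal)
    return ColocResult(fit=bf, events=assemble_events(bf))


def vcp_scores(events, P: int):
    """Per-variant colocalization probability for one locus.

    ``VCP_j = 1 - prod_s (1 - W_js)`` over the retained events of the
    locus, using locus-normalized weights; values lie in [0, 1].
    """
    vcp = np.zeros(P)
    one_minus = np.ones(P)
    for ev in events:
        one_minus *= np.clip(1.0 - ev.w_full, 0.0, 1.0)
    vcp = 1.0 - one_minus
    return vcp


def max_vcp(per_gene):
    """MaxVCP variant annotation: the maximum VCP across genes.

    ``per_gene`` maps gene ids to ``(variant_ids, vcp_array)`` pairs;
    returns a dict variant id -> MaxVCP.
    """
    out: dict[str, float] = {}
    for ids, vcp in per_gene.values():
        for vid, val in zip(ids, vcp):
            if val > out.get(vid, 0.0):
                out[vid] = float(val)
    return out
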