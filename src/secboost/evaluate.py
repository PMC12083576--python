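"""Benchmark statistics for simulated colocalization experiments.

The headline metrics are deliberately stringent, scored at the level of a
whole colocalization configuration:

* **power** — for each true causal variant j with true trait set T_j, an
  event earns credit only if its confidence set contains j *and* its
  trait set is a subset of T_j; the credit is the number of correctly
  assigned traits, and power is total credit over total true trait
  assignments.
* **FDR** — an event is a false discovery if its confidence set misses
  every causal variant, or contains one but assigns any trait outside
  that variant's true set.

Variant-level ranking quality is summarized by precision-recall curves of
the per-variant colocalization probabilities, gene-level metrics mirror
region-based benchmarks (focal-trait detection after merging nested
configurations), and the excess-of-overlap statistic quantifies agreement
between two sets of variant-gene links against chance, with jackknife
standard errors over blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PowerFDR",
    "power_fdr",
    "variant_prc",
    "merge_nested",
    "gene_level_metrics",
    "eoo",
]


@dataclass
class PowerFDR:
    power: float
    fdr: float | None      # None when no events were detected
    coverage: float | None  # fraction of events containing a causal variant
    n_events: int
    n_causal: int


def _truth_sets(truth):
    """Accept a SimTruth or a plain {variant key: trait set} mapping."""
    if hasattr(truth, "trait_sets"):
        return truth.trait_sets()
    return {j: set(t) for j, t in dict(truth).items()}


def _cos_set(ev):
    cos = ev.cos
    return set(cos.tolist()) if isinstance(cos, np.ndarray) else set(cos)


def power_fdr(truths, events_per_locus) -> PowerFDR:
    """Stringent configuration-level power, FDR and coverage.

    ``truths`` and ``events_per_locus`` are aligned lists over loci;
    each truth is a SimTruth (or mapping causal variant -> trait set) and
    each events entry a list of ColocEvent.
    """
    truths = list(truths)
    events_per_locus = list(events_per_locus)
    if len(truths) != len(events_per_locus):
        raise ValueError("truths and events are not aligned by locus")
    credit = 0
    denom = 0
    n_false = 0
    n_events = 0
    n_cov = 0
    for truth, events in zip(truths, events_per_locus):
        tsets = _truth_sets(truth)
        for j, T_true in tsets.items():
            denom += len(T_true)
            best = 0
            for ev in events:
                That = set(ev.traits)
                if j in _cos_set(ev) and That <= T_true:
                    best = max(best, len(T_true & That))
            credit += best
        for ev in events:
            n_events += 1
            cos = _cos_set(ev)
            That = set(ev.traits)
            hit = any(j in cos for j in tsets)
            ok = any(j in cos and That <= tsets[j] for j in tsets)
            n_cov += int(hit)
            n_false += int(not ok)
    return PowerFDR(
        power=credit / denom if denom else float("nan"),
        fdr=n_false / n_events if n_events else None,
        coverage=n_cov / n_events if n_events else None,
        n_events=n_events,
        n_causal=sum(len(_truth_sets(t)) for t in truths),
    )


def variant_prc(scores, positives):
    """Precision-recall curve and AUPRC of per-variant scores.

    Thresholds sweep the unique score values; the area uses the step-wise
    (no linear interpolation) summation ``sum_i (R_i - R_{i-1}) P_i``, the
    conservative convention for precision-recall curves.

    Returns ``(precision, recall, thresholds, auprc)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.zeros(s.shape[0], dtype=bool)
    pos = np.asarray(list(positives), dtype=np.intp) \
        if not isinstance(positives, np.ndarray) else positives
    if pos.dtype == bool:
        y = pos.astype(bool)
    else:
        y[pos] = True
    if not y.any():
        raise ValueError("no positive variants in the truth")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # operating points at the last instance of each distinct score
    last = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / y.sum()
    thresholds = s_sorted[last]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    auprc = float(np.sum((recall - r_prev) * precision))
    return precision, recall, thresholds, auprc


def merge_nested(configs):
    """Merge trait configurations that are identical or strictly nested.

    E.g. {1,2} and {1,2,3} merge into {1,2,3}.  Returns the maximal
    configurations, sorted for determinism.
    """
    sets = [frozenset(c) for c in configs]
    out = []
    for c in sets:
        if any(c < d for d in sets):
            continue
        if c not in out:
            out.append(c)
    return sorted((set(c) for c in out), key=lambda c: sorted(c))


def gene_level_metrics(truths, events_per_locus, focal):
    """Gene(region)-level power and FDR for a focal trait.

    A gene is truly colocalized if any true configuration contains the
    focal trait; it counts as detected if, after merging nested
    configurations, any detected configuration contains the focal trait.

    Returns ``(power, fdr)``; FDR is None when nothing was detected.
    """
    if focal is None:
        raise ValueError("focal trait must be given")
    n_true = n_hit = n_det = n_fp = 0
    for truth, events in zip(truths, events_per_locus):
        tsets = _truth_sets(truth)
        truly = any(focal in T for T in merge_nested(tsets.values())) \
            if tsets else False
        det_cfgs = merge_nested([set(ev.traits) for ev in events]) \
            if events else []
        detected = any(focal in c for c in det_cfgs)
        n_true += int(truly)
        n_hit += int(truly and detected)
        n_det += int(detected)
        n_fp += int(detected and not truly)
    power = n_hit / n_true if n_true else float("nan")
    fdr = n_fp / n_det if n_det else None
    return power, fdr


def eoo(overlap, n1, T1, n2, T2, T12, blocks=None):
    """Excess of overlap between two sets of variant-gene links.

    ``EOO = (|VG1 ∩ VG2| / T12) / ((|VG1|/T1) (|VG2|/T2))`` — the ratio of
    the observed shared fraction to its expectation under independence
    (EOO = 1 exactly at chance level).

    ``blocks``, when given, is a sequence of per-block count tuples
    ``(overlap, n1, T1, n2, T2, T12)`` (e.g. per chromosome); the standard
    error then comes from leave-one-block-out jackknifing.

    Returns ``(eoo, se)`` with ``se = None`` when no blocks are supplied.
    """
    for name, v in [("n1", n1), ("T1", T1), ("n2", n2), ("T2", T2),
                    ("T12", T12)]:
        if v <= 0:
            raise ValueError(f"count {name} must be positive")
    point = (overlap / T12) / ((n1 / T1) * (n2 / T2))
    if blocks is None:
        return point, None
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("blocks must be (B, 6) count tuples")
    tot = arr.sum(axis=0)
    B = arr.shape[0]
    if B < 2:
        raise ValueError("need at least 2 blocks for a jackknife")
    thetas = []
    for i in range(B):
        o, a1, t1, a2, t2, t12 = tot - arr[i]
        if min(a1, t1, a2, t2, t12) <= 0:
            raise ValueError("leave-one-out block leaves a zero denominator")
        thetas.append((o / t12) / ((a1 / t1) * (a2 / t2)))
    thetas = np.asarray(thetas)
    se = float(np.sqrt((B - 1) / B * np.sum((thetas - thetas.mean()) ** 2)))
    return point, se
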