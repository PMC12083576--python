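"""Event assembly: clustering, weights, CoS, purity, VCP."""

import numpy as np
import pytest

import secboost as sb
from secboost.learner import UpdateRecord
from secboost.postprocess import (
    build_cos,
    cluster_sec,
    combine_trait_weights,
    cos_purity,
    event_weights,
    max_vcp,
    sec_units,
    vcp_scores,
)


def rec(k, anchors, xi, gains, mode="coupled"):
    """Shorthand UpdateRecord: xi maps trait -> (indices, weights)."""
    return UpdateRecord(
        round=k, mode=mode, anchor=anchors,
        xi={t: (np.asarray(i, dtype=np.intp), np.asarray(w, dtype=float))
            for t, (i, w) in xi.items()},
        signs={t: np.ones(len(v[0])) for t, v in xi.items()},
        eta={t: 0.1 for t in xi},
        gain=gains,
    )


class TestClusterSec:
    def test_single_anchor_one_cluster(self):
        records = [
            rec(k, {"T1": 3}, {"T1": ([3, 4], [0.9, 0.1])}, {"T1": 1.0})
            for k in range(4)
        ]
        clusters = cluster_sec(records, P=10)
        assert len(clusters) == 1
        assert len(clusters[0]) == 4

    def test_disjoint_supports_two_clusters(self):
        records = [
            rec(0, {"T1": 0}, {"T1": ([0, 1], [0.8, 0.2])}, {"T1": 1.0}),
            rec(1, {"T1": 5}, {"T1": ([5, 6], [0.7, 0.3])}, {"T1": 1.0}),
            rec(2, {"T1": 0}, {"T1": ([0, 1], [0.75, 0.25])}, {"T1": 1.0}),
        ]
        clusters = cluster_sec(records, P=8)
        parts = sorted(tuple(sorted(u.record for u in c)) for c in clusters)
        assert parts == [(0, 2), (1,)]

    def test_mixed_anchor_round_splits_into_units(self):
        # one trait-specific round touching two effects must not bridge them
        records = [
            rec(0, {"T1": 0}, {"T1": ([0], [1.0])}, {"T1": 2.0}),
            rec(1, {"T1": 0, "T2": 5},
                {"T1": ([0], [1.0]), "T2": ([5], [1.0])},
                {"T1": 1.0, "T2": 1.0}, mode="trait-specific"),
            rec(2, {"T2": 5}, {"T2": ([5], [1.0])}, {"T2": 2.0}),
        ]
        units = sec_units(records)
        assert len(units) == 4
        clusters = cluster_sec(records, P=8)
        anchor_sets = sorted(({u.anchor for u in c} for c in clusters),
                             key=sorted)
        assert anchor_sets == [{0}, {5}]

    def test_two_block_partition_matches_exhaustive_modularity(self):
        """Interleaved partially-overlapping supports on two blocks: the
        recovered partition maximizes modularity over all 2-partitions."""
        rng = np.random.default_rng(3)
        records = []
        for k in range(6):
            block = k % 2
            base = 0 if block == 0 else 25
            # anchor-centred decaying weights with per-round jitter, a
            # partially shifting support, and alternating anchors so the
            # partition rests on modularity rather than anchor forcing
            lead = (k // 2) % 2
            idx = np.array([base + lead, base + 1 - lead,
                            base + 2 + (k % 3)])
            w = np.array([0.6, 0.3, 0.1]) + rng.uniform(0, 0.05, 3)
            w = w / w.sum()
            records.append(rec(k, {"T1": int(idx[0])},
                               {"T1": (idx, w)}, {"T1": 1.0}))
        clusters = cluster_sec(records, P=50)
        got = sorted(tuple(sorted(u.record for u in c)) for c in clusters)
        assert got == [(0, 2, 4), (1, 3, 5)]

        # exhaustive check: no 2-partition of rounds has higher modularity
        import networkx as nx
        from secboost.postprocess import _unit_vectors, _cosine_rows
        units = sec_units(records)
        per_trait, _ = _unit_vectors(units, records, 50)
        M = np.vstack([per_trait["T1"][i] for i in range(6)])
        S = _cosine_rows(M)
        G = nx.Graph()
        G.add_nodes_from(range(6))
        for a in range(6):
            for b in range(a + 1, 6):
                if S[a, b] > 0.5:
                    G.add_edge(a, b, weight=S[a, b])
        best_q, best_part = -np.inf, None
        for mask in range(1, 2 ** 5):  # proper 2-partitions up to symmetry
            A = [i for i in range(6) if (mask >> i) & 1 or i == 5]
            B = [i for i in range(6) if i not in A]
            if not B:
                continue
            q = nx.community.modularity(G, [set(A), set(B)], weight="weight")
            if q > best_q:
                best_q, best_part = q, sorted([tuple(sorted(A)),
                                               tuple(sorted(B))])
        assert got == best_part


class TestEventWeights:
    def test_gain_weighted_mean(self):
        # gains [1, 3], rescaled xi for one variant [0.8, 0.4] -> 0.5
        records = [
            rec(0, {"T1": 0}, {"T1": ([0, 1], [0.8, 0.2])}, {"T1": 1.0}),
            rec(1, {"T1": 0}, {"T1": ([0, 1], [0.4, 0.6])}, {"T1": 3.0}),
        ]
        w_trait, w_js, gain = event_weights(sec_units(records), records, P=3)
        assert w_trait["T1"][0] == pytest.approx((0.8 + 3 * 0.4) / 4)
        assert gain["T1"] == pytest.approx(4.0)

    def test_power_mean_combination(self):
        # |T|=2, W1=0.5, W2=0.8, v=1.5 -> 0.4^0.75
        w = combine_trait_weights(
            {"a": np.array([0.5]), "b": np.array([0.8])}, v=1.5)
        assert w[0] == pytest.approx(0.4 ** 0.75)
        assert w[0] == pytest.approx(0.5030, abs=5e-4)

    def test_single_trait_power(self):
        w = combine_trait_weights({"a": np.array([0.6])}, v=1.5)
        assert w[0] == pytest.approx(0.6 ** 1.5)

    def test_zero_gain_cluster_rejected(self):
        records = [rec(0, {"T1": 0}, {"T1": ([0], [1.0])}, {"T1": 0.0})]
        with pytest.raises(ValueError, match="zero total"):
            event_weights(sec_units(records), records, P=2)

    def test_support_removal_never_increases_weight(self):
        """Dropping a round from a cluster cannot raise the weight of a
        variant that round supported."""
        records = [
            rec(0, {"T1": 0}, {"T1": ([0, 1], [0.9, 0.1])}, {"T1": 2.0}),
            rec(1, {"T1": 0}, {"T1": ([0, 1], [0.7, 0.3])}, {"T1": 1.0}),
        ]
        full, *_ = event_weights(sec_units(records), records, P=3)
        reduced, *_ = event_weights(sec_units(records[:1]), records, P=3)
        assert reduced["T1"][1] <= full["T1"][1] + 1e-12


class TestBuildCos:
    @pytest.mark.parametrize("w,alpha,expected", [
        ([0.6, 0.3, 0.08, 0.02], 0.95, [0, 1, 2]),
        ([0.0, 1.0, 0.0], 0.95, [1]),
    ])
    def test_examples(self, w, alpha, expected):
        assert build_cos(np.array(w), alpha).tolist() == expected

    def test_uniform_weights(self):
        cos = build_cos(np.full(100, 0.01), alpha=0.95)
        assert len(cos) == 95

    def test_alpha_one_spans_positive_weights(self):
        cos = build_cos(np.array([0.2, 0.0, 0.8]), alpha=1.0)
        assert sorted(cos.tolist()) == [0, 2]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            build_cos(np.zeros(4), 0.95)

    def test_ties_break_to_lower_index(self):
        cos = build_cos(np.array([0.25, 0.25, 0.25, 0.25]), alpha=0.5)
        assert cos.tolist() == [0, 1]


class TestPurityAndVcp:
    def test_singleton_purity(self):
        assert cos_purity([3], np.array([[1.0]])) == (1.0, False)

    def test_min_of_pairs(self):
        R = np.array([[1.0, 0.9, 0.6], [0.9, 1.0, -0.7], [0.6, -0.7, 1.0]])
        purity, flagged = cos_purity([0, 1, 2], R)
        assert purity == pytest.approx(0.6)
        assert not flagged

    def test_missing_pairs_flagged(self):
        R = np.array([[1.0, np.nan], [np.nan, 1.0]])
        purity, flagged = cos_purity([0, 1], R)
        assert flagged

    def test_vcp_closed_forms(self):
        class _E:
            def __init__(self, w): self.w_full = np.asarray(w)
        assert vcp_scores([_E([0.5, 0.0])], 2)[0] == pytest.approx(0.5)
        v = vcp_scores([_E([0.4, 0]), _E([0.5, 0])], 2)
        assert v[0] == pytest.approx(1 - 0.6 * 0.5)

    def test_max_vcp(self):
        out = max_vcp({"g1": (["a", "b"], [0.7, 0.1]),
                       "g2": (["a", "c"], [0.2, 0.9])})
        assert out == {"a": 0.7, "b": 0.1, "c": 0.9}


class TestFilters:
    def test_low_purity_event_dropped(self):
        """A locus where the only coupling spans two uncorrelated variants
        yields no retained event."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 4))
        ids = list("abcd")
        shared = 0.4 * x[:, 0] + 0.4 * x[:, 2]
        y1 = shared + rng.standard_normal(500)
        y2 = shared + rng.standard_normal(500)
        dss = [sb.TraitDataset.from_raw("T1", y1, x, ids),
               sb.TraitDataset.from_raw("T2", y2, x, ids)]
        res = sb.colocalize(dss)
        for ev in res.events:
            assert ev.purity >= 0.5

    def test_bounds_everywhere(self, shared_signal_locus):
        res = sb.colocalize(shared_signal_locus.datasets)
        assert res.events, "expected one event on a 5%-PVE shared signal"
        for ev in res.events:
            assert 0 <= ev.purity <= 1
            assert np.all(ev.w_full >= 0) and np.all(ev.w_full <= 1)
            assert ev.w_full.sum() == pytest.approx(1.0)
            assert ev.w.sum() >= ev.coverage - 1e-9
            for wt in ev.w_trait.values():
                assert np.all(wt >= -1e-15) and np.all(wt <= 1 + 1e-12)
        v = res.vcp
        assert np.all(v >= 0) and np.all(v <= 1)
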