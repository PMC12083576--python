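"""Multi-trait scheduling logic and the full boosting loop."""

import numpy as np
import pytest

import secboost as sb
from secboost.core import LDReference
from secboost.coupling import (
    BoostConfig,
    _rel_gap,
    _work_from_dataset,
    best_joint_variant,
    check_equivalence,
    schedule_round,
    fineboost,
)
from secboost.sumstats import harmonize
from conftest import make_trait


def make_works(datasets):
    universe, masks = harmonize(datasets)
    cache = {}
    return [_work_from_dataset(d, m, cache) for d, m in zip(datasets, masks)]


class TestBestJointVariant:
    def test_l1_aggregation(self, rng):
        # |X^T r| rows [3,1] and [1,2.5] -> sums [4, 3.5] -> variant 0
        n = 4
        X1 = np.zeros((n, 2)); X2 = np.zeros((n, 2))
        X1[0, 0], X1[1, 1] = 3.0, 1.0
        X2[0, 0], X2[1, 1] = -1.0, 2.5
        r = np.zeros(n); r[0] = 1.0; r2 = np.zeros(n); r2[0] = 1.0; r2[1] = 1.0

        class _D:  # minimal dataset view
            def __init__(self, X): self.X = X
        assert best_joint_variant([r, r2], [_D(X1), _D(X2)]) == 0

    def test_single_trait_reduces_to_argmax(self, rng):
        ds = make_trait(rng, n=50, p=7, beta=[0, 0, 0.8, 0, 0, 0, 0])
        j = best_joint_variant([ds.Y], [ds])
        assert j == int(np.argmax(np.abs(ds.X.T @ ds.Y)))

    def test_matches_exhaustive_scan(self, rng):
        dss = [make_trait(rng, n=40, p=20, trait_id=f"T{i}") for i in range(3)]
        rs = [d.Y for d in dss]
        got = best_joint_variant(rs, dss)
        scores = [sum(abs(float(d.X[:, j] @ r)) for d, r in zip(dss, rs))
                  for j in range(20)]
        assert got == int(np.argmax(scores))


class TestEquivalence:
    def test_identity_always_equivalent(self, rng):
        ds = make_trait(rng, n=30, p=4)
        ld = LDReference.from_genotypes(ds.X, ds.variant_ids)
        assert check_equivalence(2, 2, ds, ld, epsilon=1e-9)

    def test_low_ld_gate(self, rng):
        # |LD| = 0.5 < 0.8 -> never equivalent
        ds = make_trait(rng, n=200, p=2)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDReference(R, ds.variant_ids)
        assert not check_equivalence(0, 1, ds, ld)

    def test_relative_gap_rule(self):
        # delta-loglik pair (2.00, 1.90): relative gap 0.05 < 0.1
        assert _rel_gap(2.0, 1.9) == pytest.approx(0.05)
        assert _rel_gap(2.0, 1.9) < 0.1
        assert _rel_gap(2.0, 1.0) > 0.1

    def test_tight_proxy_equivalent(self, rng):
        # nearly collinear columns with one shared signal
        x = rng.standard_normal(300)
        X = np.column_stack([x, x + 0.05 * rng.standard_normal(300)])
        y = 0.5 * x + rng.standard_normal(300)
        ds = sb.TraitDataset.from_raw("t", y, X, ["a", "b"])
        ld = LDReference.from_genotypes(X, ["a", "b"])
        assert check_equivalence(0, 1, ds, ld)


class TestScheduling:
    def test_logic1_shared_causal(self, rng):
        x = rng.standard_normal((400, 6))
        shared = x[:, 0]
        dss = []
        for i in range(2):
            y = 0.6 * shared + rng.standard_normal(400)
            dss.append(sb.TraitDataset.from_raw(
                f"T{i+1}", y, x, [f"v{j}" for j in range(6)]))
        plan = schedule_round(make_works(dss), BoostConfig())
        assert plan.mode == "coupled"
        assert plan.updates[0][1] == ("T1", "T2")

    def test_sublogic22_private_signals(self, rng):
        """Each trait's best is private (mutual LD ~ 0) and the joint best
        j* (a weaker shared variant) is equivalent to neither: every trait
        updates at its own anchor."""
        x = rng.standard_normal((400, 6))  # independent columns
        y1 = 0.5 * x[:, 0] + 0.3 * x[:, 2] + rng.standard_normal(400)
        y2 = 0.5 * x[:, 4] + 0.3 * x[:, 2] + rng.standard_normal(400)
        ids = [f"v{j}" for j in range(6)]
        dss = [sb.TraitDataset.from_raw("T1", y1, x, ids),
               sb.TraitDataset.from_raw("T2", y2, x, ids)]
        works = make_works(dss)
        jb = [int(w.idx[w.best_local()]) for w in works]
        assert jb == [0, 4]  # private bests; the joint argmax is v2
        plan = schedule_round(works, BoostConfig())
        assert "trait-specific" in plan.mode
        anchors = {t: j for j, ts in plan.updates for t in ts}
        assert anchors["T1"] == 0 and anchors["T2"] == 4

    def test_logic32_delays_coupling(self, rng):
        """Traits 1+2 share variant 0; trait 3 has a stronger private
        signal at variant 5: the round defers the shared anchor and
        updates trait 3, and a later round couples traits 1+2."""
        x = rng.standard_normal((500, 8))
        ids = [f"v{j}" for j in range(8)]
        y1 = 0.35 * x[:, 0] + rng.standard_normal(500)
        y2 = 0.35 * x[:, 0] + rng.standard_normal(500)
        y3 = 0.60 * x[:, 5] + rng.standard_normal(500)
        dss = [sb.TraitDataset.from_raw(f"T{i+1}", y, x, ids)
               for i, y in enumerate([y1, y2, y3])]
        plan = schedule_round(make_works(dss), BoostConfig())
        assert plan.mode.startswith("delayed")
        updated = {t for _, ts in plan.updates for t in ts}
        assert updated == {"T3"}
        # stepping the full loop: a later round couples T1 and T2
        fit = sb.fit(dss)
        coupled = [r for r in fit.records
                   if set(r.xi) >= {"T1", "T2"} and "T3" not in r.xi]
        assert coupled, "T1/T2 never received their coupled update"

    def test_trait_appears_at_most_once_per_round(self, rng):
        from secboost.coupling import RoundPlan
        with pytest.raises(ValueError):
            RoundPlan("coupled", [(0, ("T1",)), (1, ("T1",))])


class TestFit:
    def test_single_trait_identical_to_fineboost(self, rng):
        loc = sb.simulate_locus(N=500, P=100, L=2, n_causal=1, phi=0.05,
                                seed=5)
        ds = loc.datasets[0]
        f1 = sb.fit([ds])
        f2 = fineboost(ds)
        assert len(f1.records) == len(f2.records)
        for a, b in zip(f1.records, f2.records):
            assert a.anchor == b.anchor and a.mode == b.mode
            np.testing.assert_array_equal(a.xi[ds.trait_id][0],
                                          b.xi[ds.trait_id][0])
            np.testing.assert_array_equal(a.xi[ds.trait_id][1],
                                          b.xi[ds.trait_id][1])
        np.testing.assert_array_equal(f1.beta[ds.trait_id],
                                      f2.beta[ds.trait_id])

    def test_deterministic(self):
        loc = sb.simulate_locus(N=400, P=120, L=3, n_causal=2, phi=0.05,
                                seed=21)
        f1, f2 = sb.fit(loc.datasets), sb.fit(loc.datasets)
        assert [r.anchor for r in f1.records] == [r.anchor for r in f2.records]
        for t in f1.trait_ids:
            np.testing.assert_array_equal(f1.beta[t], f2.beta[t])
            assert f1.rss[t] == f2.rss[t]

    def test_gains_nonnegative_and_sse_monotone(self):
        loc = sb.simulate_locus(N=500, P=150, L=3, n_causal=2, phi=0.05,
                                seed=33)
        fit = sb.fit(loc.datasets)
        assert all(g >= 0 for r in fit.records for g in r.gain.values())
        for t in fit.trait_ids:
            assert fit.rss[t] <= fit.rss0[t]

    def test_residual_identity_holds(self):
        """Moment updates agree with the explicit r = Y - X beta."""
        loc = sb.simulate_locus(N=400, P=100, L=2, n_causal=1, phi=0.05,
                                seed=8)
        fit = sb.fit(loc.datasets)
        for ds in loc.datasets:
            r = ds.Y - ds.X @ fit.beta[ds.trait_id]
            assert float(r @ r) == pytest.approx(fit.rss[ds.trait_id],
                                                 rel=1e-6)

    def test_logic1_dominates_for_fully_shared_causal(self):
        """Single shared causal variant: coupled rounds dominate updates."""
        n_coupled = n_rounds = 0
        for s in range(10):
            loc = sb.simulate_locus(N=800, P=150, L=3, n_causal=1,
                                    phi=0.05, seed=900 + s,
                                    config_table={3: 1.0})
            fit = sb.fit(loc.datasets)
            for r in fit.records:
                if r.mode == "finishing":  # single-trait polish rounds
                    continue
                n_rounds += 1
                n_coupled += int(len(r.xi) > 1 or r.mode == "coupled")
        assert n_coupled / n_rounds >= 0.9

    def test_two_copies_of_trait_colocalize(self):
        """Shared causal at 5% PVE: one event containing both traits."""
        good = 0
        n_rep = 30
        for s in range(n_rep):
            loc = sb.simulate_locus(N=1000, P=150, L=2, n_causal=1,
                                    phi=0.05, seed=4000 + s)
            events = sb.colocalize(loc.datasets).events
            good += int(len(events) == 1 and
                        set(events[0].traits) == {"T1", "T2"})
        assert good / n_rep >= 0.95

    def test_null_data_produces_no_events(self):
        n_with = 0
        for s in range(25):
            loc = sb.simulate_locus(N=600, P=200, L=3, seed=7000 + s,
                                    null=True)
            n_with += int(len(sb.colocalize(loc.datasets).events) > 0)
        assert n_with == 0

    def test_focal_included_when_focal_strongest(self):
        """E-SEC never drops the focal trait when it carries the locus's
        strongest signal."""
        for s in range(5):
            loc = sb.simulate_locus(
                N=900, P=120, L=3, n_causal=1,
                phi={"T1": 0.08, "T2": 0.05, "T3": 0.05},
                seed=600 + s, focal="T1", config_table={2: 0.5, 3: 0.5})
            events = sb.colocalize(loc.datasets, focal="T1").events
            for ev in events:
                assert "T1" in ev.traits

    def test_unknown_focal_rejected(self, rng):
        ds = make_trait(rng, n=40, p=5)
        with pytest.raises(ValueError, match="focal"):
            sb.fit([ds], focal="nope")
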