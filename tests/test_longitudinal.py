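"""Cross-day registration, identity chaining, stability, and the expansion
index."""

import numpy as np
import pandas as pd
import pytest

from nociscope.ensembles import define_ensembles
from nociscope.longitudinal import (allodynia_expansion_index, chain_days,
                                    light_touch_ensemble_fraction,
                                    register_pair, stable_responder_fraction)
from tests.test_ensembles import PANEL, responder_table


def spaced_cloud(rng, n, lo=10.0, hi=290.0, spacing=10.0):
    pts = []
    while len(pts) < n:
        cand = rng.uniform(lo, hi, 2)
        if not pts or np.min(np.hypot(*(np.array(pts) - cand).T)) >= spacing:
            pts.append(cand)
    return np.array(pts)


class TestRegisterPair:
    def test_identity_mapping_for_identical_clouds(self, rng):
        a = spaced_cloud(rng, 40)
        pair = register_pair(a, a.copy(), 5.0)
        assert len(pair.matches) == 40
        assert np.allclose(pair.distances, 0.0, atol=1e-9)
        assert (pair.matches[:, 0] == pair.matches[:, 1]).all()

    def test_global_shift_fully_recovered(self, rng):
        a = spaced_cloud(rng, 60)
        perm = rng.permutation(60)
        b = a[perm] + np.array([2.0, 3.0])
        pair = register_pair(a, b, 5.0)
        assert len(pair.matches) == 60
        assert all(perm[ib] == ia for ia, ib in pair.matches)
        assert np.allclose(pair.translation, [2.0, 3.0], atol=0.5)

    def test_distant_clouds_left_unmatched(self, rng):
        a = spaced_cloud(rng, 10, lo=10, hi=50)
        # restore raw distances: a cloud of different shape far away after
        # median-offset correction still cannot pair within threshold
        b = spaced_cloud(rng, 10, lo=10, hi=290, spacing=25.0)
        pair = register_pair(a, b, max_distance=0.5)
        assert len(pair.matches) == 0
        assert len(pair.unmatched_a) == 10 and len(pair.unmatched_b) == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            register_pair(np.zeros((0, 2)), np.ones((3, 2)), 5.0)

    def test_precision_recall_under_jitter_and_drift(self, rng):
        """<=1 px jitter and <=3 px drift at 5 px threshold: >= 0.95."""
        precision, recall = [], []
        for _ in range(10):
            a = spaced_cloud(rng, 100)
            perm = rng.permutation(len(a))
            b = a[perm] + rng.uniform(-3, 3, 2) + rng.standard_normal((len(a), 2))
            pair = register_pair(a, b, 5.0)
            correct = sum(1 for ia, ib in pair.matches if perm[ib] == ia)
            precision.append(correct / len(pair.matches))
            recall.append(correct / len(a))
        assert np.mean(precision) >= 0.95 and np.mean(recall) >= 0.95


def pair_from_permutation(rng, n, perm, day_a, day_b):
    a = spaced_cloud(rng, n)
    b = a[perm]
    return register_pair(a, b, 5.0, day_a=day_a, day_b=day_b)


class TestChainDays:
    def test_full_chain_spans_all_days(self, rng):
        perm1, perm2 = rng.permutation(12), rng.permutation(12)
        frags = [pair_from_permutation(rng, 12, perm1, 0, 1),
                 pair_from_permutation(rng, 12, perm2, 1, 2)]
        regmap = chain_days(frags)
        assert regmap.days == (0, 1, 2)
        assert len(regmap.gids_spanning(0, 2)) == 12

    def test_missing_intermediate_day_breaks_chain(self, rng):
        a = spaced_cloud(rng, 8)
        b = a[:4]                       # half the cells vanish on day 1
        frag1 = register_pair(a, b, 5.0, day_a=0, day_b=1)
        c = a.copy()                    # they reappear on day 2
        frag2 = register_pair(b, c, 5.0, day_a=1, day_b=2)
        regmap = chain_days([frag1, frag2])
        day0 = regmap.neurons_on(0)
        day2 = regmap.neurons_on(2)
        # cells 4..7 must have fresh global ids on day 2 (no gap jumping)
        for n in range(4, 8):
            assert day2[n] != day0[n]
        for n in range(4):
            assert day2[n] == day0[n]

    def test_matches_brute_force_transitive_closure(self, rng):
        perms = [rng.permutation(10) for _ in range(3)]
        frags = [pair_from_permutation(rng, 10, p, d, d + 1)
                 for d, p in enumerate(perms)]
        regmap = chain_days(frags)
        # oracle: follow each day-0 cell through the permutation chain
        for n0 in range(10):
            gid = regmap.global_ids[(0, n0)]
            n = n0
            for d, p in enumerate(perms):
                n = int(np.argwhere(p == n)[0][0]) if False else int(np.where(p == n)[0][0])
                assert regmap.global_ids[(d + 1, n)] == gid

    def test_chaining_is_associative(self, rng):
        perms = [rng.permutation(15) for _ in range(2)]
        frags = [pair_from_permutation(rng, 15, p, d, d + 1)
                 for d, p in enumerate(perms)]
        full = chain_days(frags)
        first = chain_days(frags[:1])
        ext = chain_days(frags)
        assert full.global_ids == ext.global_ids
        assert all(full.global_ids[k] == first.global_ids[k]
                   for k in first.global_ids)

    def test_endpoint_mismatch_rejected(self, rng):
        frags = [pair_from_permutation(rng, 5, rng.permutation(5), 0, 1),
                 pair_from_permutation(rng, 5, rng.permutation(5), 2, 3)]
        with pytest.raises(ValueError, match="chain"):
            chain_days(frags)


def identity_regmap(n, days):
    gids = {(d, i): i for d in days for i in range(n)}
    return type("RM", (), {
        "days": tuple(days),
        "global_ids": gids,
        "neurons_on": lambda self, day: {i: i for i in range(n)},
        "gids_spanning": lambda self, a, b: set(range(n)),
    })()


class TestStableResponderFraction:
    def test_all_responsive_gives_one(self):
        tables = {d: responder_table({"pin": set(range(6))}, PANEL, 6)
                  for d in (-7, 42)}
        frac = stable_responder_fraction(tables, identity_regmap(6, (-7, 42)))
        assert frac == 1.0

    def test_counts_and_partial_stability(self):
        tables = {-7: responder_table({"pin": {0, 1, 2}}, PANEL, 6),
                  42: responder_table({"noxious_heat": {1, 2, 5}}, PANEL, 6)}
        frac, (stable, aligned) = stable_responder_fraction(
            tables, identity_regmap(6, (-7, 42)), return_counts=True)
        assert (stable, aligned) == (2, 6)
        assert frac == pytest.approx(2 / 6)

    def test_short_span_rejected(self):
        tables = {0: responder_table({}, PANEL, 3),
                  5: responder_table({}, PANEL, 3)}
        with pytest.raises(ValueError, match="min_span_days"):
            stable_responder_fraction(tables, identity_regmap(3, (0, 5)))


class TestExpansionIndex:
    def _sets(self, resp):
        return define_ensembles(responder_table(resp, PANEL, 20), n_neurons=20)

    def test_no_change_is_zero(self):
        s = self._sets({"pin": {0, 1, 2, 3}, "light_touch": {0}})
        assert allodynia_expansion_index(s, s) == 0.0

    def test_zero_pre_fraction_rejected(self):
        pre = self._sets({"pin": {0, 1}})
        post = self._sets({"pin": {0, 1}, "light_touch": {0}})
        with pytest.raises(ValueError, match="undefined"):
            allodynia_expansion_index(pre, post)

    def test_quadrupling_gives_300_percent(self):
        pre = self._sets({"pin": {0, 1, 2, 3}, "light_touch": {0}})
        post = self._sets({"pin": {0, 1, 2, 3}, "light_touch": {0, 1, 2, 3}})
        assert allodynia_expansion_index(pre, post) == pytest.approx(300.0)

    def test_epoch_lists_are_averaged(self):
        a = self._sets({"pin": {0, 1, 2, 3}, "light_touch": {0}})       # 0.25
        b = self._sets({"pin": {0, 1, 2, 3}, "light_touch": {0, 1, 2}})  # 0.75
        idx = allodynia_expansion_index([a, b], [b, b])
        assert idx == pytest.approx(100 * (0.75 - 0.5) / 0.5)

    def test_light_touch_fraction_helper(self):
        s = self._sets({"pin": {0, 1, 2, 3}, "light_touch": {1, 9}})
        assert light_touch_ensemble_fraction(s) == pytest.approx(0.25)
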