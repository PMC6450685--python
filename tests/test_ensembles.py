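"""Responder classification, ensemble definition, overlap algebra, and
activation fractions."""

import numpy as np
import pandas as pd
import pytest

from nociscope.config import NOXIOUS_STIMULI
from nociscope.ensembles import (classify_responders, define_ensembles,
                                 ensemble_activation, overlap_counts)
from nociscope.types import TrialTensor


def zscored_tensor(values, labels, frame_rate=20.0, pre_s=5.0, post_s=10.0):
    return TrialTensor(values=np.asarray(values, dtype=float),
                       trial_labels=np.asarray(labels),
                       window=(pre_s, post_s), frame_rate=frame_rate,
                       zscored=True)


def noise_tensor(rng, n_trials=10, n_neurons=30, label="pin"):
    v = rng.standard_normal((n_trials, n_neurons, 300))
    return zscored_tensor(v, [label] * n_trials)


class TestClassifyResponders:
    def test_planted_deterministic_responder_always_detected(self, rng):
        t = noise_tensor(rng)
        t.values[:, 0, 100:140] += 5.0    # +5 z in the response window
        table = classify_responders(t, n_shuffles=1000, seed=0)
        row = table[(table.neuron == 0)].iloc[0]
        assert row.responsive and row.p_value <= 2 / 1001

    def test_pure_noise_false_discoveries_bounded(self):
        """On null data the responsive fraction stays within 3 binomial SDs
        of the FDR-controlled expectation (which is below q)."""
        fps = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            table = classify_responders(noise_tensor(rng, n_neurons=50),
                                        n_shuffles=1000, seed=seed)
            fps.append(table.responsive.mean())
        # full-null BH: P(any rejection) <= q, so mean FP fraction is tiny
        assert np.mean(fps) <= 0.05 + 3 * np.std(fps) / np.sqrt(len(fps))

    def test_insufficient_trials_names_stimulus(self, rng):
        t = noise_tensor(rng, n_trials=3, label="noxious_cold")
        with pytest.raises(ValueError, match="noxious_cold"):
            classify_responders(t, n_shuffles=1000)

    def test_requires_zscored_input(self, rng):
        t = noise_tensor(rng)
        t.zscored = False
        with pytest.raises(ValueError, match="z-scored"):
            classify_responders(t)

    def test_shuffle_count_floor(self, rng):
        with pytest.raises(ValueError, match="1000"):
            classify_responders(noise_tensor(rng), n_shuffles=100)


def responder_table(resp_map, stimuli, n_neurons):
    rows = []
    for s in stimuli:
        for n in range(n_neurons):
            hit = n in resp_map.get(s, set())
            rows.append((n, s, 1.0 if hit else 0.0, 50.0,
                         0.0001 if hit else 0.9, 0.001 if hit else 0.95, hit))
    return pd.DataFrame(rows, columns=["neuron", "stimulus", "effect",
                                       "null_percentile", "p_value", "q_value",
                                       "responsive"])


PANEL = ("noxious_heat", "noxious_cold", "pin", "light_touch", "sucrose")


class TestDefineEnsembles:
    def test_pin_only_neuron_is_pain_specific(self):
        table = responder_table({"pin": {3}}, PANEL, 10)
        sets = define_ensembles(table, n_neurons=10)
        assert 3 in sets.nociceptive and 3 in sets.pain_specific

    def test_empty_table_gives_empty_sets(self):
        table = responder_table({}, PANEL, 8)
        sets = define_ensembles(table, n_neurons=8)
        assert not sets.nociceptive and not sets.pain_specific
        assert sets.fractions["nociceptive"] == 0.0

    def test_light_touch_responder_not_pain_specific(self):
        table = responder_table({"pin": {1}, "light_touch": {1, 2}}, PANEL, 5)
        sets = define_ensembles(table, n_neurons=5)
        assert 1 in sets.nociceptive and 1 not in sets.pain_specific
        assert 2 not in sets.nociceptive

    def test_missing_noxious_stimulus_rejected(self):
        table = responder_table({}, ("noxious_heat", "pin"), 5)
        with pytest.raises(ValueError, match="noxious_cold"):
            define_ensembles(table, n_neurons=5)

    def test_set_identities(self):
        table = responder_table({"noxious_heat": {0, 1}, "noxious_cold": {1, 2},
                                 "pin": {4}, "light_touch": {2}}, PANEL, 10)
        sets = define_ensembles(table, n_neurons=10)
        assert sets.pain_specific <= sets.nociceptive
        assert sets.nociceptive == frozenset({0, 1, 2, 4})
        assert sets.pain_specific == frozenset({0, 1, 4})


class TestOverlapCounts:
    def test_disjoint_sets_have_zero_intersections(self):
        table = responder_table({"noxious_heat": {0}, "noxious_cold": {1},
                                 "pin": {2}}, PANEL, 6)
        sets = define_ensembles(table, n_neurons=6)
        venn = overlap_counts(sets, list(NOXIOUS_STIMULI))
        multi = venn[venn[[c for c in venn.columns
                           if c.startswith("in_")]].sum(axis=1) > 1]
        assert (multi["count"] == 0).all()

    def test_matches_brute_force_set_algebra_on_hand_labels(self):
        resp = {"noxious_heat": {0, 1, 2, 3}, "noxious_cold": {2, 3, 4},
                "pin": {3, 5}, "light_touch": {1, 3, 6}}
        sets = define_ensembles(responder_table(resp, PANEL, 10), n_neurons=10)
        venn = overlap_counts(sets, ["noxious_heat", "noxious_cold", "pin"])
        universe = set(range(10))
        for _, row in venn.iterrows():
            region = universe.copy()
            for s in ["noxious_heat", "noxious_cold", "pin"]:
                region &= resp[s] if row[f"in_{s}"] else universe - resp[s]
            assert row["count"] == len(region)
        # sum of exclusive regions equals the union size
        union = resp["noxious_heat"] | resp["noxious_cold"] | resp["pin"]
        assert venn["count"].sum() == len(union)

    def test_nociceptive_label_and_guard(self):
        sets = define_ensembles(
            responder_table({"pin": {0, 1}, "light_touch": {1, 2}}, PANEL, 5),
            n_neurons=5)
        venn = overlap_counts(sets, ["light_touch", "nociceptive"])
        both = venn[(venn["in_light_touch"]) & (venn["in_nociceptive"])]
        assert both["count"].iloc[0] == 1
        with pytest.raises(ValueError, match="5 sets"):
            overlap_counts(sets, ["a"] * 6)


class TestEnsembleActivation:
    def test_constructed_fractions(self):
        v = np.zeros((2, 4, 300))
        v[0, :2, 100:140] = 5.0          # half the ensemble active on trial 0
        v[1, :, 100:140] = 5.0           # all active on trial 1
        t = zscored_tensor(v, ["pin", "pin"])
        act = ensemble_activation(t, {0, 1, 2, 3}, z_active=2.0)
        assert act.tolist() == [0.5, 1.0]

    def test_none_active_is_zero(self):
        t = zscored_tensor(np.zeros((1, 3, 300)), ["pin"])
        assert ensemble_activation(t, {0, 1, 2}).tolist() == [0.0]

    def test_empty_ensemble_rejected(self):
        t = zscored_tensor(np.zeros((1, 3, 300)), ["pin"])
        with pytest.raises(ValueError, match="empty"):
            ensemble_activation(t, set())


class TestAmplitudeMonotonicity:
    def test_recovered_fraction_nondecreasing_in_amplitude(self, small_config):
        """Raising the planted response amplitude never reduces the
        recovered responsive fraction (pooled over seeds)."""
        from nociscope.synthetic import generate_session
        from nociscope.preprocessing import slice_trials, zscore_trials
        fracs = []
        for amp in (0.1, 0.35, 1.0):
            vals = []
            for seed in (1, 2):
                cfg = small_config.replace(response_amplitude_dff=amp,
                                           spontaneous_amplitude_dff=1.0)
                session, _ = generate_session(cfg, seed)
                z = zscore_trials(slice_trials(session))
                table = classify_responders(z, n_shuffles=1000, seed=seed)
                vals.append(table.responsive.mean())
            fracs.append(np.mean(vals))
        assert fracs[0] <= fracs[1] + 0.01 <= fracs[2] + 0.02
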