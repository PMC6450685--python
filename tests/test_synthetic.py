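"""Generator contracts: documented tuning fractions (against an independent
enumeration oracle), determinism, kernel exactness, cohort bookkeeping,
longitudinal dynamics, movie rendering, and the copula calibration."""

from itertools import product

import numpy as np
import pytest

from nociscope.config import NOXIOUS_STIMULI, make_default_config, neuropathic_config
from nociscope.synthetic import (coupling_from_spearman, generate_cohort,
                                 generate_longitudinal_cohort, generate_session,
                                 render_movie, solve_noxious_coins,
                                 transient_kernel, tuning_pattern_distribution)
from nociscope.synthetic.tuning import draw_tuning, expected_fractions


def enumerate_fractions_oracle(config):
    """Independent enumeration over the tuning-assignment distribution.

    Re-derives every branch probability from the config fields alone (class
    mass, pain-specific share, conditioned noxious coins, class-conditional
    and baseline non-noxious coins) and sums pattern probabilities without
    using the package's distribution helper.
    """
    panel = config.stimulus_panel
    nox = list(config.noxious_stimuli)
    non_nox = [s for s in panel if s not in nox]
    q = solve_noxious_coins(config)
    # verify the coin solution itself satisfies the conditional-marginal
    # identity r_s = q_s / Z before trusting it
    z = 1.0 - np.prod(1.0 - q)
    for qi, s in zip(q, nox):
        assert qi / z == pytest.approx(
            config.membership_probs[s] / config.ensemble_prob, abs=1e-9)
    base = config.baseline_probs()
    ens, ps = config.ensemble_prob, config.pain_specific_prob

    totals = {s: 0.0 for s in panel}
    union = specific = lt_union = 0.0
    for bits in product((0, 1), repeat=9):
        pattern = dict(zip(panel, bits))
        has_nox = any(pattern[s] for s in nox)
        # P(pattern): sum over the three branches
        prob = 0.0
        if has_nox:
            p_nox = np.prod([q[i] if pattern[s] else 1 - q[i]
                             for i, s in enumerate(nox)]) / z
            if not any(pattern[s] for s in non_nox):
                prob += ens * ps * p_nox
            p_nn = np.prod([config.within_ensemble_probs[s] if pattern[s]
                            else 1 - config.within_ensemble_probs[s]
                            for s in non_nox])
            prob += ens * (1 - ps) * p_nox * p_nn
        else:
            p_nn = np.prod([base[s] if pattern[s] else 1 - base[s]
                            for s in non_nox])
            prob += (1 - ens) * p_nn
        for s in panel:
            if pattern[s]:
                totals[s] += prob
        if has_nox:
            union += prob
            if not any(pattern[s] for s in non_nox):
                specific += prob
            if pattern.get("light_touch"):
                lt_union += prob
    return totals, union, specific, lt_union / union


class TestDefaultConfig:
    def test_neuron_count_and_panel(self, default_config):
        assert default_config.neurons_per_session_mean == 117
        assert len(set(default_config.stimulus_panel)) == 9

    def test_documented_fractions_against_enumeration_oracle(self, default_config):
        totals, union, specific, lt_in = enumerate_fractions_oracle(default_config)
        assert union == pytest.approx(0.24, abs=1e-6)
        assert totals["noxious_heat"] == pytest.approx(0.15, abs=1e-6)
        assert totals["noxious_cold"] == pytest.approx(0.13, abs=1e-6)
        assert totals["pin"] == pytest.approx(0.13, abs=1e-6)
        assert totals["light_touch"] == pytest.approx(0.07, abs=1e-6)
        assert totals["sucrose"] == pytest.approx(0.18, abs=1e-6)
        assert lt_in == pytest.approx(0.18, abs=1e-6)
        assert specific == pytest.approx(0.06, abs=0.002)
        ef = expected_fractions(default_config)
        assert ef["nociceptive"] == pytest.approx(union, abs=1e-9)
        assert ef["pain_specific"] == pytest.approx(specific, abs=1e-9)

    def test_pattern_distribution_sums_to_one(self, default_config):
        dist = tuning_pattern_distribution(default_config)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_rates_match_over_many_draws(self, default_config):
        rng = np.random.default_rng(0)
        tuning, is_ens, is_ps = draw_tuning(default_config, 200_000, rng)
        ef = expected_fractions(default_config)
        for j, s in enumerate(default_config.stimulus_panel):
            emp = tuning[:, j].mean()
            sd = np.sqrt(ef[s] * (1 - ef[s]) / 200_000)
            assert abs(emp - ef[s]) < 4 * sd, s
        assert abs(is_ens.mean() - 0.24) < 4 * np.sqrt(0.24 * 0.76 / 200_000)


class TestGenerateSession:
    def test_byte_identical_determinism(self, small_config):
        s1, t1 = generate_session(small_config, 7)
        s2, t2 = generate_session(small_config, 7)
        assert np.array_equal(s1.traces, s2.traces)
        assert np.array_equal(s1.behavior, s2.behavior)
        assert np.array_equal(s1.centroids, s2.centroids)
        assert np.array_equal(t1.tuning_matrix, t2.tuning_matrix)
        assert [e.onset_s for e in s1.events] == [e.onset_s for e in s2.events]

    def test_mean_neuron_count_near_117(self, small_config):
        cfg = small_config.replace(neurons_per_session_mean=117,
                                   neurons_per_session_sd=8,
                                   trials_per_stimulus=1,
                                   inter_trial_interval_s=(2.0, 3.0),
                                   lead_in_s=5.0, tail_s=5.0)
        counts = [generate_session(cfg, s)[0].n_neurons for s in range(30)]
        sem = np.std(counts, ddof=1) / np.sqrt(30)
        assert abs(np.mean(counts) - 117) < 2 * sem + 1e-9

    def test_zero_noise_matches_convolution_oracle(self, small_config):
        cfg = small_config.replace(noise_sd_dff=0.0, trials_per_stimulus=5)
        session, truth = generate_session(cfg, 3)
        fr = cfg.frame_rate
        t_grid = np.arange(session.n_frames) / fr
        tr, td = cfg.transient_rise_tau, cfg.transient_decay_tau
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        for n in range(0, session.n_neurons, 7):
            dff = np.zeros(session.n_frames)
            for onset, amp in truth.planted_transients[n]:
                dt = t_grid - onset
                # the documented kernel is truncated at 1e-3 of peak
                mask = (dt >= 0) & (dt < td * np.log(1000.0))
                k = (np.exp(-dt[mask] / td) - np.exp(-dt[mask] / tr)) / peak
                dff[mask] += amp * np.clip(k, 0, None)
            expected = cfg.baseline_fluorescence * (1.0 + dff)
            assert np.allclose(session.traces[n], expected, atol=1e-3)

    def test_behavior_stream_length_and_events_sorted(self, small_session):
        session, _ = small_session
        assert len(session.behavior) == session.n_frames
        onsets = [e.onset_s for e in session.events]
        assert onsets == sorted(onsets)
        assert len(session.events) == 9 * 6


class TestKernel:
    def test_unit_peak_and_positivity(self):
        k = transient_kernel(20.0, 0.1, 1.0)
        assert 0.97 <= k.max() <= 1.0  # peak between grid points
        assert np.all(k >= 0)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            transient_kernel(20.0, 1.0, 0.1)


class TestCohorts:
    def test_cohort_count_arithmetic(self, small_config):
        cfg = small_config.replace(n_animals=3, sessions_per_animal=2,
                                   trials_per_stimulus=1,
                                   inter_trial_interval_s=(2.0, 3.0),
                                   lead_in_s=5.0, tail_s=5.0)
        cohort = generate_cohort(cfg, 1)
        assert len(cohort) == 6

    def test_disjoint_seeds_give_distinct_traces(self, small_config):
        cfg = small_config.replace(trials_per_stimulus=1,
                                   inter_trial_interval_s=(2.0, 3.0),
                                   lead_in_s=5.0, tail_s=5.0)
        s1, _ = generate_session(cfg, 1)
        s2, _ = generate_session(cfg, 2)
        assert s1.traces.shape != s2.traces.shape or \
            not np.array_equal(s1.traces, s2.traces)

    def test_full_carryover_keeps_every_global_id(self, small_config):
        cfg = small_config.replace(n_animals=1, sessions_per_animal=3,
                                   carryover_prob=1.0,
                                   neurons_per_session_sd=0,
                                   trials_per_stimulus=1,
                                   inter_trial_interval_s=(2.0, 3.0),
                                   lead_in_s=5.0, tail_s=5.0)
        cohort = generate_cohort(cfg, 4)
        gid_sets = [set(t.global_cell_ids.tolist()) for _, t in cohort]
        assert gid_sets[0] == gid_sets[1] == gid_sets[2]


class TestLongitudinal:
    def _short(self, **kw):
        base = dict(trials_per_stimulus=5, inter_trial_interval_s=(4.0, 6.0),
                    lead_in_s=5.0, tail_s=5.0)
        base.update(kw)
        return neuropathic_config(**base)

    def test_noop_injury_keeps_tuning(self):
        cfg = self._short(n_animals=1, persistence_prob=1.0, carryover_prob=1.0,
                          neurons_per_session_sd=0,
                          post_injury_light_touch_recruit_prob=0.0)
        (s_pre, t_pre), (s_post, t_post) = generate_longitudinal_cohort(cfg, 5)
        shared = np.isin(t_post.global_cell_ids, t_pre.global_cell_ids)
        pre_by_gid = {g: row for g, row in
                      zip(t_pre.global_cell_ids, t_pre.tuning_matrix)}
        for g, row in zip(t_post.global_cell_ids[shared],
                          t_post.tuning_matrix[shared]):
            assert np.array_equal(row, pre_by_gid[g])

    def test_day_grid_and_condition_flags(self):
        cfg = self._short(n_animals=1)
        cohort = generate_longitudinal_cohort(cfg, 1)
        assert [s.day for s, _ in cohort] == [-7, 42]
        assert all(s.condition == "neuropathic" for s, _ in cohort)

    def test_injury_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            self._short(n_animals=1, days=(-7, -1), injury_day=0)

    def test_recruitment_matches_binomial_oracle(self):
        cfg = self._short(n_animals=25)
        lt_j = cfg.stimulus_panel.index("light_touch")
        pre_f, post_cnt, post_tot = [], 0, 0
        for s, t in generate_longitudinal_cohort(cfg, 9):
            ens = t.is_ensemble
            if s.day < 0:
                pre_f.append(t.tuning_matrix[ens, lt_j].mean())
            else:
                post_cnt += int(t.tuning_matrix[ens, lt_j].sum())
                post_tot += int(ens.sum())
        f_pre = 0.18
        r = cfg.post_injury_light_touch_recruit_prob
        expected = f_pre + (1 - f_pre) * r
        sd = np.sqrt(expected * (1 - expected) / post_tot)
        assert abs(post_cnt / post_tot - expected) < 3 * sd
        assert abs(np.mean(pre_f) - f_pre) < 0.03

    def test_missing_injury_day_rejected(self):
        cfg = self._short(n_animals=1)
        object.__setattr__(cfg, "injury_day", None)
        with pytest.raises(ValueError):
            generate_longitudinal_cohort(cfg, 1)


class TestRenderMovie:
    def test_single_neuron_zero_noise_peak_at_centroid(self, small_config):
        cfg = small_config.replace(neurons_per_session_mean=1,
                                   neurons_per_session_sd=0,
                                   trials_per_stimulus=1, noise_sd_dff=0.0,
                                   event_rate_hz=0.0,
                                   inter_trial_interval_s=(2.0, 3.0),
                                   lead_in_s=5.0, tail_s=5.0)
        session, truth = generate_session(cfg, 2)
        movie, fps, cents = render_movie(session, 60, 60, cell_radius=3.0,
                                         seed=1, noise_sd=0.0)
        f = int(np.argmax(session.traces[0]))
        peak_px = np.unravel_index(np.argmax(movie[f]), movie[f].shape)
        assert np.hypot(peak_px[1] - cents[0][0], peak_px[0] - cents[0][1]) < 1.0

    def test_linear_mixture_exactness_at_zero_noise(self, small_config):
        cfg = small_config.replace(neurons_per_session_mean=5,
                                   neurons_per_session_sd=0,
                                   trials_per_stimulus=1,
                                   inter_trial_interval_s=(2.0, 3.0),
                                   lead_in_s=5.0, tail_s=5.0)
        session, _ = generate_session(cfg, 3)
        movie, fps, _ = render_movie(session, 80, 80, cell_radius=3.0,
                                     seed=2, noise_sd=0.0)
        flat = fps.reshape(5, -1)
        expected = (session.traces.T @ flat).reshape(movie.shape)
        assert np.allclose(movie, expected, rtol=1e-10, atol=1e-8)

    def test_capacity_25_cells_100px(self, rendered_movie):
        assert rendered_movie["footprints"].shape[0] == 25

    def test_impossible_placement_raises(self, small_session):
        session, _ = small_session
        with pytest.raises(RuntimeError, match="enlarge"):
            render_movie(session, 20, 20, cell_radius=5.0, seed=0)


class TestCoupling:
    def test_trivial_endpoints(self):
        assert coupling_from_spearman(0.0) == 0.0
        assert coupling_from_spearman(1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            coupling_from_spearman(1.2)

    def test_monte_carlo_spearman_of_copula(self):
        from nociscope.stats import spearman
        r = coupling_from_spearman(0.54)
        rng = np.random.default_rng(0)
        z1 = rng.standard_normal(100_000)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(100_000)
        assert spearman(z1, z2) == pytest.approx(0.54, abs=0.01)

    def test_planted_session_level_coupling(self, small_config):
        """The session-level gain copula reproduces the (attenuation-
        corrected) target Spearman between planted activation and planted
        behavior amplitude across many sessions."""
        from nociscope.stats import spearman
        cfg = small_config.replace(neurons_per_session_mean=80,
                                   trials_per_stimulus=5,
                                   inter_trial_interval_s=(4.0, 6.0),
                                   lead_in_s=5.0, tail_s=5.0)
        A, B = [], []
        for sd in range(250):
            _, t = generate_session(cfg, 3000 + sd)
            A.append(float(np.nanmean(t.planted_activation)))
            B.append(float(np.nanmean(t.planted_behavior_amplitudes)))
        rho_eff = (6 / np.pi) * np.arcsin(coupling_from_spearman(
            min(0.999, cfg.behavior_coupling_rho *
                cfg.coupling_attenuation_correction)) / 2)
        # within-session averaging of the lognormal bout jitter attenuates
        # the planted correlation slightly below the copula target
        assert spearman(A, B) == pytest.approx(rho_eff, abs=0.08)
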