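"""Tests of the behavioral analyses: SDT, staircase, motion energy,
reverse correlation, and the group accuracy summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cuedecode as cd
from cuedecode import behavior
from cuedecode.behavior import (motion_energy, per_epoch_evidence,
                                perceptual_template, run_staircase,
                                sdt_measures, summarize_behavior,
                                template_congruency_contrast,
                                weibull_observer)
from cuedecode.synthetic import (DesignSpec, ObserverParams,
                                 draw_coherence_profile, render_dot_movie,
                                 simulate_choices)


def _table_from(direction, cue, choice):
    n = len(direction)
    return pd.DataFrame({"direction": direction, "cue": cue, "choice": choice,
                         "condition": ["acoustic"] * n,
                         "congruent": np.array(direction) == np.array(cue),
                         "correct": (np.array(choice) == np.array(direction)
                                     ).astype(int)})


class TestSDT:
    def _balanced_table(self, h, fa, n=1000, rng=None):
        """Construct trials with exact hit/false-alarm rates (left=signal)."""
        rng = rng or np.random.default_rng(0)
        direction, cue, choice = [], [], []
        for side in (-1, 1):
            for _ in range(n // 2):
                d = -1 if len(direction) % 2 == 0 else 1
                direction.append(d)
                cue.append(side)
        direction = np.array(direction)
        cue = np.array(cue)
        choice = np.where(direction == -1,
                          np.where(rng.uniform(size=n) < h, -1, 1),
                          np.where(rng.uniform(size=n) < fa, -1, 1))
        return _table_from(direction, cue, choice)

    def test_equal_rates_give_zero_dprime(self):
        table = self._balanced_table(0.5, 0.5, n=4000)
        res = sdt_measures(table)
        assert res.d_prime == pytest.approx(0, abs=0.15)

    def test_dprime_inverse_normal_oracle(self):
        """H=0.8, FA=0.2 gives d' = z(0.8) - z(0.2) = 1.683."""
        direction = np.repeat([-1, 1], 500)
        cue = np.tile([-1, 1], 500)
        # deterministic rates: exactly 80% hits, 20% false alarms
        choice = np.concatenate([
            np.where(np.arange(500) < 400, -1, 1),
            np.where(np.arange(500) < 100, -1, 1)])
        res = sdt_measures(_table_from(direction, cue, choice))
        # log-linear correction shifts rates slightly from 0.8/0.2
        expect = sps.norm.ppf((400 + .5) / 501) - sps.norm.ppf((100 + .5) / 501)
        assert res.d_prime == pytest.approx(expect, abs=1e-9)
        assert res.d_prime == pytest.approx(1.683, abs=0.02)

    def test_combined_bias_sign_alignment(self):
        """Opposite per-side criteria of magnitude 0.3 combine to 0.3."""
        rng = np.random.default_rng(5)
        # cue-left trials biased toward 'left', cue-right toward 'right'
        n = 40000
        direction = rng.choice([-1, 1], n)
        cue = rng.choice([-1, 1], n)
        # criterion c = +-0.3 via shifted response thresholds
        z = rng.standard_normal(n) + 0.8 * direction * -1  # left=signal axis
        crit = np.where(cue == -1, -0.4 - 0.3, -0.4 + 0.3)
        choice = np.where(z > crit, -1, 1)
        res = sdt_measures(_table_from(direction, cue, choice))
        c_l, c_r = res.criterion_c[-1], res.criterion_c[1]
        assert res.combined_bias == pytest.approx(abs(c_r - c_l) / 2)
        assert res.combined_bias == pytest.approx(0.3, abs=0.05)

    def test_single_class_rejected(self):
        table = _table_from([1] * 10, [1] * 10, [1] * 10)
        with pytest.raises(ValueError, match="direction"):
            sdt_measures(table)


class TestStaircase:
    def test_converges_near_70_7_percent(self):
        """The transformed 2-down/1-up rule converges at the level where
        p^2 = 0.5, i.e. ~70.7% correct (a Weibull observer probes it)."""
        obs = weibull_observer(threshold=20, slope=3, lapse=0.02)
        pcs = [obs(run_staircase(obs, n_trials=400, seed=s).threshold)
               for s in range(25)]
        assert np.mean(pcs) * 100 == pytest.approx(70.7, abs=2.0)

    def test_step_observer_brackets_transition(self):
        step_obs = lambda level: np.where(np.asarray(level) >= 20.0, 1.0, 0.0)
        res = run_staircase(step_obs, n_trials=200, n_tracks=1, seed=3)
        tr = res.tracks[0]
        assert min(tr.reversals[-6:]) <= 20.0 <= max(tr.reversals[-6:])

    def test_interleaved_tracks_agree(self):
        """Interleaved tracks on the same observer land on the same level
        (mean spread over runs within 2x the final step size)."""
        obs = weibull_observer(threshold=25, slope=4, lapse=0.01)
        spreads = []
        for s in range(5):
            res = run_staircase(obs, n_trials=600, n_tracks=3, seed=s,
                                n_reversals_avg=40)
            assert res.converged
            spreads.append(np.ptp(res.track_thresholds))
        assert np.mean(spreads) <= 2 * 2.0

    def test_too_few_trials_flagged(self):
        obs = weibull_observer()
        res = run_staircase(obs, n_trials=8, n_tracks=1, seed=0)
        assert not res.converged


class TestMotionEnergy:
    def test_full_coherence_sign_convention(self):
        movie = render_dot_movie(np.full(8, 100.0), direction=1, seed=2,
                                 n_dots=400, n_frames=96)
        ev = motion_energy(movie)
        assert (ev > 0).all()

    def test_mirror_negates_evidence(self):
        movie = render_dot_movie(np.full(8, 60.0), direction=1, seed=4,
                                 n_dots=400, n_frames=96)
        ev = motion_energy(movie)
        movie.positions = movie.positions * np.array([-1.0, 1.0])
        ev_m = motion_energy(movie)
        np.testing.assert_allclose(ev_m, -ev, rtol=1e-7, atol=1e-12)

    def test_zero_coherence_null_mean(self):
        rng = np.random.default_rng(8)
        evs = []
        for _ in range(60):
            movie = render_dot_movie(np.zeros(4), direction=1,
                                     seed=rng.integers(2**31 - 1),
                                     n_dots=300, n_frames=48)
            evs.append(motion_energy(movie).mean())
        evs = np.asarray(evs)
        sem = evs.std(ddof=1) / np.sqrt(len(evs))
        assert abs(evs.mean()) < 2.5 * sem + 1e-12

    def test_short_movie_rejected(self):
        movie = render_dot_movie(np.full(8, 50.0), direction=1, seed=0,
                                 n_dots=50, n_frames=6)
        with pytest.raises(ValueError, match="shorter"):
            motion_energy(movie)

    def test_ground_truth_backend_matches_design(self, behaviour_only_table):
        ev = per_epoch_evidence(behaviour_only_table)
        coh = behaviour_only_table[[f"coh_e{i}" for i in range(1, 9)]].to_numpy()
        d = behaviour_only_table["direction"].to_numpy()
        np.testing.assert_allclose(ev, d[:, None] * coh / 100)


class TestPerceptualTemplate:
    def test_null_choices_give_standard_normal_z(self, rng):
        zs = []
        for _ in range(40):
            ev = rng.standard_normal((200, 8))
            choices = rng.choice([-1, 1], 200)
            t = perceptual_template(ev, choices, n_shuffles=150,
                                    seed=rng.integers(2**31 - 1))
            zs.append(t.weights_z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.2
        assert zs.std() == pytest.approx(1.0, abs=0.25)

    def test_planted_single_epoch_kernel_recovered(self):
        """An observer reading only epoch 5 produces the max |z| there."""
        spec = DesignSpec(trials_per_cell=400)
        kernel = np.zeros(8)
        kernel[4] = 1.0
        obs = ObserverParams(beta_motion=6, beta_cue=0,
                             beta_alpha_motion=0, beta_alpha_cue=0,
                             temporal_kernel=tuple(kernel))
        table = cd.generate_design(spec, seed=21)
        table = simulate_choices(table, obs, seed=22)
        t = perceptual_template(per_epoch_evidence(table),
                                table["choice"].to_numpy(),
                                n_shuffles=200, seed=23)
        assert np.argmax(np.abs(t.weights_z)) == 4

    def test_z_invariant_to_affine_evidence_rescaling(self, rng):
        ev = rng.standard_normal((300, 8))
        choices = rng.choice([-1, 1], 300)
        t1 = perceptual_template(ev, choices, n_shuffles=120, seed=9)
        t2 = perceptual_template(5.0 * ev + 2.0, choices, n_shuffles=120, seed=9)
        np.testing.assert_allclose(t1.weights_z, t2.weights_z, atol=1e-9)

    def test_one_sided_choices_rejected(self, rng):
        with pytest.raises(ValueError, match="choice"):
            perceptual_template(rng.standard_normal((50, 8)), np.ones(50),
                                n_shuffles=100)

    def test_flat_positive_kernel_significant_at_group_level(self):
        """With a flat positive kernel, every epoch's group template is
        positive and the bootstrap CI excludes zero at n=20."""
        rng = np.random.default_rng(31)
        templates = []
        for _ in range(20):
            table = cd.generate_design(DesignSpec(trials_per_cell=60),
                                       seed=rng.integers(2**31 - 1))
            table = simulate_choices(
                table, ObserverParams(beta_motion=6, beta_cue=0.3),
                seed=rng.integers(2**31 - 1))
            ev = per_epoch_evidence(table)
            templates.append(perceptual_template(
                ev, table["choice"].to_numpy(), n_shuffles=150,
                seed=rng.integers(2**31 - 1)).weights_z)
        from cuedecode.stats import percentile_bootstrap
        boot = percentile_bootstrap(np.asarray(templates), n_boot=500, seed=1)
        assert (boot.estimate > 0).all()
        assert (boot.ci_low > 0).all()


class TestTemplateCongruencyContrast:
    def test_identical_inputs_give_zero_difference(self, rng):
        t = rng.standard_normal((12, 8))
        res = template_congruency_contrast(t, t.copy(), n_boot=300, seed=0)
        np.testing.assert_allclose(res.estimate, 0, atol=1e-12)
        assert (res.ci_low <= 0).all() and (res.ci_high >= 0).all()

    def test_planted_boost_detected(self, rng):
        cong = rng.standard_normal((15, 8))
        incong = rng.standard_normal((15, 8))
        cong[:, 3:5] += 2.0
        res = template_congruency_contrast(cong, incong, n_boot=500, seed=2)
        assert (res.ci_low[3:5] > 0).all()

    def test_unpaired_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="paired"):
            template_congruency_contrast(rng.standard_normal((10, 8)),
                                         rng.standard_normal((9, 8)))


class TestSummarizeBehavior:
    @pytest.fixture(scope="class")
    def cohort(self):
        rng = np.random.default_rng(55)
        spec = DesignSpec(trials_per_cell=80)
        obs = ObserverParams(beta_cue=0.5)
        tables = []
        for _ in range(20):
            t = cd.generate_design(spec, seed=rng.integers(2**31 - 1))
            tables.append(simulate_choices(t, obs,
                                           seed=rng.integers(2**31 - 1)))
        return tables

    def test_congruency_benefit_in_every_condition(self, cohort):
        res = summarize_behavior(cohort)
        for cond, stats in res["posthoc"].items():
            assert stats["mean_congruent"] > stats["mean_incongruent"]
            assert stats["p"] < 0.05
        assert res["anova"]["congruency"]["p"] < 0.001

    def test_identical_cells_give_null_anova(self):
        base = np.random.default_rng(0).normal(0.7, 0.05, size=20)
        cells = np.tile(base[:, None, None], (1, 3, 2))
        from cuedecode.stats import two_way_rm_anova
        res = two_way_rm_anova(cells + 1e-12 *
                               np.random.default_rng(1).normal(size=cells.shape))
        assert res["A"]["eta_p2"] < 0.6
        assert res["B"]["F"] < 10

    def test_cohens_d_matches_direct_formula(self, cohort):
        res = summarize_behavior(cohort)
        cells = res["cells"]
        diff = cells[:, 0, 0] - cells[:, 0, 1]
        assert res["posthoc"]["acoustic"]["d"] == \
            pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_empty_cell_reported_by_name(self):
        t = cd.generate_design(DesignSpec(trials_per_cell=10), seed=0)
        t = simulate_choices(t, seed=1)
        t2 = t[~((t.condition == "precue") & t.congruent)]
        with pytest.raises(ValueError, match="precue"):
            summarize_behavior([t2, t2])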