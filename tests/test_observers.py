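import numpy as np
import pytest

import motmem as mm
from motmem.design import build_experiment, preset_config
from motmem.observers import simulate_responses


@pytest.fixture(scope="module")
def exp1b_trials():
    return build_experiment(preset_config("exp1b"), np.random.default_rng(0))


def test_guessing_observer_scores_at_chance(guessing_log):
    """Uniform random reports give mean TP of 0.5."""
    assert len(guessing_log) >= 10_000
    assert guessing_log.tp.mean() == pytest.approx(0.5, abs=0.01)


def test_noiseless_high_capacity_observer_is_perfect(exp1b_trials):
    params = mm.ObserverParams(
        architecture="exclusive", sm_sigma_deg=0.0, stm_sigma_deg=0.0,
        stm_capacity=4, lapse_rate=0.0, sm_tau_ms=1e12,
    )
    log = simulate_responses(exp1b_trials, params, np.random.default_rng(2))
    assert (log.tp == 1.0).all()


def test_overwriting_observer_matches_analytic_ceiling():
    """A noiseless overwriting reporter queried pre-deviation scores at
    the analytic ceiling 0.583 (interior-angle deviations, unconstrained)."""
    config = preset_config(
        "exp1b", deviation_convention="interior_angle", min_direction_sep_deg=0.0
    )
    rng = np.random.default_rng(3)
    trials = build_experiment(config, rng)
    params = mm.ObserverParams(
        architecture="overwriting", sm_sigma_deg=0.0, lapse_rate=0.0
    )
    log = simulate_responses(trials, params, rng)
    pre = log[log.segment == "pre_deviation"]
    assert len(pre) >= 1000
    assert pre.tp.mean() == pytest.approx(0.583, abs=0.02)
    # when queried post-deviation the same observer is perfect
    post = log[log.segment == "post_deviation"]
    assert (post.tp == 1.0).all()


def test_response_record_invariants(exp1b_trials):
    log = simulate_responses(exp1b_trials, mm.ObserverParams(), np.random.default_rng(4))
    assert ((log.error_deg > -180) & (log.error_deg <= 180)).all()
    assert log.tp.between(0, 1).all()
    sr = log[log.scope == "single_report"]
    assert (sr.report_order == 1).all()
    fr = log[log.scope == "full_report"]
    assert (fr.groupby(["stimulus_condition", "block", "trial"]).report_order.max() == 3).all()


def test_simulation_determinism(exp1b_trials):
    a = simulate_responses(exp1b_trials, mm.ObserverParams(), np.random.default_rng(5))
    b = simulate_responses(exp1b_trials, mm.ObserverParams(), np.random.default_rng(5))
    assert a.equals(b)


class TestReportOrderPolicy:
    @staticmethod
    def _fr_trial(trials):
        return next(
            t for t in trials
            if t.report_condition.scope == "full_report" and t.set_size == 3
        )

    def test_uniform_policy_is_uniform(self, exp1b_trials):
        trial = self._fr_trial(exp1b_trials)
        params = mm.ObserverParams(report_policy="uniform")
        rng = np.random.default_rng(6)
        counts = {}
        for _ in range(6000):
            perm = tuple(mm.report_order_policy(trial, params, rng))
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 6
        freqs = np.array(list(counts.values())) / 6000
        assert np.allclose(freqs, 1 / 6, atol=0.03)

    def test_memory_first_uniform_when_all_in_sm(self, exp1b_trials):
        trial = self._fr_trial(exp1b_trials)
        params = mm.ObserverParams(report_policy="memory_first")
        rng = np.random.default_rng(7)
        all_in = np.ones(3, bool)
        perms = {
            tuple(mm.report_order_policy(trial, params, rng, sm_available=all_in))
            for _ in range(300)
        }
        assert len(perms) == 6

    def test_memory_first_orders_sm_then_stm(self, exp1b_trials):
        trial = self._fr_trial(exp1b_trials)
        params = mm.ObserverParams(report_policy="memory_first")
        rng = np.random.default_rng(8)
        sm = np.array([False, True, False])
        stm = np.array([True, False, False])
        perm = mm.report_order_policy(trial, params, rng, sm_available=sm, stm_stored=stm)
        assert list(perm) == [1, 0, 2]

    def test_single_disk_trial(self):
        trials = build_experiment(preset_config("exp3"), np.random.default_rng(9))
        trial = next(
            t for t in trials
            if t.set_size == 1 and t.report_condition.scope == "full_report"
        )
        perm = mm.report_order_policy(trial, mm.ObserverParams(), np.random.default_rng(0))
        assert list(perm) == [0]


class TestCohorts:
    def test_zero_jitter_gives_identical_parameters(self):
        cohort = mm.make_cohort(4, mm.ObserverParams(), jitter=0.0,
                                rng=np.random.default_rng(0))
        assert len({p.sm_sigma_deg for p in cohort}) == 1
        assert len({p.seed for p in cohort}) == 4

    def test_jitter_gives_distinct_parameters(self):
        cohort = mm.make_cohort(4, mm.ObserverParams(), jitter=0.1,
                                rng=np.random.default_rng(1))
        assert len({p.sm_sigma_deg for p in cohort}) == 4

    def test_cohort_trial_volume(self, exclusive_log):
        """4 observers x 1600 trials yield 6400 response-bearing trials."""
        trials = exclusive_log.groupby(
            ["observer", "stimulus_condition", "block", "trial"]
        ).ngroups
        assert trials == 6400


class TestQualitativeSignatures:
    """The generative architectures reproduce the qualitative SM pattern."""

    def test_exclusive_post_only(self, exclusive_log):
        cells = exclusive_log.groupby(["segment", "scope"]).tp.mean()
        post_sr = cells["post_deviation", "single_report"]
        post_fr = cells["post_deviation", "full_report"]
        pre_sr = cells["pre_deviation", "single_report"]
        pre_fr = cells["pre_deviation", "full_report"]
        fr1 = exclusive_log[
            (exclusive_log.scope == "full_report") & (exclusive_log.report_order == 1)
        ].groupby("segment").tp.mean()
        # current segment: SR advantage, SR close to FR1
        assert post_sr - post_fr > 0.05
        assert abs(post_sr - fr1["post_deviation"]) < 0.33 * (post_sr - post_fr)
        # previous segment: no SR advantage, SR clearly below FR1
        assert pre_sr - pre_fr < 0.03
        assert fr1["pre_deviation"] - pre_sr > 0.05

    def test_shared_both_segments(self, shared_log):
        cells = shared_log.groupby(["segment", "scope"]).tp.mean()
        for segment in ("pre_deviation", "post_deviation"):
            assert (
                cells[segment, "single_report"] - cells[segment, "full_report"] > 0.05
            )

    def test_exclusive_decay_with_cue_delay(self):
        """Post-deviation SR performance decays monotonically over
        0-1600 ms cue delays and approaches full-report level."""
        rng = np.random.default_rng(21)
        cohort = mm.make_cohort(4, mm.ObserverParams(), jitter=0.1, rng=rng)
        log = mm.simulate_cohort("exp2", cohort, seed=22)
        post = log[log.segment == "post_deviation"]
        sr = post[post.scope == "single_report"].groupby("cue_delay_ms").tp.mean()
        assert (sr.sort_index().diff().dropna() < 0).all()
        fr = post[post.scope == "full_report"].groupby("cue_delay_ms").tp.mean()
        gap = (sr - fr).sort_index()
        assert gap.iloc[0] > 0.1 and gap.iloc[-1] < 0.05

    def test_set_size_hits_full_report_harder(self):
        rng = np.random.default_rng(23)
        cohort = mm.make_cohort(4, mm.ObserverParams(), jitter=0.1, rng=rng)
        log = mm.simulate_cohort("exp3", cohort, seed=24)
        post = log[log.segment == "post_deviation"]
        piv = post.groupby(["scope", "set_size"]).tp.mean().unstack()
        sr_drop = piv.loc["single_report", 1] - piv.loc["single_report", 4]
        fr_drop = piv.loc["full_report", 1] - piv.loc["full_report", 4]
        assert fr_drop > sr_drop + 0.05
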