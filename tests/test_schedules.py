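"""Schedule primitives: interval generation, arming, and the COD contract."""

import numpy as np
import pytest
from scipy import stats

import rulechoice as rc
from rulechoice.schedules import ConcurrentPair, Outcome, ScheduleState

# Independent direct evaluation of the interval progression for (T=10, n=20),
# k=1, frozen before the engine was built:
#   t_1 = 10 * (1 + ln 20 + 19 ln 19 - 20 ln 20)
T1_MEAN10_N20 = 0.2542740663653831


class TestFleshlerHoffman:
    @pytest.mark.parametrize("mean_s,n", [(60, 20), (10, 20), (5, 7), (0.5, 3),
                                          (123.4, 50)])
    def test_mean_equals_programmed_mean(self, mean_s, n):
        lst = rc.fleshler_hoffman_intervals(mean_s, n)
        assert lst.n_intervals == n == len(lst.intervals_s)
        assert np.mean(lst.intervals_s) == pytest.approx(mean_s, rel=1e-9)

    def test_single_interval_list_is_the_mean(self):
        assert rc.fleshler_hoffman_intervals(60, 1).intervals_s == (60.0,)

    def test_first_interval_matches_direct_evaluation(self):
        lst = rc.fleshler_hoffman_intervals(10, 20)
        assert lst.intervals_s[0] == pytest.approx(T1_MEAN10_N20, rel=1e-12)

    def test_intervals_strictly_positive_and_increasing(self):
        lst = rc.fleshler_hoffman_intervals(60, 20)
        arr = np.asarray(lst.intervals_s)
        assert (arr > 0).all()
        assert (np.diff(arr) > 0).all()

    @pytest.mark.parametrize("mean_s,n", [(0, 20), (-5, 20), (60, 0), (60, -1)])
    def test_invalid_parameters_rejected(self, mean_s, n):
        with pytest.raises(rc.InvalidParameterError):
            rc.fleshler_hoffman_intervals(mean_s, n)


class TestDrawInterval:
    def test_forced_draw_empties_the_list(self):
        lst = rc.IntervalList(mean_s=7.5, n_intervals=1, intervals_s=(7.5,))
        assert rc.draw_interval(lst, np.random.default_rng(0)) == 7.5
        assert lst.remaining == []

    def test_twenty_draws_are_a_permutation_of_the_list(self):
        rng = np.random.default_rng(3)
        lst = rc.fleshler_hoffman_intervals(60, 20)
        draws = [lst.draw(rng) for _ in range(20)]
        assert sorted(draws) == sorted(lst.intervals_s)
        # 21st draw regenerates a fresh list
        extra = lst.draw(rng)
        assert extra in lst.intervals_s

    def test_first_draws_uniform_over_the_list(self):
        """First draw from a fresh list is uniform over the 20 values
        (chi-square goodness of fit over 10,000 fresh lists)."""
        rng = np.random.default_rng(12)
        template = rc.fleshler_hoffman_intervals(60, 20)
        index = {v: i for i, v in enumerate(template.intervals_s)}
        counts = np.zeros(20)
        for _ in range(10_000):
            fresh = rc.fleshler_hoffman_intervals(60, 20)
            counts[index[fresh.draw(rng)]] += 1
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_draw_stream_approximates_exponential(self):
        """Across regenerating lists the draw distribution is close to
        exponential with the programmed mean (constant setup hazard)."""
        rng = np.random.default_rng(7)
        lst = rc.fleshler_hoffman_intervals(60, 20)
        draws = [lst.draw(rng) for _ in range(10_000)]
        ks = stats.kstest(draws, "expon", args=(0, 60))
        assert ks.statistic < 0.05


def make_pair(left="VI", right="EXT", mean_s=10.0, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    def sched(kind):
        return ScheduleState.vi(mean_s, rng) if kind == "VI" else ScheduleState.ext()
    return ConcurrentPair(left=sched(left), right=sched(right), rng=rng, **kwargs)


class TestAdvanceTime:
    def test_boundary_arming(self):
        pair = make_pair()
        pair.left.time_to_arm_s = 0.5
        pair.advance_time(0.5)
        assert pair.left.armed and pair.left.time_to_arm_s == 0.0
        assert pair.left.armed_at_s == pytest.approx(0.5)

    def test_ext_never_arms(self):
        pair = make_pair()
        pair.advance_time(1e6)
        assert not pair.right.armed

    def test_cod_timer_decrements_and_blocks(self):
        pair = make_pair()
        pair.register_response("left")
        assert pair.register_response("right") is Outcome.COD_TRIGGERED
        pair.advance_time(1.0)
        assert pair.cod_remaining_s == pytest.approx(2.0)
        assert pair.register_response("right") is Outcome.BLOCKED

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(rc.InvalidParameterError):
            make_pair().advance_time(0.0)


class TestRegisterResponse:
    def test_first_component_response_never_triggers_cod(self):
        for side in ("left", "right"):
            pair = make_pair()
            assert pair.register_response(side) in (Outcome.RECORDED,
                                                    Outcome.REINFORCED)

    def test_armed_same_side_response_is_reinforced(self):
        pair = make_pair()
        pair.register_response("left")
        pair.left.armed = True
        pair.left.armed_at_s = pair.t_s
        assert pair.register_response("left") is Outcome.REINFORCED
        assert not pair.left.armed  # disarmed, next interval drawn
        assert pair.left.time_to_arm_s > 0

    def test_cod_state_machine_hand_trace(self):
        """Hand-executed trace: run of left responses, switch to armed right,
        COD, then reinforcement only >= 3 s after the changeover."""
        pair = make_pair(left="EXT", right="VI")
        pair.advance_time(0.01)
        assert pair.register_response("left") is Outcome.RECORDED
        pair.advance_time(1.0)
        assert pair.register_response("left") is Outcome.RECORDED
        pair.right.armed = True  # reinforcer set up on the other side
        pair.right.armed_at_s = pair.t_s
        assert pair.register_response("right") is Outcome.COD_TRIGGERED
        assert pair.right.armed  # changeover press cannot collect
        pair.advance_time(2.99)
        assert pair.register_response("right") is Outcome.BLOCKED
        pair.advance_time(0.01)
        assert pair.register_response("right") is Outcome.REINFORCED

    def test_post_cod_response_to_pre_cod_side_retriggers(self):
        pair = make_pair()
        pair.register_response("left")
        pair.register_response("right")  # changeover
        pair.advance_time(3.0)
        assert pair.register_response("left") is Outcome.COD_TRIGGERED

    def test_unconditional_post_cod_flag_delivers_on_vi_only(self):
        pair = make_pair(left="EXT", right="VI", mean_s=1e6,
                         reinforce_post_cod_unconditionally=True)
        pair.register_response("left")
        pair.register_response("right")
        pair.advance_time(3.0)
        assert pair.register_response("right") is Outcome.REINFORCED
        # ... but a switch onto EXT never delivers
        pair.register_response("left")
        pair.advance_time(3.0)
        assert pair.register_response("left") is Outcome.RECORDED

    def test_reinforcer_conservation_against_elapsed_intervals(self):
        """Reinforcers delivered never exceed intervals fully elapsed.

        Intervals run sequentially and every completed 20-interval list sums
        to 20 x mean, so deliveries are bounded by t/mean + list length.
        """
        rng = np.random.default_rng(9)
        pair = make_pair(mean_s=2.0, seed=9)
        delivered = 0
        t = 0.0
        for _ in range(2000):
            t += float(rng.uniform(0.01, 0.5))
            side = "left" if rng.random() < 0.8 else "right"
            if pair.register_response(side, t_s=t) is Outcome.REINFORCED:
                delivered += 1
        assert 0 < delivered <= t / 2.0 + 20


class TestProbeRates:
    def test_obtained_rate_converges_to_programmed_rate(self):
        res = rc.run_probe(10, 10_000, response_rate_hz=5, seed=4)
        assert res.rate_per_min == pytest.approx(6.0, rel=0.10)

    def test_ext_probe_delivers_nothing(self):
        res = rc.run_probe(None, 5_000, response_rate_hz=5, seed=4)
        assert res.n_reinforcers == 0

    def test_inter_reinforcer_times_close_to_exponential(self):
        """Constant-probability property: obtained inter-reinforcer times of
        a densely responding probe are close to exponential."""
        res = rc.run_probe(5, 10_000, response_rate_hz=5, seed=1)
        ks = stats.kstest(res.inter_reinforcer_times_s, "expon", args=(0, 5))
        assert ks.statistic < 0.08
        assert res.inter_reinforcer_times_s.mean() == pytest.approx(5.0, rel=0.1)
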