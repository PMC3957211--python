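"""Axon allocation, delay programming, emission and STDDP adaptation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polychron.axons import (
    AdaptationPolicy,
    AxonArray,
    ImperfectionModel,
    adapt_delay,
    program_delay,
)
from polychron.errors import CapacityError, ProgrammingError
from polychron.events import Pattern


def _pattern(neurons, times):
    return Pattern(neurons=np.array(neurons), times=np.array(times, dtype=float))


class TestAllocation:
    def test_each_spike_becomes_one_module_input(self):
        arr = AxonArray(10)
        pat = _pattern([3, 1, 4, 1, 5, 9], [0, 7, 13, 22, 30, 41])
        arr.train_pattern(pat)
        assert arr.n_allocated == 6
        np.testing.assert_array_equal(arr.input_addr[:6], pat.neurons)
        # module k's outputs are the next four spikes of the pattern
        for k in range(6):
            expect = pat.neurons[k + 1 : k + 5]
            np.testing.assert_array_equal(arr.out_addr[k, : len(expect)], expect)
            np.testing.assert_allclose(
                arr.delays[k, : len(expect)], pat.times[k + 1 : k + 5] - pat.times[k]
            )

    def test_two_spike_pattern_leaves_trailing_outputs_unconfigured(self):
        arr = AxonArray(10)
        arr.train_pattern(_pattern([0, 1], [0.0, 5.0]))
        assert arr.n_out[0] == 1 and arr.n_out[1] == 0

    def test_patterns_do_not_share_modules_across_boundaries(self):
        arr = AxonArray(10)
        arr.train_pattern(_pattern([0, 1], [0.0, 5.0]))
        arr.train_pattern(_pattern([2, 3], [0.0, 6.0]))
        # the first pattern's trailing module must not latch the second's spikes
        assert arr.n_out[0] == 1 and arr.n_out[1] == 0
        assert arr.n_out[2] == 1
        assert arr.pattern_slices == [(0, 2), (2, 4)]

    @pytest.mark.parametrize("length,capacity", [(20, 5), (25, 4), (33, 3), (50, 2)])
    def test_capacity_is_floor_modules_over_length(self, length, capacity):
        arr = AxonArray(100)
        rng = np.random.default_rng(0)
        for _ in range(capacity):
            neurons = rng.permutation(500)[:length]
            times = np.cumsum(rng.uniform(5, 15, length))
            arr.train_pattern(_pattern(neurons, times))
        with pytest.raises(CapacityError) as err:
            arr.train_pattern(
                _pattern(rng.permutation(500)[:length], np.cumsum(rng.uniform(5, 15, length)))
            )
        assert err.value.pattern_index == capacity


class TestDelayProgramming:
    def test_digital_programming_is_exact(self):
        arr = AxonArray(4)
        arr.begin_pattern()
        arr.on_training_spike(0.0, 1)
        stored = program_delay(arr, 0, 0, 0.0, 12.5)
        assert stored == 12.5

    def test_zero_or_overrange_delay_rejected(self):
        arr = AxonArray(4, max_delay=100.0)
        with pytest.raises(ProgrammingError):
            program_delay(arr, 0, 0, 5.0, 5.0)
        with pytest.raises(ProgrammingError):
            program_delay(arr, 0, 0, 0.0, 150.0)

    def test_analog_programming_error_is_within_three_sigma(self):
        arr = AxonArray(1, imperfection=ImperfectionModel(sigma=0.10, seed=5))
        draws = np.array([program_delay(arr, 0, 0, 0.0, 10.0, arr.imperfection) for _ in range(2000)])
        rel = np.abs(draws / 10.0 - 1.0)
        assert (rel < 0.30).mean() > 0.99

    def test_quantization_rounds_to_grid(self):
        arr = AxonArray(4, quantization=0.1)
        arr.begin_pattern()
        arr.on_training_spike(0.0, 1)
        arr.on_training_spike(5.23, 2)
        assert arr.delays[0, 0] == pytest.approx(5.2)


class TestEmission:
    def test_delays_emit_on_their_lines(self):
        arr = AxonArray(5)
        arr.train_pattern(_pattern([7, 1, 2, 3, 4], [0, 3, 5, 8, 11]))
        out = arr.on_postsyn_spike(7, 100.0)
        assert [(te, addr, line) for te, addr, line, _, _ in out] == [
            (103.0, 1, 0),
            (105.0, 2, 1),
            (108.0, 3, 2),
            (111.0, 4, 3),
        ]

    def test_unknown_address_emits_nothing(self):
        arr = AxonArray(4)
        arr.train_pattern(_pattern([7, 1], [0, 3]))
        assert arr.on_postsyn_spike(99, 10.0) == []

    def test_modules_sharing_an_input_address_all_fire(self):
        arr = AxonArray(4)
        arr.train_pattern(_pattern([7, 1], [0, 3]))
        arr.train_pattern(_pattern([7, 2], [0, 4]))
        out = arr.on_postsyn_spike(7, 0.0)
        assert sorted((addr, te) for te, addr, _, _, _ in out) == [(1, 3.0), (2, 4.0)]

    def test_retrigger_cancels_pending_emissions(self):
        arr = AxonArray(4)
        arr.train_pattern(_pattern([7, 1], [0, 3]))
        first = arr.on_postsyn_spike(7, 0.0)
        second = arr.on_postsyn_spike(7, 1.0)
        _, _, _, m, gen1 = first[0]
        assert not arr.emission_valid(m, gen1)
        _, _, _, _, gen2 = second[0]
        assert arr.emission_valid(m, gen2)

    def test_serialization_round_trip(self):
        arr = AxonArray(10)
        arr.train_pattern(_pattern([3, 1, 4, 1, 5], [0, 7, 13, 22, 30]))
        clone = AxonArray.from_json(arr.to_json())
        np.testing.assert_array_equal(clone.input_addr, arr.input_addr)
        np.testing.assert_array_equal(clone.out_addr, arr.out_addr)
        np.testing.assert_allclose(clone.delays, arr.delays)
        assert clone.pattern_slices == arr.pattern_slices


class TestAdaptation:
    @pytest.mark.parametrize("strategy", ["exact", "fixed_step", "proportional"])
    def test_zero_error_is_a_fixed_point(self, strategy):
        policy = AdaptationPolicy(strategy=strategy)
        assert adapt_delay(8.0, 20.0, 20.0, policy) == 8.0

    def test_proportional_halving_over_five_presentations(self):
        policy = AdaptationPolicy(strategy="proportional", coefficient=0.5)
        target, delay = 10.0, 18.0
        errors = []
        for _ in range(5):
            delay = adapt_delay(delay, delay, target, policy)
            errors.append(delay - target)
        assert errors == pytest.approx([4.0, 2.0, 1.0, 0.5, 0.25])

    def test_exact_strategy_reaches_target_in_one_step(self):
        policy = AdaptationPolicy(strategy="exact")
        assert adapt_delay(30.0, 30.0, 12.5, policy) == pytest.approx(12.5)

    def test_fixed_step_moves_by_step_toward_target(self):
        policy = AdaptationPolicy(strategy="fixed_step", step=0.1)
        assert adapt_delay(10.0, 10.0, 9.0, policy) == pytest.approx(9.9)
        assert adapt_delay(10.0, 10.0, 11.0, policy) == pytest.approx(10.1)

    def test_overshoot_is_clamped_to_range(self):
        policy = AdaptationPolicy(strategy="exact")
        assert adapt_delay(5.0, 200.0, 0.0, policy, max_delay=100.0) > 0
        assert adapt_delay(5.0, 0.0, 200.0, policy, max_delay=100.0) == 100.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.floats(min_value=-20, max_value=20),
        st.integers(min_value=1, max_value=8),
    )
    def test_proportional_contraction_is_geometric(self, coeff, err0, n):
        policy = AdaptationPolicy(strategy="proportional", coefficient=coeff)
        target = 30.0
        delay = target + err0
        for _ in range(n):
            delay = adapt_delay(delay, delay, target, policy)
        assert delay - target == pytest.approx((1 - coeff) ** n * err0, abs=1e-9)

    def test_replay_converges_from_random_delays(self):
        arr = AxonArray(20, seed=3)
        pat = _pattern([3, 1, 4, 1, 5, 9, 2, 6], np.cumsum([0, 7, 9, 6, 11, 8, 5, 12]))
        arr.train_pattern(pat, program=False)
        arr.randomize_delays(np.random.default_rng(1))
        policy = AdaptationPolicy(strategy="proportional", coefficient=0.5)
        for _ in range(25):
            arr.adapt_on_replay(0, pat, policy)
        for k in range(len(pat)):
            n = int(arr.n_out[k])
            np.testing.assert_allclose(
                arr.delays[k, :n], pat.times[k + 1 : k + 1 + n] - pat.times[k], atol=1e-4
            )

    def test_fixed_step_refinement_reaches_residual_bound(self):
        # analog schedule: program with 10% error, then fixed-step iterations
        imp = ImperfectionModel(sigma=0.10, residual=0.3, seed=9)
        arr = AxonArray(20, imperfection=imp)
        pat = _pattern([3, 1, 4, 5, 9], np.cumsum([0, 7.0, 9.0, 6.0, 11.0]))
        arr.train_pattern(pat)
        policy = AdaptationPolicy(strategy="fixed_step", step=0.1)
        for _ in range(60):  # enough iterations to walk off the largest error
            arr.adapt_on_replay(0, pat, policy)
        for k in range(len(pat)):
            n = int(arr.n_out[k])
            err = arr.delays[k, :n] - (pat.times[k + 1 : k + 1 + n] - pat.times[k])
            assert np.all(np.abs(err) <= imp.residual + policy.step + 1e-9)
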