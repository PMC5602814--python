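"""DP solver: state updates, forward pass, ranking, backtracking, oracle."""

import numpy as np
import pytest

from csccp import (
    MassPeak,
    ScaffoldConfiguration,
    backtrack,
    brute_force_solve,
    dp_forward,
    finalize_top_r,
    integerize,
    solve_csccp,
    state_update,
)
from csccp.model import CsccpError
from csccp.solver import FeasibilityError, TracebackCorruptionError, _base_layer
from csccp.synthetic import GeneratorSpec, generate_instance


def problem_for(cfg, lo, hi, D=0):
    return integerize(MassPeak(float(lo), float(hi), D), cfg)


class TestStateUpdate:
    def test_base_layer_single_reachable(self, two_by_two):
        problem = problem_for(two_by_two, 0, 4)
        C = _base_layer(4, 2)
        probs, records = state_update(two_by_two, problem, C, s=0, w=2, R=2)
        # only sidechain 1 (mass 2) reaches w=2 from the base state
        assert probs[0] == pytest.approx(0.1)
        assert records[0] == (1, 0)
        assert probs[1] == 0.0 and records[1] is None

    def test_unreachable_mass_all_invalid(self, two_by_two):
        problem = problem_for(two_by_two, 0, 7)
        C = _base_layer(7, 2)
        probs, records = state_update(two_by_two, problem, C, s=0, w=7, R=2)
        assert probs == [0.0, 0.0] and records == [None, None]

    def test_probability_tie_smaller_k_wins(self):
        cfg = ScaffoldConfiguration(
            "TIE", 0, [2], [[3.0, 3.0]], [[0.4, 0.4]]
        )
        problem = problem_for(cfg, 0, 3)
        C = _base_layer(3, 2)
        probs, records = state_update(cfg, problem, C, s=0, w=3, R=2)
        assert probs == [pytest.approx(0.4)] * 2
        assert records[0].k == 0 and records[1].k == 1


class TestDpForward:
    def test_single_compound(self):
        cfg = ScaffoldConfiguration("ONE", 0, [1], [[10.0]], [[0.5]])
        table = dp_forward(cfg, problem_for(cfg, 0, 12), R=2)
        valid = np.argwhere(table.C_plus > 0)
        assert valid.tolist() == [[10, 0]]
        assert table.C_plus[10, 0] == 0.5

    def test_final_layer_matches_hand_enumeration(self, two_by_two):
        table = dp_forward(two_by_two, problem_for(two_by_two, 0, 4), R=2)
        C = table.C_plus
        assert C[2, 0] == pytest.approx(0.72)
        assert C[3, 0] == pytest.approx(0.18)
        assert C[3, 1] == pytest.approx(0.08)
        assert C[4, 0] == pytest.approx(0.02)
        assert np.count_nonzero(C) == 4

    def test_all_zero_probabilities_annihilate(self):
        cfg = ScaffoldConfiguration("Z", 0, [2, 2], [[1, 2], [1, 2]], np.zeros((2, 2)))
        table = dp_forward(cfg, problem_for(cfg, 0, 4), R=3)
        assert np.count_nonzero(table.C_plus) == 0

    def test_device_refusal_and_force(self, two_by_two):
        from csccp import DeviceProfile

        tiny = DeviceProfile(global_memory_bytes=8, shared_memory_bytes=49152)
        problem = problem_for(two_by_two, 0, 4)
        with pytest.raises(FeasibilityError):
            dp_forward(two_by_two, problem, R=2, device=tiny)
        table = dp_forward(two_by_two, problem, R=2, device=tiny, force=True)
        assert np.count_nonzero(table.C_plus) == 4


class TestEngineAndStorageEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_vectorized_bit_identical_to_sequential(self, seed, oracle_spec):
        """The all-masses-at-once update equals the four-nested-loop one."""
        cfg, peak = generate_instance(seed, oracle_spec)
        problem = integerize(peak, cfg)
        t_seq = dp_forward(cfg, problem, R=3, engine="sequential")
        t_vec = dp_forward(cfg, problem, R=3, engine="vectorized")
        np.testing.assert_array_equal(t_seq.C_plus, t_vec.C_plus)
        for (ks, rs), (kv, rv) in zip(t_seq.layers, t_vec.layers):
            np.testing.assert_array_equal(ks, kv)
            np.testing.assert_array_equal(rs, rv)

    @pytest.mark.parametrize("seed", range(12))
    def test_packed_storage_identical_results(self, seed, oracle_spec):
        cfg, peak = generate_instance(seed, oracle_spec)
        raw = solve_csccp(cfg, peak, 3, traceback="raw")
        packed = solve_csccp(cfg, peak, 3, traceback="packed")
        assert raw == packed


class TestFinalizeTopR:
    def test_window_restriction(self, two_by_two):
        problem = problem_for(two_by_two, 3, 3)
        table = dp_forward(two_by_two, problem, R=2)
        assert finalize_top_r(table, problem, 2) == [
            (3, 0, pytest.approx(0.18)),
            (3, 1, pytest.approx(0.08)),
        ]

    def test_empty_window(self, two_by_two):
        problem = problem_for(two_by_two, 5, 9)
        table = dp_forward(two_by_two, problem, R=2)
        assert finalize_top_r(table, problem, 2) == []

    def test_top_one_over_window(self, two_by_two):
        problem = problem_for(two_by_two, 2, 4)
        table = dp_forward(two_by_two, problem, R=1)
        assert finalize_top_r(table, problem, 1) == [(2, 0, pytest.approx(0.72))]


class TestBacktrack:
    def test_recovers_selections(self, two_by_two):
        problem = problem_for(two_by_two, 0, 4)
        table = dp_forward(two_by_two, problem, R=2)
        assert backtrack(table, problem, two_by_two, 3, 0) == (0, 1)
        assert backtrack(table, problem, two_by_two, 3, 1) == (1, 0)

    def test_single_position(self):
        cfg = ScaffoldConfiguration("ONE", 0, [1], [[10.0]], [[0.5]])
        problem = problem_for(cfg, 0, 12)
        table = dp_forward(cfg, problem, R=1)
        assert backtrack(table, problem, cfg, 10, 0) == (0,)

    def test_invalid_cell_raises(self, two_by_two):
        problem = problem_for(two_by_two, 0, 4)
        table = dp_forward(two_by_two, problem, R=2)
        with pytest.raises(TracebackCorruptionError):
            backtrack(table, problem, two_by_two, 1, 0)


class TestSolveCsccp:
    def test_running_example(self, two_by_two):
        out = solve_csccp(two_by_two, MassPeak(3, 3, 0), 3)
        assert [(c.selection, c.rank) for c in out] == [((0, 1), 0), ((1, 0), 1)]
        assert out[0].probability == pytest.approx(0.18)
        assert out[1].probability == pytest.approx(0.08)

    def test_r1_returns_argmax(self, two_by_two):
        out = solve_csccp(two_by_two, MassPeak(0, 10, 0), 1)
        assert len(out) == 1
        assert out[0].selection == (0, 0)
        assert out[0].probability == pytest.approx(0.72)

    def test_invalid_configuration_refused(self):
        bad = ScaffoldConfiguration("B", 0, [1], [[1.0]], [[1.5]])
        with pytest.raises(CsccpError):
            solve_csccp(bad, MassPeak(0, 2, 0), 1)

    def test_rank_monotone_window_sound(self, oracle_spec):
        for seed in range(30):
            cfg, peak = generate_instance(seed, oracle_spec)
            problem = integerize(peak, cfg)
            out = solve_csccp(cfg, peak, 5)
            probs = [c.probability for c in out]
            assert probs == sorted(probs, reverse=True)
            for c in out:
                assert problem.w_prime_min <= c.total_mass_int <= problem.w_prime_max
                assert c.probability > 0


class TestBruteForceOracle:
    def test_equiprobable_cube(self):
        """2^3 selections, all prob 0.125, all masses in [0, 3]."""
        cfg = ScaffoldConfiguration(
            "CUBE", 0, [2, 2, 2],
            [[0, 1], [0, 1], [0, 1]],
            [[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]],
        )
        out = brute_force_solve(cfg, MassPeak(0, 3, 0), 8)
        assert len(out) == 8
        assert all(c.probability == pytest.approx(0.125) for c in out)

    def test_empty_window(self, two_by_two):
        assert brute_force_solve(two_by_two, MassPeak(5, 9, 0), 3) == []

    def test_cap_refusal(self):
        cfg = ScaffoldConfiguration(
            "BIG", 0, [10] * 3, np.ones((3, 10)), np.full((3, 10), 0.1)
        )
        with pytest.raises(CsccpError):
            brute_force_solve(cfg, MassPeak(0, 30, 0), 3, cap=100)

    @pytest.mark.parametrize("R", [1, 3, 8])
    def test_dp_equals_oracle(self, R, oracle_spec):
        """Exact selection-by-selection agreement on random instances."""
        for seed in range(R, 60, 3):
            cfg, peak = generate_instance(seed, oracle_spec)
            assert solve_csccp(cfg, peak, R) == brute_force_solve(cfg, peak, R)

    def test_oracle_completeness(self, oracle_spec):
        """No enumerable in-window compound beats the last returned rank."""
        for seed in range(15):
            cfg, peak = generate_instance(seed, oracle_spec)
            dp = solve_csccp(cfg, peak, 3)
            all_hits = brute_force_solve(cfg, peak, 10**6)
            if dp:
                worst = dp[-1].probability
                better = [c for c in all_hits if c.probability > worst * (1 + 1e-12)]
                assert len(better) <= len(dp) - 1
            else:
                assert all_hits == []
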