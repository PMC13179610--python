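"""Probing policies, greedy selection, and offline evaluators."""

from itertools import combinations, product

import numpy as np
import pytest

from regprobe import (
    ADAPTIVITY_GAP_BOUND,
    ProbingInstance,
    WeightRealization,
    amp,
    ampcov,
    brute_force_select,
    evaluate_probe_set,
    f_cov,
    greedy_select,
    namp,
    nampcov,
    off,
    offline_ip,
    offline_lp_bound,
    run_policy,
    sample_realization,
)

from conftest import random_small_instance


class TestGreedySelect:
    def test_prop1_steps_and_value(self, counterexample):
        sel, value = greedy_select(counterexample.weights, 2)
        # picks regulator 4 (gain 3) then regulator 3 (gain 1)
        assert sel == [3, 2] and value == 4.0

    def test_l_zero_empty(self, counterexample):
        assert greedy_select(counterexample.weights, 0) == ([], 0.0)

    def test_nemhauser_ratio_on_exhaustive_binary_instances(self):
        # all 2^(6*4)? too many -- all C(6,2)-style binary matrices with
        # 6 regulators x 4 positions drawn from a fixed exhaustive family
        rng = np.random.default_rng(0)
        bound = 1 - 1 / np.e
        for _ in range(200):
            W = (rng.random((6, 4)) < 0.4).astype(float)
            opt = brute_force_select(W, 2)[1]
            if opt == 0:
                continue
            _, val = greedy_select(W, 2)
            assert val / opt >= bound - 1e-12

    def test_stops_when_gains_vanish(self):
        W = np.array([[2.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
        sel, value = greedy_select(W, 3)
        assert sel == [0] and value == 2.0


class TestOfflineEvaluators:
    def test_prop1_ip_and_off(self, counterexample):
        assert offline_ip(counterexample.weights, 2) == pytest.approx(4.0)
        assert off(counterexample.weights, 2)[1] == 4.0

    def test_sandwich_on_random_instances(self):
        # greedy Off <= brute force = IP <= LP on 50 random 6x6 instances
        rng = np.random.default_rng(42)
        for _ in range(50):
            W = rng.integers(0, 4, size=(6, 6)).astype(float)
            l = int(rng.integers(1, 5))
            bf = brute_force_select(W, l)[1]
            ip = offline_ip(W, l)
            lp = offline_lp_bound(W, l)
            greedy = off(W, l)[1]
            assert ip == pytest.approx(bf, abs=1e-6)
            assert lp >= ip - 1e-6
            assert greedy <= bf + 1e-9

    def test_layered_lp_equals_edge_variable_relaxation(self):
        # the shipped LP bound uses the layered (threshold-level) program;
        # its optimum must match the classic per-edge y-variable relaxation
        # solved independently, for integer and fractional weights alike
        from scipy.optimize import linprog

        from regprobe.algorithms import _coverage_program

        def edge_form(W, l):
            c, A, b, _, n_e = _coverage_program(W, l)
            if n_e == 0:
                return 0.0
            res = linprog(c, A_ub=A, b_ub=b, bounds=(0, 1), method="highs")
            assert res.success
            return -res.fun

        rng = np.random.default_rng(8)
        for _ in range(20):
            W = rng.integers(0, 5, size=(6, 5)).astype(float)
            l = int(rng.integers(1, 4))
            assert offline_lp_bound(W, l) == pytest.approx(edge_form(W, l), abs=1e-6)
        for _ in range(10):
            W = rng.random((5, 4)) * (rng.random((5, 4)) > 0.3)
            l = int(rng.integers(1, 4))
            assert offline_lp_bound(W, l) == pytest.approx(edge_form(W, l), abs=1e-6)

    def test_all_zero_matrix(self):
        assert offline_ip(np.zeros((3, 3)), 2) == 0.0
        assert offline_lp_bound(np.zeros((3, 3)), 2) == 0.0

    def test_l_at_least_one_required(self, counterexample):
        with pytest.raises(ValueError):
            offline_ip(counterexample.weights, 0)

    def test_adaptivity_gap_constant(self):
        assert round(ADAPTIVITY_GAP_BOUND, 2) == 1.58


class TestAmp:
    def test_deterministic_probes_by_score_order(self, counterexample):
        real = WeightRealization(counterexample.weights)
        run = amp(counterexample.instance, real, 4, 2, "sum")
        # row sums (1,1,1,3): regulator 4 first, rest by index
        assert run.probe_order == (3, 0, 1, 2)
        assert run.value == 4.0  # rows 4 and 1

    def test_probe_everything_reaches_optimum(self, rng):
        for kind in ("max", "sum"):
            inst = random_small_instance(rng, n_a=4, n_b=3, vmax=2)
            real = sample_realization(inst, rng)
            run = amp(inst, real, 4, 4, kind)
            W = real.weights
            scores = W.max(axis=1) if kind == "max" else W.sum(axis=1)
            assert run.value == pytest.approx(scores.sum())

    def test_two_by_one_first_probe_maximizes_expected_value(self):
        # pmfs over {0,1}: p0 = 0.9, p1 = 0.4; k = l = 1
        pmfs = np.array([[[0.1, 0.9]], [[0.6, 0.4]]])
        inst = ProbingInstance.from_pmfs(pmfs)
        real = WeightRealization(np.array([[1.0], [0.0]]))
        run = amp(inst, real, 1, 1, "sum")
        assert run.probe_order == (0,)

    def test_expected_final_value_matches_decision_tree(self):
        # 2 regulators x 1 position, Bernoulli weights; k=l=1 -- the policy
        # probes the higher-mean regulator, so its expected value is that
        # regulator's mean; verify by enumerating all 4 realizations
        p = np.array([0.7, 0.4])
        pmfs = np.zeros((2, 1, 2))
        pmfs[:, 0, 0] = 1 - p
        pmfs[:, 0, 1] = p
        inst = ProbingInstance.from_pmfs(pmfs)
        total = 0.0
        for w0, w1 in product((0, 1), repeat=2):
            prob = (p[0] if w0 else 1 - p[0]) * (p[1] if w1 else 1 - p[1])
            real = WeightRealization(np.array([[w0], [w1]], dtype=float))
            run = amp(inst, real, 1, 1, "sum")
            total += prob * run.value
        assert total == pytest.approx(0.7)

    def test_budget_validation(self, rng):
        inst = random_small_instance(rng)
        real = sample_realization(inst, rng)
        with pytest.raises(ValueError):
            amp(inst, real, 2, 3, "sum")  # l > k


class TestNamp:
    def test_deterministic_matches_amp_probe_set(self, counterexample):
        real = WeightRealization(counterexample.weights)
        for kind in ("max", "sum"):
            a = amp(counterexample.instance, real, 3, 2, kind)
            n = namp(counterexample.instance, 3, 2, kind)
            assert set(a.probe_order) == set(n)

    def test_prop1_sum_probes_tie_to_lowest_index(self, counterexample):
        # row sums 1,1,1,3: regulator 4 then the tie -> regulator 1
        assert namp(counterexample.instance, 2, 2, "sum") == [0, 3]

    def test_dominant_regulator_always_probed(self, rng):
        inst = random_small_instance(rng, n_a=5, n_b=3, vmax=2)
        pmfs = inst.pmfs.copy()
        pmfs[2] = 0.0
        pmfs[2, :, 2] = 1.0  # point mass at the top value everywhere
        dominant = ProbingInstance.from_pmfs(pmfs)
        for kind in ("max", "sum"):
            assert 2 in namp(dominant, 1, 1, kind)

    def test_probe_set_independent_of_realization(self, small_network_instance):
        sets = {tuple(namp(small_network_instance, 5, 2, "sum")) for _ in range(3)}
        assert len(sets) == 1


class TestAmpCov:
    def test_prop1_reaches_optimum(self, counterexample):
        real = WeightRealization(counterexample.weights)
        run = ampcov(counterexample.instance, real, 4, 2)
        assert run.value == 4.0

    def test_k_equals_l_uses_exact_phase_only(self, rng):
        # with k = l every probe comes from the exact-marginal phase, whose
        # step gains are the realized coverage increments
        inst = random_small_instance(rng, n_a=5, n_b=4, vmax=3)
        real = sample_realization(inst, rng)
        run = ampcov(inst, real, 3, 3)
        assert len(run.step_gains) == 3
        assert run.selected <= set(run.probe_order)

    def test_expected_value_matches_policy_tree_enumeration(self):
        # 3 regulators x 2 positions over {0,1}, k=2, l=1: enumerate all 2^6
        # realizations, run the policy on each, and compare the expected
        # value to an independent brute-force walk of the same decision tree
        rng = np.random.default_rng(5)
        p = rng.random((3, 2)) * 0.8 + 0.1
        pmfs = np.stack([1 - p, p], axis=2)
        inst = ProbingInstance.from_pmfs(pmfs)
        total = 0.0
        weight_total = 0.0
        for bits in range(2**6):
            w = np.array([(bits >> i) & 1 for i in range(6)]).reshape(3, 2).astype(float)
            prob = float(np.prod(np.where(w == 1, p, 1 - p)))
            run = ampcov(inst, WeightRealization(w), 2, 1)
            total += prob * run.value
            weight_total += prob
        assert weight_total == pytest.approx(1.0)
        # independent oracle: replay the policy defn by hand over the tree
        exp_gain0 = (pmfs[:, :, 1]).sum(axis=1)  # E[(w-0)+] per regulator
        first = int(np.argmax(exp_gain0))
        oracle = 0.0
        others = [a for a in range(3) if a != first]
        for w_first in product((0, 1), repeat=2):
            prob1 = np.prod([p[first, b] if v else 1 - p[first, b] for b, v in enumerate(w_first)])
            covered = np.array(w_first, dtype=float)
            # past the first l probes, a candidate's score is the greedy
            # selection value of {realized rows} + {its expected row} minus
            # the greedy value of the realized rows alone; at l=1 this is
            # max(0, sum of expected row - best realized row sum)
            base = covered.sum()
            gains = [max(0.0, p[a].sum() - base) for a in others]
            second = others[int(np.argmax(gains))]
            for w_second in product((0, 1), repeat=2):
                prob2 = np.prod(
                    [p[second, b] if v else 1 - p[second, b] for b, v in enumerate(w_second)]
                )
                rows = np.array([covered, np.array(w_second, dtype=float)])
                best = max(rows.sum(axis=1))  # l=1: best single row
                oracle += prob1 * prob2 * best
        assert total == pytest.approx(oracle, abs=1e-10)

    def test_feasibility_invariants(self, small_network_instance, rng):
        real = sample_realization(small_network_instance, rng)
        run = ampcov(small_network_instance, real, 8, 3)
        assert len(run.probe_order) == 8
        assert len(run.selected) <= 3
        assert run.selected <= set(run.probe_order)
        assert run.value == pytest.approx(f_cov(sorted(run.selected), real.weights))


class TestNampCov:
    def test_prop1_prefix_and_tail(self, counterexample):
        # exact phase picks 4 (gain 3) then 3 (gain 1); third probe is the
        # row-sum tie between regulators 1 and 2, broken to the lowest index
        assert nampcov(counterexample.instance, 3, 2) == [3, 2, 0]

    def test_k_equals_l_equals_one_picks_best_expected_row(self, rng):
        inst = random_small_instance(rng, n_a=5, n_b=4, vmax=3)
        probe = nampcov(inst, 1, 1)
        assert probe == [int(np.argmax(inst.expected().sum(axis=1)))]

    def test_probe_set_deterministic_function_of_instance(self, small_network_instance):
        a = nampcov(small_network_instance, 6, 3)
        b = nampcov(small_network_instance, 6, 3)
        assert a == b

    def test_prefix_matches_expected_fcov_greedy_oracle(self, rng):
        from regprobe import expected_fcov

        inst = random_small_instance(rng, n_a=6, n_b=4, vmax=3)
        prefix = nampcov(inst, 3, 3)
        chosen = []
        for _ in range(3):
            gains = []
            for a in range(6):
                if a in chosen:
                    gains.append(-np.inf)
                    continue
                base = expected_fcov(chosen, inst) if chosen else 0.0
                gains.append(expected_fcov(chosen + [a], inst) - base)
            chosen.append(int(np.argmax(gains)))
        assert prefix == chosen


class TestRunPolicy:
    @pytest.mark.parametrize("algorithm", ["amp", "namp", "ampcov", "nampcov", "off"])
    def test_feasibility_for_all_policies(self, small_network_instance, rng, algorithm):
        objective = "sum" if algorithm in ("amp", "namp") else "cov"
        real = sample_realization(small_network_instance, rng)
        run = run_policy(small_network_instance, real, algorithm, 6, 2, objective)
        assert len(run.selected) <= 2
        assert run.selected <= set(run.probe_order)

    def test_deterministic_full_probe_equals_off(self, counterexample):
        real = WeightRealization(counterexample.weights)
        n = counterexample.instance.n_regulators
        off_value = off(counterexample.weights, 2)[1]
        for algorithm in ("ampcov", "nampcov"):
            run = run_policy(counterexample.instance, real, algorithm, n, 2)
            assert run.value == off_value

    def test_adaptive_mean_at_k_equals_l_dominates_nonadaptive(self):
        # on sampled small instances the adaptive coverage policy should
        # (weakly) beat the non-adaptive one on average at k = l; tested as
        # a one-sided mean comparison with generous tolerance
        rng = np.random.default_rng(11)
        amp_vals, namp_vals = [], []
        for i in range(100):
            inst = random_small_instance(rng, n_a=6, n_b=5, vmax=3)
            real = sample_realization(inst, rng)
            amp_vals.append(ampcov(inst, real, 3, 3).value)
            probe = nampcov(inst, 3, 3)
            namp_vals.append(evaluate_probe_set(probe, real, 3).value)
        assert np.mean(amp_vals) >= np.mean(namp_vals) - 0.05 * np.mean(namp_vals)

    def test_evaluate_probe_set_consistency(self, counterexample):
        real = WeightRealization(counterexample.weights)
        run = evaluate_probe_set([3, 2], real, 2)
        assert run.value == 4.0 and run.selected == frozenset({2, 3})
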