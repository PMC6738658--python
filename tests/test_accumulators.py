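import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskgaze.accumulators import (VARIANTS, AccumulatorState, AttributeInputs,
                                   ProcessParams, batch_final_states,
                                   choice_prob_from_final, init_inputs,
                                   layer2_inputs, make_batch, run_sequence,
                                   step)
from riskgaze.design import DesignConfig

from conftest import make_problem, make_trial, random_clean_sequence


def naive_simulate(problem, seq, params, config, variant,
                   default_substitution=True):
    """Brute-force scalar reference: a plain loop over the update rules."""
    xs = [problem.option_a.amount, problem.option_b.amount]
    ps = [problem.option_a.prob, problem.option_b.prob]
    x_def = (min(config.amount_levels) + max(config.amount_levels)) / 2
    p_def = (min(config.prob_levels) + max(config.prob_levels)) / 2
    seen = [default_substitution is False] * 4
    a = [0.0, 0.0, 0.0, 0.0]
    y = [0.0, 0.0]

    def raw(m):
        if m % 2 == 0:
            return xs[m // 2] if seen[m] else x_def
        return ps[m // 2] if seen[m] else p_def

    def subj(m):
        v = raw(m)
        if m % 2 == 0:
            return v ** params.alpha
        g = params.gamma
        return v ** g / (v ** g + (1 - v) ** g) ** (1 / g)

    def norm(m):
        v = raw(m)
        if m % 2 == 0:
            lo, hi = min(config.amount_levels), max(config.amount_levels)
        else:
            lo, hi = min(config.prob_levels), max(config.prob_levels)
        return (v - lo) / (hi - lo)

    pair = [2, 3, 0, 1]
    for k in seq:
        seen[k] = True
        keep = 1 - params.lam
        opt, oth = (0, 1) if k < 2 else (1, 0)
        y = [keep * y[0], keep * y[1]]
        if variant in ("two_layer", "hybrid"):
            new_a = []
            for m in range(4):
                w = 1.0 if m == k else params.theta
                v = keep * a[m] + w * subj(m)
                if variant == "hybrid":
                    v = max(v - params.iota * a[pair[m]], 0.0)
                new_a.append(v)
            a = new_a
            y[0] += a[0] * a[1]
            y[1] += a[2] * a[3]
        elif variant == "one_layer":
            su = [subj(0) * subj(1), subj(2) * subj(3)]
            y[opt] += su[opt]
            y[oth] += params.theta * su[oth]
        elif variant == "wa_normalized":
            d = norm(k) - params.theta * norm(pair[k])
            y[opt] += d
            y[oth] -= d
        else:
            vf, vo = raw(k), raw(pair[k])
            if vf > params.theta * vo:
                y[opt] += 1.0
            elif vf < params.theta * vo:
                y[oth] += 1.0
    return y


def random_params(rng, variant):
    return ProcessParams(alpha=float(rng.uniform(0.2, 1.8)),
                         gamma=float(rng.uniform(0.3, 1.8)),
                         theta=float(rng.uniform(0, 1)),
                         lam=float(rng.uniform(0, 1)),
                         iota=float(rng.uniform(0, 0.5)),
                         beta=1.0)


class TestStepExamples:
    def test_two_layer_hand_example(self, config):
        # subjective values (2, .5, 1, .8) via identity transforms
        prob = make_problem(2, 0.5, 1, 0.8)
        params = ProcessParams(alpha=1, gamma=1, theta=0.3, lam=0.0)
        inp = init_inputs(prob, config)
        inp.seen[:] = True
        st_ = step(AccumulatorState(), 0, inp, params, "two_layer")
        np.testing.assert_allclose(st_.layer1, [2, 0.15, 0.3, 0.24])
        np.testing.assert_allclose(st_.layer2, [0.3, 0.072])

    def test_two_layer_full_leak_zero_attenuation(self, config):
        prob = make_problem(2, 0.5, 1, 0.8)
        params = ProcessParams(alpha=1, gamma=1, theta=0.0, lam=1.0)
        inp = init_inputs(prob, config)
        inp.seen[:] = True
        st_ = step(AccumulatorState(layer1=np.ones(4), layer2=np.ones(2)),
                   0, inp, params, "two_layer")
        # a_xA = 2, a_pA = 0 -> product gated to 0
        assert st_.layer2[0] == pytest.approx(0.0)

    def test_wa_normalized_hand_example(self, config):
        prob = make_problem(24, 0.1, 6, 0.5)
        params = ProcessParams(theta=0.5, lam=0.0)
        inp = init_inputs(prob, config)
        inp.seen[:] = True
        st_ = step(AccumulatorState(), 0, inp, params, "wa_normalized")
        assert st_.layer2[0] == pytest.approx(21 / 27 - 0.5 * 3 / 27)
        assert st_.layer2[1] == pytest.approx(-(21 / 27 - 0.5 * 3 / 27))

    def test_wa_categorical_winner_increments(self, config):
        prob = make_problem(20, 0.5, 10, 0.2)
        params = ProcessParams(theta=1.0, lam=0.0)
        inp = init_inputs(prob, config)
        inp.seen[:] = True
        st_ = step(AccumulatorState(), 0, inp, params, "wa_categorical")
        np.testing.assert_allclose(st_.layer2, [1.0, 0.0])

    def test_wa_categorical_tie_no_increment(self, config):
        prob = make_problem(10, 0.5, 10, 0.2)
        params = ProcessParams(theta=1.0, lam=0.0)
        inp = init_inputs(prob, config)
        inp.seen[:] = True
        st_ = step(AccumulatorState(), 0, inp, params, "wa_categorical")
        np.testing.assert_allclose(st_.layer2, [0.0, 0.0])

    def test_unknown_variant(self, config):
        prob = make_problem(24, .1, 6, .5)
        inp = init_inputs(prob, config)
        inp.seen[:] = True
        with pytest.raises(ValueError):
            step(AccumulatorState(), 0, inp, ProcessParams(), "three_layer")


class TestInitInputs:
    def test_paper_defaults(self, config):
        prob = make_problem(24, .1, 6, .5)
        inp = init_inputs(prob, config)
        np.testing.assert_allclose(inp.raw(), [16.5, 0.55, 16.5, 0.55])

    def test_substitution_at_first_fixation(self, config):
        prob = make_problem(24, .1, 6, .5)
        inp = init_inputs(prob, config)
        inp.seen[0] = True
        np.testing.assert_allclose(inp.raw(), [24, 0.55, 16.5, 0.55])

    def test_identity_transforms_pass_raw_defaults(self, config):
        prob = make_problem(24, .1, 6, .5)
        inp = init_inputs(prob, config)
        np.testing.assert_allclose(inp.subjective(1.0, 1.0),
                                   [16.5, 0.55, 16.5, 0.55])


class TestRunSequenceClosedForms:
    def test_one_layer_no_leak_full_attention(self, config):
        prob = make_problem(24, .2, 6, .5)
        params = ProcessParams(alpha=0.8, gamma=0.7, theta=1.0, lam=0.0)
        seq = [0, 1, 2, 3, 0, 1, 2]
        res = run_sequence(prob, seq, params, "one_layer", config,
                           default_substitution=False)
        su_a = 24 ** 0.8 * (0.2 ** 0.7 / (0.2 ** 0.7 + 0.8 ** 0.7) ** (1 / 0.7))
        assert res["Y_A"] == pytest.approx(len(seq) * su_a, rel=1e-12)

    def test_one_layer_no_leak_zero_attenuation(self, config):
        prob = make_problem(24, .2, 6, .5)
        params = ProcessParams(alpha=1.0, gamma=1.0, theta=0.0, lam=0.0)
        seq = [0, 2, 1, 2, 3, 0]
        res = run_sequence(prob, seq, params, "one_layer", config,
                           default_substitution=False)
        n_a = sum(1 for k in seq if k < 2)
        assert res["Y_A"] == pytest.approx(n_a * 24 * 0.2, rel=1e-12)

    def test_two_layer_cascade_sum_of_squares(self, config):
        prob = make_problem(24, .2, 6, .5)
        params = ProcessParams(alpha=1.0, gamma=1.0, theta=1.0, lam=0.0)
        T = 7
        res = run_sequence(prob, [0] * 1 + [1, 0] * 3, params, "two_layer",
                           config, default_substitution=False)
        expected = 24 * 0.2 * T * (T + 1) * (2 * T + 1) / 6
        assert res["Y_A"] == pytest.approx(expected, rel=1e-12)

    def test_empty_sequence_errors(self, config):
        with pytest.raises(ValueError):
            run_sequence(make_problem(24, .1, 6, .5), [], ProcessParams(),
                         "one_layer", config)


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_naive_simulator(self, variant, config):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            prob = make_problem(*_random_problem(rng))
            seq = random_clean_sequence(rng, int(rng.integers(1, 16)))
            params = random_params(rng, variant)
            res = run_sequence(prob, seq, params, variant, config)
            ref = naive_simulate(prob, seq, params, config, variant)
            assert res["Y_A"] == pytest.approx(ref[0], rel=1e-12, abs=1e-12)
            assert res["Y_B"] == pytest.approx(ref[1], rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_batch_matches_run_sequence(self, variant, config):
        rng = np.random.default_rng(7)
        trials = []
        for i in range(25):
            prob = make_problem(*_random_problem(rng), pid=f"p{i}")
            seq = random_clean_sequence(rng, int(rng.integers(1, 14)))
            trials.append(make_trial(prob, seq, tid=f"t{i}"))
        params = random_params(rng, variant)
        batch = make_batch(trials, config)
        Y = batch_final_states(batch, params, variant)
        for i, t in enumerate(trials):
            ref = run_sequence(t.problem, t.aoi_indices, params, variant, config)
            assert Y[i, 0] == pytest.approx(ref["Y_A"], rel=1e-12, abs=1e-12)
            assert Y[i, 1] == pytest.approx(ref["Y_B"], rel=1e-12, abs=1e-12)


class TestInvariantReductions:
    def test_hybrid_iota_zero_equals_two_layer(self, config):
        rng = np.random.default_rng(5)
        for _ in range(20):
            prob = make_problem(*_random_problem(rng))
            seq = random_clean_sequence(rng, 10)
            p = random_params(rng, "hybrid")
            p0 = ProcessParams(**{**p.__dict__, "iota": 0.0})
            a = run_sequence(prob, seq, p0, "hybrid", config)
            b = run_sequence(prob, seq, p0, "two_layer", config)
            assert a["Y_A"] == b["Y_A"] and a["Y_B"] == b["Y_B"]  # bit-exact

    def test_lam_zero_is_perfect_integration(self, config):
        rng = np.random.default_rng(6)
        prob = make_problem(24, .2, 6, .5)
        seq = random_clean_sequence(rng, 12)
        for variant in VARIANTS:
            params = ProcessParams(alpha=0.8, gamma=0.7, theta=0.4, lam=0.0,
                                   iota=0.1)
            res = run_sequence(prob, seq, params, variant, config)
            inputs = layer2_inputs(prob, seq, params, variant, config)
            np.testing.assert_allclose([res["Y_A"], res["Y_B"]],
                                       inputs.sum(axis=0), rtol=1e-12)

    def test_lam_one_is_memoryless(self, config):
        # with full leak the final state depends only on the last fixation
        # (once all attributes have been seen)
        prob = make_problem(24, .2, 6, .5)
        seq = [0, 1, 2, 3, 0, 2]
        params = ProcessParams(alpha=0.8, gamma=0.7, theta=0.4, lam=1.0)
        for variant in VARIANTS:
            res = run_sequence(prob, seq, params, variant, config)
            last_only = run_sequence(prob, seq[-1:], params, variant, config,
                                     default_substitution=False)
            np.testing.assert_allclose(
                res["trace_layer2"][-1],
                [last_only["Y_A"], last_only["Y_B"]], rtol=1e-12)

    def test_two_layer_full_leak_matches_one_layer(self, config):
        prob = make_problem(24, .2, 6, .5)
        seq = [0, 1, 2, 3, 0, 2, 1]
        params = ProcessParams(alpha=0.8, gamma=0.7, theta=1.0, lam=1.0)
        two = layer2_inputs(prob, seq, params, "two_layer", config)
        one = layer2_inputs(prob, seq, params, "one_layer", config)
        np.testing.assert_allclose(two, one, rtol=1e-12)

    def test_swap_symmetry(self, config):
        rng = np.random.default_rng(8)
        for variant in VARIANTS:
            xa, pa, xb, pb = _random_problem(rng)
            prob = make_problem(xa, pa, xb, pb)
            mirror = make_problem(xb, pb, xa, pa)
            seq = random_clean_sequence(rng, 11)
            mirrored = [(k + 2) % 4 for k in seq]
            p = random_params(rng, variant)
            a = run_sequence(prob, seq, p, variant, config)
            b = run_sequence(mirror, mirrored, p, variant, config)
            assert a["Y_A"] == pytest.approx(b["Y_B"], abs=1e-12)
            assert a["Y_B"] == pytest.approx(b["Y_A"], abs=1e-12)

    def test_wa_categorical_bounded_by_fixations(self, config):
        rng = np.random.default_rng(9)
        prob = make_problem(24, .2, 6, .5)
        for _ in range(10):
            n = int(rng.integers(1, 20))
            seq = random_clean_sequence(rng, n)
            params = ProcessParams(theta=float(rng.uniform(0, 1)), lam=0.0)
            res = run_sequence(prob, seq, params, "wa_categorical", config)
            assert res["Y_A"] + res["Y_B"] <= n + 1e-12


class TestChoiceProb:
    def test_equal_states(self):
        assert choice_prob_from_final(2.0, 2.0, 5.0) == pytest.approx(0.5)

    def test_swap_complement(self):
        p = choice_prob_from_final(3.0, 1.0, 0.7)
        q = choice_prob_from_final(1.0, 3.0, 0.7)
        assert p + q == pytest.approx(1.0)

    def test_symmetric_problem_symmetric_sequence(self, config):
        prob = make_problem(24, .2, 24, .2)
        seq = [0, 2, 1, 3]  # balanced over both options
        params = ProcessParams(alpha=0.8, gamma=0.7, theta=0.4, lam=0.3)
        res = run_sequence(prob, seq, params, "two_layer", config)
        # same lottery twice with count-matched fixations: near-symmetric
        rev = run_sequence(prob, [(k + 2) % 4 for k in seq], params,
                           "two_layer", config)
        p1 = choice_prob_from_final(res["Y_A"], res["Y_B"], params.beta)
        p2 = choice_prob_from_final(rev["Y_A"], rev["Y_B"], params.beta)
        assert p1 + p2 == pytest.approx(1.0)


def _random_problem(rng):
    xa, xb = rng.uniform(1, 30, 2)
    pa, pb = rng.uniform(0.05, 1.0, 2)
    return float(xa), float(pa), float(xb), float(pb)
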