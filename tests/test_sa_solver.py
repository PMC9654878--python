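import math

import numpy as np
import pytest

from ecgstego.embed_core import frame_snr, optimal_frame_modification
from ecgstego.sa_solver import (
    SAParams,
    acceptance_probability,
    anneal,
    anneal_frames,
    project_mean_floor,
    project_sum_cap,
)


class TestAcceptanceProbability:
    def test_improvements_always_accepted(self):
        assert acceptance_probability(-2.0, 1.0) == 1.0
        assert acceptance_probability(0.0, 5.0) == 1.0

    def test_metropolis_value(self):
        assert np.isclose(acceptance_probability(1.0, 1.0), math.exp(-1))

    def test_vanishes_for_huge_penalty(self):
        assert acceptance_probability(1e6, 1.0) == 0.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 0.0)


class TestSAParams:
    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            SAParams(initial_temperature=1e-3, final_temperature=1.0)
        with pytest.raises(ValueError):
            SAParams(cooling_rate=1.0)
        with pytest.raises(ValueError):
            SAParams(iterations_per_temperature=0)

    def test_default_schedule_size(self):
        p = SAParams()
        assert p.n_temperatures == 135
        assert p.total_iterations == 135 * 50


class TestProjections:
    def test_mean_floor_exact(self, rng):
        x = rng.normal(size=(20, 4))
        floor = rng.uniform(0.5, 2.0, 20)
        y = project_mean_floor(x, floor)
        assert np.all(y >= 0)
        assert np.all(y.mean(axis=1) >= floor)

    def test_sum_cap_exact_and_clamped(self, rng):
        x = rng.uniform(0, 10, size=(20, 4))
        cap = rng.uniform(0.0, 10.0, 20)
        y = project_sum_cap(x, cap)
        assert np.all(y >= 0)
        assert np.all(y.sum(axis=1) <= cap)

    def test_sum_cap_is_water_filling(self):
        y = project_sum_cap(np.array([[0.5, 7.5]]), np.array([6.0]))
        assert np.allclose(y, [[0.0, 6.0]])


class TestAnneal:
    def test_finds_known_optimum_in_one_dimension(self):
        energy = lambda x: float((x[0] - 5.0) ** 2)
        project = lambda x: np.maximum(x, 0.0)
        best = anneal(np.array([0.5]), energy, project, SAParams(proposal_sd=0.25, seed=3))
        assert abs(best[0] - 5.0) < 1e-3

    def test_reaches_oracle_frame_snr(self):
        # Frame (3,5), bit 1, eps=1: oracle SNR is 12.3045 dB.
        orig = np.array([3.0, 5.0])
        floor = np.array([orig.mean() + 1.0])
        best = anneal(
            orig + 1.0,
            lambda x: -frame_snr(orig, x),
            lambda x: project_mean_floor(x, floor)[0],
            SAParams(proposal_sd=0.25, seed=0),
        )
        assert frame_snr(orig, best) > 12.3045 - 0.5
        assert best.mean() >= floor[0]

    def test_same_seed_same_trajectory(self):
        energy = lambda x: float((x ** 2).sum())
        project = lambda x: np.maximum(x, 0.0)
        p = SAParams(proposal_sd=1.0, seed=11)
        a, trace_a = anneal(np.array([3.0, 4.0]), energy, project, p, return_trace=True)
        b, trace_b = anneal(np.array([3.0, 4.0]), energy, project, p, return_trace=True)
        assert np.array_equal(a, b)
        assert trace_a == trace_b

    def test_best_energy_never_increases(self):
        energy = lambda x: float((x[0] - 2.0) ** 2)
        project = lambda x: np.maximum(x, 0.0)
        _, trace = anneal(
            np.array([9.0]), energy, project,
            SAParams(proposal_sd=0.5, seed=2), return_trace=True,
        )
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_zero_temperature_limit_is_projected_greedy_descent(self):
        energy = lambda x: float((x[0] - 5.0) ** 2)
        project = lambda x: np.maximum(x, 0.0)
        p = SAParams(
            initial_temperature=1e-9, final_temperature=1e-10, cooling_rate=0.5,
            iterations_per_temperature=300, proposal_sd=0.5, seed=7,
        )
        got = anneal(np.array([0.5]), energy, project, p)
        # independent greedy reference consuming the same random stream
        rng = np.random.default_rng(7)
        cur = project(np.array([0.5]))
        e_cur = energy(cur)
        best, e_best = cur.copy(), e_cur
        t = p.initial_temperature
        while t > p.final_temperature:
            for _ in range(p.iterations_per_temperature):
                cand = project(cur + rng.normal(0.0, 0.5, 1))
                e_cand = energy(cand)
                rng.uniform()  # the annealer draws one uniform per iteration
                if e_cand <= e_cur:
                    cur, e_cur = cand, e_cand
                    if e_cur < e_best:
                        best, e_best = cand.copy(), e_cur
            t *= p.cooling_rate
        assert np.array_equal(got, best)


class TestAnnealFrames:
    def test_feasible_and_near_oracle(self, rng):
        n = 3
        mags = rng.uniform(2500, 8000, size=(8, n))  # bit-0 targets stay reachable
        bits = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=np.uint8)
        eps, delta = 2000.0, 2e-3
        oracle = np.stack(
            [optimal_frame_modification(mags[f], int(bits[f]), eps, delta).magnitudes
             for f in range(8)]
        )
        out = anneal_frames(mags, bits, eps, delta, SAParams(seed=5), initial=oracle)
        m = mags.mean(axis=1)
        for f in range(8):
            if bits[f] == 1:
                assert out[f].mean() >= m[f] + eps
            else:
                assert out[f].sum() <= (m[f] - eps - delta) * n
            sa_cost = ((out[f] - mags[f]) ** 2).sum()
            oracle_cost = ((oracle[f] - mags[f]) ** 2).sum()
            assert sa_cost >= oracle_cost - 1e-6  # oracle is the true optimum
            assert sa_cost <= oracle_cost * 10 ** 0.05  # within 0.5 dB

    def test_frame_results_independent_of_batching(self, rng):
        mags = rng.uniform(0, 5000, size=(6, 2))
        bits = np.array([1, 0, 0, 1, 1, 0], dtype=np.uint8)
        oracle = np.stack(
            [optimal_frame_modification(mags[f], int(bits[f]), 1000.0, 0.0).magnitudes
             for f in range(6)]
        )
        p = SAParams(seed=2)
        whole = anneal_frames(mags, bits, 1000.0, 0.0, p, initial=oracle)
        chunked = anneal_frames(mags, bits, 1000.0, 0.0, p, initial=oracle, chunk_size=2)
        assert np.array_equal(whole, chunked)
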