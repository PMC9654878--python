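import math

import numpy as np
import pytest

from _oracles import grid_search_modification, uniform_shift_snr_db
from ecgstego.embed_core import (
    EmbedParams,
    embed,
    frame_mean,
    frame_snr,
    optimal_frame_modification,
    thresholds,
)
from ecgstego.extract_core import ExtractParams, extract
from ecgstego.payload_codec import BitPayload
from ecgstego.signal_core import synth_ecg


class TestFrameStatistics:
    def test_frame_mean(self):
        assert frame_mean([3.0, 5.0]) == 4.0
        assert frame_mean([7.25]) == 7.25
        assert frame_mean([0.0, 0.0, 0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            frame_mean([])

    def test_thresholds(self):
        assert thresholds(4.0, 1.0) == (5.0, 3.0)
        assert thresholds(0.0, 2000.0) == (2000.0, -2000.0)
        with pytest.raises(ValueError):
            thresholds(4.0, 0.0)


class TestOptimalFrameModification:
    def test_bit1_adds_strength_uniformly(self):
        out = optimal_frame_modification([3.0, 5.0], 1, 1.0)
        assert np.allclose(out.magnitudes, [4.0, 6.0])
        assert not out.infeasible
        assert out.magnitudes.mean() >= 5.0  # h1

    def test_bit0_subtracts_uniformly(self):
        out = optimal_frame_modification([3.0, 5.0], 0, 1.0)
        assert np.allclose(out.magnitudes, [2.0, 4.0])

    def test_bit0_water_filling_clamps_at_zero(self):
        # m=4, target mean 3; uniform subtraction would drive 0.5 negative.
        out = optimal_frame_modification([0.5, 7.5], 0, 1.0)
        assert np.allclose(out.magnitudes, [0.0, 6.0])
        cost = ((out.magnitudes - [0.5, 7.5]) ** 2).sum()
        assert np.isclose(cost, 2.5)

    def test_zero_strength_limit_is_identity_for_bit1(self, rng):
        mags = rng.uniform(0, 10, 4)
        out = optimal_frame_modification(mags, 1, 0.0)
        assert np.array_equal(out.magnitudes, mags)

    def test_frame_too_small_for_bit0_flagged(self):
        out = optimal_frame_modification([1.0, 1.0], 0, 2.0)
        assert out.infeasible
        assert np.array_equal(out.magnitudes, [0.0, 0.0])

    def test_matches_exhaustive_grid_search(self, rng):
        # The closed form is never beaten by any feasible grid point.
        for _ in range(150):
            n = int(rng.integers(1, 5))
            mags = rng.integers(0, 7, n).astype(float)
            bit = int(rng.integers(0, 2))
            eps = float(rng.integers(1, 3))
            out = optimal_frame_modification(mags, bit, eps)
            ref, ref_cost = grid_search_modification(mags, bit, eps)
            if out.infeasible:
                assert ref is None
                continue
            cost = ((out.magnitudes - mags) ** 2).sum()
            assert cost <= ref_cost + 1e-9


class TestFrameSnr:
    def test_hand_computed_value(self):
        assert np.isclose(frame_snr([3.0, 5.0], [4.0, 6.0]), -10 * math.log10(2 / 34))

    def test_zero_modification_is_infinite(self):
        assert frame_snr([3.0, 5.0], [3.0, 5.0]) == math.inf

    def test_log_law_under_scaling(self):
        orig = np.array([3.0, 5.0])
        small = orig + 0.1
        big = orig + 1.0
        assert np.isclose(frame_snr(orig, small) - frame_snr(orig, big), 20.0)

    def test_zero_energy_frame_errors(self):
        with pytest.raises(ValueError):
            frame_snr([0.0, 0.0], [1.0, 0.0])


class TestEmbed:
    def setup_method(self):
        self.sig = synth_ecg(4096, seed=3)
        self.body = np.random.default_rng(9).integers(0, 2, 16, dtype=np.uint8)
        self.pay = BitPayload.from_body(self.body)

    def test_round_trip_all_constraints_hold(self):
        params = EmbedParams(strength=4000.0, block_size=4, solver="oracle")
        res = embed(self.sig, self.pay, params)
        f = res.frames
        ones = f["bit"] == 1
        assert (f.loc[ones, "statistic"] >= f.loc[ones, "h1"]).all()
        assert (f.loc[~ones, "statistic"] <= f.loc[~ones, "h0"]).all()
        got = extract(res.signal, ExtractParams(block_size=4))
        assert np.array_equal(got.bits, self.pay.bits)

    def test_only_approximation_band_changes(self):
        params = EmbedParams(solver="oracle")
        res = embed(self.sig, self.pay, params)
        orig = __import__("ecgstego").dwt(self.sig, 5)
        for j in range(5):
            assert np.array_equal(res.pyramid.details[j], orig.details[j])
        assert not np.array_equal(res.pyramid.approx, orig.approx)

    def test_frames_beyond_payload_untouched(self):
        params = EmbedParams(solver="oracle")
        res = embed(self.sig, self.pay, params)
        orig = __import__("ecgstego").dwt(self.sig, 5)
        used = len(self.pay.bits) * 4
        assert np.array_equal(res.pyramid.approx[used:], orig.approx[used:])

    def test_whole_signal_snr_matches_parseval_closed_form(self):
        params = EmbedParams(strength=3000.0, block_size=4, solver="oracle")
        res = embed(self.sig, self.pay, params)
        expected = uniform_shift_snr_db(
            self.sig.samples, self.pay.bits, 3000.0, params.delta, 4
        )
        assert res.n_infeasible == 0
        assert np.isclose(res.snr_db, expected, rtol=1e-6)

    def test_snr_strictly_decreasing_in_strength(self):
        snrs = [
            embed(self.sig, self.pay, EmbedParams(strength=e, solver="oracle")).snr_db
            for e in (1000.0, 2000.0, 4000.0)
        ]
        assert snrs[0] > snrs[1] > snrs[2]

    def test_capacity_exceeded_names_capacity(self):
        bits = np.zeros(33, dtype=np.uint8)  # capacity is 32 at n=4, k=5
        with pytest.raises(ValueError, match="I=32"):
            embed(self.sig, bits, EmbedParams(solver="oracle"))

    def test_raw_bit_payloads_accepted(self):
        bits = np.array([1, 0, 1, 1], dtype=np.uint8)
        res = embed(self.sig, bits, EmbedParams(solver="oracle"))
        assert np.array_equal(res.bits, bits)

    def test_sa_solver_validates_same_constraints(self):
        res = embed(self.sig, self.pay, EmbedParams(solver="sa"))
        f = res.frames
        ones = f["bit"] == 1
        assert (f.loc[ones, "statistic"] >= f.loc[ones, "h1"]).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EmbedParams(strength=-1.0)
        with pytest.raises(ValueError):
            EmbedParams(solver="magic")
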