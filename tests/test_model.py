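import math

import numpy as np
import pytest

from sagloc import (
    Direction,
    DTFSet,
    InternalRepresentation,
    InvalidParameterError,
    ModelConfig,
    binaural_weights,
    interspectral_distance,
    predict_pmv,
    similarity,
)
from sagloc.model import PMV, Predictor
from sagloc.periphery import band_magnitudes

BANDS = np.arange(28, dtype=float) * 100.0 + 700.0


def rep(values):
    return InternalRepresentation(BANDS[: len(values)], np.asarray(values, float))


class TestInterspectralDistance:
    def test_identical_is_zero(self):
        r = rep(np.arange(28.0))
        assert interspectral_distance(r, r) == 0.0

    def test_constant_offset_is_zero(self):
        # a +6 dB overall level change leaves the SD metric unchanged
        r = rep(np.arange(28.0))
        shifted = rep(np.arange(28.0) + 6.0)
        assert interspectral_distance(r, shifted) == pytest.approx(0.0, abs=1e-12)

    def test_sample_sd_oracle(self):
        # SD with denominator N-1 of differences {0, 10, 20} is 10
        a = rep([0.0, 0.0, 0.0])
        b = rep([0.0, 10.0, 20.0])
        assert interspectral_distance(a, b) == pytest.approx(10.0)

    def test_band_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            interspectral_distance(rep([0.0, 1.0]), rep([0.0, 1.0, 2.0]))


class TestSimilarity:
    def test_zero_distance(self):
        assert similarity(0.0, 2.0) == 1.0

    def test_distance_equals_u(self):
        assert similarity(1.7, 1.7) == pytest.approx(math.exp(-0.5))

    def test_analytic_value(self):
        assert similarity(2.0, 1.0) == pytest.approx(math.exp(-2.0))

    @pytest.mark.parametrize("u", [0.0, -1.0])
    def test_invalid_u(self, u):
        with pytest.raises(InvalidParameterError):
            similarity(1.0, u)


class TestBinauralWeights:
    def test_midline_symmetry(self):
        assert binaural_weights(0.0) == (0.5, 0.5)

    def test_at_width(self):
        w_l, w_r = binaural_weights(13.3, 13.3)
        assert w_l == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))
        assert w_l + w_r == pytest.approx(1.0)

    def test_contralateral_silenced(self):
        w_l, _ = binaural_weights(-90.0, 13.3)
        assert w_l == pytest.approx(1.0 / (1.0 + math.exp(90.0 / 13.3)), rel=1e-6)
        assert w_l < 0.002


class TestPredictPmv:
    def test_self_match_peaks_at_target(self, listener_dtf):
        pmv = predict_pmv(Direction(0.0, 0.0), listener_dtf, U=0.1)
        assert pmv.response_angles[np.argmax(pmv.probabilities)] == 0.0

    def test_cue_free_is_uniform(self, flat_dtf):
        pmv = predict_pmv(Direction(0.0, 40.0), flat_dtf, U=2.0)
        assert np.allclose(pmv.probabilities, 1.0 / pmv.probabilities.size)

    def test_level_rove_invariance(self, listener_dtf):
        # +5 dB on the incoming DTF leaves the PMV untouched
        shifted = DTFSet(
            listener_id="S",
            directions=list(listener_dtf.directions),
            freq=listener_dtf.freq,
            magnitude=listener_dtf.magnitude + 5.0,
            sampling_rate=listener_dtf.sampling_rate,
        )
        base = predict_pmv(Direction(0.0, 30.0), listener_dtf, U=2.0)
        roved = predict_pmv(Direction(0.0, 30.0), shifted, listener_dtf, U=2.0)
        assert np.abs(roved.probabilities - base.probabilities).max() <= 1e-9

    def test_off_grid_target_snaps_to_nearest(self, listener_dtf):
        on = predict_pmv(Direction(0.0, 30.0), listener_dtf, U=2.0)
        off = predict_pmv(Direction(0.0, 31.0), listener_dtf, U=2.0)
        assert np.allclose(on.probabilities, off.probabilities)

    def test_uncovered_segment_rejected(self, listener_dtf):
        with pytest.raises(InvalidParameterError):
            predict_pmv(Direction(60.0, 0.0), listener_dtf, U=2.0)

    def test_entropy_nondecreasing_in_u(self, predictor):
        entropies = [
            predictor.pmv(Direction(0.0, 0.0), u).entropy()
            for u in np.arange(0.5, 4.01, 0.5)
        ]
        assert np.all(np.diff(entropies) >= -1e-12)

    def test_template_order_irrelevant(self, listener_dtf, rng):
        order = rng.permutation(listener_dtf.n_directions)
        shuffled = DTFSet(
            listener_id="P",
            directions=[listener_dtf.directions[i] for i in order],
            freq=listener_dtf.freq,
            magnitude=listener_dtf.magnitude[order],
            sampling_rate=listener_dtf.sampling_rate,
        )
        a = predict_pmv(Direction(20.0, 90.0), listener_dtf, U=1.5)
        b = predict_pmv(Direction(20.0, 90.0), shuffled, U=1.5)
        assert np.allclose(a.response_angles, b.response_angles)
        assert np.allclose(a.probabilities, b.probabilities)

    def test_matches_hand_composed_stages(self, listener_dtf):
        # oracle: compose distance -> similarity -> binaural weighting ->
        # normalization by hand on a 3-template slice of the listener's set
        target = Direction(20.0, 90.0)
        U = 1.8
        idx = [
            listener_dtf.direction_index(Direction(20.0, p)) for p in (0.0, 90.0, 180.0)
        ]
        directions = [listener_dtf.directions[i] for i in idx]
        toy = DTFSet(
            listener_id="T",
            directions=directions,
            freq=listener_dtf.freq,
            magnitude=listener_dtf.magnitude[idx],
            sampling_rate=listener_dtf.sampling_rate,
        )
        pmv = predict_pmv(target, toy, U=U)

        _, reps = band_magnitudes(listener_dtf.freq, listener_dtf.magnitude[idx])
        i_target = 1  # polar 90
        w_l = 1.0 / (1.0 + math.exp(-target.lateral / 13.3))
        sis = []
        for j in range(3):
            si = 0.0
            for ear, w in ((0, w_l), (1, 1.0 - w_l)):
                d = np.std(reps[i_target, ear] - reps[j, ear], ddof=1)
                si += w * math.exp(-(d**2) / (2.0 * U**2))
            sis.append(si)
        expected = np.array(sis) / np.sum(sis)
        assert np.allclose(pmv.probabilities, expected, atol=1e-12)


class TestPmvType:
    def test_rejects_bad_sum(self):
        with pytest.raises(InvalidParameterError):
            PMV(np.array([0.0, 10.0]), np.array([0.5, 0.6]))

    def test_rejects_negative(self):
        with pytest.raises(InvalidParameterError):
            PMV(np.array([0.0, 10.0]), np.array([-0.1, 1.1]))

    def test_random_pmvs_normalized(self, predictor, rng):
        for _ in range(20):
            lat = float(rng.choice([-20.0, 0.0, 20.0]))
            pol = float(rng.choice(np.arange(-30.0, 211.0, 5.0)))
            u = float(rng.uniform(0.3, 4.0))
            pmv = predictor.pmv(Direction(lat, pol), u)
            assert abs(pmv.probabilities.sum() - 1.0) <= 1e-10
            assert np.all(pmv.probabilities >= 0.0)
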