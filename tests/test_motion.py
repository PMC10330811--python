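import numpy as np
import pytest

from ceustrack.motion import (
    AttentionMap,
    KalmanParams,
    MotionState,
    attention_map,
    flow_to_measurement,
    kf_predict,
    kf_update,
    sigma_from_history,
)


def params_with(P0=None, Q=None, R=None):
    p = KalmanParams()
    if Q is not None:
        p.Q = Q
    if R is not None:
        p.R = R
    return p


class TestPredict:
    def test_position_advances_by_velocity(self):
        state = MotionState([10, 10, 2, -1], np.zeros((4, 4)))
        p = params_with(Q=np.zeros((4, 4)))
        pred = kf_predict(state, p)
        assert np.allclose(pred.position, [12, 9])
        assert np.allclose(pred.velocity, [2, -1])

    def test_noiseless_propagation_keeps_zero_covariance(self):
        state = MotionState([0, 0, 0, 0], np.zeros((4, 4)))
        pred = kf_predict(state, params_with(Q=np.zeros((4, 4))))
        assert np.allclose(pred.P, 0)

    def test_scalar_analogue_covariance_doubles(self):
        # A acts as identity on the x block; P=1, Q=1 => P- = 2
        state = MotionState([0, 0, 0, 0], np.diag([1.0, 0, 0, 0]))
        pred = kf_predict(state, params_with(Q=np.diag([1.0, 0, 0, 0])))
        assert pred.P[0, 0] == pytest.approx(2.0)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError):
            MotionState([0, 0, 0, 0], -np.eye(4))


class TestUpdate:
    def test_scalar_half_gain_worked_example(self):
        # P- = 1, R = 1 => K = 1/2; x- = 2, z = 4 => x^ = 3
        pred = MotionState([2, 0, 0, 0], np.diag([1.0, 0, 0, 0]))
        p = params_with(R=np.eye(2))
        new = kf_update(pred, [4.0, 0.0], p)
        assert new.x[0] == pytest.approx(3.0)
        assert new.P[0, 0] == pytest.approx(0.5)

    def test_perfect_measurement_limit(self):
        pred = MotionState([2, 5, 0, 0], np.eye(4))
        p = params_with(R=1e-12 * np.eye(2))
        new = kf_update(pred, [7.0, 1.0], p)
        assert np.allclose(new.position, [7.0, 1.0], atol=1e-6)

    def test_zero_gain_keeps_prior(self):
        pred = MotionState([2, 5, 1, 1], np.zeros((4, 4)))
        new = kf_update(pred, [100.0, 100.0], params_with(R=np.eye(2)))
        assert np.allclose(new.x, [2, 5, 1, 1])

    def test_nonfinite_measurement_rejected(self):
        pred = MotionState([0, 0, 0, 0], np.eye(4))
        with pytest.raises(ValueError):
            kf_update(pred, [np.nan, 0.0], KalmanParams())


class TestFilterBehaviour:
    def test_converges_on_noiseless_constant_velocity(self):
        """Position error vanishes and velocity is within 5% after 20 steps."""
        vel = np.array([1.5, -0.8])
        params = KalmanParams.default(q=1e-6, r=1.0)
        state = MotionState.initial([0.0, 0.0])
        pos = np.zeros(2)
        for _ in range(20):
            pos = pos + vel
            state = kf_update(kf_predict(state, params), pos, params)
        assert np.linalg.norm(state.position - pos) < 0.1
        assert np.linalg.norm(state.velocity - vel) <= 0.05 * np.linalg.norm(vel)

    def test_filtering_beats_raw_measurements_under_noise(self):
        """200-step constant-velocity track, measurement noise sd 2 px."""
        rng = np.random.default_rng(42)
        vel = np.array([0.8, -0.5])
        params = KalmanParams.default()
        state = MotionState.initial([0.0, 0.0])
        pos = np.zeros(2)
        raw_err, filt_err = [], []
        for _ in range(200):
            pos = pos + vel
            z = pos + rng.normal(0, 2.0, 2)
            state = kf_update(kf_predict(state, params), z, params)
            raw_err.append(np.sum((z - pos) ** 2))
            filt_err.append(np.sum((state.position - pos) ** 2))
        assert np.sqrt(np.mean(filt_err)) < np.sqrt(np.mean(raw_err))

    def test_covariance_stays_symmetric_psd(self):
        rng = np.random.default_rng(3)
        params = KalmanParams.default()
        state = MotionState.initial([10.0, 10.0])
        for _ in range(50):
            state = kf_predict(state, params)
            state = kf_update(state, rng.normal(10, 5, 2), params)
            assert np.allclose(state.P, state.P.T)
            assert np.linalg.eigvalsh(state.P).min() >= -1e-10


class TestFlowMeasurement:
    class _Flow:
        def __init__(self, u, degenerate=False, unreliable=False):
            self.u = u
            self.degenerate = degenerate
            self.unreliable = unreliable

        @property
        def vector(self):
            return np.asarray(self.u, dtype=float)

    def test_adds_flow_to_previous_center(self):
        z = flow_to_measurement((50, 50), self._Flow((2, -1)))
        assert np.allclose(z, [52, 49])

    def test_degenerate_flow_gives_no_measurement(self):
        assert flow_to_measurement((50, 50), self._Flow((2, -1), degenerate=True)) is None

    def test_zero_flow_keeps_center(self):
        z = flow_to_measurement((50, 50), self._Flow((0, 0)))
        assert np.allclose(z, [50, 50])


class TestSigmaFromHistory:
    def test_empty_history_returns_midrange_default(self):
        assert sigma_from_history([]) == 6.0

    def test_constant_distances_give_zero(self):
        assert sigma_from_history([2, 2, 2, 2]) == pytest.approx(0.0)

    def test_textbook_sample_sd(self):
        assert sigma_from_history([0, 2, 4, 6, 8]) == pytest.approx(3.1623, abs=1e-4)

    def test_only_last_ten_used(self):
        history = [100.0] * 5 + [3.0] * 10
        assert sigma_from_history(history) == pytest.approx(0.0)


class TestAttention:
    def test_center_has_attention_one(self):
        att = attention_map((10, 10), 5.0, (21, 21))
        assert att.values[10, 10] == 1.0

    @pytest.mark.parametrize("raw,expected", [(0.5, 3.0), (1.0, 3.0), (20.0, 9.0), (5.0, 5.0)])
    def test_sigma_clamped_to_3_9(self, raw, expected):
        att = attention_map((10, 10), raw, (21, 21))
        assert att.sigma == expected

    def test_hand_computed_value_at_d_equals_sigma(self):
        att = attention_map((0, 0), 5.0, (1, 11), origin=(0, 0), step=1.0)
        # d = 5 at column 5; Att = exp(-1/2)
        assert att.values[0, 5] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_far_candidates_masked_below_threshold(self):
        att = attention_map((0, 0), 5.0, (1, 40), origin=(0, 0), step=1.0)
        assert att.values[0, 30] < 1e-4
        assert not att.valid_mask[0, 30]

    def test_mask_is_exactly_threshold_set(self):
        att = attention_map((15, 7), 4.0, (30, 30))
        assert np.array_equal(att.valid_mask, att.values >= att.threshold)

    def test_monotone_nonincreasing_in_distance(self):
        att = attention_map((0, 0), 6.0, (1, 50), origin=(0, 0), step=1.0)
        assert np.all(np.diff(att.values[0]) <= 1e-15)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            attention_map((0, 0), 5.0, (0, 5))
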