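"""Feedbacks, MPCR, transition table, propensities and mean field."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichesim import (
    HSCParameters,
    build_transition_table,
    calibrate_mpcr,
    eval_feedback,
    eval_mpcr,
    eval_propensities,
    find_homeostasis,
    mean_field_rhs,
    single_lineage_signals,
)

counts_st = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)
coef_st = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


class TestFeedback:
    @pytest.mark.parametrize(
        "bL, bM, L, M, expected",
        [
            (0.0, 0.0, 123.0, 456.0, 1.0),       # no inhibition without coefficients
            (0.7, 0.9, 0.0, 0.0, 1.0),           # no cells, no inhibition
            (1e-3, 1e-3, 200.0, 300.0, 1 / 1.5), # direct evaluation
        ],
    )
    def test_closed_form(self, bL, bM, L, M, expected):
        assert eval_feedback(bL, bM, L, M) == pytest.approx(expected, abs=1e-12)

    @given(bL=coef_st, bM=coef_st, L=counts_st, M=counts_st)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_range_and_monotonicity(self, bL, bM, L, M):
        h = eval_feedback(bL, bM, L, M)
        assert 0.0 < h <= 1.0
        # inhibition can only deepen as blood-cell counts rise
        assert eval_feedback(bL, bM, L + 1.0, M) <= h
        assert eval_feedback(bL, bM, L, M + 1.0) <= h

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            eval_feedback(-0.1, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            eval_feedback(0.1, 0.1, -1.0, 1.0)


class TestMPCR:
    def test_nonresponsive_theta_zero_is_constant(self):
        g = 0.37
        vals = [eval_mpcr(0.0, g, L, M) for L, M in [(1, 1), (5, 500), (300, 2)]]
        assert np.allclose(vals, g / (1 + g), atol=1e-15)

    def test_symmetric_counts_give_half(self):
        assert eval_mpcr(1.0, 1.0, 77.0, 77.0) == pytest.approx(0.5)

    def test_zero_count_substitution(self):
        # L = 0 is treated as 1 when forming the ratio
        assert eval_mpcr(1.0, 1.0, 0.0, 50.0) == pytest.approx(50 / 51)
        assert eval_mpcr(1.0, 1.0, 50.0, 0.0) == pytest.approx((1 / 50) / (1 + 1 / 50))

    @given(
        theta=st.floats(min_value=0.0, max_value=5.0),
        gamma=st.floats(min_value=1e-3, max_value=10.0),
        L=counts_st,
        M=counts_st,
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_range_and_monotonicity(self, theta, gamma, L, M):
        p = eval_mpcr(theta, gamma, L, M)
        assert 0.0 < p < 1.0
        # more myeloid cells push commitment towards the lymphoid route
        assert eval_mpcr(theta, gamma, L, M + 1.0) >= p - 1e-12
        assert eval_mpcr(theta, gamma, L + 1.0, M) <= p + 1e-12


class TestCalibration:
    @pytest.mark.parametrize(
        "theta, rho, expected",
        [(1.0, 1.0, 1.0), (0.0, 0.5, 0.5), (5.0, 0.5, 0.015625)],
    )
    def test_closed_form(self, theta, rho, expected):
        assert calibrate_mpcr(theta, rho) == pytest.approx(expected, rel=1e-12)

    def test_hand_check_theta_five(self):
        # at the target state L = rho*M the committed fraction is rho/(1+rho)
        assert eval_mpcr(5.0, 0.015625, 50.0, 100.0) == pytest.approx(1 / 3, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.0, 5.0])
    @pytest.mark.parametrize("m", [10.0, 100.0, 1000.0])
    @pytest.mark.parametrize("rho", [0.5, 1.0, 2.0])
    def test_round_trip(self, theta, m, rho):
        gamma = calibrate_mpcr(theta, rho)
        assert eval_mpcr(theta, gamma, rho * m, m) == pytest.approx(
            rho / (1 + rho), abs=1e-12
        )


class TestTransitionTable:
    def test_structure(self, table):
        assert table.stoich.shape == (6, 14)
        assert len(table.transitions) == 14
        assert set(np.unique(table.stoich)) <= {-1, 0, 1, 2}
        # each transition changes at most two species
        assert (np.count_nonzero(table.stoich, axis=0) <= 2).all()

    def test_symmetric_differentiation_net_gain(self, table):
        # one S becomes two MPP: net +1 cell
        assert table.stoich[:, 2].sum() == 1
        assert table.stoich[0, 2] == -1 and table.stoich[1, 2] == 2

    def test_capacity_zeroes_symmetric_renewal(self, params, table):
        state = np.array([10, 0, 0, 0, 0, 0])
        sig = single_lineage_signals(state, params)
        a = eval_propensities(state, sig, table)
        assert a[0] == 0.0

    def test_text_dump_mentions_every_process(self, table):
        text = table.to_text()
        assert "symmetric differentiation" in text and text.count("\n") == 14


class TestPropensities:
    def test_all_zero_state(self, params, table):
        zero = np.zeros(6)
        a = eval_propensities(zero, single_lineage_signals(zero, params), table)
        assert np.all(a == 0.0)

    def test_hand_values_single_stem_cell(self, params, table):
        state = np.array([1, 0, 0, 0, 0, 0])
        sig = single_lineage_signals(state, params)  # no blood cells: h = 1
        a = eval_propensities(state, sig, table)
        assert a[0] == pytest.approx(2.5 * 1 * 0.9)   # logistic factor (1 - 1/10)
        assert a[3] == pytest.approx(0.004)

    def test_hand_value_myeloid_death(self, params, table):
        state = np.array([0, 0, 0, 0, 0, 100])
        sig = single_lineage_signals(state, params)
        a = eval_propensities(state, sig, table)
        assert a[13] == pytest.approx(1.0)
        assert np.all(a[:13] == 0.0)

    def test_zero_reactant_means_zero_propensity(self, params, table, rng):
        state = rng.integers(0, 50, size=6)
        state[0] = min(state[0], int(params.K))
        a = eval_propensities(state, single_lineage_signals(state, params), table)
        for j, tr in enumerate(table.transitions):
            if state[tr.reactant] == 0:
                assert a[j] == 0.0
            assert a[j] >= 0.0

    def test_above_capacity_clamps_with_warning(self, params, table):
        state = np.array([12, 0, 0, 0, 0, 0])
        sig = single_lineage_signals(state, params)
        with pytest.warns(RuntimeWarning):
            a = eval_propensities(state, sig, table)
        assert a[0] == 0.0


class TestMeanField:
    def test_zero_state_is_fixed(self, params):
        assert np.all(mean_field_rhs(np.zeros(6), params) == 0.0)

    def test_pure_myeloid_death(self, params):
        x = np.zeros(6)
        x[5] = 100.0
        rhs = mean_field_rhs(x, params)
        assert rhs[5] == pytest.approx(-1.0)
        assert np.all(rhs[:5] == 0.0)

    def test_homeostatic_fixed_point(self, params):
        xstar = find_homeostasis(params)
        assert np.linalg.norm(mean_field_rhs(xstar, params)) < 1e-8
        # defaults were calibrated for a few hundred myeloid cells
        assert 100 < xstar[5] < 1000
        assert xstar[0] < params.K

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HSCParameters(r_sym=-1.0)
        with pytest.raises(ValueError):
            HSCParameters(rho=0.0)
        with pytest.raises(ValueError):
            HSCParameters(gamma=0.0)
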