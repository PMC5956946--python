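"""Discrimination/reclassification statistics against exhaustive oracles."""

import numpy as np
import pandas as pd
import pytest
from oracles import (
    auc_pairs,
    idi_direct,
    nri_counts,
    slope_direct,
    survival_concordance_pairs,
    vif_from_corr,
)

from metsrisk.perform_metrics import (
    c_statistic_binary,
    c_statistic_survival,
    continuous_nri,
    discrimination_slope,
    idi,
    survival_idi_nri,
    vif,
)


def _binary_instance(n, seed, ties=False):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.3
    p = rng.random(n)
    if ties:
        p = np.round(p, 1)  # force many exact ties
    return p, y


def _survival_instance(n, seed, cens=0.3):
    rng = np.random.default_rng(seed)
    t = np.round(rng.exponential(3000, n)) + 1
    c = np.round(rng.exponential(3000 / cens, n)) + 1
    time = np.minimum(t, c)
    event = t <= c
    risk = np.round(rng.random(n), 2)
    return time, event, risk


class TestCStatisticBinary:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        assert c_statistic_binary([0.1, 0.2, 0.8, 0.9], y).value == 1.0

    @pytest.mark.parametrize("seed,ties", [(0, False), (1, True), (2, True)])
    def test_equals_exhaustive_pair_count(self, seed, ties):
        p, y = _binary_instance(300, seed, ties)
        assert c_statistic_binary(p, y, ci=False).value == pytest.approx(
            auc_pairs(p, y), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        p, y = _binary_instance(500, 3, ties=True)
        assert c_statistic_binary(p, y, ci=False).value == pytest.approx(
            roc_auc_score(y, p), abs=1e-12
        )

    def test_uninformative_marker_near_half(self):
        p, y = _binary_instance(10000, 4)
        est = c_statistic_binary(p, y)
        assert abs(est.value - 0.5) < 0.02
        assert est.lower < 0.5 < est.upper

    def test_monotone_transform_invariance(self):
        p, y = _binary_instance(400, 5)
        a = c_statistic_binary(p, y, ci=False).value
        b = c_statistic_binary(np.exp(3 * p), y, ci=False).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="events"):
            c_statistic_binary([0.1, 0.2], np.array([True, True]))

    def test_delong_ci_brackets_value(self):
        p, y = _binary_instance(500, 6)
        est = c_statistic_binary(p, y)
        assert est.lower <= est.value <= est.upper
        assert est.se > 0


class TestCStatisticSurvival:
    def test_perfectly_informative_risk(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2000, 200) + 1
        risk = 1.0 / t  # strictly decreasing in event time
        est = c_statistic_survival(t, np.ones(200, bool), risk, horizon=1e9, ci=False)
        assert est.value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_exhaustive_pair_enumeration(self, seed):
        time, event, risk = _survival_instance(300, seed)
        ours = c_statistic_survival(time, event, risk, horizon=3652, ci=False).value
        assert ours == pytest.approx(
            survival_concordance_pairs(time, event, risk, 3652), abs=1e-12
        )

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(9)
        time, event, _ = _survival_instance(5000, 7, cens=0.25)
        risk = rng.random(5000)
        est = c_statistic_survival(time, event, risk, horizon=3652, ci=False)
        assert abs(est.value - 0.5) < 0.02

    def test_bootstrap_ci_brackets_value(self):
        time, event, risk = _survival_instance(300, 3)
        est = c_statistic_survival(time, event, risk, 3652, n_boot=50, seed=1)
        assert est.lower <= est.value <= est.upper

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            c_statistic_survival(
                [100.0, 200.0], np.array([False, False]), [0.1, 0.2], 3652
            )


class TestIdiAndSlope:
    def test_slope_and_idi_match_direct(self):
        rng = np.random.default_rng(11)
        y = rng.random(400) < 0.4
        p_old, p_new = rng.random(400), rng.random(400)
        assert discrimination_slope(p_old, y) == pytest.approx(
            slope_direct(p_old, y), abs=1e-12
        )
        assert idi(p_old, p_new, y, ci=False).value == pytest.approx(
            idi_direct(p_old, p_new, y), abs=1e-12
        )

    def test_identical_models_give_zero(self):
        p, y = _binary_instance(200, 12)
        assert idi(p, p, y, ci=False).value == 0.0

    def test_hand_computed_extreme_case(self):
        y = np.array([True, True, False, False])
        p_old = np.full(4, 0.5)
        p_new = np.array([0.8, 0.8, 0.2, 0.2])
        assert idi(p_old, p_new, y, ci=False).value == pytest.approx(0.6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        y = rng.random(300) < 0.3
        a, b = rng.random(300), rng.random(300)
        assert idi(a, b, y, ci=False).value == pytest.approx(
            -idi(b, a, y, ci=False).value, abs=1e-15
        )

    def test_ci_brackets_and_se_positive(self):
        rng = np.random.default_rng(14)
        y = rng.random(500) < 0.3
        est = idi(rng.random(500), rng.random(500), y)
        assert est.lower <= est.value <= est.upper
        assert est.se > 0


class TestContinuousNri:
    def test_no_reclassification_gives_zeros(self):
        p, y = _binary_instance(100, 21)
        res = continuous_nri(p, p, y, ci=False)
        assert (res.overall.value, res.event.value, res.nonevent.value) == (0, 0, 0)

    def test_extreme_case_overall_two(self):
        y = np.array([True, True, False, False])
        p_old = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.6, 0.7, 0.3, 0.2])
        res = continuous_nri(p_old, p_new, y, ci=False)
        assert res.event.value == 1.0
        assert res.nonevent.value == 1.0
        assert res.overall.value == 2.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_sign_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random(500) < 0.35
        p_old = np.round(rng.random(500), 1)
        p_new = np.round(rng.random(500), 1)  # ties with p_old occur
        res = continuous_nri(p_old, p_new, y, ci=False)
        o, e, ne = nri_counts(p_old, p_new, y)
        assert res.overall.value == pytest.approx(o, abs=1e-12)
        assert res.event.value == pytest.approx(e, abs=1e-12)
        assert res.nonevent.value == pytest.approx(ne, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_decomposition_identity_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = rng.random(257) < 0.4
        p_old, p_new = rng.random(257), rng.random(257)
        res = continuous_nri(p_old, p_new, y, ci=False)
        assert res.overall.value == res.event.value + res.nonevent.value


class TestSurvivalIdiNri:
    def _predictions(self, n, seed):
        rng = np.random.default_rng(seed)
        p_old = rng.random(n)
        p_new = np.clip(p_old + rng.normal(0, 0.1, n), 0, 1)
        return p_old, p_new

    @pytest.mark.parametrize("method", ["km", "complete_case"])
    def test_reduces_to_binary_without_censoring(self, method):
        rng = np.random.default_rng(31)
        n = 400
        t = np.round(rng.exponential(3000, n)) + 1
        event = np.ones(n, dtype=bool)  # everyone followed to an event
        p_old, p_new = self._predictions(n, 32)
        y = t <= 3652
        rep = survival_idi_nri(t, event, p_old, p_new, 3652, method=method)
        assert rep.idi.value == pytest.approx(idi_direct(p_old, p_new, y), abs=1e-12)
        o, e, ne = nri_counts(p_old, p_new, y)
        assert rep.nri.overall.value == pytest.approx(o, abs=1e-12)
        assert rep.nri.event.value == pytest.approx(e, abs=1e-12)
        assert rep.nri.nonevent.value == pytest.approx(ne, abs=1e-12)

    def test_censoring_after_horizon_is_still_binary(self):
        rng = np.random.default_rng(33)
        n = 300
        t = np.round(rng.exponential(2500, n)) + 1
        event = t <= 3000
        t = np.where(event, t, 4000.0)  # censored, but after the horizon
        p_old, p_new = self._predictions(n, 34)
        y = event & (t <= 3652)
        rep = survival_idi_nri(t, event, p_old, p_new, 3652, method="km")
        assert rep.idi.value == pytest.approx(idi_direct(p_old, p_new, y), abs=1e-12)

    def test_risk_linked_censoring_biases_complete_case(self):
        # Events exponential with P(event by tau) = 0.2 in both groups, so
        # the true event NRI is 0.  Half of the "up" group is censored at
        # tau/2; complete-case analysis then keeps only their early events
        # (P = 1 - 0.8**0.5 = 0.1056), deflating P(up|event) to
        # 0.1528/0.3528 = 0.433 and the event NRI to about -0.134, while
        # KM weighting recovers the generative truth of 0.
        rng = np.random.default_rng(35)
        n = 20000
        tau = 3652.0
        rate = -np.log(0.8) / tau
        t = rng.exponential(1 / rate, n)
        p_old = np.full(n, 0.2)
        p_new = np.where(np.arange(n) % 2 == 0, 0.5, 0.1)  # half up, half down
        up = p_new > p_old
        censor = up & (rng.random(n) < 0.5)
        time = np.where(censor, np.minimum(t, tau / 2), np.minimum(t, tau + 1000))
        event = np.where(censor, t <= tau / 2, t <= tau + 1000)
        km = survival_idi_nri(time, event.astype(bool), p_old, p_new, tau, method="km")
        cc = survival_idi_nri(
            time, event.astype(bool), p_old, p_new, tau, method="complete_case"
        )
        assert abs(km.nri.event.value) < 0.03
        p_early = 1 - 0.8**0.5
        # kept up-group events per capita: 0.5*(0.2 + p_early); down: 0.2
        expected_cc = (0.5 * (0.2 + p_early) - 0.2) / (0.2 + 0.5 * (0.2 + p_early))
        assert cc.nri.event.value == pytest.approx(expected_cc, abs=0.03)
        assert cc.nri.event.value < km.nri.event.value - 0.05

    def test_null_marker_centred_on_zero(self):
        rng = np.random.default_rng(36)
        reps = []
        for k in range(40):
            n = 1500
            t = np.round(rng.exponential(9000, n)) + 1
            c = np.round(rng.exponential(20000, n)) + 1
            time = np.minimum(t, c)
            event = t <= c
            p_old = rng.random(n)
            p_new = np.clip(p_old + rng.normal(0, 0.05, n), 0, 1)
            rep = survival_idi_nri(time, event, p_old, p_new, 3652, method="km")
            reps.append(rep.nri.overall.value)
        assert abs(np.mean(reps)) < 0.03

    def test_all_censored_before_horizon_rejected(self):
        with pytest.raises(ValueError):
            survival_idi_nri(
                np.array([100.0, 200.0]),
                np.array([False, False]),
                np.array([0.1, 0.2]),
                np.array([0.2, 0.1]),
                3652,
            )


class TestAlgebraicProperties:
    """Invariants that must hold on arbitrary inputs, not just fixtures."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
                st.booleans(),
            ),
            min_size=10,
            max_size=120,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nri_decomposition_and_idi_antisymmetry(data):
        p_old = np.array([d[0] for d in data])
        p_new = np.array([d[1] for d in data])
        y = np.array([d[2] for d in data])
        if y.all() or not y.any():
            y[0] = ~y[0]
        res = continuous_nri(p_old, p_new, y, ci=False)
        assert res.overall.value == res.event.value + res.nonevent.value
        assert res.event.value <= 1.0 and res.nonevent.value <= 1.0
        assert idi(p_old, p_new, y, ci=False).value == pytest.approx(
            -idi(p_new, p_old, y, ci=False).value, abs=1e-15
        )

    @staticmethod
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_c_statistic_bounded_and_complement_symmetric(seed):
        rng = np.random.default_rng(seed)
        n = 60
        p = np.round(rng.random(n), 1)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        c = c_statistic_binary(p, y, ci=False).value
        assert 0.0 <= c <= 1.0
        assert c_statistic_binary(-p, y, ci=False).value == pytest.approx(
            1.0 - c, abs=1e-12
        )


class TestVif:
    def test_orthogonal_covariates_unit_vif(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.standard_normal((2000, 3)), columns=list("abc"))
        # orthogonalise exactly
        Q, _ = np.linalg.qr(X.to_numpy() - X.to_numpy().mean(0))
        res = vif(pd.DataFrame(Q, columns=list("abc")))
        np.testing.assert_allclose(res.to_numpy(), 1.0, atol=1e-10)

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(5000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(5000)
        X = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        np.testing.assert_allclose(vif(X).to_numpy(), expected, rtol=1e-10)
        assert expected == pytest.approx(5.26, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_inverse_correlation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((500, 4))
        X = pd.DataFrame(Z @ np.array(
            [[1, 0.5, 0, 0], [0, 1, 0.3, 0], [0, 0, 1, 0.7], [0.2, 0, 0, 1]]
        ), columns=list("abcd"))
        np.testing.assert_allclose(
            vif(X).to_numpy(), vif_from_corr(X.to_numpy()), rtol=1e-8
        )

    def test_duplicated_covariate_flagged_severe(self):
        rng = np.random.default_rng(43)
        x = rng.standard_normal(100)
        res = vif(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)}))
        assert np.isinf(res["a"]) and np.isinf(res["b"])
        assert res["c"] < 10

    def test_single_covariate_rejected(self):
        with pytest.raises(ValueError, match="two"):
            vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
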