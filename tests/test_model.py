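import numpy as np
import pytest

from hemaclone import (
    FeedbackParams,
    ModelParams,
    NoSteadyStateError,
    ParamError,
    SystemState,
    compute_signals,
    effective_rates,
    healthy_plus_seed,
    healthy_steady_state,
    make_lineage,
    make_toy_fixture,
    rhs,
    scaled_mds_params,
    takeover_predicate,
)


class TestSignals:
    def test_empty_pools_give_unit_signals(self, baseline):
        state = SystemState(t=0.0, counts=np.zeros(baseline.n_compartments))
        sig = compute_signals(state, baseline)
        assert sig.s_p == 1.0 and sig.s_a == 1.0

    def test_half_saturation_of_self_renewal(self, baseline):
        # put exactly 1/k_a cells into one niche compartment
        counts = np.zeros(baseline.n_compartments)
        counts[0] = 1.0 / baseline.feedback.k_a
        sig = compute_signals(SystemState(t=0.0, counts=counts), baseline)
        assert sig.s_a == pytest.approx(0.5, abs=1e-12)
        assert sig.s_p == 1.0  # niche cells do not drive proliferation

    def test_steady_state_signal_matches_fixed_point_condition(self, baseline, baseline_ss):
        # stem balance a_max * s_a* = 1/2 with a_max = 0.7
        sig = compute_signals(baseline_ss, baseline)
        assert sig.s_a == pytest.approx(1.0 / 1.4, rel=1e-12)

    def test_negative_counts_rejected(self, baseline):
        counts = np.zeros(baseline.n_compartments)
        counts[2] = -1.0
        with pytest.raises(ParamError):
            compute_signals(SystemState(t=0.0, counts=counts), baseline)


class TestEffectiveRates:
    def test_unit_signal_returns_maxima(self, baseline):
        state = SystemState(t=0.0, counts=np.zeros(baseline.n_compartments))
        a, p = effective_rates(state, baseline)
        layout = baseline.layout()
        assert np.allclose(a[layout.divides], layout.a_max[layout.divides])
        # MDS stem divides maximally once per 100 days
        assert p[baseline.index("mds", "MDS-LT-HSC")] == pytest.approx(0.01)

    def test_stem_self_renewal_is_half_at_equilibrium(self, baseline, baseline_ss):
        a, _ = effective_rates(baseline_ss, baseline)
        assert a[baseline.index("normal", "LT-HSC")] == pytest.approx(0.5, rel=1e-12)

    def test_terminal_compartments_report_zero(self, baseline, baseline_ss):
        a, p = effective_rates(baseline_ss, baseline)
        for lin, name in [("normal", "mature"), ("mds", "dysplastic")]:
            j = baseline.index(lin, name)
            assert a[j] == 0.0 and p[j] == 0.0


class TestRhs:
    def _single(self, a_max):
        return ModelParams(
            lineages=[make_lineage("normal", ["stem"], [a_max], [0.1], niche_depth=1)],
            feedback=FeedbackParams(k_p=1e-300, k_a=1e-300, niche_depth=1),
        )

    def test_balanced_division_is_stationary(self):
        params = self._single(0.5)  # signals ~ 1, so a_eff = 0.5
        state = SystemState(t=0.0, counts=np.array([123.0]))
        assert rhs(state, params)[0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_self_renewal_grows_exponentially(self):
        params = self._single(1.0)
        state = SystemState(t=0.0, counts=np.array([40.0]))
        assert rhs(state, params)[0] == pytest.approx(0.1 * 40.0, rel=1e-12)

    def test_fixed_point_has_zero_derivative(self, baseline, baseline_ss):
        deriv = rhs(baseline_ss, baseline)
        positive = baseline_ss.counts > 0
        rel = np.abs(deriv[positive]) / baseline_ss.counts[positive]
        assert rel.max() < 1e-8


class TestHealthySteadyState:
    def test_niche_occupancy_identity(self):
        params, _, expected = make_toy_fixture("one_compartment", a_max=0.7, k_a=1e-6)
        ss = healthy_steady_state(params)
        assert ss.counts[0] == pytest.approx(0.4 / 1e-6, rel=1e-12)
        assert ss.counts[0] == pytest.approx(expected["steady_count"], rel=1e-12)

    def test_no_positive_fixed_point_below_half(self):
        params, _, _ = make_toy_fixture("one_compartment", a_max=0.6)
        params.lineages[0].compartments[0].a_max = 0.5
        with pytest.raises(NoSteadyStateError, match="no positive steady state"):
            healthy_steady_state(params)

    def test_mds_compartments_left_empty(self, baseline, baseline_ss):
        for comp in baseline.lineage("mds").compartments:
            assert baseline_ss.get(baseline, "mds", comp.name) == 0.0

    def test_supercritical_downstream_rejected(self, healthy):
        params = healthy.copy()
        params.lineage("normal").compartments[1].a_max = 0.75  # above the stem's 0.7
        with pytest.raises(NoSteadyStateError, match="subcritical"):
            healthy_steady_state(params)


class TestTakeoverPredicate:
    def test_paper_defaults_predict_takeover(self, baseline):
        assert takeover_predicate(baseline)  # 0.9 > 0.7

    def test_proliferation_alone_is_not_sufficient(self, baseline):
        params = scaled_mds_params(baseline, a_mds_stem=0.7, p_scale=10.0)
        assert not takeover_predicate(params)

    def test_single_lineage_rejected(self, healthy):
        with pytest.raises(ParamError):
            takeover_predicate(healthy)

    def test_marginal_excess_gives_positive_initial_growth(self, baseline):
        params = scaled_mds_params(baseline, a_mds_stem=0.701, p_scale=1.0)
        assert takeover_predicate(params)
        state = healthy_plus_seed(params, 1.0)
        j = params.index("mds", "MDS-LT-HSC")
        assert rhs(state, params)[j] > 0.0
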