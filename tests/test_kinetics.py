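import math

import numpy as np
import pytest
from scipy.integrate import quad

from motorchain import (
    AbsoluteConfiguration,
    RelativeConfiguration,
    canonical_representative,
    default_parameters,
    project,
)
from motorchain import kinetics as K
from motorchain.mechanics import cargo_equilibrium, motor_load, thermal_density

P = default_parameters()


class TestSingleMotorRates:
    def test_binding_efficiency(self):
        assert K.binding_efficiency(-1e-3, P) == 1.0
        assert K.binding_efficiency(P.F_s / 2, P) == pytest.approx(0.25)
        assert K.binding_efficiency(P.F_s, P) == 0.0

    def test_unloaded_step_rate(self):
        # K_m = (105 + 55)/2e6 = 8e-5 M
        assert K.step_rate_at_force(0.0, P) == pytest.approx(100.96, abs=0.01)

    def test_stalled_motor_cannot_step(self):
        assert K.step_rate_at_force(P.F_s, P) == 0.0
        assert K.step_rate_at_force(P.F_s + 0.001, P) == 0.0

    def test_step_rate_monotone_under_load(self):
        forces = np.linspace(0.0, P.F_s, 200)
        rates = [K.step_rate_at_force(f, P) for f in forces]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_unloaded_processivity(self):
        assert K.processivity(0.0, P) == pytest.approx(854.7, abs=0.5)

    def test_processivity_decays_with_load(self):
        forces = np.linspace(0.0, 0.02, 100)
        lengths = [K.processivity(f, P) for f in forces]
        assert all(a > b for a, b in zip(lengths, lengths[1:]))
        assert K.processivity(0.1, P) < 1e-6

    def test_unloaded_detach_rate(self):
        assert K.detach_rate_at_force(0.0, P) == pytest.approx(0.9448, abs=0.001)

    def test_above_stall_detach_is_constant(self):
        assert K.detach_rate_at_force(P.F_s + 1e-6, P) == P.P_back
        assert K.detach_rate_at_force(0.05, P) == P.P_back

    @pytest.mark.parametrize("F", [-0.002, 0.0, 0.001, 0.003, 0.0059])
    def test_step_detach_ratio_is_processivity(self, F):
        ratio = K.step_rate_at_force(F, P) / K.detach_rate_at_force(F, P)
        assert ratio == pytest.approx(K.processivity(F, P) / P.d_s, rel=1e-12)


class TestThermalAveraging:
    def test_noiseless_single_motor_bears_full_load(self):
        p = default_parameters(m_bar=1, sigma_th=0.0, F_load=0.002)
        Z = AbsoluteConfiguration((0,), (1,))
        assert K.site_step_rate(Z, 0, p) == pytest.approx(
            K.step_rate_at_force(p.F_load, p)
        )
        assert K.site_detach_rate(Z, 0, p) == pytest.approx(
            K.detach_rate_at_force(p.F_load, p)
        )

    def test_rate_linear_in_site_occupancy(self):
        # doubling the motors on a slack rear site (which leaves x_eq
        # untouched) exactly doubles that site's rates
        p = default_parameters(m_bar=4, F_load=0.001)
        Z1 = AbsoluteConfiguration((-10, 0), (1, 1))
        Z2 = AbsoluteConfiguration((-10, 0), (2, 1))
        from motorchain.mechanics import cargo_equilibrium
        assert cargo_equilibrium(Z2, p).x_eq == pytest.approx(
            cargo_equilibrium(Z1, p).x_eq
        )
        assert K.site_step_rate(Z2, -10, p) == pytest.approx(
            2 * K.site_step_rate(Z1, -10, p)
        )
        assert K.site_detach_rate(Z2, -10, p) == pytest.approx(
            2 * K.site_detach_rate(Z1, -10, p)
        )

    def test_small_noise_limit_matches_point_evaluation(self):
        Z = AbsoluteConfiguration((0,), (1,))
        p0 = default_parameters(m_bar=1, sigma_th=0.0, F_load=0.002)
        p_eps = p0.replace(sigma_th=1e-7)
        assert K.site_step_rate(Z, 0, p_eps) == pytest.approx(
            K.site_step_rate(Z, 0, p0), rel=1e-6
        )

    @pytest.mark.parametrize("site", [0, 20])
    @pytest.mark.parametrize(
        "point_rate,site_rate",
        [(K.step_rate_at_force, K.site_step_rate),
         (K.detach_rate_at_force, K.site_detach_rate)],
    )
    def test_quadrature_matches_adaptive_integration(self, site, point_rate,
                                                     site_rate):
        p = default_parameters(m_bar=2, F_load=0.003)
        Z = AbsoluteConfiguration((0, 20), (1, 1))
        eq = cargo_equilibrium(Z, p)
        a_k = site * p.d_s
        ref, _ = quad(
            lambda x: point_rate(motor_load(a_k, x, p), p)
            * thermal_density(x - eq.x_eq, p),
            eq.x_eq - 3 * p.sigma_th, eq.x_eq + 3 * p.sigma_th,
            points=[a_k - p.l0 - p.F_s / p.k_el, a_k - p.l0, a_k + p.l0],
            limit=200,
        )
        assert site_rate(Z, site, p, eq) == pytest.approx(ref, rel=1e-8)

    def test_integrand_switch_across_stall_boundary(self):
        # place the thermal window astride the stall position so the
        # detach rate mixes the below-stall branch with P_back
        p = default_parameters(m_bar=1, F_load=0.006 - 1e-5)
        Z = AbsoluteConfiguration((0,), (1,))
        rate = K.site_detach_rate(Z, 0, p)
        below = K.detach_rate_at_force(p.F_load, p)
        assert below < rate < p.P_back


class TestAttachment:
    def test_full_ensemble_cannot_attach(self):
        p = default_parameters(m_bar=1)
        assert K.attachment_events(AbsoluteConfiguration((0,), (1,)), p) == []

    def test_admissible_site_census(self):
        # l0 = 20 nm, x_eq pinned on a site => 5 admissible sites
        p = default_parameters(m_bar=2, l0=20.0, F_load=0.0)
        Z = AbsoluteConfiguration((0,), (1,))
        events = K.attachment_events(Z, p)
        assert len(events) == 5
        for ev in events:
            assert ev.rate == pytest.approx(1 * p.P_att / 5)
            assert ev.displacement == 0.0

    def test_total_attachment_rate(self):
        p = default_parameters(m_bar=4)
        Z = AbsoluteConfiguration((0,), (2,))
        total = sum(e.rate for e in K.attachment_events(Z, p))
        assert total == pytest.approx((p.m_bar - 2) * p.P_att)


class TestAbsoluteTransitions:
    def test_single_motor_census(self):
        p = default_parameters(m_bar=1, F_load=0.001)
        events = K.absolute_transitions(AbsoluteConfiguration((0,), (1,)), p)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["detach", "step"]

    def test_total_outflow_finite_positive(self):
        p = default_parameters(m_bar=3, F_load=0.002)
        Z = AbsoluteConfiguration((0, 5), (1, 2))
        total = sum(e.rate for e in K.absolute_transitions(Z, p))
        assert 0 < total < math.inf

    def test_step_displacements_bounded_by_period(self):
        p = default_parameters(m_bar=3, F_load=0.002)
        Z = AbsoluteConfiguration((0, 14, 28), (1, 1, 1))
        saw_positive = False
        for ev in K.absolute_transitions(Z, p):
            if ev.kind == "step":
                assert 0.0 <= ev.displacement <= p.d_s + 1e-9
                saw_positive = saw_positive or ev.displacement > 0
        assert saw_positive

    def test_taut_rearguard_detachment_advances_cargo(self):
        # wide pair: rearguard actively pulls back; its detachment lets
        # the equilibrium jump forward by more than one period
        p = default_parameters(m_bar=2, F_load=0.001)
        Z = AbsoluteConfiguration((0, 32), (1, 1))
        detaches = {
            e.site: e for e in K.absolute_transitions(Z, p) if e.kind == "detach"
        }
        assert detaches[0].rearguard
        assert detaches[0].displacement > p.d_s
        assert not detaches[32].rearguard
        assert detaches[32].displacement < 0

    def test_extent_cap_suppresses_boundary_events(self):
        p = default_parameters(m_bar=2, F_load=0.001, n_cap=10)
        Z = AbsoluteConfiguration((0, 9), (1, 1))  # span == cap
        events = K.absolute_transitions(Z, p)
        assert all(e.target.span <= 10 for e in events)


class TestRelativeProjection:
    def test_lone_motor_step_is_self_transition(self):
        p = default_parameters(m_bar=1, sigma_th=0.0, F_load=0.0)
        groups = K.relative_rates(RelativeConfiguration.from_string("M"), p)
        by_target = {str(g.target): g for g in groups}
        self_group = by_target["M"]
        assert self_group.rate == pytest.approx(K.step_rate_at_force(0.0, p))
        assert self_group.mean_displacement == pytest.approx(p.d_s)

    def test_pair_detachments_aggregate(self):
        # from M|M either motor's detachment reaches M: the projected
        # rate sums both elementary events
        p = default_parameters(m_bar=2, sigma_th=0.0, F_load=0.0)
        sigma = RelativeConfiguration.from_string("M|M")
        groups = {str(g.target): g for g in K.relative_rates(sigma, p)}
        g = groups["M"]
        assert len(g.events) == 2
        assert {e.site for e in g.events} == {0, 1}
        assert g.rate == pytest.approx(sum(e.rate for e in g.events))

    def test_row_sum_equals_total_outflow(self):
        p = default_parameters(m_bar=3, F_load=0.002)
        sigma = RelativeConfiguration.from_string("M|M|M")
        Z = canonical_representative(sigma)
        total = sum(e.rate for e in K.absolute_transitions(Z, p))
        groups = K.relative_rates(sigma, p)
        assert sum(g.rate for g in groups) == pytest.approx(total)

    @pytest.mark.parametrize("alpha", [-13, -1, 4, 27])
    def test_representative_independence(self, alpha, rng):
        # rates computed from any shifted representative agree exactly
        p = default_parameters(m_bar=3, F_load=0.001)
        for _ in range(10):
            sites = np.sort(rng.choice(np.arange(0, 12), size=3, replace=False))
            Z = AbsoluteConfiguration.from_occupancy({int(s): 1 for s in sites})
            ev0 = K.absolute_transitions(Z, p)
            ev1 = K.absolute_transitions(Z.shift(alpha), p)
            assert len(ev0) == len(ev1)
            for a, b in zip(ev0, ev1):
                assert a.kind == b.kind
                assert b.site == a.site + alpha
                assert b.rate == pytest.approx(a.rate, rel=1e-12, abs=1e-15)
                assert b.displacement == pytest.approx(
                    a.displacement, rel=1e-9, abs=1e-9
                )

    def test_attachments_at_slack_sites_carry_zero_displacement(self):
        p = default_parameters(m_bar=2, F_load=0.001)
        groups = K.relative_rates(RelativeConfiguration.from_string("M"), p)
        for g in groups:
            for ev in g.events:
                if ev.kind == "attach":
                    assert ev.displacement == 0.0

    def test_all_rates_nonnegative(self):
        p = default_parameters(m_bar=2, F_load=0.004)
        for s in ("M", "MM", "M|M", "M|||M"):
            for g in K.relative_rates(RelativeConfiguration.from_string(s), p):
                assert g.rate >= 0.0
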