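"""Kinetics core: closed form vs moment-ODE oracle, half-times, length scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amylokin import (
    IncompleteReactionError,
    KineticTrace,
    RateConstants,
    ReactionConditions,
    derive_parameters,
    half_time,
    integrate_moments,
    mass_fraction_closed_form,
    predicted_length_scale,
)


def _grid_for(rates, cond, target=0.999):
    """Time grid long enough for near-complete conversion (oracle-based)."""
    for t_max in (0.3, 1.0, 3.0, 10.0, 30.0):
        t = np.linspace(0.0, t_max, 400)
        traj = integrate_moments(rates, cond, t)
        if traj.M[-1] / cond.m_total > target:
            return t, traj
    return t, traj


class TestOracleEquivalence:
    @pytest.mark.parametrize("prod_k2", [1e2, 1e3, 1e4])
    @pytest.mark.parametrize("prod_kn", [1e-5, 1e-4, 1e-3])
    @pytest.mark.parametrize("seed_fraction", [0.0, 0.05, 0.25])
    def test_closed_form_tracks_ode(self, prod_k2, prod_kn, seed_fraction):
        """Analytic solution within 0.01 of the moment ODE in normalized mass,
        across two decades of k+k2 and k+kn and up to 25% seeds."""
        k_plus = 1e4
        rates = RateConstants(k_n=prod_kn / k_plus, k_plus=k_plus, k_2=prod_k2 / k_plus)
        cond = ReactionConditions(2.0, seed_fraction)
        t, traj = _grid_for(rates, cond)
        analytic = mass_fraction_closed_form(t, rates, cond).values
        assert np.max(np.abs(analytic - traj.M / cond.m_total)) < 0.01

    def test_reference_set_agreement(self, reference_rates, unseeded):
        """The reference parameter set agrees with the oracle to <1% everywhere."""
        t = np.linspace(0.0, 0.3, 200)
        traj = integrate_moments(reference_rates, unseeded, t)
        analytic = mass_fraction_closed_form(t, reference_rates, unseeded).values
        assert np.max(np.abs(analytic - traj.M / 2.0)) < 0.01
        assert traj.M[-1] / 2.0 > 1 - 1e-3  # complete conversion at long times


class TestProductInvariance:
    def test_exact_power_of_two_rescaling(self, unseeded):
        """(k+ -> 2k+, k2 -> k2/2, kn -> kn/2) leaves the unseeded solution
        unchanged: it depends on the rates only through k+k2 and k+kn."""
        a = RateConstants(k_n=1e-8, k_plus=1e4, k_2=0.1)
        b = RateConstants(k_n=0.5e-8, k_plus=2e4, k_2=0.05)
        pa, pb = derive_parameters(a, unseeded), derive_parameters(b, unseeded)
        for attr in ("kappa", "lamb", "C_plus", "C_minus", "B_plus", "B_minus", "k_inf", "k_inf_tilde"):
            assert getattr(pa, attr) == pytest.approx(getattr(pb, attr), rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_arbitrary_product_preserving_rescaling(self, scale, unseeded):
        rates = RateConstants(k_n=1e-8, k_plus=1e4, k_2=0.1)
        scaled = RateConstants(
            k_n=rates.k_n / scale, k_plus=rates.k_plus * scale, k_2=rates.k_2 / scale
        )
        t = np.linspace(0.0, 1.0, 50)
        va = mass_fraction_closed_form(t, rates, unseeded).values
        vb = mass_fraction_closed_form(t, scaled, unseeded).values
        assert np.max(np.abs(va - vb)) < 1e-9


class TestSentinelsAndLimits:
    def test_no_nucleation_source_is_flat(self, unseeded):
        """kn = 0 and no seeds: nothing can create aggregates."""
        rates = RateConstants(k_n=0.0, k_plus=1e4, k_2=0.5)
        params = derive_parameters(rates, unseeded)
        assert params.flat
        tr = mass_fraction_closed_form(np.linspace(0, 5, 20), rates, unseeded)
        assert np.all(tr.values == 0.0)

    def test_elongation_only_seeded_limit(self):
        """kn = k2 = 0 with seeds: M(t) = M0 + m0 (1 - exp(-2 k+ P0 t)),
        checked against the numerical oracle."""
        rates = RateConstants(k_n=0.0, k_plus=500.0, k_2=0.0)
        cond = ReactionConditions(2.0, 0.25, seed_length=500.0)
        t = np.linspace(0.0, 2.0, 200)
        traj = integrate_moments(rates, cond, t)
        expected = cond.M0 + cond.m0 * (1.0 - np.exp(-2 * rates.k_plus * cond.P0 * t))
        assert np.max(np.abs(traj.M - expected)) < 1e-6
        analytic = mass_fraction_closed_form(t, rates, cond).values
        assert np.max(np.abs(analytic - expected / 2.0)) < 1e-12

    def test_all_rates_zero_is_static(self):
        rates = RateConstants(0.0, 0.0, 0.0)
        cond = ReactionConditions(2.0, 0.25)
        traj = integrate_moments(rates, cond, np.linspace(0, 5, 50))
        assert np.allclose(traj.m, cond.m0)
        assert np.allclose(traj.M, cond.M0)
        assert np.allclose(traj.P, cond.P0)

    def test_k2_zero_with_primary_requires_ode(self, unseeded):
        rates = RateConstants(k_n=1e-4, k_plus=1e3, k_2=0.0)
        with pytest.raises(ValueError, match="k_2 > 0"):
            derive_parameters(rates, unseeded)

    def test_endpoints_and_overflow(self, reference_rates, unseeded):
        """Curve starts at 0 unseeded and saturates to exactly 1 deep past
        the transition (kappa*t > 700 short-circuits, no numeric fault)."""
        t = np.array([0.0, 1e-4, 0.01, 0.05, 0.1, 0.2, 50.0, 1e4])
        v = mass_fraction_closed_form(t, reference_rates, unseeded).values
        assert v[0] == 0.0
        assert v[-1] == 1.0
        assert np.all(np.diff(v) >= -1e-12)


class TestConservationAndPositivity:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        log_k2=st.floats(-3, 0),
        log_kn=st.floats(-9, -6),
        seed_fraction=st.sampled_from([0.0, 0.05, 0.25]),
    )
    def test_mass_conserved_and_states_nonnegative(self, log_k2, log_kn, seed_fraction):
        rates = RateConstants(k_n=10**log_kn, k_plus=1e4, k_2=10**log_k2)
        cond = ReactionConditions(2.0, seed_fraction)
        t = np.linspace(0.0, 2.0, 300)
        traj = integrate_moments(rates, cond, t)
        assert np.max(np.abs(traj.m + traj.M - cond.m_total)) < 1e-6 * cond.m_total
        assert traj.m.min() >= 0 and traj.P.min() >= 0 and traj.M.min() >= 0


class TestHalfTime:
    def test_crossing_at_grid_point(self):
        t = np.linspace(0.0, 2.0, 21)
        v = np.clip(t / 2.0, 0, 1)  # value 0.5 exactly at t = 1.0
        assert half_time(KineticTrace(t, v, normalized=True)) == pytest.approx(1.0)

    def test_against_closed_form_root(self, reference_rates, unseeded):
        """Half-time of the ODE-oracle trace equals the bisection root of the
        analytic curve to better than 0.5%."""
        from scipy.optimize import brentq

        t = np.linspace(0.0, 0.3, 2000)
        traj = integrate_moments(reference_rates, unseeded, t)
        t50_ode = half_time(KineticTrace(t, traj.M / 2.0, normalized=True))
        params = derive_parameters(reference_rates, unseeded)

        def f(x):
            return float(
                mass_fraction_closed_form(
                    np.linspace(0.0, x, 8), reference_rates, unseeded, params=params
                ).values[-1]
                - 0.5
            )

        t50_cf = brentq(f, 1e-4, 0.3)
        assert abs(t50_ode - t50_cf) / t50_cf < 0.005

    def test_incomplete_reaction_raises(self):
        t = np.linspace(0.0, 1.0, 10)
        with pytest.raises(IncompleteReactionError):
            half_time(KineticTrace(t, np.full(10, 0.2), normalized=True))

    def test_unnormalized_rejected(self):
        t = np.linspace(0.0, 1.0, 10)
        with pytest.raises(ValueError):
            half_time(KineticTrace(t, np.linspace(0, 100, 10), normalized=False))

    def test_strictly_decreasing_in_k2(self, fixture_rates, unseeded):
        """Dose-dependence: faster secondary nucleation, earlier half-time."""
        t = np.linspace(0.0, 3.0, 600)
        t50s = [
            half_time(mass_fraction_closed_form(t, fixture_rates.scaled(f_2=f), unseeded))
            for f in (1.0, 1.5, 2.5, 5.0)
        ]
        assert all(a > b for a, b in zip(t50s, t50s[1:]))

    def test_high_seed_blunts_k2_sensitivity(self, fixture_rates):
        """At 25% seeds elongation dominates, so a k2 fold-change moves the
        half-time much less (relatively) than in the unseeded reaction."""
        t = np.linspace(0.0, 4.0, 1200)

        def rel_change(cond):
            a = half_time(mass_fraction_closed_form(t, fixture_rates, cond))
            b = half_time(mass_fraction_closed_form(t, fixture_rates.scaled(f_2=5.0), cond))
            return (a - b) / a

        assert rel_change(ReactionConditions(2.0, 0.25)) < rel_change(ReactionConditions(2.0, 0.0))


class TestLengthScaling:
    def test_identity_and_reference_values(self):
        assert predicted_length_scale(1.0, 1.0) == 1.0
        assert predicted_length_scale(5.0, 1.0) == pytest.approx(1 / math.sqrt(5))

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (-1.0, 1.0), (5.0, 0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            predicted_length_scale(*bad)

    def test_plateau_mean_length_follows_prediction(self, fixture_rates, unseeded):
        """M/P at completion (mean length in monomer units) drops by about
        1/sqrt(5) when k2 is scaled five-fold: ODE cross-check of the law."""
        t = np.linspace(0.0, 12.0, 600)
        base = integrate_moments(fixture_rates, unseeded, t)
        fast = integrate_moments(fixture_rates.scaled(f_2=5.0), unseeded, t)
        ratio = (fast.M[-1] / fast.P[-1]) / (base.M[-1] / base.P[-1])
        assert abs(ratio - 1 / math.sqrt(5)) / (1 / math.sqrt(5)) < 0.15
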