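"""Deterministic layer: occupancy, thresholds, steady state, regimes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernacap import (
    KineticParameters,
    Occupancies,
    cerna_gain,
    classify_regime,
    load_parameters,
    mirna_threshold,
    occupancy_inverse,
    rescale_omega,
    save_parameters,
    steady_state,
    steady_state_residuals,
    tf_occupancy,
)
from cernacap.presets import preset


class TestOccupancy:
    def test_hill_equilibrium_values(self, fig2):
        p = fig2.params
        assert tf_occupancy(0.0, p) == 0.0
        assert tf_occupancy(1e6, p) == pytest.approx(1.0, abs=1e-12)
        # direct evaluation at f = 30, h = 5, kout/kin = 63300
        assert tf_occupancy(30.0, p) == pytest.approx(0.99740, abs=1e-4)

    def test_inverse_closed_form(self, fig2):
        p = fig2.params
        assert occupancy_inverse(0.5, p) == pytest.approx(p.kout_over_kin ** 0.2)
        assert occupancy_inverse(0.99, p) == pytest.approx(22.877, abs=1e-2)

    def test_negative_input_rejected(self, fig2):
        with pytest.raises(ValueError):
            tf_occupancy(-1.0, fig2.params)
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                occupancy_inverse(bad, fig2.params)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(f=st.floats(min_value=0.01, max_value=200.0))
    def test_round_trip_identity(self, f):
        p = preset("fig2").params
        n = tf_occupancy(f, p)
        assert occupancy_inverse(n, p) == pytest.approx(f, rel=1e-8)

    def test_strictly_increasing(self, fig2):
        f = np.geomspace(0.1, 100, 50)
        n = np.array([tf_occupancy(x, fig2.params) for x in f])
        assert np.all(np.diff(n) > 0)


class TestThresholdAndGain:
    def test_fig2_thresholds(self, fig2):
        # (d/k+) * (1 + k-/(sigma+kappa)) with the packaged constants
        assert mirna_threshold(fig2.params, 1) == pytest.approx(50.05, abs=0.01)
        assert mirna_threshold(fig2.params, 2) == pytest.approx(100.10, abs=0.01)

    def test_no_dissociation_limit(self):
        p = KineticParameters(
            b1=1, b2=1, beta=1, d1=0.2, d2=0.1, delta=0.1,
            kplus1=0.002, kplus2=0.001, kminus1=0.0, kminus2=0.0,
            kappa1=0.1, kappa2=0.1, sigma1=1.0, sigma2=1.0,
        )
        assert mirna_threshold(p, 1) == pytest.approx(0.2 / 0.002)

    def test_decoupled_sentinel(self):
        p = KineticParameters(
            b1=1, b2=1, beta=1, d1=0.1, d2=0.1, delta=0.1,
            kplus1=0.0, kplus2=0.001, kminus1=0, kminus2=0,
            kappa1=0, kappa2=0, sigma1=1, sigma2=1,
        )
        assert math.isinf(mirna_threshold(p, 1))

    def test_gain_midpoint_and_decay(self, fig2):
        mu0 = mirna_threshold(fig2.params, 1)
        assert cerna_gain(0.0, fig2.params, 1) == 1.0
        assert cerna_gain(mu0, fig2.params, 1) == pytest.approx(0.5)
        assert cerna_gain(9 * mu0, fig2.params, 1) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            cerna_gain(-1.0, fig2.params, 1)


class TestSteadyState:
    def test_decoupled_birth_death(self, birth_death):
        params, occ = birth_death
        ss = steady_state(params, occ)
        assert ss.m1 == pytest.approx(params.b1 * occ.n1 / params.d1)
        assert ss.m2 == pytest.approx(params.b2 * occ.n2 / params.d2)
        assert ss.mu == pytest.approx(params.beta * occ.nmu / params.delta)
        assert ss.c1 == 0.0 and ss.c2 == 0.0

    def test_no_repressor(self, fig2):
        p = fig2.params.replace(beta=0.0)
        occ = fig2.occ.replace(n1=0.5)
        ss = steady_state(p, occ)
        assert ss.mu == 0.0
        assert ss.m1 == pytest.approx(p.b1 * 0.5 / p.d1)
        assert ss.m2 == pytest.approx(p.b2 * occ.n2 / p.d2)

    def test_balance_residuals_vanish(self, fig2):
        for f1 in (0.0, 5.0, 10.0, 30.0):
            occ = fig2.occ.replace(n1=tf_occupancy(f1, fig2.params))
            ss = steady_state(fig2.params, occ)
            res = steady_state_residuals(fig2.params, ss)
            assert np.max(np.abs(res)) < 1e-7

    def test_threshold_linear_form(self, fig2):
        # m_i equals the unrepressed level times the sigmoidal gain at mu
        occ = fig2.occ.replace(n1=tf_occupancy(10.0, fig2.params))
        ss = steady_state(fig2.params, occ)
        for i, (m, n) in ((1, (ss.m1, occ.n1)), (2, (ss.m2, occ.n2))):
            free = fig2.params.b(i) * n / fig2.params.d(i)
            assert m == pytest.approx(free * cerna_gain(ss.mu, fig2.params, i),
                                      rel=1e-9)

    def test_cross_talk_positivity(self, fig2):
        """Activating the competitor derepresses the target monotonically."""
        f_grid = np.linspace(0.0, 30.0, 16)
        m2 = [
            steady_state(
                fig2.params, fig2.occ.replace(n1=tf_occupancy(f, fig2.params))
            ).m2
            for f in f_grid
        ]
        assert np.all(np.diff(m2) >= -1e-9)

    def test_monotone_repression_in_mirna_supply(self, fig2):
        occ = fig2.occ.replace(n1=0.5)
        m2 = [
            steady_state(fig2.params.replace(beta=b), occ).m2
            for b in np.linspace(0.0, 300.0, 12)
        ]
        assert np.all(np.diff(m2) <= 1e-9)


class TestRegimes:
    @pytest.mark.parametrize(
        "mu, mu0, expected",
        [(0.0, 50.0, "free"), (50.0, 50.0, "susceptible"),
         (5000.0, 50.0, "repressed"), (4.9, 50.0, "free"), (501.0, 50.0, "repressed")],
    )
    def test_band_classification(self, mu, mu0, expected):
        assert classify_regime(mu, mu0) == expected

    def test_band_is_configurable(self):
        assert classify_regime(4.0, 50.0, ratio_band=10.0) == "free"
        assert classify_regime(4.0, 50.0, ratio_band=20.0) == "susceptible"


class TestOmegaRescaling:
    def test_identity_and_scaling(self, fig2):
        p = fig2.params
        assert rescale_omega(p, 1.0) == p
        q = rescale_omega(p, 0.5)
        assert q.delta == pytest.approx(0.5 * p.delta)
        assert q.kplus1 == pytest.approx(0.5 * p.kplus1)
        assert q.kplus2 == pytest.approx(0.5 * p.kplus2)
        assert (q.b1, q.kminus1, q.sigma2) == (p.b1, p.kminus1, p.sigma2)
        with pytest.raises(ValueError):
            rescale_omega(p, 0.0)

    def test_mean_response_preserved(self):
        """The rescaling leaves the target's mean response curve unchanged
        when back-fluxes are negligible against synthesis."""
        ps1 = preset("fig9", "miRNA", omega=1.0)
        ps01 = preset("fig9", "miRNA", omega=0.1)
        # verify the smallness conditions at the most-titrating input
        occ_top = ps1.occ.replace(n1=0.99)
        ss = steady_state(ps1.params, occ_top)
        assert ps1.params.kminus1 * ss.c1 < 0.01 * ps1.params.b1 * 0.99
        assert (ps1.params.kminus1 + ps1.params.kappa1) * ss.c1 \
            < 0.01 * ps1.params.beta * occ_top.nmu
        for f in (0.0, 5.0, 10.0, 22.9):
            occ1 = ps1.occ.replace(n1=tf_occupancy(f, ps1.params))
            occ2 = ps01.occ.replace(n1=tf_occupancy(f, ps01.params))
            a = steady_state(ps1.params, occ1).m2
            b = steady_state(ps01.params, occ2).m2
            assert b == pytest.approx(a, rel=0.01)


class TestParameterIO:
    def test_validation(self):
        with pytest.raises(ValueError):
            KineticParameters(
                b1=-1, b2=1, beta=1, d1=0.1, d2=0.1, delta=0.1,
                kplus1=0, kplus2=0, kminus1=0, kminus2=0,
                kappa1=0, kappa2=0, sigma1=0, sigma2=0,
            )
        with pytest.raises(ValueError):
            KineticParameters(
                b1=1, b2=1, beta=1, d1=0.0, d2=0.1, delta=0.1,
                kplus1=0, kplus2=0, kminus1=0, kminus2=0,
                kappa1=0, kappa2=0, sigma1=0, sigma2=0,
            )
        with pytest.raises(ValueError):
            Occupancies(n1=1.2, n2=0.0, nmu=0.0)

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_round_trip(self, tmp_path, fig2, suffix):
        path = tmp_path / f"params{suffix}"
        save_parameters(fig2.params, path)
        assert load_parameters(path) == fig2.params
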