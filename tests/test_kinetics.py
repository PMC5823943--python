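"""Effective constants, modulation factors and the turnover laws."""

import math

import numpy as np
import pytest

import stochzyme as sz
from stochzyme.errors import InvalidParameterError, UnsupportedModeError
from stochzyme.kinetics import _es_integrals_quadrature


def uncompetitive(T_cat, k_off=2.3, k_on=0.1, k_on_esi=3.0, k_off_esi=10.0):
    return sz.InhibitionScheme(
        mode="uncompetitive", k_on=k_on, T_cat=T_cat,
        T_off=sz.make_exponential(k_off),
        k_on_ESI=k_on_esi, T_off_ESI=sz.make_exponential(k_off_esi),
    )


class TestEffectiveConstants:
    def test_markovian_limit_reproduces_classical_km(self):
        """exp/exp: p_cat = k_cat/(k_cat+k_off), K_m = (k_off+k_cat)/k_on."""
        k_cat, k_off, k_on = 0.4, 2.3, 0.1
        sch = sz.InhibitionScheme(
            mode="none", k_on=k_on,
            T_cat=sz.make_exponential(k_cat), T_off=sz.make_exponential(k_off),
        )
        ec = sz.effective_constants(sch)
        assert ec.p_cat == pytest.approx(k_cat / (k_cat + k_off), rel=1e-12)
        assert ec.K_m == pytest.approx((k_off + k_cat) / k_on, rel=1e-12)
        assert ec.v_max == pytest.approx(ec.p_cat / ec.mean_W_ES0, rel=1e-12)

    def test_two_state_closed_form(self, fig5a_scheme):
        """Hyperexponential catalysis vs the rational closed form."""
        p, k1, k2, ko = 0.1, 50.0, 0.5, 2.3
        ec = sz.effective_constants(fig5a_scheme)
        assert ec.p_cat == pytest.approx(
            p * k1 / (k1 + ko) + (1 - p) * k2 / (k2 + ko), rel=1e-12
        )
        assert ec.mean_W_ES0 == pytest.approx(
            p / (k1 + ko) + (1 - p) / (k2 + ko), rel=1e-12
        )

    def test_quadrature_path_matches_fast_path(self, fig5a_scheme):
        """The generic quadrature route reproduces the Laplace shortcut."""
        for s in (0.0, 0.5, 3.0):
            w_q, p_q = _es_integrals_quadrature(
                fig5a_scheme.T_cat, fig5a_scheme.T_off, s
            )
            from stochzyme.kinetics import _es_integrals

            w_f, p_f = _es_integrals(fig5a_scheme.T_cat, fig5a_scheme.T_off, s)
            assert w_q == pytest.approx(w_f, rel=1e-9)
            assert p_q == pytest.approx(p_f, rel=1e-9)

    def test_simulator_confirms_p_cat(self, fig5a_scheme):
        visits = sz.simulate_es_visits(
            fig5a_scheme.T_cat, fig5a_scheme.T_off, n=100_000, seed=21
        )
        ec = sz.effective_constants(fig5a_scheme)
        se = math.sqrt(ec.p_cat * (1 - ec.p_cat) / 100_000)
        assert visits.p_cat == pytest.approx(ec.p_cat, abs=3 * se)

    def test_absent_channels_give_infinite_constants(self, fig5a_scheme):
        ec = sz.effective_constants(fig5a_scheme)
        assert math.isinf(ec.K_EI)
        assert ec.K_ESI == pytest.approx(1.0 / (0.1 * 3.0))


class TestTransformFunctionals:
    def test_unity_at_zero(self, fig5a_scheme, markovian_uncompetitive):
        for sch in (fig5a_scheme, markovian_uncompetitive):
            assert sz.f_tilde_M(sch, 0.0) == pytest.approx(1.0, abs=1e-12)
            assert sz.f_tilde_P(sch, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_exponential_closed_forms(self, markovian_uncompetitive):
        k_cat, k_off = 0.1, 2.3
        for s in (0.3, 3.0, 30.0):
            assert sz.f_tilde_M(markovian_uncompetitive, s) == pytest.approx(
                (k_cat + k_off) / (k_cat + k_off + s), rel=1e-12
            )
            assert sz.f_tilde_P(markovian_uncompetitive, s) == pytest.approx(
                (k_cat + k_off) / (k_cat + k_off + s), rel=1e-12
            )

    def test_two_state_rational_form(self, fig5a_scheme):
        """Hyperexponential catalysis gives a rational transform; verify at
        the transform argument k_on_ESI * 1 μM."""
        p, k1, k2, ko = 0.1, 50.0, 0.5, 2.3
        s = 3.0 * 1.0
        lap = p * k1 / (k1 + ko + s) + (1 - p) * k2 / (k2 + ko + s)
        w0 = p / (k1 + ko) + (1 - p) / (k2 + ko)
        assert sz.f_tilde_M(fig5a_scheme, s) == pytest.approx(
            ((1 - lap) / (ko + s)) / w0, rel=1e-12
        )


class TestModulationFactors:
    def test_unity_at_zero_inhibitor(self, fig5a_scheme):
        mf = sz.modulation_factors(fig5a_scheme, 0.0)
        assert mf.A == 1.0
        assert mf.B == 1.0

    def test_markovian_case_stays_at_unity(self, markovian_uncompetitive):
        for I in np.geomspace(1e-3, 100.0, 20):
            mf = sz.modulation_factors(markovian_uncompetitive, I)
            assert mf.A == pytest.approx(1.0, abs=1e-10)
            assert mf.B == pytest.approx(1.0, abs=1e-10)

    def test_two_state_decreasing_and_plateau(self, fig5a_scheme):
        I_grid = np.geomspace(1e-3, 1e4, 60)
        A = np.array([sz.modulation_factors(fig5a_scheme, I, check=False).A for I in I_grid])
        B = np.array([sz.modulation_factors(fig5a_scheme, I, check=False).B for I in I_grid])
        assert np.all(A <= 1.0 + 1e-12) and np.all(B <= 1.0 + 1e-12)
        assert np.all(np.diff(A) < 0) and np.all(np.diff(B) < 0)
        # plateau: the drop over the last decade is a small fraction of the
        # total drop and the curves keep flattening
        for curve in (A, B):
            last = curve[-9] - curve[-1]
            prev = curve[-17] - curve[-9]
            assert last < 0.05 * (curve[0] - curve[-1])
            assert last < prev

    def test_dual_representation_identity(self, fig5a_scheme):
        """Laplace-form and probabilistic-form A, B agree (raises if not)."""
        for I in (0.1, 1.0, 10.0):
            mf = sz.modulation_factors(fig5a_scheme, I, check=True)
            assert 0 < mf.A <= 1 and 0 < mf.B <= 1

    def test_dual_representation_all_families(self):
        for T_cat in (
            sz.make_hyperexponential2(0.1, 50.0, 0.5),
            sz.make_gamma(4.0, 0.25),
            sz.make_moment_matched("weibull", 2.0, 1.5),
            sz.make_moment_matched("lognormal", 2.0, 1.5),
        ):
            sch = uncompetitive(T_cat)
            mf = sz.modulation_factors(sch, 2.0, check=True, check_tol=1e-8)
            assert math.isfinite(mf.A) and math.isfinite(mf.B)

    def test_negative_inhibitor_rejected(self, fig5a_scheme):
        with pytest.raises(InvalidParameterError):
            sz.modulation_factors(fig5a_scheme, -1.0)

    def test_wrong_mode_rejected(self):
        sch = sz.InhibitionScheme(
            mode="none", k_on=0.1,
            T_cat=sz.make_exponential(1.0), T_off=sz.make_exponential(1.0),
        )
        with pytest.raises(UnsupportedModeError):
            sz.modulation_factors(sch, 1.0)


class TestClassicalTurnover:
    def test_uninhibited_is_michaelis_menten(self):
        for S in (0.5, 10.0, 1e4):
            assert sz.turnover_classical(10.0, 0.5, math.inf, math.inf, S, 0.0) == (
                pytest.approx(0.5 * S / (10.0 + S), rel=1e-12)
            )

    def test_equal_constants_give_pure_scaling(self):
        K = 4.0
        for S in (1.0, 30.0):
            k0 = sz.turnover_classical(10.0, 0.5, math.inf, math.inf, S, 0.0)
            k = sz.turnover_classical(10.0, 0.5, K, K, S, 8.0)
            assert k == pytest.approx(k0 / (1 + 8.0 / K), rel=1e-12)

    def test_saturating_substrate_limit(self):
        k = sz.turnover_classical(10.0, 0.5, math.inf, 4.0, 1e12, 8.0)
        assert k == pytest.approx(0.5 / (1 + 8.0 / 4.0), rel=1e-6)

    def test_invalid_substrate(self):
        with pytest.raises(InvalidParameterError):
            sz.turnover_classical(10.0, 0.5, math.inf, math.inf, 0.0, 0.0)


class TestTurnoverLaws:
    def test_competitive_depends_on_EI_mean_only(self):
        base = dict(
            mode="competitive", k_on=0.1,
            T_cat=sz.make_gamma(4.0, 0.25), T_off=sz.make_exponential(2.3),
            k_on_EI=1.0,
        )
        a = sz.InhibitionScheme(**base, T_off_EI=sz.make_exponential(2.0))
        b = sz.InhibitionScheme(**base, T_off_EI=sz.make_moment_matched("weibull", 0.5, 2.0))
        for S in (1.0, 10.0, 100.0):
            for I in (0.0, 2.0, 20.0):
                assert sz.turnover_competitive(a, S, I) == pytest.approx(
                    sz.turnover_competitive(b, S, I), rel=1e-12
                )

    def test_markovian_reduction_all_modes(self):
        """All-exponential schemes reduce to the classical law on a 5x5 grid."""
        k_cat, k_off, k_on = 0.4, 2.3, 0.1
        K_m_cl = (k_off + k_cat) / k_on
        cases = {
            "competitive": dict(k_on_EI=1.0, T_off_EI=sz.make_exponential(2.0)),
            "uncompetitive": dict(k_on_ESI=3.0, T_off_ESI=sz.make_exponential(10.0)),
            "mixed": dict(
                k_on_EI=1.0, T_off_EI=sz.make_exponential(2.0),
                k_on_ESI=3.0, T_off_ESI=sz.make_exponential(10.0),
            ),
        }
        for mode, extra in cases.items():
            sch = sz.InhibitionScheme(
                mode=mode, k_on=k_on,
                T_cat=sz.make_exponential(k_cat), T_off=sz.make_exponential(k_off),
                **extra,
            )
            K_EI = 2.0 / 1.0 if "k_on_EI" in extra else math.inf
            K_ESI = 10.0 / 3.0 if "k_on_ESI" in extra else math.inf
            for S in np.geomspace(0.5, 200.0, 5):
                for I in np.linspace(0.0, 20.0, 5):
                    k = sz.turnover(sch, S, I)
                    k_cl = sz.turnover_classical(K_m_cl, k_cat, K_EI, K_ESI, S, I)
                    assert k == pytest.approx(k_cl, rel=1e-10)

    def test_lineweaver_burk_affine_in_inverse_substrate(self, fig5a_scheme):
        """1/k_turn is affine in 1/S at fixed I for every mode."""
        mixed = sz.InhibitionScheme(
            mode="mixed", k_on=0.1,
            T_cat=sz.make_hyperexponential2(0.1, 50.0, 0.5),
            T_off=sz.make_exponential(2.3),
            k_on_EI=1.0, T_off_EI=sz.make_exponential(2.0),
            k_on_ESI=3.0, T_off_ESI=sz.make_exponential(10.0),
        )
        comp = sz.InhibitionScheme(
            mode="competitive", k_on=0.1,
            T_cat=sz.make_hyperexponential2(0.1, 50.0, 0.5),
            T_off=sz.make_exponential(2.3),
            k_on_EI=1.0, T_off_EI=sz.make_exponential(2.0),
        )
        for sch in (fig5a_scheme, mixed, comp):
            for I in (0.0, 2.0, 9.0):
                S1, S2 = 1.0, 50.0
                y1, y2 = 1 / sz.turnover(sch, S1, I), 1 / sz.turnover(sch, S2, I)
                slope = (y1 - y2) / (1 / S1 - 1 / S2)
                intercept = y1 - slope / S1
                for S in (0.2, 5.0, 500.0):
                    assert 1 / sz.turnover(sch, S, I) == pytest.approx(
                        slope / S + intercept, rel=1e-10
                    )

    def test_mixed_reduces_to_competitive_without_ESI(self):
        common = dict(
            k_on=0.1, T_cat=sz.make_hyperexponential2(0.1, 50.0, 0.5),
            T_off=sz.make_exponential(2.3),
            k_on_EI=1.0, T_off_EI=sz.make_exponential(2.0),
        )
        mixed = sz.InhibitionScheme(mode="mixed", **common)
        comp = sz.InhibitionScheme(mode="competitive", **common)
        for S in (1.0, 30.0):
            for I in (0.0, 5.0, 50.0):
                assert sz.turnover_mixed(mixed, S, I) == pytest.approx(
                    sz.turnover_competitive(comp, S, I), rel=1e-12
                )

    def test_mixed_reduces_to_uncompetitive_without_EI(self, fig5a_scheme):
        mixed = sz.InhibitionScheme(
            mode="mixed", k_on=0.1,
            T_cat=sz.make_hyperexponential2(0.1, 50.0, 0.5),
            T_off=sz.make_exponential(2.3),
            k_on_ESI=3.0, T_off_ESI=sz.make_exponential(10.0),
        )
        for S in (1.0, 30.0):
            for I in (0.0, 5.0, 50.0):
                assert sz.turnover_mixed(mixed, S, I) == pytest.approx(
                    sz.turnover_uncompetitive(fig5a_scheme, S, I), rel=1e-12
                )

    def test_uncompetitive_saturating_limit_tracks_B(self, fig5a_scheme):
        """1/k_turn([S] -> inf) ~ (1 + I/K_ESI) B(I) / v_max."""
        ec = sz.effective_constants(fig5a_scheme)
        for I in (0.5, 5.0):
            B = sz.modulation_factors(fig5a_scheme, I, check=False).B
            expected = (1 + I / ec.K_ESI) * B / ec.v_max
            assert 1 / sz.turnover(fig5a_scheme, 1e9, I) == pytest.approx(
                expected, rel=1e-6
            )

    def test_mode_mismatch_raises(self, fig5a_scheme):
        with pytest.raises(UnsupportedModeError):
            sz.turnover_competitive(fig5a_scheme, 10.0, 1.0)
        with pytest.raises(UnsupportedModeError):
            sz.turnover_mixed(fig5a_scheme, 10.0, 1.0)


class TestSchemeValidation:
    def test_missing_dwell_distribution(self):
        with pytest.raises(InvalidParameterError):
            sz.InhibitionScheme(
                mode="uncompetitive", k_on=0.1,
                T_cat=sz.make_exponential(1.0), T_off=sz.make_exponential(1.0),
                k_on_ESI=3.0,  # no T_off_ESI
            )

    def test_zero_binding_constant_means_absent_channel(self):
        sch = sz.InhibitionScheme(
            mode="uncompetitive", k_on=0.1,
            T_cat=sz.make_hyperexponential2(0.1, 50.0, 0.5),
            T_off=sz.make_exponential(2.3),
            k_on_ESI=0.0,
        )
        assert not sch.has_ESI
        ec = sz.effective_constants(sch)
        assert math.isinf(ec.K_ESI)
        # no ESI channel: rate is the uninhibited MM rate at any I
        assert sz.turnover(sch, 10.0, 50.0) == pytest.approx(
            sz.turnover(sch, 10.0, 0.0), rel=1e-12
        )

    def test_wrong_channel_for_mode(self):
        with pytest.raises(InvalidParameterError):
            sz.InhibitionScheme(
                mode="competitive", k_on=0.1,
                T_cat=sz.make_exponential(1.0), T_off=sz.make_exponential(1.0),
                k_on_ESI=3.0, T_off_ESI=sz.make_exponential(1.0),
            )
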