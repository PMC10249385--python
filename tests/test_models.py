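"""Retention-model evaluation and parameter conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from gcretention import (
    ABCParams,
    ConversionDomainError,
    DomainError,
    KCentricParams,
    ThermoParams,
    abc_to_kcentric,
    abc_to_thermo,
    kcentric_to_abc,
    lnk_abc,
    lnk_kcentric,
    lnk_thermo,
    retention_factor,
    thermo_to_abc,
)
from gcretention.constants import R_GAS


valid_kcentric = st.builds(
    KCentricParams,
    Tchar=st.floats(330.0, 600.0),
    thetachar=st.floats(18.0, 80.0),
    dCp=st.floats(0.0, 400.0),
    beta0=st.floats(60.0, 500.0),
)


class TestLnkAbc:
    def test_zero_coefficients(self):
        assert lnk_abc(350.0, ABCParams(A=0.0, B=0.0, C=0.0, beta0=1.0)) == 0.0

    def test_two_parameter_root(self):
        # A + B/T = 0 at T = -B/A
        assert lnk_abc(400.0, ABCParams(A=-10.0, B=4000.0, C=0.0, beta0=1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_converted_tchar(self, cinnamaldehyde_abc):
        kc, _ = abc_to_kcentric(cinnamaldehyde_abc)
        assert lnk_abc(kc.Tchar, cinnamaldehyde_abc) == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_temperature_rejected(self, cinnamaldehyde_abc):
        with pytest.raises(DomainError):
            lnk_abc(0.0, cinnamaldehyde_abc)
        with pytest.raises(DomainError):
            lnk_abc(-10.0, cinnamaldehyde_abc)


class TestLnkKcentric:
    def test_zero_at_tchar(self, true_kcentric):
        assert lnk_kcentric(true_kcentric.Tchar, true_kcentric) == pytest.approx(0.0, abs=1e-14)

    def test_slope_at_tchar_is_minus_inverse_thetachar(self, true_kcentric):
        h = 1e-3
        slope = (
            lnk_kcentric(true_kcentric.Tchar + h, true_kcentric)
            - lnk_kcentric(true_kcentric.Tchar - h, true_kcentric)
        ) / (2 * h)
        assert slope == pytest.approx(-1.0 / true_kcentric.thetachar, abs=1e-6)

    def test_phase_ratio_halving_doubles_k(self):
        p = KCentricParams(Tchar=400.0, thetachar=30.0, dCp=100.0, beta0=250.0)
        assert lnk_kcentric(p.Tchar, p, beta1=125.0) == pytest.approx(math.log(2.0))

    def test_zero_thetachar_rejected(self):
        p = KCentricParams(Tchar=400.0, thetachar=0.0, dCp=0.0, beta0=1.0)
        with pytest.raises(DomainError):
            lnk_kcentric(380.0, p)

    def test_strictly_decreasing_near_tchar(self, true_kcentric):
        T = np.linspace(true_kcentric.Tchar - 30, true_kcentric.Tchar + 30, 61)
        lnk = np.asarray(lnk_kcentric(T, true_kcentric))
        assert np.all(np.diff(lnk) < 0)


class TestThermoConversion:
    # Published reference values (Tref = 90 C): name -> (A, B, C, dHref, dSref)
    TABLE = {
        "cinnamaldehyde": (-82.062, 10505.0, 10.503, -55627.0, -80.181),
        "geraniol": (-88.825, 10625.0, 11.451, -53770.0, -82.087),
        "limonene": (-75.098, 8393.5, 9.8499, -40046.0, -59.733),
        "linalool": (-83.176, 9508.6, 10.803, -46441.0, -72.290),
        "PCB 28": (-101.55, 13300.0, 13.001, -71330.0, -98.992),
        "glyceryl trihexanoate": (-188.84, 22064.0, 24.456, -109610.0, -168.13),
    }

    @pytest.mark.parametrize("name", sorted(TABLE))
    def test_printed_reference_rows(self, name):
        A, B, C, dH, dS = self.TABLE[name]
        th = abc_to_thermo(ABCParams(A=A, B=B, C=C, beta0=250.0), 363.15)
        assert th.dHref == pytest.approx(dH, rel=1e-3)
        assert th.dSref == pytest.approx(dS, rel=1e-3)
        assert th.dCp == pytest.approx(C * R_GAS, rel=1e-12)

    def test_two_parameter_limit(self):
        th = abc_to_thermo(ABCParams(A=-5.0, B=1000.0, C=0.0, beta0=1.0), 363.15)
        assert th.dCp == 0.0
        assert th.dHref == pytest.approx(-1000.0 * R_GAS)

    def test_roundtrip_identity(self, cinnamaldehyde_abc):
        th = abc_to_thermo(cinnamaldehyde_abc, 363.15)
        back = thermo_to_abc(th, beta0=250.0)
        for attr in ("A", "B", "C"):
            assert getattr(back, attr) == pytest.approx(
                getattr(cinnamaldehyde_abc, attr), rel=1e-12
            )

    def test_geraniol_inverse_of_printed_row(self):
        # thermodynamic row (dHref, dSref, dCp = C*R) back to the printed ABC
        A, B, C, dH, dS = self.TABLE["geraniol"]
        th = ThermoParams(dHref=dH, dSref=dS, dCp=C * R_GAS, Tref=363.15)
        back = thermo_to_abc(th, beta0=250.0)
        # input rounding of the printed dH/dS limits the agreement
        assert back.A == pytest.approx(A, rel=1e-3)
        assert back.B == pytest.approx(B, rel=1e-3)
        assert back.C == pytest.approx(C, rel=1e-6)


class TestKcentricConversion:
    def test_two_parameter_closed_form(self):
        kc, lam = abc_to_kcentric(ABCParams(A=-10.0, B=4000.0, C=0.0, beta0=1.0))
        assert lam is None
        assert kc.Tchar == pytest.approx(400.0)
        assert kc.thetachar == pytest.approx(40.0)
        assert kc.dCp == 0.0

    def test_two_parameter_inverse(self):
        abc = kcentric_to_abc(KCentricParams(Tchar=400.0, thetachar=40.0, dCp=0.0, beta0=1.0))
        assert abc.A == pytest.approx(-10.0)
        assert abc.B == pytest.approx(4000.0)
        assert abc.C == pytest.approx(0.0, abs=1e-15)

    def test_against_bruteforce_root(self, cinnamaldehyde_abc):
        """Tchar must agree with a bisection root of ln k = 0 and thetachar
        with the negative inverse slope there."""
        p = cinnamaldehyde_abc
        f = lambda T: lnk_abc(T, p)
        root = brentq(f, 200.0, 800.0, xtol=1e-10)
        kc, lam = abc_to_kcentric(p)
        assert kc.Tchar == pytest.approx(root, abs=1e-6)
        h = 1e-4
        slope = (f(root + h) - f(root - h)) / (2 * h)
        assert kc.thetachar == pytest.approx(-1.0 / slope, rel=1e-6)
        assert -1.0 / math.e < lam.x < 0.0
        assert lam.w < -1.0
        assert lam.branch == -1

    def test_out_of_domain_flagged_not_fixed(self):
        # nearly linear ln k curve: no zero crossing, no Tchar
        p = ABCParams(A=-5.0, B=9000.0, C=10.0, beta0=1.0)
        with pytest.raises(ConversionDomainError) as exc:
            abc_to_kcentric(p)
        assert exc.value.x is not None and exc.value.x <= -1.0 / math.e

    def test_negative_c_requires_explicit_fallback(self):
        p = ABCParams(A=-10.0, B=4000.0, C=-0.5, beta0=1.0)
        with pytest.raises(ConversionDomainError):
            abc_to_kcentric(p)
        kc, lam = abc_to_kcentric(p, allow_two_param_fallback=True)
        assert lam is None
        assert kc.dCp == 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=valid_kcentric)
    def test_roundtrip_and_curve_identity(self, p):
        abc = kcentric_to_abc(p)
        back, _ = abc_to_kcentric(abc)
        assert back.Tchar == pytest.approx(p.Tchar, rel=1e-9)
        assert back.thetachar == pytest.approx(p.thetachar, rel=1e-9)
        assert back.dCp == pytest.approx(p.dCp, rel=1e-9, abs=1e-9)
        T = np.linspace(300.0, 600.0, 50)
        dev = np.abs(np.asarray(lnk_abc(T, abc)) - np.asarray(lnk_kcentric(T, p)))
        assert dev.max() < 1e-9

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(p=valid_kcentric, Tref=st.floats(300.0, 500.0))
    def test_three_parameterizations_identical_curves(self, p, Tref):
        abc = kcentric_to_abc(p)
        th = abc_to_thermo(abc, Tref)
        T = np.linspace(310.0, 590.0, 40)
        lk = np.asarray(lnk_kcentric(T, p))
        la = np.asarray(lnk_abc(T, abc))
        lt = np.asarray(lnk_thermo(T, th, p.beta0))
        assert np.max(np.abs(lk - la)) < 1e-9
        assert np.max(np.abs(lk - lt)) < 1e-9

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(p=valid_kcentric, beta1=st.floats(60.0, 500.0))
    def test_distribution_coefficient_invariant_under_beta(self, p, beta1):
        """K = k*beta does not depend on the column's phase ratio."""
        T = p.Tchar + 12.3
        lnK0 = lnk_kcentric(T, p) + math.log(p.beta0)
        lnK1 = lnk_kcentric(T, p, beta1=beta1) + math.log(beta1)
        assert lnK0 == pytest.approx(lnK1, abs=1e-12)


class TestRetentionFactor:
    @pytest.mark.parametrize(
        "tR,tM,expected", [(2.0, 1.0, 1.0), (10.0, 2.0, 4.0), (3.7, 3.7, 0.0)]
    )
    def test_values(self, tR, tM, expected):
        assert retention_factor(tR, tM) == pytest.approx(expected)

    def test_negative_retention_rejected(self):
        with pytest.raises(DomainError):
            retention_factor(0.9, 1.0)
        with pytest.raises(DomainError):
            retention_factor(1.0, 0.0)
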