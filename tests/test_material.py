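"""Constitutive model: fibril law, Neo-Hookean matrix, permeability,
stress decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poroindent.exceptions import DegenerateDeformationError
from poroindent.material import (
    ConstitutiveConstants,
    FRPEParameters,
    StrainState,
    StressDecomposition,
    fibril_stress,
    lame_parameters,
    nonfibrillar_stress,
    permeability,
    total_stress,
)


class TestFibrilStress:
    @pytest.mark.parametrize(
        "Ef0, EfEps, eps, expected",
        [
            (5.0, 100.0, -0.05, 0.0),  # tension-only: no compressive stress
            (1.0, 0.0, 0.1, 0.1),  # Hooke limit at zero strain-dependency
            (1.0, 10.0, 0.1, 0.2),  # (1 + 10*0.1)*0.1, by hand
            (0.0, 0.0, 0.3, 0.0),
        ],
    )
    def test_values(self, Ef0, EfEps, eps, expected):
        assert fibril_stress(Ef0, EfEps, eps) == pytest.approx(expected, abs=1e-15)

    @given(
        eps=st.floats(min_value=-0.5, max_value=0.0),
        Ef0=st.floats(min_value=0.0, max_value=50.0),
        EfEps=st.floats(min_value=0.0, max_value=500.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_zero_on_compressive_halfline(self, eps, Ef0, EfEps):
        assert fibril_stress(Ef0, EfEps, eps) == 0.0

    def test_strictly_increasing_and_convex_in_tension(self):
        eps = np.linspace(1e-4, 0.3, 200)
        s = fibril_stress(1.0, 10.0, eps)
        assert np.all(np.diff(s) > 0)
        assert np.all(np.diff(s, 2) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            fibril_stress(1.0, 1.0, np.nan)


class TestNonfibrillarStress:
    def test_reference_state_is_stress_free(self):
        s = nonfibrillar_stress(0.5, 0.42, StrainState())
        assert np.allclose(s, 0.0)

    @pytest.mark.parametrize("nu", [0.0, 0.3, 0.42])
    def test_infinitesimal_limit_matches_linear_elasticity(self, nu):
        E, eps = 0.5, 1e-6
        lam, mu = lame_parameters(E, nu)
        s = nonfibrillar_stress(E, nu, StrainState.from_small_strain(eps_zz=eps))
        assert s[2, 2] == pytest.approx(lam * eps, rel=1e-3)
        assert s[1, 1] == pytest.approx((lam + 2 * mu) * eps, rel=1e-3)

    def test_volumetric_compression_matches_energy_derivative(self):
        # sigma for F = J^(1/3) I from central differences of the stored
        # energy  W = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2
        E, nu, J = 0.5, 0.42, 0.9
        lam, mu = lame_parameters(E, nu)

        def W(stretch):
            I1 = 3.0 * stretch**2
            Jv = stretch**3
            return 0.5 * mu * (I1 - 3.0) - mu * np.log(Jv) + 0.5 * lam * np.log(Jv) ** 2

        lam_s = J ** (1.0 / 3.0)
        h = 1e-6
        dWdl = (W(lam_s + h) - W(lam_s - h)) / (2 * h)
        # Cauchy pressure: sigma = (lam_s / (3 J)) dW/dlam_s on the diagonal
        sigma_expected = lam_s / (3.0 * J) * dWdl
        s = nonfibrillar_stress(E, nu, StrainState(F_rr=lam_s, F_zz=lam_s, F_tt=lam_s))
        assert np.allclose(np.diag(s), sigma_expected, rtol=1e-4)

    def test_inverted_state_rejected(self):
        with pytest.raises(DegenerateDeformationError):
            nonfibrillar_stress(0.5, 0.42, StrainState(F_zz=-0.5))


class TestPermeability:
    def test_reference_and_strain_independence(self):
        assert permeability(2.0, 5.0, 4.0, 4.0) == pytest.approx(2.0)
        assert permeability(2.0, 0.0, 1.0, 4.0) == pytest.approx(2.0)

    def test_power_law_by_hand(self):
        # k0 (1+e)^M/(1+e0)^M = 2 * (4/5)^5
        assert permeability(2.0, 5.0, 3.0, 4.0) == pytest.approx(2.0 * 0.8**5)

    def test_log_linear_in_volume_ratio(self):
        e = np.linspace(0.5, 8.0, 40)
        k = permeability(3.0, 4.0, e, 4.0)
        x = np.log((1 + e) / 5.0)
        slope = np.polyfit(x, np.log(k), 1)[0]
        assert slope == pytest.approx(4.0, rel=1e-12)

    def test_monotone_decreasing_under_compaction(self):
        e = np.linspace(3.9, 0.5, 30)
        assert np.all(np.diff(permeability(2.0, 6.0, e, 4.0)) < 0)

    def test_invalid_void_ratio(self):
        with pytest.raises(ValueError):
            permeability(1.0, 1.0, -1.5, 4.0)


class TestTotalStress:
    def test_zero_and_drained_limits(self):
        z = np.zeros((3, 3))
        assert np.allclose(total_stress(z, z, 0.0), 0.0)
        s_nf = np.diag([1.0, 2.0, 3.0])
        assert np.allclose(total_stress(s_nf, z, 0.0), s_nf)

    @given(data=st.integers(min_value=0, max_value=2**32 - 1))
    @settings(deadline=None, max_examples=50)
    def test_decomposition_reconstructs_exactly(self, data):
        rng = np.random.default_rng(data)
        s_nf = rng.normal(size=(3, 3))
        s_f = rng.normal(size=(3, 3))
        p = float(rng.normal())
        d = StressDecomposition(sigma_nf=s_nf, sigma_f=s_f, p=p)
        assert np.array_equal(d.sigma_t, s_nf + s_f - p * np.eye(3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_stress(np.zeros((3, 3)), np.zeros((2, 2)), 0.0)


class TestParameterTypes:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            FRPEParameters(Ef0=-1.0, EfEps=0.0, Enf=0.5, k0=1.0, M=0.0)
        with pytest.raises(ValueError):
            FRPEParameters(Ef0=0.0, EfEps=0.0, Enf=0.0, k0=1.0, M=0.0)
        with pytest.raises(ValueError):
            ConstitutiveConstants(nu_nf=0.5)

    def test_unit_conversion_roundtrip(self):
        p = FRPEParameters(Ef0=1.0, EfEps=1.0, Enf=0.5, k0=7.0, M=1.0)
        assert p.k0_internal == pytest.approx(7.0e-3)
        assert FRPEParameters.from_array(p.as_array()) == p

    def test_void_ratio_follows_volume_change(self):
        st_ = StrainState(F_rr=0.95, F_zz=0.95, F_tt=0.95)
        e = st_.void_ratio(4.0)
        assert e == pytest.approx(0.95**3 * 5.0 - 1.0)
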