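"""Personalized LMWH pharmacokinetics: arithmetic oracles and dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemosim.pk_lmwh import (
    IU_PER_ML_TO_NM,
    PatientRecord,
    PKParameters,
    blood_volume,
    blood_half_life_h,
    heparin_in_sample,
    interstitial_volume,
    ka_from_cholesterol,
    kelim_from_creatinine,
    personalized_parameters,
    simulate_pk,
)


def _patient(**kw):
    defaults = dict(patient_id="p", sex="M", weight_kg=92.0, hematocrit=0.477,
                    creatinine_umol_l=38.0, cholesterol_mmol_l=3.12,
                    ldl_mmol_l=1.94, dose_iu=4000.0, dose_times_h=(0.0,))
    defaults.update(kw)
    return PatientRecord(**defaults)


class TestArithmetic:
    """The personalization formulas, exact to 1e-10."""

    def test_blood_volume_male(self):
        # patient 2 of the reference group: 92 kg, hematocrit 47.7%
        assert blood_volume("M", 92.0, 0.477) == pytest.approx(
            1.4 * 92 * 0.075 * 0.523, abs=1e-10)

    def test_blood_volume_female(self):
        assert blood_volume("F", 53.0, 0.324) == pytest.approx(
            1.4 * 53 * 0.065 * 0.676, abs=1e-10)

    def test_blood_volume_vanishes_at_full_hematocrit(self):
        assert blood_volume("M", 80.0, 1 - 1e-9) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("w, expected", [(80.0, 6.0), (40.0, 3.0), (96.0, 7.2)])
    def test_interstitial_volume(self, w, expected):
        assert interstitial_volume(w) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("chol, expected", [
        (0.0, 0.0), (3.12, 4.68e-6), (6.87, 1.0305e-5)])
    def test_ka_from_cholesterol(self, chol, expected):
        assert ka_from_cholesterol(chol) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("creat, expected", [
        (33.0, 7.7e-5), (38.0, (1 + 33 / 38) * 3.85e-5)])
    def test_kelim_from_creatinine(self, creat, expected):
        assert kelim_from_creatinine(creat) == pytest.approx(expected, abs=1e-10)

    def test_kelim_limit_high_creatinine(self):
        assert kelim_from_creatinine(1e9) == pytest.approx(3.85e-5, rel=1e-6)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            blood_volume("M", 80.0, 1.2)
        with pytest.raises(ValueError):
            kelim_from_creatinine(0.0)
        with pytest.raises(ValueError):
            ka_from_cholesterol(-1.0)


class TestDynamics:
    def test_mass_conserved_without_elimination(self):
        p = _patient(creatinine_umol_l=1e12)  # Kelim -> 3.85e-5... not zero
        params = PKParameters(vb_l=5.0, vint_l=6.0, kelim=0.0, ka=1e-5)
        state = simulate_pk(p, params, times_h=np.linspace(0, 48, 49))
        total = (state.interstitial_iu
                 + (state.free_iu_ml + state.bound_iu_ml) * 5.0 * 1000.0)
        assert np.allclose(total, p.dose_iu, rtol=1e-9)

    def test_monoexponential_limit(self):
        """Ka = 0, Kin >> Kout: after absorption the blood level decays at Kelim."""
        p = _patient()
        kelim = 5e-5
        params = PKParameters(vb_l=5.0, vint_l=6.0, kin=5e-3, kout=0.0,
                              ka=0.0, kd=0.0, kelim=kelim)
        t = np.linspace(5.0, 20.0, 16)
        state = simulate_pk(p, params, times_h=t)
        c = state.free_iu_ml
        rate = -np.gradient(np.log(c), t * 3600.0)
        assert np.allclose(rate, kelim, rtol=1e-2)

    def test_closed_form_two_state_oracle(self):
        """With exchange off, the blood bolus follows the analytic 2-state solution.

        For x' = M x, M = [[-(ka+kelim), kd], [ka, -kd]], the oracle is
        the eigendecomposition of the hand-written matrix; the module's
        system matrix restricted to the blood states must reproduce it
        to 1e-8.
        """
        from hemosim.pk_lmwh import _system_matrix

        ka, kd, kelim = 4.68e-6, 1e-5, 7e-5
        params = PKParameters(vb_l=5.0, vint_l=6.0, kin=0.0, kout=0.0,
                              ka=ka, kd=kd, kelim=kelim)
        A = _system_matrix(params)
        # interstitial decouples; blood (free, bound) block is the 2-state system
        M = np.array([[-(ka + kelim), kd], [ka, -kd]])
        assert np.allclose(A[1:, 1:], M, atol=1e-15)
        w, V = np.linalg.eig(M)
        x0 = np.array([1.0, 0.0])
        from scipy.linalg import expm
        for t_h in (1.0, 6.0, 24.0):
            x_exact = (V @ (np.exp(w * t_h * 3600.0) * np.linalg.solve(V, x0))).real
            x_num = expm(A * t_h * 3600.0)[1:, 1:] @ x0
            assert np.allclose(x_num, x_exact, atol=1e-8)

    def test_dose_linearity_and_superposition(self):
        p1 = _patient(dose_iu=4000.0)
        p2 = _patient(dose_iu=8000.0)
        params = personalized_parameters(p1)
        t = np.linspace(0, 24, 25)
        s1 = simulate_pk(p1, params, times_h=t)
        s2 = simulate_pk(p2, params, times_h=t)
        assert np.allclose(2 * s1.total_iu_ml, s2.total_iu_ml, rtol=1e-9)

        both = _patient(dose_times_h=(0.0, 12.0))
        s_both = simulate_pk(both, params, times_h=t)
        s_a = simulate_pk(_patient(dose_times_h=(0.0,)), params, times_h=t)
        s_b = simulate_pk(_patient(dose_times_h=(12.0,)), params, times_h=t)
        assert np.allclose(s_both.total_iu_ml, s_a.total_iu_ml + s_b.total_iu_ml,
                           rtol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(chol=st.floats(2.0, 8.0), creat=st.floats(30.0, 120.0))
    def test_monotonicity_in_cholesterol_and_creatinine(self, chol, creat):
        """Higher cholesterol slows terminal decline; higher creatinine slows elimination."""
        t = np.linspace(0, 24, 49)
        base = _patient(cholesterol_mmol_l=chol, creatinine_umol_l=creat)
        hi_chol = _patient(cholesterol_mmol_l=chol + 1.0, creatinine_umol_l=creat)
        hi_creat = _patient(cholesterol_mmol_l=chol, creatinine_umol_l=creat + 30.0)
        c0 = simulate_pk(base, personalized_parameters(base), t).total_iu_ml
        c1 = simulate_pk(hi_chol, personalized_parameters(hi_chol), t).total_iu_ml
        c2 = simulate_pk(hi_creat, personalized_parameters(hi_creat), t).total_iu_ml
        assert c1[-1] >= c0[-1]
        assert c2[-1] >= c0[-1]

    def test_half_life_in_literature_band(self):
        """Typical patient: blood-level half-life of LMWH in the 4.5-5 h band."""
        p = _patient()
        state = simulate_pk(p, personalized_parameters(p),
                            times_h=np.linspace(0, 36, 721))
        assert 4.5 <= blood_half_life_h(state) <= 5.0


class TestSampling:
    def test_zero_level_converts_to_zero(self):
        p = _patient()
        state = simulate_pk(p, personalized_parameters(p), times_h=[0.0, 1.0])
        assert heparin_in_sample(state, 0.0) == pytest.approx(0.0)

    def test_iu_conversion_round_trip(self):
        assert 1.0 * IU_PER_ML_TO_NM == pytest.approx(2222.22, rel=1e-3)

    def test_sampling_grid_matches_continuous_solution(self):
        p = _patient()
        params = personalized_parameters(p)
        dense = simulate_pk(p, params, times_h=np.linspace(0, 13, 1301))
        for t in (3.0, 6.0, 12.0):
            direct = simulate_pk(p, params, times_h=[t])
            assert heparin_in_sample(dense, t) == pytest.approx(
                direct.total_iu_ml[0] * IU_PER_ML_TO_NM, rel=1e-4)
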