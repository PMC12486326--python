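"""Linear de-mixing: spindle inversion and spindle/tendon-organ decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import propriodemix as pdx

from conftest import K_TRUE, KF_IB, KF_II, constant_rate

K_PUB = pdx.GainMatrix(**K_TRUE)
GAINS = pdx.ForceGains(kF_II=KF_II, kF_Ib=KF_IB)


class TestDemixSpindle:
    def test_unit_force_inversion_identity(self):
        # rates for [F; Y] = [1 N; 0 N/s] are the first K column
        r_ia = constant_rate(K_TRUE["k11"], afferent_class="Ia")
        r_ii = constant_rate(K_TRUE["k21"], afferent_class="II")
        d = pdx.demix_spindle(r_ia, r_ii, K_PUB)
        np.testing.assert_allclose(d.F_est, 1.0, atol=1e-12)
        np.testing.assert_allclose(d.Y_est, 0.0, atol=1e-12)

    def test_zero_rates_zero_estimates(self):
        d = pdx.demix_spindle(constant_rate(0), constant_rate(0), K_PUB)
        assert np.all(d.F_est == 0) and np.all(d.Y_est == 0)

    def test_against_cramer_rule_oracle(self):
        # independent 2x2 solve by Cramer's rule for R = [100; 50] sp/s
        det = K_TRUE["k11"] * K_TRUE["k22"] - K_TRUE["k12"] * K_TRUE["k21"]
        f_expected = (K_TRUE["k22"] * 100.0 - K_TRUE["k12"] * 50.0) / det
        y_expected = (K_TRUE["k11"] * 50.0 - K_TRUE["k21"] * 100.0) / det
        d = pdx.demix_spindle(constant_rate(100.0), constant_rate(50.0), K_PUB)
        np.testing.assert_allclose(d.F_est, f_expected, rtol=1e-12)
        np.testing.assert_allclose(d.Y_est, y_expected, rtol=1e-12)
        # frozen values from the oracle above
        assert d.F_est[0] == pytest.approx(0.26522, abs=1e-4)
        assert d.Y_est[0] == pytest.approx(0.30980, abs=1e-4)

    def test_conditioning_attached(self):
        d = pdx.demix_spindle(constant_rate(1), constant_rate(1), K_PUB)
        assert d.det_K == pytest.approx(K_PUB.det)
        assert d.condition_number == pytest.approx(K_PUB.condition_number)
        assert d.det_K == pytest.approx(-4486.86, abs=0.01)

    def test_singular_matrix_refused(self):
        K = pdx.GainMatrix(2.0, 1.0, 4.0, 2.0)
        with pytest.raises(ValueError, match="singular"):
            pdx.demix_spindle(constant_rate(1), constant_rate(1), K)

    def test_mismatched_grids_refused(self):
        a = constant_rate(1.0, duration=1.0)
        b = constant_rate(1.0, duration=0.5)
        with pytest.raises(ValueError, match="grid"):
            pdx.demix_spindle(a, b, K_PUB)

    def test_remix_round_trip_on_simulated_trial(self, forces15, rates15):
        d = pdx.demix_spindle(rates15["Ia"], rates15["II"], K_PUB)
        y_rect = np.clip(forces15.Y, 0, None)
        assert np.max(np.abs(d.F_est - forces15.F_C)) < 1e-9 * forces15.F_C.max()
        assert np.max(np.abs(d.Y_est - y_rect)) < 1e-9 * max(y_rect.max(), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_remix_identity_random_traces(self, seed):
        """K^-1 (K [F; Y]) = [F; Y] for any invertible non-negative K."""
        rng = np.random.default_rng(seed)
        K = pdx.GainMatrix(*rng.uniform(1.0, 500.0, 4))
        if abs(K.det) < 1e-6:
            return
        n = 200
        F = rng.uniform(0, 2.0, n)
        Y = rng.uniform(0, 50.0, n)
        R = K.matrix @ np.vstack([F, Y])
        t = np.arange(n) / 1000.0
        d = pdx.demix_spindle(pdx.RateTrace(t, R[0]), pdx.RateTrace(t, R[1]), K)
        scale = max(np.max(np.abs(F)), np.max(np.abs(Y)), 1.0)
        cond_slack = K.condition_number  # inversion error grows with cond(K)
        np.testing.assert_allclose(d.F_est, F, atol=1e-9 * scale * cond_slack)
        np.testing.assert_allclose(d.Y_est, Y, atol=1e-9 * scale * cond_slack)


class TestEstimateForces:
    def test_matched_constant_rates_cancel(self):
        dec = pdx.estimate_forces(constant_rate(KF_II), constant_rate(KF_IB),
                                  GAINS)
        np.testing.assert_allclose(dec.F_EI_est, 1.0)
        np.testing.assert_allclose(dec.F_C_est, 1.0)
        np.testing.assert_allclose(dec.F_SG_est, 0.0, atol=1e-12)

    def test_zero_rates_zero_forces(self):
        dec = pdx.estimate_forces(constant_rate(0), constant_rate(0), GAINS)
        assert np.all(dec.F_EI_est == 0)
        assert np.all(dec.F_C_est == 0)
        assert np.all(dec.F_SG_est == 0)

    def test_ib_offset_appears_as_self_generated_force(self, forces15):
        r_ii = pdx.RateTrace(forces15.t, KF_II * forces15.F_C)
        r_ib = pdx.RateTrace(forces15.t, KF_IB * forces15.F_C + 12.88)
        dec = pdx.estimate_forces(r_ii, r_ib, GAINS)
        np.testing.assert_allclose(dec.F_SG_est, 12.88 / KF_IB, atol=1e-12)
        assert dec.F_SG_est[0] == pytest.approx(0.1)

    def test_linearity_superposition(self, forces15):
        r_ii_a = pdx.RateTrace(forces15.t, KF_II * forces15.F_C)
        r_ii_b = pdx.RateTrace(forces15.t, 50.0 + 0.0 * forces15.t)
        r_ib = pdx.RateTrace(forces15.t, KF_IB * forces15.F_C)
        both = pdx.RateTrace(forces15.t, r_ii_a.rate + r_ii_b.rate)
        dec_a = pdx.estimate_forces(r_ii_a, r_ib, GAINS)
        dec_b = pdx.estimate_forces(r_ii_b, r_ib, GAINS)
        dec_ab = pdx.estimate_forces(both, r_ib, GAINS)
        np.testing.assert_allclose(dec_ab.F_EI_est,
                                   dec_a.F_EI_est + dec_b.F_EI_est, atol=1e-12)

    def test_invariant_sg_equals_c_minus_ei(self, rates15):
        dec = pdx.estimate_forces(rates15["II"], rates15["Ib"], GAINS)
        np.testing.assert_allclose(dec.F_SG_est, dec.F_C_est - dec.F_EI_est,
                                   atol=1e-15)


class TestEccentric:
    def test_zero_offset_identity(self, rates15):
        out = pdx.apply_eccentric(rates15["Ib"], pdx.EccentricScenario(0.0))
        np.testing.assert_array_equal(out.rate, rates15["Ib"].rate)

    def test_full_span_offset_shifts_sg_by_delta_over_gain(self, forces15):
        delta = 5.0
        r_ii = pdx.RateTrace(forces15.t, KF_II * forces15.F_C)
        r_ib = pdx.RateTrace(forces15.t, KF_IB * forces15.F_C)
        shifted = pdx.apply_eccentric(r_ib, pdx.EccentricScenario(delta))
        dec = pdx.estimate_forces(r_ii, shifted, GAINS)
        np.testing.assert_allclose(dec.F_SG_est, delta / KF_IB, rtol=1e-12)

    def test_half_span_offset_is_local(self):
        r_ib = constant_rate(100.0, duration=1.0)
        out = pdx.apply_eccentric(r_ib, pdx.EccentricScenario(10.0, (0.5, 1.0)))
        assert np.all(out.rate[out.t < 0.5] == 100.0)
        assert np.all(out.rate[out.t >= 0.5] == 110.0)

    def test_epoch_outside_span_rejected(self):
        r_ib = constant_rate(100.0, duration=1.0)
        with pytest.raises(ValueError, match="span"):
            pdx.apply_eccentric(r_ib, pdx.EccentricScenario(10.0, (2.0, 3.0)))

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            pdx.EccentricScenario(-1.0)


class TestInterneuron:
    def test_weighted_sum(self):
        r = pdx.interneuron_response(constant_rate(100.0), constant_rate(40.0),
                                     constant_rate(30.0),
                                     pdx.InterneuronWeights(1.0, 0.0, -1.0))
        np.testing.assert_allclose(r.rate, 70.0)

    def test_rectification(self):
        r = pdx.interneuron_response(constant_rate(10.0), constant_rate(0.0),
                                     constant_rate(50.0),
                                     pdx.InterneuronWeights(1.0, 0.0, -1.0))
        np.testing.assert_allclose(r.rate, 0.0)

    def test_force_gain_weights_give_negated_sg(self, rates15):
        w = pdx.InterneuronWeights(0.0, 1.0 / KF_II, -1.0 / KF_IB,
                                   rectify=False)
        r = pdx.interneuron_response(rates15["Ia"], rates15["II"],
                                     rates15["Ib"], w)
        dec = pdx.estimate_forces(rates15["II"], rates15["Ib"], GAINS)
        np.testing.assert_allclose(r.rate, -dec.F_SG_est, atol=1e-12)

    def test_startle_response_peaks_at_ramp_onset(self, trials):
        """Yank-driven, Ib-inhibited units fire at stretch onset, not hold."""
        params = pdx.MuscleParams()
        for tr in trials:
            if tr.rep_index != 0:
                continue
            f = pdx.simulate_forces(tr, params)
            rates = {cls: pdx.encode_afferent(f, p) for cls, p in
                     (("Ia", pdx.IA_DEFAULT), ("II", pdx.II_DEFAULT),
                      ("Ib", pdx.IB_DEFAULT))}
            w = pdx.InterneuronWeights(1.0, 0.0, -pdx.IA_DEFAULT.force_gain
                                       / pdx.IB_DEFAULT.force_gain)
            r = pdx.interneuron_response(rates["Ia"], rates["II"],
                                         rates["Ib"], w)
            ramp = tr.v > 0.5 * tr.velocity_label
            hold = (tr.L_MTU > 2.99) & (np.abs(tr.v) < 1e-9)
            onset_peak = r.rate[ramp].max()
            hold_level = r.rate[hold].max()
            assert onset_peak > hold_level
            assert r.t[np.argmax(r.rate)] < tr.t[hold][0]
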