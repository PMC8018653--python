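import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brainpk as bp


class TestCroneRenkin:
    def test_letrozole_values(self):
        """Fpf 0.036 mL/sec/g and Kin 0.422 mL/min/g give a BBB PS of
        0.469 mL/min/g, i.e. 0.84 mL/min for a 1.8 g brain."""
        ps_g, ps_total = bp.crone_renkin_ps(0.036, 0.422, 1.8, fpf_in_ml_sec=True)
        assert ps_g == pytest.approx(0.469, abs=1e-3)  # printed to 3 d.p.
        assert ps_total == pytest.approx(0.84, abs=0.01)

    def test_low_uptake_taylor_limit(self):
        ps_g, _ = bp.crone_renkin_ps(2.16, 1e-4)
        assert ps_g == pytest.approx(1e-4, rel=1e-3)

    def test_round_trip_inverts_exactly(self):
        fpf, kin = 2.16, 0.422
        ps_g, _ = bp.crone_renkin_ps(fpf, kin)
        kin_back = fpf * (1.0 - math.exp(-ps_g / fpf))
        assert kin_back == pytest.approx(kin, rel=1e-14)

    def test_flow_limited_uptake_rejected(self):
        with pytest.raises(ValueError):
            bp.crone_renkin_ps(0.4, 0.5)


class TestAccumulation:
    @pytest.mark.parametrize(
        "t_half,expected",
        [(34.0, 2.6), (9.2, 1.2)],
    )
    def test_predicted_ratio_at_reported_half_lives(self, t_half, expected):
        rac = bp.rac_predicted(math.log(2) / t_half, 24.0)
        assert round(rac, 1) == expected

    def test_no_accumulation_limit(self):
        assert bp.rac_predicted(20.0 / 24.0, 24.0) == pytest.approx(1.0, abs=1e-6)

    def test_predicted_always_above_one(self):
        for k in (0.01, 0.1, 1.0):
            assert bp.rac_predicted(k, 24.0) > 1.0

    @pytest.mark.parametrize(
        "ss,sd,expected",
        [(49300, 11700, 4.2), (4820, 2410, 2.0), (123.4, 123.4, 1.0)],
    )
    def test_observed_ratio(self, ss, sd, expected):
        assert round(bp.rac_observed(ss, sd), 1) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            bp.rac_observed(100.0, 0.0)


class TestCorrections:
    def test_recovery_correction(self):
        assert bp.recovery_correct(18.0, 0.072) == pytest.approx(250.0)
        assert bp.recovery_correct(36.0, 0.072) == pytest.approx(500.0)
        assert bp.recovery_correct(123.0, 1.0) == 123.0

    def test_recovery_must_be_positive_fraction(self):
        with pytest.raises(ValueError):
            bp.recovery_correct(10.0, 0.0)

    def test_unbound_plasma_values_match_reported(self):
        assert bp.unbound_plasma(1200.0, 0.38) == pytest.approx(456.0)
        assert bp.unbound_plasma(10700.0, 0.38) == pytest.approx(4066.0)
        assert bp.unbound_plasma(7.0, 1.0) == 7.0


class TestKpuu:
    def test_reported_single_dose_male_auc_basis(self):
        res = bp.kpuu(2410.0, 10700.0, 0.38, basis="auc_0_12")
        assert round(res.kpuu, 1) == 0.6

    def test_reported_steady_state_female_cmax_basis(self):
        res = bp.kpuu(2290.0, 4830.0, 0.38, basis="cmax")
        assert round(res.kpuu, 1) == 1.2

    def test_equal_unbound_exposures_give_unity(self):
        assert bp.kpuu(38.0, 100.0, 0.38).kpuu == pytest.approx(1.0)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_rescaling(self, scale):
        a = bp.kpuu(2410.0, 10700.0, 0.38).kpuu
        b = bp.kpuu(2410.0 * scale, 10700.0 * scale, 0.38).kpuu
        assert b == pytest.approx(a, rel=1e-12)

    def test_zero_plasma_rejected(self):
        with pytest.raises(ValueError):
            bp.kpuu(100.0, 0.0, 0.38)


class TestFuBrain:
    def test_identical_pairs(self):
        mean, sd, ratios = bp.estimate_fu_brain([50, 50, 50], [50, 50, 50])
        assert mean == 1.0 and sd == 0.0

    def test_single_pair(self):
        mean, sd, _ = bp.estimate_fu_brain([58.0], [100.0])
        assert mean == pytest.approx(0.58)
        assert sd == 0.0

    def test_noisy_ratio_recovery(self):
        """Paired samples around a true ECF/homogenate ratio of 0.58 with
        20 % noise (N = 4) recover a mean in [0.4, 0.8]."""
        rng = np.random.default_rng(7)
        hom = rng.lognormal(math.log(400), 0.2, 4)
        ecf = 0.58 * hom * rng.lognormal(0, 0.2, 4)
        mean, sd, ratios = bp.estimate_fu_brain(ecf, hom)
        assert 0.4 <= mean <= 0.8
        assert ratios.shape == (4,)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            bp.estimate_fu_brain([1.0, 2.0], [1.0])


class TestClassification:
    @pytest.mark.parametrize(
        "pred,obs,expected",
        [
            (1.45, 1.0, "reasonable"),
            (1.0, 1.0, "good"),
            (0.66, 1.0, "reasonable"),  # fold error 1.515 -> 1.5 at 1 d.p.
            (1.25, 1.0, "good"),
            (2.0, 1.0, "outside"),
            (1.0, 2.0, "outside"),
        ],
    )
    def test_fold_classification(self, pred, obs, expected):
        assert bp.classify_prediction(pred, obs) == expected

    @given(
        p=st.floats(min_value=0.1, max_value=10.0),
        o=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, p, o):
        assert bp.classify_prediction(p, o) == bp.classify_prediction(o, p)
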