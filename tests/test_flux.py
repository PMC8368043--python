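"""O2/Ar supersaturation, solubility, gas transfer, MLD and PAR operations."""

import numpy as np
import pytest

from wapflux.flux import (
    CtdProfile,
    biological_o2_supersaturation,
    gas_transfer_velocity,
    mld_from_profile,
    ncp_areal,
    ncp_table,
    ncp_volumetric,
    o2_equilibrium_concentration,
    par_mld,
    par_subsurface,
    schmidt_number_o2,
    weighted_gas_transfer,
)


class TestSupersaturation:
    def test_equilibrium_gives_zero(self):
        assert biological_o2_supersaturation(1.03, 1.03) == 0.0

    def test_five_percent(self):
        assert biological_o2_supersaturation(1.05, 1.0) == pytest.approx(5.0)

    def test_heterotrophy_sign_preserved(self):
        assert biological_o2_supersaturation(0.98, 1.0) == pytest.approx(-2.0)

    def test_rejects_non_positive_ratio(self):
        with pytest.raises(ValueError):
            biological_o2_supersaturation(0.0, 1.0)
        with pytest.raises(ValueError):
            biological_o2_supersaturation(1.0, -1.0)


class TestSolubility:
    def test_salting_out(self):
        assert o2_equilibrium_concentration(0.0, 34.0) < o2_equilibrium_concentration(
            0.0, 0.0
        )

    def test_thermal_monotonicity(self):
        assert o2_equilibrium_concentration(10.0, 34.0) < o2_equilibrium_concentration(
            0.0, 34.0
        )

    def test_matches_independent_transcription(self):
        """Agreement with a direct re-typing of the combined-fit polynomial."""
        t, s = 0.0, 34.5
        ts = np.log((298.15 - t) / (273.15 + t))
        ln_c = (
            2.00907
            + 3.22014 * ts
            + 4.05010 * ts**2
            + 4.94457 * ts**3
            - 2.56847e-1 * ts**4
            + 3.88767 * ts**5
            + s * (-6.24523e-3 - 7.37614e-3 * ts - 1.03410e-2 * ts**2 - 8.17083e-3 * ts**3)
            - 4.88682e-7 * s**2
        )
        expected = np.exp(ln_c) * 1000.0 / 22.3916  # mL/L -> mmol/m3
        got = o2_equilibrium_concentration(t, s)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_polar_seawater_magnitude(self):
        # near-freezing Antarctic surface water holds ~350-370 mmol O2 m-3
        assert 330 < o2_equilibrium_concentration(-1.0, 34.0) < 400

    def test_range_validation(self):
        with pytest.raises(ValueError):
            o2_equilibrium_concentration(45.0, 34.0)
        with pytest.raises(ValueError):
            o2_equilibrium_concentration(0.0, 50.0)


class TestGasTransfer:
    def test_zero_wind_zero_k(self):
        assert gas_transfer_velocity(0.0, 0.0) == 0.0

    def test_quadratic_in_wind(self):
        k1 = gas_transfer_velocity(5.0, 2.0)
        k2 = gas_transfer_velocity(10.0, 2.0)
        assert k2 == pytest.approx(4.0 * k1)

    def test_hand_computed_value(self):
        # k = 0.251 * u^2 * sqrt(660/Sc(0degC)) cm/h, converted to m/d
        sc = 1920.4  # Schmidt polynomial at 0 degC
        expected = 0.251 * 100.0 * np.sqrt(660.0 / sc) * 0.24
        assert gas_transfer_velocity(10.0, 0.0, 34.0) == pytest.approx(expected)

    def test_schmidt_number_at_zero(self):
        assert schmidt_number_o2(0.0) == pytest.approx(1920.4)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            gas_transfer_velocity(-1.0, 0.0)


class TestWeightedGasTransfer:
    def test_constant_history_equals_instantaneous(self):
        hist = [(float(age), 7.0) for age in range(30)]
        k = weighted_gas_transfer(hist, mld=40.0, sst=1.0)
        assert k == pytest.approx(gas_transfer_velocity(7.0, 1.0))

    def test_tiny_mld_weights_most_recent_day(self):
        hist = [(0.0, 3.0), (1.0, 15.0), (2.0, 15.0)]
        k = weighted_gas_transfer(hist, mld=1e-9, sst=0.0)
        assert k == pytest.approx(gas_transfer_velocity(3.0, 0.0))

    def test_three_day_hand_recursion(self):
        winds = [4.0, 9.0, 13.0]  # ages 0, 1, 2
        mld, sst = 50.0, 0.0
        k = [gas_transfer_velocity(u, sst, 34.0) for u in winds]
        f = [min(ki / mld, 1.0) for ki in k]
        w = [1.0, (1 - f[0]), (1 - f[0]) * (1 - f[1])]
        expected = sum(wi * ki for wi, ki in zip(w, k)) / sum(w)
        got = weighted_gas_transfer(
            [(0.0, 4.0), (1.0, 9.0), (2.0, 13.0)], mld, sst, 34.0
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_instantaneous_extremes(self):
        rng = np.random.default_rng(4)
        winds = rng.uniform(0, 15, 30)
        hist = np.column_stack([np.arange(30.0), winds])
        k = weighted_gas_transfer(hist, mld=30.0, sst=0.0)
        inst = gas_transfer_velocity(winds, 0.0)
        assert inst.min() <= k <= inst.max()

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            weighted_gas_transfer([], mld=30.0, sst=0.0)


class TestNcp:
    def test_hand_value(self):
        assert ncp_areal(2.0, 350.0, 5.0) == pytest.approx(35.0)

    def test_zero_delta_zero_ncp(self):
        assert ncp_areal(3.0, 350.0, 0.0) == 0.0

    def test_volumetric(self):
        assert ncp_volumetric(35.0, 50.0) == pytest.approx(0.7)

    def test_linearity(self):
        base = ncp_areal(2.0, 350.0, 5.0)
        assert ncp_areal(4.0, 350.0, 5.0) == pytest.approx(2 * base)
        assert ncp_areal(2.0, 700.0, 5.0) == pytest.approx(2 * base)
        assert ncp_areal(2.0, 350.0, 10.0) == pytest.approx(2 * base)

    def test_non_positive_mld_rejected(self):
        with pytest.raises(ValueError):
            ncp_volumetric(35.0, 0.0)


class TestMld:
    def test_step_profile(self):
        prof = CtdProfile([0, 10, 40, 41, 100], [27.0, 27.0, 27.0, 27.1, 27.1])
        est = mld_from_profile(prof)
        assert est.threshold_crossed
        assert est.mld == pytest.approx(40.3, abs=0.01)  # interpolated in the jump

    def test_linear_gradient(self):
        # sigma increases 0.01 per m below 10 m -> threshold 0.03 crossed at 13 m
        z = np.arange(0.0, 101.0)
        sig = 27.0 + np.where(z > 10, (z - 10) * 0.01, 0.0)
        est = mld_from_profile(CtdProfile(z, sig))
        assert est.threshold_crossed
        assert est.mld == pytest.approx(13.0, abs=1e-9)

    def test_mixed_profile_returns_deepest_with_flag(self):
        prof = CtdProfile([0, 10, 50, 100], [27.0] * 4)
        est = mld_from_profile(prof)
        assert not est.threshold_crossed
        assert est.mld == 100.0

    def test_resolution_refinement_invariance(self):
        z1 = np.array([0.0, 10.0, 30.0, 60.0, 100.0])
        sig1 = 27.0 + np.where(z1 > 10, (z1 - 10) * 0.002, 0.0)
        z2 = np.arange(0.0, 101.0, 0.5)
        sig2 = 27.0 + np.where(z2 > 10, (z2 - 10) * 0.002, 0.0)
        m1 = mld_from_profile(CtdProfile(z1, sig1)).mld
        m2 = mld_from_profile(CtdProfile(z2, sig2)).mld
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_profile_must_span_reference(self):
        with pytest.raises(ValueError):
            mld_from_profile(CtdProfile([20, 50], [27.0, 27.1]))

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            CtdProfile([10, 5], [27.0, 27.1])
        with pytest.raises(ValueError):
            CtdProfile([10], [27.0])


class TestPar:
    def test_subsurface_constant(self):
        assert par_subsurface(100.0) == pytest.approx(92.0)

    def test_shallow_layer_limit(self):
        assert par_mld(100.0, 0.1, 1e-12) == pytest.approx(100.0, rel=1e-6)

    def test_hand_value(self):
        expected = 100.0 * (1 - np.exp(-5.0)) / 5.0
        assert par_mld(100.0, 0.1, 50.0) == pytest.approx(expected)
        assert expected == pytest.approx(19.87, abs=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            par_subsurface(-1.0)
        with pytest.raises(ValueError):
            par_mld(100.0, -0.1, 50.0)


def test_ncp_table_round_trip(dataset):
    """Forward flux pipeline on the synthetic track recovers the planted NCP."""
    table = ncp_table(dataset.underway)
    truth = dataset.truth.true_ncp_areal.to_numpy()
    rel = np.abs(table["ncp_areal"].to_numpy() - truth) / np.abs(truth)
    assert rel.max() < 1e-9
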