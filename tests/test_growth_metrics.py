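"""Closed-form growth-performance algebra and the empirical S_L regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phitrend import growth_metrics as gm

SL_CONST = -(0.761 * 3.03)  # = -2.30583


class TestLengthConversion:
    @pytest.mark.parametrize(
        "length,a,b,measure,expected",
        [
            (40.0, 1.0, 1.1, "FL", 45.0),
            (30.0, 0.0, 1.0, "TL", 30.0),
            (25.0, 0.5, 1.2, "SL", 30.5),
        ],
    )
    def test_linear_evaluation(self, length, a, b, measure, expected):
        conv = gm.LengthConversion(a=a, b_len=b, source_measure=measure)
        assert gm.convert_to_total_length(length, conv) == pytest.approx(expected)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(gm.ValidationError):
            gm.convert_to_total_length(0.0, gm.IDENTITY_CONVERSION)
        with pytest.raises(gm.ValidationError):
            gm.convert_to_total_length(-5.0, gm.IDENTITY_CONVERSION)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(gm.ValidationError):
            gm.LengthConversion(a=0.0, b_len=-1.0, source_measure="FL")

    @given(
        lengths=st.lists(st.floats(1.0, 200.0), min_size=2, max_size=10),
        a=st.floats(0.0, 5.0),
        b=st.floats(0.5, 1.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_commutes_with_averaging(self, lengths, a, b):
        conv = gm.LengthConversion(a=a, b_len=b, source_measure="FL")
        converted_mean = gm.convert_to_total_length(float(np.mean(lengths)), conv)
        mean_converted = np.mean([gm.convert_to_total_length(x, conv) for x in lengths])
        assert converted_mean == pytest.approx(mean_converted, rel=1e-12)


class TestConstantSL:
    def test_default_constants(self):
        sl = gm.constant_SL()
        assert sl.value == pytest.approx(SL_CONST)
        assert sl.origin == "constant"

    @pytest.mark.parametrize(
        "m,b,expected", [(1.0, 1.0, -1.0), (0.761, 3.0, -2.283), (0.761, 3.03, SL_CONST)]
    )
    def test_product(self, m, b, expected):
        assert gm.constant_SL(m, b).value == pytest.approx(expected, abs=1e-6)

    def test_rejects_nonpositive_exponents(self):
        with pytest.raises(gm.ValidationError):
            gm.constant_SL(m=-0.1)
        with pytest.raises(gm.ValidationError):
            gm.constant_SL(b=0.0)


class TestPhi:
    def test_hand_evaluation(self):
        p = gm.VBGFParams(L_inf=50.0, K=0.5)
        phi = gm.compute_phi(p, gm.constant_SL()).phi
        # log10(0.5) + 2.30583 * log10(50)
        assert phi == pytest.approx(-0.30103 + 2.30583 * 1.69897, abs=1e-4)
        assert phi == pytest.approx(3.617, abs=1e-3)

    @pytest.mark.parametrize(
        "K,L,slv", [(1.0, 1.0, -2.0), (0.1, 10.0, -1.0)]
    )
    def test_zero_cases(self, K, L, slv):
        phi = gm.compute_phi(gm.VBGFParams(L_inf=L, K=K), gm.SLValue(value=slv)).phi
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonpositive_params(self):
        with pytest.raises(gm.ValidationError):
            gm.VBGFParams(L_inf=-1.0, K=0.5)
        with pytest.raises(gm.ValidationError):
            gm.VBGFParams(L_inf=50.0, K=0.0)

    @given(
        k1=st.floats(0.01, 3.0), k2=st.floats(0.01, 3.0),
        l1=st.floats(1.0, 300.0), l2=st.floats(1.0, 300.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_K_and_Linf(self, k1, k2, l1, l2):
        """With S_L < 0, phi increases in both parameters."""
        sl = gm.constant_SL()
        lo = gm.compute_phi(gm.VBGFParams(L_inf=min(l1, l2), K=min(k1, k2)), sl).phi
        hi = gm.compute_phi(gm.VBGFParams(L_inf=max(l1, l2), K=max(k1, k2)), sl).phi
        assert hi >= lo


class TestDeltaPhiAndRatios:
    def test_K_halving(self):
        sl = gm.constant_SL()
        d = gm.delta_phi(
            gm.VBGFParams(L_inf=50, K=0.25), gm.VBGFParams(L_inf=50, K=0.5), sl
        )
        assert d.value == pytest.approx(math.log10(0.5), abs=1e-12)

    def test_no_change(self):
        sl = gm.constant_SL()
        p = gm.VBGFParams(L_inf=80, K=0.3)
        assert gm.delta_phi(p, p, sl).value == pytest.approx(0.0, abs=1e-12)
        assert gm.K_ratio_from_delta_phi(gm.DeltaPhi(0.0)) == pytest.approx(1.0)
        assert gm.Linf_ratio_from_delta_phi(gm.DeltaPhi(0.0), sl) == pytest.approx(1.0)

    def test_both_doubling(self):
        sl = gm.constant_SL()
        d = gm.delta_phi(
            gm.VBGFParams(L_inf=100, K=0.6), gm.VBGFParams(L_inf=50, K=0.3), sl
        )
        assert d.value == pytest.approx(math.log10(2) + 2.30583 * math.log10(2), abs=1e-4)

    def test_printed_global_pair(self):
        """A 44.9% K-equivalent decline corresponds to a 22.8% L_inf decline."""
        sl = gm.constant_SL()
        d = gm.DeltaPhi(value=math.log10(1 - 0.449))
        linf_decline = 100 * (1 - gm.Linf_ratio_from_delta_phi(d, sl))
        assert round(linf_decline, 1) == 22.8

    def test_ratio_examples(self):
        assert gm.K_ratio_from_delta_phi(gm.DeltaPhi(-0.2588)) == pytest.approx(0.551, abs=5e-4)
        assert gm.K_ratio_from_delta_phi(gm.DeltaPhi(0.3)) == pytest.approx(1.9953, abs=1e-4)

    def test_zero_SL_rejected(self):
        with pytest.raises(gm.ValidationError):
            gm.Linf_ratio_from_delta_phi(gm.DeltaPhi(0.1), gm.SLValue(value=0.0))

    @given(r=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, r):
        """K_ratio(log10 r) recovers r to machine precision."""
        assert gm.K_ratio_from_delta_phi(gm.DeltaPhi(math.log10(r))) == pytest.approx(
            r, rel=1e-12
        )

    @given(rk=st.floats(0.1, 10.0), rl=st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_composition_recovers_input_ratios(self, rk, rl):
        """delta_phi followed by the ratio identities is exact for pure changes."""
        sl = gm.constant_SL()
        base = gm.VBGFParams(L_inf=50.0, K=0.4)
        d_k = gm.delta_phi(gm.VBGFParams(L_inf=50.0, K=0.4 * rk), base, sl)
        assert gm.K_ratio_from_delta_phi(d_k) == pytest.approx(rk, rel=1e-9)
        d_l = gm.delta_phi(gm.VBGFParams(L_inf=50.0 * rl, K=0.4), base, sl)
        assert gm.Linf_ratio_from_delta_phi(d_l, sl) == pytest.approx(rl, rel=1e-9)

    @given(d=st.floats(-1.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_K_and_Linf_ratio_consistency(self, d):
        """(K ratio)^(1/(m b)) equals the L_inf ratio for the same phi change."""
        sl = gm.constant_SL()
        dp = gm.DeltaPhi(value=d)
        k_ratio = gm.K_ratio_from_delta_phi(dp)
        l_ratio = gm.Linf_ratio_from_delta_phi(dp, sl)
        assert k_ratio ** (1.0 / (0.761 * 3.03)) == pytest.approx(l_ratio, rel=1e-9)


class TestTemperatureSlope:
    def test_zero_slope(self):
        assert gm.temperature_slope_to_percent(0.0, 3.0) == pytest.approx((0.0, 0.0))

    def test_low_temperature_end(self):
        pct_linf, pct_k = gm.temperature_slope_to_percent(0.023, 3.0)
        assert pct_linf == pytest.approx(7.2, abs=0.1)
        assert pct_k == pytest.approx(17.4, abs=0.2)

    def test_warm_end_of_range(self):
        phi_warm = 3.0 * math.exp(0.023 * 28)
        pct_linf, pct_k = gm.temperature_slope_to_percent(0.023, phi_warm)
        assert pct_linf == pytest.approx(14.0, abs=1.0)
        assert pct_k == pytest.approx(36.0, abs=2.0)

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(gm.ValidationError):
            gm.temperature_slope_to_percent(0.02, 0.0)


class TestEmpiricalSL:
    @staticmethod
    def _table(species, method, linf, k):
        return pd.DataFrame(
            {
                "species": species,
                "aging_method": method,
                "L_inf_cm": linf,
                "K_per_year": k,
            }
        )

    def test_perfect_fit_recovers_slope(self):
        linf = np.array([10.0, 20.0, 40.0, 80.0])
        k = 10 ** (2.0 - 2.0 * np.log10(linf))
        df = self._table(["a"] * 4, ["otolith"] * 4, linf, k)
        sl = gm.empirical_SL(df)["a"]
        assert sl.origin == "empirical"
        assert sl.value == pytest.approx(-2.0, abs=1e-10)

    def test_three_observations_fall_back_to_constant(self):
        df = self._table(["a"] * 3, ["otolith"] * 3, [10, 20, 40], [0.9, 0.5, 0.3])
        sl = gm.empirical_SL(df)["a"]
        assert sl.origin == "constant"
        assert sl.value == pytest.approx(SL_CONST)

    def test_noisy_points_match_ols_oracle(self):
        rng = np.random.default_rng(3)
        linf = np.array([15.0, 30.0, 55.0, 90.0, 140.0])
        k = 10 ** (1.5 - 1.8 * np.log10(linf) + rng.normal(0, 0.05, 5))
        df = self._table(["a"] * 5, ["otolith"] * 5, linf, k)
        x, y = np.log10(linf), np.log10(k)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert gm.empirical_SL(df)["a"].value == pytest.approx(oracle, rel=1e-10)

    def test_zero_variance_group_falls_back(self, caplog):
        df = self._table(["a"] * 4, ["otolith"] * 4, [50.0] * 4, [0.2, 0.3, 0.4, 0.5])
        with caplog.at_level("WARNING"):
            sl = gm.empirical_SL(df)["a"]
        assert sl.origin == "constant"
        assert "zero variance" in caplog.text

    def test_median_across_methods(self):
        frames = []
        for method, slope in [("otolith", -1.0), ("length_frequency", -2.0), ("unknown", -3.0)]:
            linf = np.array([10.0, 20.0, 40.0, 80.0])
            k = 10 ** (1.0 + slope * np.log10(linf))
            frames.append(self._table(["a"] * 4, [method] * 4, linf, k))
        sl = gm.empirical_SL(pd.concat(frames, ignore_index=True))["a"]
        assert sl.value == pytest.approx(-2.0, abs=1e-9)


class TestAttachGrowthPerformance:
    def test_constant_mode_adds_phi(self, clean_obs_table):
        out = gm.attach_growth_performance(clean_obs_table)
        assert len(out) == len(clean_obs_table)
        sl = gm.constant_SL()
        expected = np.log10(out["K_per_year"]) - sl.value * np.log10(out["L_inf_tl_cm"])
        np.testing.assert_allclose(out["phi"], expected)
        assert (out["S_L_origin"] == "constant").all()

    def test_unconvertible_rows_dropped(self, clean_obs_table):
        t = clean_obs_table.copy()
        t.loc[0, "length_measure"] = "FL"  # no conversion table supplied
        out = gm.attach_growth_performance(t)
        assert len(out) == len(t) - 1
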