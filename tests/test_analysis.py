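import numpy as np
import pytest

from ivlsim.analysis import (Correlogram, FILine, currentscape,
                             holding_current, normalized_xcorr,
                             polarity_adjust, total_charge)
from ivlsim.simulator import TraceSet


class TestFILine:
    def test_two_point_line(self):
        line = FILine.from_points((60.0, 8.0), (120.0, 14.0))
        assert line.m == pytest.approx(0.1)
        assert line.b == pytest.approx(2.0)

    def test_equal_rates_rejected(self):
        with pytest.raises(ValueError):
            FILine.from_points((60.0, 10.0), (120.0, 10.0))

    def test_holding_current_inverts_the_line(self):
        line = FILine(0.1, 2.0, ((60, 8), (120, 14)))
        assert holding_current(12.0, line) == pytest.approx(100.0)
        assert holding_current(line.b, line) == pytest.approx(0.0)


def synthetic_traces(seed=0, n_t=400, names=("NaT", "Kdrf", "leak", "H")):
    rng = np.random.default_rng(seed)
    time = np.arange(n_t) * 0.025
    currents = rng.normal(0.0, 5.0, size=(1, len(names), n_t))
    voltage = rng.normal(-60.0, 3.0, size=(1, n_t))
    return TraceSet(time, ["S"], list(names), voltage, currents, None, 0.025)


class TestCurrentscape:
    def test_single_outward_channel_owns_its_pool(self):
        time = np.arange(10) * 0.1
        cur = np.zeros((1, 2, 10))
        cur[0, 0] = 3.0  # outward
        tr = TraceSet(time, ["S"], ["Kdrf", "NaT"],
                      np.full((1, 10), -60.0), cur, None, 0.1)
        dec = currentscape(tr, "S")
        np.testing.assert_allclose(dec.outward_fraction[0], 1.0)
        assert np.all(np.isnan(dec.inward_fraction[0]))  # inward pool empty

    def test_two_equal_outward_channels_split_evenly(self):
        time = np.arange(5) * 0.1
        cur = np.full((1, 2, 5), 2.0)
        tr = TraceSet(time, ["S"], ["Kdrf", "M"], np.zeros((1, 5)), cur,
                      None, 0.1)
        dec = currentscape(tr, "S")
        np.testing.assert_allclose(dec.outward_fraction, 0.5)

    def test_reconstruction_identity_on_random_traces(self):
        tr = synthetic_traces(seed=3)
        dec = currentscape(tr, "S")
        for j, name in enumerate(dec.names):
            np.testing.assert_allclose(dec.reconstruct(name),
                                       tr.currents[0, j], rtol=0, atol=1e-9)
        # fractions sum to one wherever the pool is non-empty
        for frac in (dec.inward_fraction, dec.outward_fraction):
            sums = np.nansum(frac, axis=0)
            defined = ~np.all(np.isnan(frac), axis=0)
            np.testing.assert_allclose(sums[defined], 1.0, atol=1e-12)

    def test_fraction_bounds(self):
        tr = synthetic_traces(seed=11)
        dec = currentscape(tr, "S")
        for frac in (dec.inward_fraction, dec.outward_fraction):
            vals = frac[~np.isnan(frac)]
            assert np.all(vals >= 0.0) and np.all(vals <= 1.0 + 1e-12)


class TestTotalCharge:
    def test_constant_current(self):
        t = np.linspace(0, 100, 401)
        assert total_charge(np.full_like(t, 3.0), t) == pytest.approx(300.0)

    def test_full_sine_period_integrates_to_zero(self):
        t = np.linspace(0, 100, 100001)
        c = 7.0 * np.sin(2 * np.pi * t / 100.0)
        assert abs(total_charge(c, t)) < 1e-9 * 7.0 * 100.0

    def test_linear_ramp_exact(self):
        t = np.linspace(0, 50, 11)  # coarse grid: trapezoid exact for linear
        c = 4.0 * t / 50.0
        assert total_charge(c, t) == pytest.approx(100.0, rel=1e-12)


class TestPolarityAdjust:
    def test_inward_channels_negated(self):
        x = np.array([1.0, -2.0, 3.0])
        adj = polarity_adjust({"NaT": x, "CaT": x, "CaL": x, "H": x,
                               "syn_exc": x})
        for name in ("NaT", "CaT", "CaL", "H", "syn_exc"):
            np.testing.assert_array_equal(adj[name], -x)

    def test_leak_and_outward_channels_untouched(self):
        x = np.array([1.0, -2.0, 3.0])
        adj = polarity_adjust({"leak": x, "Kdrf": x, "KA": x, "syn_inh": x})
        for name in ("leak", "Kdrf", "KA", "syn_inh"):
            np.testing.assert_array_equal(adj[name], x)

    def test_double_application_is_identity_off_leak(self):
        x = np.linspace(-5, 5, 11)
        twice = polarity_adjust(polarity_adjust({"NaT": x, "Kdrf": x}))
        np.testing.assert_array_equal(twice["NaT"], x)
        np.testing.assert_array_equal(twice["Kdrf"], x)


class TestNormalizedXcorr:
    def test_autocorrelation_at_zero_lag_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        cg = normalized_xcorr(x, x, dt=0.1, max_lag=5.0)
        k0 = np.argmin(np.abs(cg.lags))
        assert cg.lags[k0] == 0.0
        assert cg.values[k0] == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(cg.values)) <= 1.0 + 1e-9

    def test_shift_theorem_fixes_lag_sign(self):
        dt = 0.1
        t = np.arange(0, 400, dt)
        delay = 2.5  # ms
        a1 = np.sin(2 * np.pi * t / 40.0)
        a2 = np.sin(2 * np.pi * (t - delay) / 40.0)  # a2 delayed copy of a1
        cg = normalized_xcorr(a1, a2, dt=dt, max_lag=10.0)
        assert cg.peak_lag == pytest.approx(-delay, abs=dt)

    def test_mirror_symmetry_between_argument_orders(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        ab = normalized_xcorr(a, b, dt=0.1, max_lag=5.0)
        ba = normalized_xcorr(b, a, dt=0.1, max_lag=5.0)
        np.testing.assert_allclose(ab.values, ba.values[::-1], atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            normalized_xcorr(np.ones(100), np.arange(100.0), dt=0.1)

    def test_polarity_invariance_of_correlograms(self):
        """Negating an inward channel first, then skipping adjustment,
        matches adjusting the original trace."""
        rng = np.random.default_rng(5)
        v = rng.normal(-60, 3, size=3000)
        i_na = rng.normal(-10, 2, size=3000)
        adjusted = polarity_adjust({"NaT": i_na})["NaT"]
        direct = normalized_xcorr(adjusted, v, dt=0.1, max_lag=5.0)
        pre_negated = normalized_xcorr(-i_na, v, dt=0.1, max_lag=5.0)
        np.testing.assert_allclose(direct.values, pre_negated.values,
                                   atol=1e-15)
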