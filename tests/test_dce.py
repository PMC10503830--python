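"""DCE concentration conversion, AIF extraction, iAUC and extended Tofts."""

import numpy as np
import pytest

from qmripd.dce import (
    Aif,
    ConcentrationSeries,
    DceSeries,
    compute_iauc,
    detect_bolus_arrival,
    extract_aif,
    fit_extended_tofts,
    signal_to_concentration,
    tofts_forward,
)
from qmripd.phantom import (
    AcquisitionSpec,
    NoiseSpec,
    generate_phantom,
    population_aif,
    simulate_dce,
)
from qmripd.t1 import spgr_signal


def dense_convolution_oracle(aif, times, ktrans, ve, vp, n_dense=200001):
    """Brute-force extended-Tofts evaluation on an oversampled grid."""
    tf = np.linspace(times[0], times[-1], n_dense)
    cpf = np.interp(tf, times, aif.cp)
    kep = ktrans / ve / 60.0
    out = []
    for t in times:
        m = tf <= t
        integ = (np.trapezoid(cpf[m] * np.exp(-kep * (t - tf[m])), tf[m])
                 if m.sum() > 1 else 0.0)
        out.append(vp * np.interp(t, times, aif.cp) + ktrans / 60.0 * integ)
    return np.array(out)


class TestSignalToConcentration:
    def make_series(self, c_true, t1_pre=0.5, r1=4.5, m0=1000.0, fa=30.0, tr=3e-3):
        times = np.arange(len(c_true)) * 8.0
        t1_t = 1.0 / (1.0 / t1_pre + r1 * np.asarray(c_true))
        sig = spgr_signal(m0, t1_t, fa, tr).reshape(1, 1, 1, -1)
        return DceSeries(sig, times, fa, tr, injection_frame=8)

    def test_flat_series_gives_zero_concentration(self):
        series = self.make_series(np.zeros(48))
        conc = signal_to_concentration(series, np.full((1, 1, 1), 0.5))
        np.testing.assert_allclose(conc.conc, 0.0, atol=1e-12)

    def test_closed_form_round_trip(self):
        c_true = np.concatenate([np.zeros(8), np.full(40, 1.0)])
        series = self.make_series(c_true)
        conc = signal_to_concentration(series, np.full((1, 1, 1), 0.5), r1=4.5)
        np.testing.assert_allclose(conc.conc[0, 0, 0], c_true, atol=1e-6)

    def test_doubling_relaxivity_halves_concentration(self):
        c_true = np.concatenate([np.zeros(8), np.full(40, 0.8)])
        series = self.make_series(c_true, r1=4.5)
        c1 = signal_to_concentration(series, np.full((1, 1, 1), 0.5), r1=4.5)
        c2 = signal_to_concentration(series, np.full((1, 1, 1), 0.5), r1=9.0)
        np.testing.assert_allclose(c2.conc, c1.conc / 2.0, atol=1e-12)

    def test_unattainable_signal_flagged(self):
        c_true = np.concatenate([np.zeros(8), np.full(40, 1.0)])
        series = self.make_series(c_true)
        series.frames[..., 20] = 1e6  # beyond the SPGR range for any T1
        conc = signal_to_concentration(series, np.full((1, 1, 1), 0.5))
        assert not conc.valid[0, 0, 0, 20]
        assert conc.valid[0, 0, 0, 10]


class TestExtractAifAndArrival:
    def test_single_voxel_identity(self):
        conc = np.zeros((2, 2, 1, 48))
        curve = np.concatenate([np.zeros(8), 5 * np.exp(-0.05 * np.arange(40))])
        conc[0, 0, 0] = curve
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = True
        cs = ConcentrationSeries(conc, np.arange(48) * 8.0)
        aif = extract_aif(cs, mask)
        np.testing.assert_array_equal(aif.cp, curve)

    def test_two_voxel_mean(self):
        conc = np.zeros((2, 1, 1, 48))
        f = np.concatenate([np.zeros(8), 4 * np.exp(-0.05 * np.arange(40))])
        g = np.concatenate([np.zeros(8), 6 * np.exp(-0.03 * np.arange(40))])
        conc[0, 0, 0], conc[1, 0, 0] = f, g
        cs = ConcentrationSeries(conc, np.arange(48) * 8.0)
        aif = extract_aif(cs, np.ones((2, 1, 1), bool))
        np.testing.assert_allclose(aif.cp, (f + g) / 2.0)

    def test_empty_mask_rejected(self):
        cs = ConcentrationSeries(np.zeros((2, 2, 1, 48)), np.arange(48) * 8.0)
        with pytest.raises(ValueError, match="empty"):
            extract_aif(cs, np.zeros((2, 2, 1), bool))

    def test_phantom_artery_round_trip(self, small_spec, times48):
        truth = generate_phantom(small_spec)
        acq = small_spec.acquisition
        aif_true = population_aif(times48, acq.injection_frame * 8.0)
        artery = truth.region_mask("artery")
        frames = simulate_dce(truth.maps["baseline"], aif_true, acq,
                              NoiseSpec(sigma_rel=0.0), seed=0, artery_mask=artery)
        series = DceSeries(frames, times48, acq.dce_flip_angle, acq.dce_tr,
                           acq.injection_frame)
        conc = signal_to_concentration(series, truth.maps["baseline"]["t1"])
        aif = extract_aif(conc, artery)
        np.testing.assert_allclose(aif.cp, aif_true.cp, atol=1e-9)

    def test_step_function_arrival(self):
        cp = np.concatenate([np.zeros(10), np.full(20, 5.0)])
        aif = Aif(np.arange(30) * 8.0, cp)
        assert detect_bolus_arrival(aif) == 10

    def test_flat_curve_rejected(self):
        aif = Aif(np.arange(30) * 8.0, np.zeros(30))
        with pytest.raises(ValueError, match="flat|exceeds"):
            detect_bolus_arrival(aif)

    def test_noisy_phantom_arrival_within_one_frame(self, times48):
        true_aif = population_aif(times48, 8 * 8.0)
        rng = np.random.default_rng(11)
        hits = []
        for _ in range(100):
            noisy = Aif(times48, true_aif.cp + rng.normal(0, 0.02, 48))
            hits.append(detect_bolus_arrival(noisy))
        assert set(hits) <= {8, 9}


class TestIauc:
    def test_constant_curve(self):
        conc = ConcentrationSeries(np.ones((1, 1, 1, 20)), np.arange(20) * 10.0)
        m = compute_iauc(conc, arrival=0, window=90.0)
        np.testing.assert_allclose(m.values, 90.0)

    def test_linear_ramp_triangle_area(self):
        times = np.arange(10) * 10.0
        curve = times / 90.0
        conc = ConcentrationSeries(curve.reshape(1, 1, 1, -1), times)
        m = compute_iauc(conc, arrival=0, window=90.0)
        np.testing.assert_allclose(m.values, 45.0)

    def test_irregular_grid_matches_riemann_oracle(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 200, 40))
        curve = np.exp(-((times - 60) / 40.0) ** 2)
        conc = ConcentrationSeries(curve.reshape(1, 1, 1, -1), times)
        arrival = 5
        m = compute_iauc(conc, arrival=arrival, window=90.0)
        tf = np.linspace(times[arrival], times[arrival] + 90.0, 200001)
        oracle = np.trapezoid(np.interp(tf, times, curve), tf)
        assert abs(m.values.flat[0] - oracle) / oracle < 0.005

    def test_window_beyond_series_truncates_with_warning(self, caplog):
        conc = ConcentrationSeries(np.ones((1, 1, 1, 5)), np.arange(5) * 10.0)
        with caplog.at_level("WARNING"):
            m = compute_iauc(conc, arrival=0, window=90.0)
        np.testing.assert_allclose(m.values, 40.0)  # integrates to the last frame
        assert "window" in caplog.text

    def test_arrival_outside_series_rejected(self):
        conc = ConcentrationSeries(np.ones((1, 1, 1, 5)), np.arange(5) * 10.0)
        with pytest.raises(ValueError):
            compute_iauc(conc, arrival=7)

    def test_doubling_frame_interval_doubles_constant_iauc(self):
        c = np.ones((1, 1, 1, 20))
        a = compute_iauc(ConcentrationSeries(c, np.arange(20) * 5.0), 0, window=60.0)
        b = compute_iauc(ConcentrationSeries(c, np.arange(20) * 10.0), 0, window=120.0)
        np.testing.assert_allclose(b.values, 2 * a.values)


class TestToftsForward:
    def test_no_exchange_is_pure_vascular(self, aif48, times48):
        ct = tofts_forward(aif48, times48, 0.0, 0.3, 0.07)
        np.testing.assert_allclose(ct, 0.07 * aif48.cp, atol=1e-15)

    def test_impulse_decays_with_kep(self):
        times = np.arange(20) * 1.0
        cp = np.zeros(20)
        cp[5] = 1.0  # single-frame bolus
        aif = Aif(times, cp)
        kt, ve = 0.6, 0.2
        kep = kt / ve / 60.0
        ct = tofts_forward(aif, times, kt, ve, 0.0)
        tail = ct[7:]
        ratios = tail[1:] / tail[:-1]
        np.testing.assert_allclose(ratios, np.exp(-kep), rtol=1e-9)

    def test_matches_dense_convolution_oracle(self, aif48, times48):
        for kt, ve, vp in [(0.1, 0.2, 0.02), (0.5, 0.4, 0.1), (2.0, 0.6, 0.01)]:
            ct = tofts_forward(aif48, times48, kt, ve, vp)
            oracle = dense_convolution_oracle(aif48, times48, kt, ve, vp)
            scale = np.abs(oracle).max()
            assert np.abs(ct - oracle).max() / scale < 1e-3

    def test_zero_ve_with_positive_ktrans_rejected(self, aif48, times48):
        with pytest.raises(ValueError, match="ve"):
            tofts_forward(aif48, times48, 0.5, 0.0, 0.05)

    def test_higher_ktrans_raises_early_uptake_iauc(self, aif48, times48):
        iaucs = []
        for kt in (0.05, 0.1, 0.2, 0.4, 0.8):
            ct = tofts_forward(aif48, times48, kt, 0.4, 0.0)
            conc = ConcentrationSeries(ct.reshape(1, 1, 1, -1), times48)
            iaucs.append(compute_iauc(conc, arrival=8, window=90.0).values.flat[0])
        assert all(a < b for a, b in zip(iaucs[:-1], iaucs[1:]))


class TestFitExtendedTofts:
    def test_noiseless_round_trip_within_1pct(self, aif48, times48):
        params = [(0.2, 0.3, 0.05), (0.05, 0.15, 0.01), (1.2, 0.6, 0.12)]
        curves = np.stack([tofts_forward(aif48, times48, *p) for p in params])
        conc = ConcentrationSeries(curves.reshape(len(params), 1, 1, -1), times48)
        maps = fit_extended_tofts(conc, aif48, np.ones((len(params), 1, 1), bool))
        for i, (kt, ve, vp) in enumerate(params):
            assert abs(maps.ktrans.values[i, 0, 0] - kt) / kt < 0.01
            assert abs(maps.ve.values[i, 0, 0] - ve) / ve < 0.01
            assert abs(maps.vp.values[i, 0, 0] - vp) / vp < 0.01
            assert maps.rss[i, 0, 0] < 1e-12

    def test_pure_vascular_voxel(self, aif48, times48):
        ct = 0.05 * aif48.cp
        conc = ConcentrationSeries(ct.reshape(1, 1, 1, -1), times48)
        maps = fit_extended_tofts(conc, aif48, np.ones((1, 1, 1), bool))
        assert maps.ktrans.values.flat[0] <= 1e-4
        assert abs(maps.vp.values.flat[0] - 0.05) < 1e-3

    def test_all_zero_curve_degenerate(self, aif48, times48):
        conc = ConcentrationSeries(np.zeros((1, 1, 1, 48)), times48)
        maps = fit_extended_tofts(conc, aif48, np.ones((1, 1, 1), bool))
        assert maps.ktrans.values.flat[0] == 0.0
        assert maps.vp.values.flat[0] == 0.0
        assert not maps.valid.any()

    def test_noisy_recovery_benchmark(self, aif48, times48):
        rng = np.random.default_rng(21)
        kt, ve, vp = 0.25, 0.35, 0.05
        clean = tofts_forward(aif48, times48, kt, ve, vp)
        n = 40
        sigma = 0.02 * np.abs(aif48.cp).max()
        curves = clean + rng.normal(0, sigma, (n, 48))
        conc = ConcentrationSeries(curves.reshape(n, 1, 1, -1), times48)
        maps = fit_extended_tofts(conc, aif48, np.ones((n, 1, 1), bool))
        rel = lambda est, tru: np.median(np.abs(est - tru) / tru)
        assert rel(maps.ktrans.values[:, 0, 0], kt) < 0.10
        assert rel(maps.ve.values[:, 0, 0], ve) < 0.10
        assert rel(maps.vp.values[:, 0, 0], vp) < 0.25
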