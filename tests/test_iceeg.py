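"""icEEG pipeline tests: detrending, line-noise regression, FIR
conformance, PLV properties and the SOZ-pair comparison."""

import numpy as np
import pytest
from scipy import signal

from seiznet.iceeg import (
    ContactSignal,
    compare_soz_pairs,
    compute_plc_table,
    fir_filters,
    local_detrend,
    plv,
    regress_line_noise,
)
from seiznet.synth import simulate_iceeg_cohort


class TestLocalDetrend:
    def test_constant_maps_to_zero(self):
        out = local_detrend(np.full(1000, 7.3), 1000.0, window=0.2)
        assert np.allclose(out, 0, atol=1e-12)

    def test_full_window_removes_mean_of_ramp(self):
        x = np.linspace(0, 1, 1000)
        out = local_detrend(x, 1000.0, window=1.0)
        assert abs(out.mean()) < 1e-3

    def test_inband_oscillation_preserved(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        x = 5 * t + np.sin(2 * np.pi * 80 * t)
        out = local_detrend(x, fs, window=1.0)
        amp = np.sqrt(2) * out[1000:3000].std()
        assert abs(amp - 1.0) < 0.05

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            local_detrend(np.zeros(100), 1000.0, window=0.0)


class TestLineRegression:
    def test_pure_60hz_removed_exactly(self):
        fs = 1000.0
        t = np.arange(5000) / fs
        x = 3.0 * np.sin(2 * np.pi * 60 * t + 0.7)
        out = regress_line_noise(x, fs)
        assert out.std() / x.std() < 1e-6

    def test_80hz_preserved(self):
        fs = 1000.0
        t = np.arange(5000) / fs
        x = np.sin(2 * np.pi * 80 * t)
        out = regress_line_noise(x, fs)
        assert abs(out.std() / x.std() - 1) < 0.01

    def test_zero_in_zero_out(self):
        assert np.allclose(regress_line_noise(np.zeros(1000), 1000.0), 0)

    def test_epoch_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            regress_line_noise(np.zeros(10), 1000.0, freqs=(60.0,))


class TestFIRFilters:
    def test_inband_80hz_within_1db(self):
        fs = 1000.0
        t = np.arange(10000) / fs
        y = fir_filters(np.sin(2 * np.pi * 80 * t), fs)
        amp = np.sqrt(2) * y[2000:].std()
        assert abs(20 * np.log10(amp)) < 1.0

    @pytest.mark.parametrize("freq", [50.0, 110.0])
    def test_stopband_attenuation(self, freq):
        fs = 1000.0
        t = np.arange(10000) / fs
        y = fir_filters(np.sin(2 * np.pi * freq * t), fs)
        amp = np.sqrt(2) * y[2000:].std()
        assert 20 * np.log10(amp + 1e-30) < -30

    def test_zero_in_zero_out(self):
        assert np.allclose(fir_filters(np.zeros(2000), 1000.0), 0)

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError, match="even"):
            fir_filters(np.zeros(2000), 1000.0, lp_order=181)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_filters(np.zeros(2000), 150.0)

    def test_realized_response_matches_design(self):
        """Time-domain gain equals freqz of the designed taps within
        0.1 dB at probe frequencies."""
        from seiznet.iceeg import _design_firs

        fs = 1000.0
        lp, bp = _design_firs(fs, 180, 150.0, 24.0, 390, (70.0, 90.0), 8.0)
        taps = np.convolve(lp, bp)
        probes = [40, 55, 65, 72, 75, 80, 85, 88, 95, 105]
        w, h = signal.freqz(taps, worN=2 * np.pi * np.array(probes) / fs)
        t = np.arange(int(10 * fs)) / fs
        for f, hf in zip(probes, h):
            if abs(hf) < 1e-3:
                continue
            y = fir_filters(np.sin(2 * np.pi * f * t), fs)
            amp = np.sqrt(2) * y[int(2 * fs):].std()
            assert abs(20 * np.log10(amp / np.abs(hf))) < 0.1


class TestPLV:
    def test_identical_signals_unity(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 80 * t)
        assert plv(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_lag_still_unity(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 80 * t)
        y = np.sin(2 * np.pi * 80 * t - np.pi / 2)
        assert plv(x, y) > 0.999

    def test_amplitude_scaling_invariance(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 80 * t)
        y = np.sin(2 * np.pi * 80 * t + 0.4) * (1 + 0.3 * np.sin(2 * np.pi * t))
        assert plv(x, y) == pytest.approx(plv(5 * x, 0.2 * y), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            plv(np.zeros(100), np.ones(100))

    def test_independent_bandlimited_noise_low(self):
        # 1e4 samples at 200 Hz = 50 s ≈ 4000 high-gamma cycles, so an
        # independent pair has expected PLV ~ sqrt(pi)/(2*sqrt(N)) << 0.05
        fs = 200.0
        taps = signal.firwin(391, [70, 90], pass_zero=False, fs=fs)
        rng = np.random.default_rng(0)
        low = 0
        for _ in range(20):
            x = signal.lfilter(taps, 1.0, rng.normal(size=10000))
            y = signal.lfilter(taps, 1.0, rng.normal(size=10000))
            low += plv(x, y) <= 0.05
        assert low >= 18


class TestCohortComparison:
    def test_sp_pairs_more_synchronized(self):
        signals = simulate_iceeg_cohort(
            n_patients=3, n_epochs=2, epoch_duration=6.0, seed=11
        )
        plc = compute_plc_table(signals)
        res, means = compare_soz_pairs(plc)
        assert (means["SOZ-SP"] > means["SOZ-control"]).all()
        assert res.t > 0
        assert res.df == 2

    def test_pair_row_count(self):
        signals = simulate_iceeg_cohort(
            n_patients=2, n_soz=1, n_sp=2, n_control=2,
            n_epochs=1, epoch_duration=4.0, seed=3,
        )
        plc = compute_plc_table(signals)
        assert len(plc) == 2 * (1 * 2 + 1 * 2)
        assert set(plc.pair_class) == {"SOZ-SP", "SOZ-control"}

    def test_single_patient_rejected(self):
        signals = simulate_iceeg_cohort(
            n_patients=1, n_epochs=1, epoch_duration=4.0, seed=5
        )
        with pytest.raises(ValueError, match="2 patients"):
            compare_soz_pairs(compute_plc_table(signals))

    def test_patient_missing_class_excluded_with_warning(self, caplog):
        import logging

        signals = simulate_iceeg_cohort(
            n_patients=3, n_epochs=1, epoch_duration=4.0, seed=6
        )
        signals = [
            s for s in signals
            if not (s.patient == "P2" and s.region_class == "control")
        ]
        plc = compute_plc_table(signals)
        with caplog.at_level(logging.WARNING, logger="seiznet.iceeg"):
            res, means = compare_soz_pairs(plc)
        assert "P2" not in means.index
        assert res.df == 1

    def test_region_class_validated(self):
        with pytest.raises(ValueError, match="region_class"):
            ContactSignal(np.zeros(10), 1000.0, "c1", "weird", "P0")
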