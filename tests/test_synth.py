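"""Generator tests: rate calibration, determinism, coupling effects,
voltage rendering and phase-coupled pairs.

The brute-force step-by-step simulator in this file is the independent
oracle for the event-driven kernel: both must draw from the same
conditionally-Bernoulli law.
"""

import numpy as np
import pytest

from seiznet._seeds import child_rng
from seiznet.connectivity import bin_spike_counts, pairwise_fc
from seiznet.spikes import SpikeTrainSet, detect_population_bursts, mean_firing_rate
from seiznet.synth import (
    SpikeTemplate,
    TreatmentDesign,
    WellConfig,
    default_spike_template,
    default_treatment_scenario,
    simulate_phase_coupled_pair,
    simulate_spike_trains,
    simulate_treatment_course,
    simulate_voltage,
)


def naive_simulate(n, n_steps, base_p, coupling, rng):
    """Brute-force reference: literal step-by-step conditional Bernoulli."""
    fired = np.zeros((n, n_steps), dtype=bool)
    prev = np.zeros(n, dtype=bool)
    for t in range(n_steps):
        p = base_p + coupling.T @ prev
        np.clip(p, 0, 1 - 1e-6, out=p)
        cur = rng.random(n) < p
        fired[:, t] = cur
        prev = cur
    return fired


class TestSpikeTrains:
    def test_zero_rate_process_is_empty(self):
        cfg = WellConfig(n_electrodes=4, duration=10, base_rate=0.0, burst_rate=0.0)
        st = simulate_spike_trains(cfg)
        assert all(t.size == 0 for t in st.trains)

    def test_seed_determinism(self, small_well):
        a = simulate_spike_trains(small_well)
        b = simulate_spike_trains(small_well)
        assert all(np.array_equal(x, y) for x, y in zip(a.trains, b.trains))
        c = simulate_spike_trains(
            WellConfig(n_electrodes=8, duration=60.0, base_rate=2.0, seed=8)
        )
        assert any(not np.array_equal(x, y) for x, y in zip(a.trains, c.trains))

    def test_counts_in_poisson_band(self):
        # 2 Hz, 300 s: mean 600, Bernoulli variance ≈ Poisson, 4-sigma band
        cfg = WellConfig(duration=300.0, base_rate=2.0, burst_rate=0.0, seed=3)
        counts = simulate_spike_trains(cfg).counts()
        in_band = np.sum((counts >= 600 - 98) & (counts <= 600 + 98))
        assert in_band >= 62

    def test_rate_linearity(self):
        c1 = simulate_spike_trains(
            WellConfig(n_electrodes=16, duration=120, base_rate=1.0,
                       burst_rate=0, seed=5)
        ).counts().sum()
        c2 = simulate_spike_trains(
            WellConfig(n_electrodes=16, duration=120, base_rate=2.0,
                       burst_rate=0, seed=6)
        ).counts().sum()
        # doubling the rate doubles total count within sampling error
        assert abs(c2 / c1 - 2.0) < 0.15

    def test_times_sorted_within_duration(self, small_well):
        st = simulate_spike_trains(small_well)
        for t in st.trains:
            assert np.all(np.diff(t) > 0)
            if t.size:
                assert 0 <= t[0] and t[-1] < small_well.duration

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="square"):
            WellConfig(n_electrodes=4, coupling=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="diagonal"):
            WellConfig(n_electrodes=2, coupling=np.eye(2))
        with pytest.raises(ValueError, match="burst_gain"):
            WellConfig(burst_gain=0.5)

    def test_kernel_matches_bruteforce_law(self):
        """Event-driven kernel vs literal simulation: same rates and
        same coupled-pair correlation (distributional oracle)."""
        n, dur = 4, 40.0
        w = np.zeros((n, n))
        w[0, 1] = 0.4
        base_p = np.full(n, 5.0 * 0.001)
        rng = np.random.default_rng(0)
        n_steps = int(dur * 1000)
        ref_counts, ref_r = [], []
        for _ in range(10):
            fired = naive_simulate(n, n_steps, base_p, w, rng)
            ref_counts.append(fired.sum(axis=1))
            bins = fired.reshape(n, -1, 50).sum(axis=2)
            ref_r.append(np.corrcoef(bins)[0, 1])
        kern_counts, kern_r = [], []
        for s in range(10):
            st = simulate_spike_trains(
                WellConfig(n_electrodes=n, duration=dur, base_rate=5.0,
                           coupling=w, burst_rate=0, seed=s)
            )
            kern_counts.append(st.counts())
            b = bin_spike_counts(st)
            kern_r.append(np.corrcoef(b.counts)[0, 1])
        ref_mean = np.mean(ref_counts, axis=0)
        kern_mean = np.mean(kern_counts, axis=0)
        # electrode 1 is driven: both should show the same rate lift
        assert np.allclose(kern_mean, ref_mean, rtol=0.15)
        assert abs(np.mean(kern_r) - np.mean(ref_r)) < 0.1
        assert np.mean(kern_r) > 0.1  # coupling induces binned correlation

    def test_coupled_pair_fc_exceeds_uncoupled_quantile(self):
        hits = 0
        for s in range(20):
            w = np.zeros((8, 8))
            w[1, 2] = 0.3
            cfg = WellConfig(n_electrodes=8, duration=120, base_rate=2.0,
                             coupling=w, burst_rate=0, seed=s)
            fc = pairwise_fc(bin_spike_counts(simulate_spike_trains(cfg)))
            iu = list(zip(*np.triu_indices(8, 1)))
            null = np.array([fc.z[i, j] for i, j in iu if (i, j) != (1, 2)])
            hits += fc.z[1, 2] > np.quantile(null, 0.95)
        assert hits >= 18


class TestTreatmentCourse:
    def test_labels_and_day_count(self):
        well = WellConfig(n_electrodes=4, duration=5, base_rate=2.0, seed=0)
        design = TreatmentDesign(n_treated_wells=2, n_control_wells=2)
        recs = simulate_treatment_course(well, design, seed=1)
        assert len(recs) == 4 * 3
        assert {r.group for r in recs} == {"treated", "control"}
        assert {r.day for r in recs} == {0, 1, 2}

    def test_rejects_short_design(self):
        with pytest.raises(ValueError):
            TreatmentDesign(n_days=1, rate_multipliers=(1.0,))

    def test_day0_multiplier_must_be_one(self):
        with pytest.raises(ValueError):
            TreatmentDesign(rate_multipliers=(2.0, 1.9, 2.5))

    def test_null_design_groups_indistinguishable(self):
        from seiznet.stats import two_sample_t

        well = WellConfig(n_electrodes=8, duration=30, base_rate=2.0,
                          burst_rate=0, seed=0)
        design = TreatmentDesign(
            rate_multipliers=(1.0, 1.0, 1.0), coupling_boost=1.0,
            n_treated_wells=3, n_control_wells=3,
        )
        rejections = 0
        for rep in range(20):
            recs = simulate_treatment_course(well, design, seed=100 + rep)
            tr = [mean_firing_rate(r.trains).well_mean_hz
                  for r in recs if r.group == "treated" and r.day == 2]
            co = [mean_firing_rate(r.trains).well_mean_hz
                  for r in recs if r.group == "control" and r.day == 2]
            if two_sample_t(np.array(tr), np.array(co)).p < 0.05:
                rejections += 1
        assert rejections <= 3  # ~binomial(20, 0.05)

    def test_rate_multiplier_reflected_in_mfr_ratio(self):
        well = WellConfig(n_electrodes=16, duration=60, base_rate=2.0,
                          burst_rate=0, seed=0)
        design = TreatmentDesign(n_treated_wells=5, n_control_wells=0)
        ratios = []
        for rep in range(4):
            recs = simulate_treatment_course(well, design, seed=rep)
            by_day = {}
            for r in recs:
                by_day.setdefault(r.day, []).append(
                    mean_firing_rate(r.trains).well_mean_hz
                )
            ratios.append(np.mean(by_day[2]) / np.mean(by_day[0]))
        assert abs(np.mean(ratios) - 2.5) < 0.15

    def test_boosted_pairs_rank_top_decile_of_day2_fc(self):
        hits = 0
        for s in range(10):
            well, design, truth = default_treatment_scenario(
                n_electrodes=16, duration=60, seed=s, n_strong_pairs=4,
            )
            design = TreatmentDesign(
                n_treated_wells=1, n_control_wells=0,
                boosted_edges=design.boosted_edges,
            )
            recs = simulate_treatment_course(well, design, seed=s)
            day2 = [r for r in recs if r.day == 2][0]
            fc = pairwise_fc(bin_spike_counts(day2.trains))
            iu = np.triu_indices(16, 1)
            thr = np.quantile(fc.z[iu], 0.9)
            frac = np.mean([fc.z[a, b] >= thr for a, b in truth["strong_pairs"]])
            hits += frac == 1.0
        assert hits >= 8


class TestVoltage:
    def test_pure_noise_sd(self):
        empty = SpikeTrainSet(trains=[np.array([])] * 2, duration=1.0)
        rec = simulate_voltage(empty, SpikeTemplate(noise_sd=3.0), seed=1)
        assert np.allclose(rec.data.std(axis=1), 3.0, rtol=0.05)

    def test_deterministic_injection_position(self):
        trains = SpikeTrainSet(trains=[np.array([1.0])], duration=2.0)
        tmpl = SpikeTemplate(waveform=default_spike_template(), noise_sd=1e-9)
        rec = simulate_voltage(trains, tmpl, seed=0)
        s0 = int(round(1.0 * rec.fs))
        w = tmpl.waveform
        assert np.allclose(rec.data[0, s0:s0 + len(w)], w, atol=1e-6)

    def test_line_component_peaks_at_60hz(self):
        empty = SpikeTrainSet(trains=[np.array([])], duration=2.0)
        rec = simulate_voltage(
            empty, SpikeTemplate(noise_sd=1.0, line_amp=50.0), seed=2
        )
        spec = np.abs(np.fft.rfft(rec.data[0]))
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        assert abs(freqs[np.argmax(spec)] - 60.0) < 0.5


class TestPhaseCoupledPair:
    def test_infinite_kappa_identical_phase(self):
        x, y = simulate_phase_coupled_pair(2000, 1000.0, (70, 90), np.inf, seed=0)
        assert np.array_equal(x, y)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            simulate_phase_coupled_pair(1000, 1000.0, (70, 90), -1.0, seed=0)

    def test_band_must_fit_nyquist(self):
        with pytest.raises(ValueError):
            simulate_phase_coupled_pair(1000, 100.0, (70, 90), 1.0, seed=0)

    def test_kappa_zero_phase_is_dispersed(self):
        from seiznet.iceeg import plv

        vals = [
            plv(*simulate_phase_coupled_pair(10000, 1000.0, (70, 90), 0.0, seed=s))
            for s in range(10)
        ]
        # uniform offset: PLV follows Rayleigh statistics, far below lock
        assert np.mean(vals) < 0.15


class TestBurstGroundTruth:
    def test_latent_intervals_cover_detected_bursts(self):
        cfg = WellConfig(n_electrodes=32, duration=120, base_rate=2.0,
                         burst_rate=6.0, burst_gain=8.0, seed=4)
        st = simulate_spike_trains(cfg)
        truth = st.meta["true_burst_intervals"]
        assert truth.shape[1] == 2 and truth.shape[0] >= 1
        binned = bin_spike_counts(st)
        mask = detect_population_bursts(binned)
        # every detected interval overlaps a true latent ON interval
        for s, e in mask.intervals:
            assert any((s < te) and (e > ts) for ts, te in truth)
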