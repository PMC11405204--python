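"""Synthetic MEA wells, treatment courses, voltage traces and
phase-coupled signal pairs with known ground truth.

The spike-train generator is a discretized conditionally-Bernoulli
process at 1-ms steps (see :mod:`seiznet._kernels`): a baseline rate,
directed pairwise excitation one step back, and a well-global two-state
Markov burst process that multiplies the baseline rate while ON. This
is deliberately not a biophysical model — it is the simplest process
that produces Poisson-like baseline firing, graded pairwise
correlation, and population bursts, which is what the downstream
connectivity analysis consumes.

The treatment course emulates a chemoconvulsant protocol: three daily
recordings per well, with treated wells receiving a per-day firing-rate
multiplier and a boost of a designated subset of couplings on treated
days, while control wells redraw from unchanged parameters each day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from ._kernels import simulate_well_kernel
from ._seeds import child_rng, child_seed
from .preprocess import VoltageRecording
from .spikes import SpikeTrainSet

logger = logging.getLogger(__name__)

__all__ = [
    "WellConfig",
    "TreatmentDesign",
    "SpikeTemplate",
    "WellDayRecording",
    "random_coupling",
    "simulate_spike_trains",
    "simulate_treatment_course",
    "simulate_voltage",
    "simulate_phase_coupled_pair",
    "simulate_iceeg_cohort",
    "expected_plv",
    "default_spike_template",
    "default_treatment_scenario",
]

DT = 0.001  # simulation step, seconds


@dataclass
class WellConfig:
    """Parameters of one synthetic MEA well.

    Defaults mirror the recording setup the pipeline targets: 64
    electrodes on an 8×8 grid and 5-minute (300 s) recordings. The
    baseline rate, burst statistics and coupling strengths are free
    parameters of the generator.
    """

    n_electrodes: int = 64
    duration: float = 300.0
    base_rate: float = 2.0  # Hz per electrode
    coupling: np.ndarray | None = None  # (n, n), [j, i] = excitation j -> i
    burst_rate: float = 4.0  # bursts per minute (ON-state entry rate)
    burst_duration: float = 0.5  # mean ON duration, seconds
    burst_gain: float = 5.0  # rate multiplier while bursting
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("need at least one electrode")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.base_rate < 0 or self.burst_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.burst_gain < 1:
            raise ValueError("burst_gain must be >= 1")
        if self.coupling is None:
            self.coupling = np.zeros((self.n_electrodes, self.n_electrodes))
        self.coupling = np.asarray(self.coupling, dtype=float)
        n = self.n_electrodes
        if self.coupling.shape != (n, n):
            raise ValueError(
                f"coupling must be square ({n}×{n}), got {self.coupling.shape}"
            )
        if np.any(self.coupling < 0):
            raise ValueError("coupling weights must be non-negative")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")


@dataclass
class TreatmentDesign:
    """Daily treatment schedule for a multi-well experiment.

    ``rate_multipliers`` scale the treated wells' baseline rate per day
    (Day 0 is the pre-treatment baseline and must be 1);
    ``coupling_boost`` multiplies a designated edge subset on treated
    days (Days ≥ 1). Defaults follow treated/baseline firing-rate
    ratios of ≈1.9 after one treatment day and ≈2.5 after two, which
    are plausible magnitudes for a chemoconvulsant hyperexcitability
    protocol — they are generator settings, not claims.
    """

    n_days: int = 3
    rate_multipliers: tuple = (1.0, 1.9, 2.5)
    coupling_boost: float = 3.0
    n_treated_wells: int = 9
    n_control_wells: int = 9
    boosted_edges: np.ndarray | None = None  # (m, 2) directed edges; None = all

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("a treatment course needs at least 2 days")
        if len(self.rate_multipliers) != self.n_days:
            raise ValueError("need one rate multiplier per day")
        if self.rate_multipliers[0] != 1.0:
            raise ValueError("Day 0 is the pre-treatment baseline; multiplier must be 1")
        if self.coupling_boost < 0:
            raise ValueError("coupling_boost must be non-negative")
        if self.boosted_edges is not None:
            self.boosted_edges = np.asarray(self.boosted_edges, dtype=int).reshape(-1, 2)


@dataclass
class SpikeTemplate:
    """Extracellular spike waveform plus additive-noise parameters."""

    waveform: np.ndarray = None  # µV, sampled at `fs` of simulate_voltage
    noise_sd: float = 3.0  # µV
    line_amp: float = 0.0  # µV, 60 Hz component
    line_freq: float = 60.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.waveform is None:
            self.waveform = default_spike_template()
        self.waveform = np.asarray(self.waveform, dtype=float)


def default_spike_template(
    fs: float = 12500.0, amplitude: float = 25.0
) -> np.ndarray:
    """Biphasic extracellular waveform, ≈2.2 ms, peak ``amplitude`` µV.

    A fast negative lobe (0.8 ms) followed by a slower, much smaller
    positive lobe (1.4 ms, 25% amplitude). The lobes are wide enough
    that a substantial part of the energy lies below 300 Hz and
    survives the MUA band-pass, and the amplitude asymmetry keeps the
    band-passed waveform single-peaked for threshold detection.
    """
    n_neg = int(round(0.0008 * fs))
    n_pos = int(round(0.0014 * fs))
    w = np.concatenate(
        [
            -np.sin(np.pi * np.arange(n_neg) / n_neg),
            0.25 * np.sin(np.pi * np.arange(n_pos) / n_pos),
        ]
    )
    return amplitude * w


def random_coupling(
    n: int,
    fraction: float,
    weight: float,
    rng: np.random.Generator,
    symmetric: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Couple a random ``fraction`` of unordered pairs at ``weight``.

    Returns ``(coupling, true_pairs)`` where ``true_pairs`` is an
    (m, 2) array of the coupled unordered pairs (i < j). By default one
    random direction per pair receives the weight; ``symmetric`` gives
    both. Note the network branching ratio — mean outgoing weight per
    electrode — must stay below 1 or excitation becomes supercritical
    and firing saturates; symmetric coupling doubles it.
    """
    iu = np.column_stack(np.triu_indices(n, k=1))
    m = int(round(fraction * len(iu)))
    pick = rng.choice(len(iu), size=m, replace=False)
    pairs = iu[np.sort(pick)]
    w = np.zeros((n, n))
    for a, b in pairs:
        if symmetric:
            w[a, b] = w[b, a] = weight
        elif rng.random() < 0.5:
            w[a, b] = weight
        else:
            w[b, a] = weight
    return w, pairs


def simulate_spike_trains(config: WellConfig) -> SpikeTrainSet:
    """Draw one recording from the conditionally-Bernoulli well model.

    Per 1-ms step, electrode ``i`` fires with probability
    ``base_rate·dt·gain(t) + Σ_j coupling[j, i]·fired[j, t−1]``, clipped
    to 1 − 1e-6 (clips are logged). The burst gain applies while a
    well-global two-state Markov process is ON; its entry rate is
    ``burst_rate`` per minute and its mean ON duration
    ``burst_duration`` seconds. Identical config (incl. seed) gives
    bit-identical spike times.
    """
    n_steps = int(round(config.duration / DT))
    base_p = np.full(config.n_electrodes, config.base_rate * DT)
    p_on = (config.burst_rate / 60.0) * DT
    p_off = DT / config.burst_duration if config.burst_duration > 0 else 1.0
    fired, burst, n_clipped = simulate_well_kernel(
        config.seed,
        n_steps,
        base_p,
        np.ascontiguousarray(config.coupling),
        p_on,
        p_off,
        config.burst_gain,
    )
    if n_clipped:
        logger.warning(
            "simulate_spike_trains: %d firing probabilities clipped at %g",
            int(n_clipped),
            1.0 - 1e-6,
        )
    trains = [
        (np.flatnonzero(fired[i]) + 0.5) * DT for i in range(config.n_electrodes)
    ]
    # true burst intervals from the latent state sequence
    b = burst.astype(np.int8)
    onsets = np.flatnonzero(np.diff(np.concatenate([[0], b])) == 1)
    offsets = np.flatnonzero(np.diff(np.concatenate([b, [0]])) == -1) + 1
    intervals = np.column_stack([onsets, offsets]) * DT
    return SpikeTrainSet(
        trains=trains,
        duration=config.duration,
        provenance="simulated",
        meta={
            "true_burst_intervals": intervals,
            "n_clipped": int(n_clipped),
            "config_seed": config.seed,
        },
    )


@dataclass
class WellDayRecording:
    """One well-day draw of a treatment course."""

    well_id: int
    group: str  # "treated" | "control"
    day: int
    trains: SpikeTrainSet
    config: WellConfig = field(repr=False, default=None)


def simulate_treatment_course(
    well: WellConfig,
    design: TreatmentDesign,
    seed: int | None = None,
) -> list[WellDayRecording]:
    """Simulate every well × day of a treatment experiment.

    Control wells redraw from the unchanged base configuration each day
    (fresh seeds). Treated wells scale ``base_rate`` by the day's
    multiplier and multiply the boosted edge subset (all nonzero
    couplings unless ``design.boosted_edges`` narrows it) by
    ``coupling_boost`` on Days ≥ 1. Child seeds derive from
    ``(seed, well index, day)`` so adding wells never perturbs existing
    draws.
    """
    root = well.seed if seed is None else seed
    boost_mask = np.zeros_like(well.coupling, dtype=bool)
    if design.boosted_edges is None:
        boost_mask[well.coupling > 0] = True
    else:
        for a, b in design.boosted_edges:
            boost_mask[a, b] = True
    out = []
    n_total = design.n_treated_wells + design.n_control_wells
    for w in range(n_total):
        treated = w < design.n_treated_wells
        for day in range(design.n_days):
            cfg_seed = child_seed(root, w, day)
            rate = well.base_rate
            coupling = well.coupling.copy()
            if treated and day >= 1:
                rate = well.base_rate * design.rate_multipliers[day]
                coupling[boost_mask] *= design.coupling_boost
            cfg = WellConfig(
                n_electrodes=well.n_electrodes,
                duration=well.duration,
                base_rate=rate,
                coupling=coupling,
                burst_rate=well.burst_rate,
                burst_duration=well.burst_duration,
                burst_gain=well.burst_gain,
                seed=cfg_seed,
            )
            out.append(
                WellDayRecording(
                    well_id=w,
                    group="treated" if treated else "control",
                    day=day,
                    trains=simulate_spike_trains(cfg),
                    config=cfg,
                )
            )
    return out


def simulate_voltage(
    trains: SpikeTrainSet,
    tmpl: SpikeTemplate | None = None,
    fs: float = 12500.0,
    seed: int = 0,
) -> VoltageRecording:
    """Render spike trains into a noisy extracellular voltage trace.

    Gaussian noise of SD ``tmpl.noise_sd`` plus the template waveform
    inserted at each spike time (start sample = round(t·fs)) plus an
    optional mains sinusoid of amplitude ``tmpl.line_amp``.
    """
    tmpl = tmpl or SpikeTemplate()
    wlen = len(tmpl.waveform)
    # sampling must resolve the template: at least 4 samples across it
    if wlen < 4:
        raise ValueError("fs too low for the template bandwidth (waveform < 4 samples)")
    n_samples = int(round(trains.duration * fs))
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, tmpl.noise_sd, size=(trains.n_electrodes, n_samples))
    if tmpl.line_amp:
        t = np.arange(n_samples) / fs
        data += tmpl.line_amp * np.sin(2 * np.pi * tmpl.line_freq * t)
    for ch, times in enumerate(trains.trains):
        for s in np.round(times * fs).astype(int):
            end = min(s + wlen, n_samples)
            if s < n_samples:
                data[ch, s:end] += tmpl.waveform[: end - s]
    return VoltageRecording(data=data, fs=fs, stage="raw")


def expected_plv(kappa: float) -> float:
    """Population phase-locking value of a von Mises(0, κ) phase offset:
    I₁(κ)/I₀(κ)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def _vonmises_ppf_interp(u: np.ndarray, kappa: float) -> np.ndarray:
    """Fast von Mises(0, κ) quantile via a tabulated CDF."""
    grid = np.linspace(-np.pi, np.pi, 4097)
    cdf = stats.vonmises.cdf(grid, kappa)
    return np.interp(u, cdf, grid)


def simulate_phase_coupled_pair(
    n_samples: int,
    fs: float,
    band: tuple[float, float] = (70.0, 90.0),
    kappa: float = 2.0,
    seed: int = 0,
    decorr_cycles: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two narrowband signals with a von Mises(0, κ) phase offset.

    The first signal is a carrier at the band center; the second
    carries a slowly varying phase offset δ(t) whose stationary
    marginal is exactly von Mises(0, κ). δ(t) is built by mapping a
    unit-variance AR(1) Gaussian (correlation time ``decorr_cycles``
    carrier cycles) through the Gaussian CDF and the von Mises
    quantile, so the marginal is exact while δ stays smooth relative to
    the carrier — the construction the Hilbert phase can track. The
    population PLV is I₁(κ)/I₀(κ); with κ = 0 the offset is uniform and
    the empirical PLV follows Rayleigh statistics in the number of
    effective cycles.

    ``kappa=np.inf`` returns an identical-phase pair (PLV = 1).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("band must lie within (0, fs/2)")
    fc = 0.5 * (f_lo + f_hi)
    t = np.arange(n_samples) / fs
    phase1 = 2 * np.pi * fc * t
    x = np.cos(phase1)
    if np.isinf(kappa):
        return x, x.copy()
    rng = np.random.default_rng(seed)
    tau = decorr_cycles / fc
    a = np.exp(-1.0 / (fs * tau))
    eps = rng.normal(size=n_samples)
    g = np.empty(n_samples)
    g[0] = eps[0]
    s = np.sqrt(1 - a * a)
    for k in range(1, n_samples):
        g[k] = a * g[k - 1] + s * eps[k]
    u = special.ndtr(g)
    if kappa == 0:
        delta = 2 * np.pi * (u - 0.5)
    else:
        delta = _vonmises_ppf_interp(u, kappa)
    y = np.cos(phase1 + delta)
    return x, y


def simulate_iceeg_cohort(
    n_patients: int = 3,
    n_soz: int = 1,
    n_sp: int = 2,
    n_control: int = 2,
    n_epochs: int = 3,
    epoch_duration: float = 10.0,
    fs: float = 1000.0,
    band: tuple[float, float] = (70.0, 90.0),
    kappa_sp: float = 2.0,
    kappa_control: float = 0.5,
    noise_sd: float = 0.05,
    line_amp: float = 1.0,
    drift_amp: float = 2.0,
    seed: int = 0,
) -> list:
    """Synthetic icEEG cohort with class-dependent phase coupling.

    Each patient contributes SOZ, seizure-spread (SP) and control
    contacts over several interictal epochs. SP contacts phase-couple
    to the SOZ carrier with concentration ``kappa_sp``, control
    contacts with the weaker ``kappa_control``, so SOZ-SP pairs are the
    more synchronized class by construction. Wideband noise, a 60 Hz
    mains component and a slow drift are added so the preprocessing
    chain has realistic work to do.
    """
    from .iceeg import ContactSignal

    n_samples = int(round(epoch_duration * fs))
    t = np.arange(n_samples) / fs
    out = []
    for p in range(n_patients):
        for ep in range(n_epochs):
            rng = child_rng(seed, p, ep)

            def _dress(sig, r):
                return (
                    sig
                    + noise_sd * r.normal(size=n_samples)
                    + line_amp * np.sin(2 * np.pi * 60.0 * t + r.uniform(0, 2 * np.pi))
                    + drift_amp * np.sin(2 * np.pi * 0.3 * t + r.uniform(0, 2 * np.pi))
                )

            carrier = None
            for s in range(n_soz):
                x, _ = simulate_phase_coupled_pair(
                    n_samples, fs, band, kappa=np.inf,
                    seed=child_seed(seed, p, ep, 0, s),
                )
                carrier = x
                out.append(
                    ContactSignal(
                        data=_dress(x, child_rng(seed, p, ep, 10, s)),
                        fs=fs, contact=f"SOZ{s}", region_class="SOZ",
                        patient=f"P{p}", epoch=ep,
                    )
                )
            for s in range(n_sp):
                _, y = simulate_phase_coupled_pair(
                    n_samples, fs, band, kappa=kappa_sp,
                    seed=child_seed(seed, p, ep, 1, s),
                )
                out.append(
                    ContactSignal(
                        data=_dress(y, child_rng(seed, p, ep, 11, s)),
                        fs=fs, contact=f"SP{s}", region_class="SP",
                        patient=f"P{p}", epoch=ep,
                    )
                )
            for s in range(n_control):
                _, y = simulate_phase_coupled_pair(
                    n_samples, fs, band, kappa=kappa_control,
                    seed=child_seed(seed, p, ep, 2, s),
                )
                out.append(
                    ContactSignal(
                        data=_dress(y, child_rng(seed, p, ep, 12, s)),
                        fs=fs, contact=f"CTRL{s}", region_class="control",
                        patient=f"P{p}", epoch=ep,
                    )
                )
            del carrier
    return out


def default_treatment_scenario(
    n_electrodes: int = 64,
    duration: float = 300.0,
    base_rate: float = 2.0,
    seed: int = 0,
    background_fraction: float = 0.05,
    background_weight: float = 0.1,
    n_strong_pairs: int = 15,
    strong_weight: float = 0.2,
) -> tuple[WellConfig, TreatmentDesign, dict]:
    """Study-condition scenario: weak directed background coupling plus a
    small reciprocal subset that the treatment preferentially strengthens.

    Background excitation (one random direction on
    ``background_fraction`` of pairs at ``background_weight``) gives the
    well graded, sub-threshold connectivity. A further ``n_strong_pairs``
    reciprocal pairs at ``strong_weight`` form the designated
    strengthenable subset: on treated days the design multiplies exactly
    these edges by ``coupling_boost``, driving reverberant pairwise
    firing and a separated (bimodal) tail of strong functional
    connections, while the network stays subcritical (total outgoing
    weight per electrode < 1).

    Returns ``(well, design, truth)`` where ``truth`` holds the
    background and boosted pair lists.
    """
    rng = child_rng(seed, 0xA11)
    coupling, bg_pairs = random_coupling(
        n_electrodes, background_fraction, background_weight, rng, symmetric=False
    )
    iu = np.column_stack(np.triu_indices(n_electrodes, k=1))
    free = np.array(
        [k for k, (a, b) in enumerate(iu)
         if coupling[a, b] == 0 and coupling[b, a] == 0]
    )
    pick = rng.choice(free.size, size=n_strong_pairs, replace=False)
    strong_pairs = iu[free[np.sort(pick)]]
    boosted_edges = []
    for a, b in strong_pairs:
        coupling[a, b] = coupling[b, a] = strong_weight
        boosted_edges.append((a, b))
        boosted_edges.append((b, a))
    well = WellConfig(
        n_electrodes=n_electrodes,
        duration=duration,
        base_rate=base_rate,
        coupling=coupling,
        seed=seed,
    )
    design = TreatmentDesign(boosted_edges=np.array(boosted_edges))
    truth = {"background_pairs": bg_pairs, "strong_pairs": strong_pairs}
    return well, design, truth
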