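"""Conditioning of raw multielectrode-array voltage traces.

The conditioning chain mirrors standard multi-unit-activity (MUA)
preprocessing for extracellular recordings sampled at 12.5 kHz:

1. :func:`downsample` — anti-aliased integer decimation to 2.5 kHz,
2. :func:`bandpass_mua` — order-20 Butterworth band-pass, 0.1–300 Hz,
3. :func:`notch_line` — order-4 Butterworth band-stop cascade at 60 Hz
   and its first two harmonics (±1 Hz stop edges),
4. :func:`zscore` — per-channel standardization (population SD).

All IIR stages are realized as second-order sections; a direct-form
order-20 band-pass is numerically explosive and is never constructed.
Filtering is causal by default; every stage accepts ``zero_phase=True``
for forward-backward filtering when phase distortion matters more than
causality (e.g. spike-timing studies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "VoltageRecording",
    "downsample",
    "bandpass_mua",
    "notch_line",
    "zscore",
    "preprocess_chain",
]


@dataclass
class VoltageRecording:
    """Multichannel extracellular voltage trace.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in µV (or z-units once standardized).
    fs : float
        Sampling rate in Hz.
    electrode_ids : ndarray of int
        One id per channel.
    grid_positions : ndarray, shape (n_channels, 2)
        (row, col) of each electrode on the array. Must be unique.
    stage : str
        Provenance tag: ``raw``, ``filtered`` or ``zscored``.
    """

    data: np.ndarray
    fs: float
    electrode_ids: np.ndarray = field(default=None)
    grid_positions: np.ndarray = field(default=None)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.data.shape[0]
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(n_ch)
        self.electrode_ids = np.asarray(self.electrode_ids)
        if len(self.electrode_ids) != n_ch:
            raise ValueError("electrode_ids length must match channel count")
        if self.grid_positions is None:
            # default: square-ish row-major grid
            side = int(np.ceil(np.sqrt(n_ch)))
            self.grid_positions = np.array(
                [(i // side, i % side) for i in range(n_ch)]
            )
        self.grid_positions = np.asarray(self.grid_positions)
        pos = [tuple(p) for p in self.grid_positions]
        if len(set(pos)) != n_ch:
            raise ValueError("grid positions must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _apply_sos(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        # even padding: odd (default) reflection can excite multi-second
        # ringing at a very low high-pass corner (0.1 Hz)
        y = signal.sosfiltfilt(sos, x, axis=-1, padtype="even")
    else:
        y = signal.sosfilt(sos, x, axis=-1)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(
            "filter produced non-finite output; unstable realization"
        )
    return y


def downsample(
    rec: VoltageRecording,
    target_fs: float = 2500.0,
    *,
    zero_phase: bool = False,
) -> VoltageRecording:
    """Anti-aliased decimation to ``target_fs`` by an integer factor.

    An 8th-order Butterworth low-pass at 0.4·target_fs precedes the
    decimation so the 60 Hz line-harmonics region cannot alias.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs {rec.fs} is not an integer multiple of target {target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return replace(rec, data=rec.data.copy())
    sos = signal.butter(8, 0.4 * target_fs, btype="low", fs=rec.fs, output="sos")
    y = _apply_sos(rec.data, sos, zero_phase)
    return replace(rec, data=y[:, ::factor], fs=target_fs, stage="filtered")


def bandpass_mua(
    rec: VoltageRecording,
    low: float = 0.1,
    high: float = 300.0,
    order: int = 20,
    *,
    zero_phase: bool = False,
) -> VoltageRecording:
    """Butterworth band-pass isolating multi-unit activity.

    ``order`` is the overall band-pass order (an order-20 band-pass is
    built from an order-10 low/high prototype), realized as cascaded
    second-order sections.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ValueError("require 0 < low < high < Nyquist")
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = signal.butter(
        order // 2, [low, high], btype="bandpass", fs=rec.fs, output="sos"
    )
    y = _apply_sos(rec.data, sos, zero_phase)
    return replace(rec, data=y, stage="filtered")


def notch_line(
    rec: VoltageRecording,
    freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
    order: int = 4,
    half_bw: float = 1.0,
    *,
    zero_phase: bool = False,
) -> VoltageRecording:
    """Cascade of Butterworth band-stop filters removing mains noise.

    Each notch has stop edges ``[f - half_bw, f + half_bw]``; defaults
    target 60 Hz and its first two harmonics.
    """
    y = rec.data
    for f in freqs:
        if f >= rec.fs / 2:
            raise ValueError(f"notch frequency {f} Hz at or above Nyquist")
        sos = signal.butter(
            order // 2,
            [f - half_bw, f + half_bw],
            btype="bandstop",
            fs=rec.fs,
            output="sos",
        )
        y = _apply_sos(y, sos, zero_phase)
    return replace(rec, data=y, stage="filtered")


def zscore(rec: VoltageRecording) -> VoltageRecording:
    """Per-channel standardization to mean 0, SD 1 (population SD).

    Constant channels cannot be scaled; they map to all-zeros and a
    warning is logged.
    """
    if rec.n_samples < 2:
        raise ValueError("need more than one sample per channel")
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)  # population SD (ddof=0)
    flat = sd[:, 0] == 0
    if np.any(flat):
        logger.warning(
            "zscore: %d constant channel(s) mapped to zeros: %s",
            int(flat.sum()),
            rec.electrode_ids[flat].tolist(),
        )
        sd[flat] = 1.0
    y = (rec.data - mu) / sd
    y[flat] = 0.0
    return replace(rec, data=y, stage="zscored")


def preprocess_chain(
    rec: VoltageRecording,
    target_fs: float = 2500.0,
    band: tuple[float, float] = (0.1, 300.0),
    bp_order: int = 20,
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0),
    *,
    zero_phase: bool = False,
    standardize: bool = True,
) -> VoltageRecording:
    """Full conditioning chain: downsample → band-pass → notch → z-score."""
    out = downsample(rec, target_fs, zero_phase=zero_phase)
    out = bandpass_mua(out, band[0], band[1], bp_order, zero_phase=zero_phase)
    out = notch_line(out, notch_freqs, zero_phase=zero_phase)
    if standardize:
        out = zscore(out)
    return out
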